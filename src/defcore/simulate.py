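"""Synthetic pangenome and phage-contig generation with planted truth.

The generator emits inputs in the exact dialects the readers consume and
returns a ground-truth record sufficient to score every pipeline output.
The mutation model is deliberately minimal -- uniform substitutions, no
indels -- so identity levels are analytically controlled: orthologs
mutated at rate d from a shared ancestor differ pairwise at <= 2*d*L
positions, and the generator asserts post hoc that all planted ortholog
pairs clear the identity threshold while all decoy pairs fall below it.

Determinism: all randomness flows from one ``random.Random(rng_seed)``
(Mersenne Twister), which is reproducible across platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .io import Dataset, write_dataset
from .models import GeneRecord, GenomeManifest, MGEAnnotation, SystemInstance
from .votu import ANIRecord, build_ani_table, write_ani_table

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

GENE_LEN_BP = 300
GENE_SPACING_BP = 400  # start-to-start distance
_SLOT_GAP = 14  # ranks between planted groups; > island gap limit + 1


@dataclass(frozen=True)
class PlantedBlock:
    family: str
    presence_frac: float
    n_components: int
    in_island: bool = False
    mge_class: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.presence_frac <= 1:
            raise ValueError("presence_frac must be in (0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


DEFAULT_PLANTED_BLOCKS = (
    PlantedBlock("Gabija", 1.0, 2, in_island=True),
    PlantedBlock("Septu", 1.0, 2, in_island=True),
    PlantedBlock("Zorya_TypeII", 1.0, 2, in_island=True),
    PlantedBlock("RM_Type_I", 0.95, 2, mge_class="prophage"),
    PlantedBlock("Thoeris_I", 0.90, 2),
    PlantedBlock("AbiD", 0.50, 3),
)

EXTRA_ISLAND_FAMILIES = ("Hachiman", "Lamassu", "Wadjet")


@dataclass
class SimConfig:
    n_species: int = 5
    genomes_per_species: int = 20
    genes_per_genome: int = 110
    planted_blocks: tuple[PlantedBlock, ...] = DEFAULT_PLANTED_BLOCKS
    within_block_divergence_frac: float = 0.02
    decoy_paralog_identity_pct: float = 85.0
    n_decoy_genomes: int = 2
    plant_extra_island: bool = True  # accessory island of per-genome-unique systems
    plant_overlapping_mges: bool = True  # disjoint-from-genes plasmid+integron pair
    protein_length: int = 120
    circular: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # planted orthologs must clear the 95% identity gate, decoys must not
        L = self.protein_length
        n_mut = round(self.within_block_divergence_frac * L)
        if (L - 2 * n_mut) / L < 0.95:
            raise ValueError("within_block_divergence_frac too high for the 95% identity gate")
        if self.decoy_paralog_identity_pct >= 95:
            raise ValueError("decoy_paralog_identity_pct must fall below the 95% gate")


@dataclass
class BlockTruth:
    family: str
    n_components: int
    presence_count: int
    expected_classification: str
    member_uids: dict[str, str]  # genome_id -> system_uid
    in_island: bool
    mge_class: str | None
    kind: str  # "planted" | "decoy" | "unique"


@dataclass
class SpeciesTruth:
    species_id: str
    genome_ids: list[str]
    blocks: list[BlockTruth]
    islands_per_genome: dict[str, list[tuple[int, int]]]  # rank spans
    context: dict[str, str]  # system_uid -> expected context
    removed_mge_uids: list[str]
    genome_sizes: dict[str, int]

    @property
    def hcads_blocks(self) -> list[BlockTruth]:
        return [b for b in self.blocks if b.expected_classification != "accessory"]

    @property
    def hcads_uids(self) -> set[str]:
        return {uid for b in self.hcads_blocks for uid in b.member_uids.values()}


@dataclass
class GroundTruth:
    species: dict[str, SpeciesTruth] = field(default_factory=dict)


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def _mutate(rng: random.Random, seq: str, n_mut: int, alphabet: str) -> str:
    """Substitute exactly ``n_mut`` distinct positions, each to a new letter."""
    positions = rng.sample(range(len(seq)), n_mut)
    out = list(seq)
    for p in positions:
        choices = [c for c in alphabet if c != out[p]]
        out[p] = rng.choice(choices)
    return "".join(out)


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def expected_classification(presence: int, total: int, cfg: PipelineConfig | None = None) -> str:
    quasi_min = cfg.quasi_core_min_frac if cfg else 0.90
    if presence == total:
        return "core"
    if presence / total >= quasi_min - 1e-12:
        return "quasi_core"
    return "accessory"


def simulate_pangenome(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[Dataset, GroundTruth]:
    """Generate a multi-species pangenome with planted conservation structure.

    If ``out_dir`` is given, all input files are written there in the
    standard layout (manifest.tsv, genes/, systems.tsv, mges.tsv,
    proteins.faa).
    """
    rng = random.Random(cfg.rng_seed)
    truth = GroundTruth()

    manifest: list[GenomeManifest] = []
    genes: list[GeneRecord] = []
    systems: list[SystemInstance] = []
    mges: list[MGEAnnotation] = []
    proteins: dict[str, str] = {}

    for si in range(cfg.n_species):
        species_id = f"SP{si:02d}"
        st = _simulate_species(cfg, rng, species_id, manifest, genes, systems, mges, proteins)
        truth.species[species_id] = st

    dataset = Dataset(manifest=manifest, genes=genes, systems=systems, mges=mges, proteins=proteins)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset, truth


def _layout_slots(cfg: SimConfig) -> tuple[list[tuple], int]:
    """Assign contiguous rank slots to each planted group, well separated.

    Returns (groups, ranks_needed).  Each group is a tuple
    (kind, payload, ranks) where ranks is the list of gene ranks used.
    """
    groups: list[tuple] = []
    cursor = 5
    island_blocks = [b for b in cfg.planted_blocks if b.in_island]
    if island_blocks:
        n = sum(b.n_components for b in island_blocks)
        groups.append(("island", tuple(island_blocks), list(range(cursor, cursor + n))))
        cursor += n + _SLOT_GAP
    for b in cfg.planted_blocks:
        if b.in_island:
            continue
        groups.append(("block", b, list(range(cursor, cursor + b.n_components))))
        cursor += b.n_components + _SLOT_GAP
    if cfg.plant_extra_island:
        n = 2 * len(EXTRA_ISLAND_FAMILIES)
        groups.append(("extra_island", EXTRA_ISLAND_FAMILIES, list(range(cursor, cursor + n))))
        cursor += n + _SLOT_GAP
    if cfg.n_decoy_genomes > 0 and cfg.planted_blocks:
        b0 = cfg.planted_blocks[0]
        groups.append(("decoy", b0, list(range(cursor, cursor + b0.n_components))))
        cursor += b0.n_components + _SLOT_GAP
    return groups, cursor


def _simulate_species(
    cfg: SimConfig,
    rng: random.Random,
    species_id: str,
    manifest: list[GenomeManifest],
    genes: list[GeneRecord],
    systems: list[SystemInstance],
    mges: list[MGEAnnotation],
    proteins: dict[str, str],
) -> SpeciesTruth:
    n = cfg.genomes_per_species
    L = cfg.protein_length
    n_mut = round(cfg.within_block_divergence_frac * L)
    n_mut_decoy = round((1 - cfg.decoy_paralog_identity_pct / 100.0) * L)

    groups, cursor = _layout_slots(cfg)
    # cursor carries a trailing slot gap; last planted rank is cursor - _SLOT_GAP - 1.
    # The circular wrap gap back to the first planted rank (5) must also exceed the
    # island gap limit, which needs 7 spare ranks beyond the last planted one.
    last_used = cursor - _SLOT_GAP - 1
    if last_used + 8 > cfg.genes_per_genome:
        raise ValueError(
            f"infeasible layout: need {last_used + 8} ranks, have {cfg.genes_per_genome}"
        )

    genome_ids = [f"{species_id}_G{gi:02d}" for gi in range(n)]
    replicon = "chrom"
    gene_span_bp = cfg.genes_per_genome * GENE_SPACING_BP
    base_size = gene_span_bp + 20_000

    # which genomes carry each planted block
    block_members: dict[int, list[str]] = {}
    for bi, blk in enumerate(cfg.planted_blocks):
        k = round(blk.presence_frac * n)
        block_members[bi] = sorted(rng.sample(genome_ids, k))
    decoy_genomes = sorted(rng.sample(genome_ids, min(cfg.n_decoy_genomes, n)))

    # ancestors, one per (block, component)
    ancestors = {
        (bi, ci): _random_protein(rng, L)
        for bi, blk in enumerate(cfg.planted_blocks)
        for ci in range(blk.n_components)
    }

    truth_blocks: list[BlockTruth] = [
        BlockTruth(
            family=blk.family,
            n_components=blk.n_components,
            presence_count=len(block_members[bi]),
            expected_classification=expected_classification(len(block_members[bi]), n),
            member_uids={},
            in_island=blk.in_island,
            mge_class=blk.mge_class,
            kind="planted",
        )
        for bi, blk in enumerate(cfg.planted_blocks)
    ]
    context: dict[str, str] = {}
    islands_per_genome: dict[str, list[tuple[int, int]]] = {}
    removed_mge_uids: list[str] = []
    genome_sizes: dict[str, int] = {}
    member_seqs: dict[tuple[int, int], list[str]] = {key: [] for key in ancestors}
    decoy_seqs: dict[int, list[str]] = {}

    for genome_id in genome_ids:
        size_bp = base_size + rng.randrange(0, 5_000)
        genome_sizes[genome_id] = size_bp
        manifest.append(
            GenomeManifest(
                species_id=species_id,
                genome_id=genome_id,
                genome_size_bp=size_bp,
                completeness_pct=100.0,
                contamination_pct=0.0,
            )
        )

        occupied: dict[int, tuple[str, str | None]] = {}  # rank -> (gene_id, none)
        genome_islands: list[tuple[int, int]] = []

        def add_gene(rank: int, gene_id: str, seq: str) -> None:
            occupied[rank] = (gene_id, None)
            proteins[gene_id] = seq

        def add_system(uid: str, family: str, gene_ids: list[str]) -> None:
            systems.append(
                SystemInstance(
                    system_uid=uid,
                    genome_id=genome_id,
                    replicon_id=replicon,
                    family=family,
                    polarity="defense",
                    component_gene_ids=tuple(gene_ids),
                    complete=True,
                )
            )

        for kind, payload, ranks in groups:
            if kind == "island":
                present_ranks: list[int] = []
                present_families: set[str] = set()
                pos = 0
                for blk in payload:
                    bi = cfg.planted_blocks.index(blk)
                    block_ranks = ranks[pos : pos + blk.n_components]
                    pos += blk.n_components
                    if genome_id not in block_members[bi]:
                        for r in block_ranks:
                            add_gene(r, f"{genome_id}_g{r:04d}", _random_protein(rng, L))
                        continue
                    present_ranks.extend(block_ranks)
                    present_families.add(blk.family)
                    uid = f"{genome_id}_sys_b{bi}"
                    gids = []
                    for ci, r in enumerate(block_ranks):
                        gid = f"{genome_id}_g{r:04d}"
                        seq = _mutate(rng, ancestors[(bi, ci)], n_mut, AA)
                        member_seqs[(bi, ci)].append(seq)
                        add_gene(r, gid, seq)
                        gids.append(gid)
                    add_system(uid, blk.family, gids)
                    truth_blocks[bi].member_uids[genome_id] = uid
                    context[uid] = "chromosome"
                # group spans < gap limit, so present genes always chain together
                if len(present_ranks) >= 5 and len(present_families) >= 3:
                    genome_islands.append((min(present_ranks), max(present_ranks)))
            elif kind == "block":
                blk = payload
                bi = cfg.planted_blocks.index(blk)
                if genome_id not in block_members[bi]:
                    for r in ranks:
                        add_gene(r, f"{genome_id}_g{r:04d}", _random_protein(rng, L))
                    continue
                uid = f"{genome_id}_sys_b{bi}"
                gids = []
                for ci, r in enumerate(ranks):
                    gid = f"{genome_id}_g{r:04d}"
                    seq = _mutate(rng, ancestors[(bi, ci)], n_mut, AA)
                    member_seqs[(bi, ci)].append(seq)
                    add_gene(r, gid, seq)
                    gids.append(gid)
                add_system(uid, blk.family, gids)
                truth_blocks[bi].member_uids[genome_id] = uid
                if blk.mge_class is not None:
                    context[uid] = blk.mge_class
                    start_bp = 1 + ranks[0] * GENE_SPACING_BP - 50
                    end_bp = 1 + ranks[-1] * GENE_SPACING_BP + GENE_LEN_BP + 50
                    mges.append(
                        MGEAnnotation(
                            mge_uid=f"{genome_id}_mge_b{bi}",
                            genome_id=genome_id,
                            replicon_id=replicon,
                            start=max(1, start_bp),
                            end=end_bp,
                            mge_class=blk.mge_class,
                        )
                    )
                else:
                    context[uid] = "chromosome"
            elif kind == "extra_island":
                families = payload
                gene_pos = 0
                for fi, family in enumerate(families):
                    uid = f"{genome_id}_sys_x{fi}"
                    gids = []
                    for _ in range(2):
                        r = ranks[gene_pos]
                        gene_pos += 1
                        gid = f"{genome_id}_g{r:04d}"
                        add_gene(r, gid, _random_protein(rng, L))
                        gids.append(gid)
                    add_system(uid, family, gids)
                    context[uid] = "chromosome"
                    truth_blocks.append(
                        BlockTruth(
                            family=family,
                            n_components=2,
                            presence_count=1,
                            expected_classification="accessory",
                            member_uids={genome_id: uid},
                            in_island=True,
                            mge_class=None,
                            kind="unique",
                        )
                    )
                genome_islands.append((ranks[0], ranks[-1]))
            elif kind == "decoy":
                blk = payload
                bi = cfg.planted_blocks.index(blk)
                if genome_id not in decoy_genomes:
                    for r in ranks:
                        add_gene(r, f"{genome_id}_g{r:04d}", _random_protein(rng, L))
                    continue
                uid = f"{genome_id}_sys_decoy"
                gids = []
                for ci, r in enumerate(ranks):
                    gid = f"{genome_id}_g{r:04d}"
                    seq = _mutate(rng, ancestors[(bi, ci)], n_mut_decoy, AA)
                    decoy_seqs.setdefault(ci, []).append(seq)
                    add_gene(r, gid, seq)
                    gids.append(gid)
                add_system(uid, blk.family, gids)
                context[uid] = "chromosome"
                truth_blocks.append(
                    BlockTruth(
                        family=blk.family,
                        n_components=blk.n_components,
                        presence_count=1,
                        expected_classification="accessory",
                        member_uids={genome_id: uid},
                        in_island=False,
                        mge_class=None,
                        kind="decoy",
                    )
                )

        # filler genes on every unoccupied rank
        for r in range(cfg.genes_per_genome):
            if r not in occupied:
                add_gene(r, f"{genome_id}_g{r:04d}", _random_protein(rng, L))

        for r in range(cfg.genes_per_genome):
            gid = occupied[r][0]
            start = 1 + r * GENE_SPACING_BP
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=replicon,
                    gene_id=gid,
                    rank=r,
                    start=start,
                    end=start + GENE_LEN_BP - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    is_circular_replicon=cfg.circular,
                )
            )

        if cfg.plant_overlapping_mges:
            # gene-free tail region: a nested pair that overlap-exclusion removes
            tail = gene_span_bp + 2_000
            outer = MGEAnnotation(
                mge_uid=f"{genome_id}_mge_ovl_plasmid",
                genome_id=genome_id,
                replicon_id=replicon,
                start=tail,
                end=tail + 3_000,
                mge_class="plasmid",
            )
            inner = MGEAnnotation(
                mge_uid=f"{genome_id}_mge_ovl_integron",
                genome_id=genome_id,
                replicon_id=replicon,
                start=tail + 500,
                end=tail + 1_500,
                mge_class="integron_mobile",
            )
            mges.extend([outer, inner])
            removed_mge_uids.extend([outer.mge_uid, inner.mge_uid])

        islands_per_genome[genome_id] = sorted(genome_islands)

    _assert_identity_contract(cfg, member_seqs, decoy_seqs)

    return SpeciesTruth(
        species_id=species_id,
        genome_ids=genome_ids,
        blocks=truth_blocks,
        islands_per_genome=islands_per_genome,
        context=context,
        removed_mge_uids=removed_mge_uids,
        genome_sizes=genome_sizes,
    )


def _assert_identity_contract(
    cfg: SimConfig,
    member_seqs: dict[tuple[int, int], list[str]],
    decoy_seqs: dict[int, list[str]],
) -> None:
    """Planted pairs >= 95% identity, decoy-vs-member pairs < 95%."""
    for key, seqs in member_seqs.items():
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                assert _identity(a, b) >= 95.0, f"planted pair below gate in block {key}"
    b0 = 0  # decoys are drawn against the first planted block
    for ci, dseqs in decoy_seqs.items():
        members = member_seqs.get((b0, ci), [])
        for d in dseqs:
            for m in members:
                assert _identity(d, m) < 95.0, "decoy pair reached the identity gate"
            for d2 in dseqs:
                if d2 is not d:
                    assert _identity(d, d2) < 95.0


# ---------------------------------------------------------------------------
# phage-contig arm
# ---------------------------------------------------------------------------


@dataclass
class PhageTruth:
    votu_members: dict[str, list[str]]  # planted vOTU index -> contig ids
    hccds: dict[str, list[tuple[str, str, int]]]  # votu -> (family, classification, presence)
    system_uids: dict[str, str]  # system_uid -> family


def simulate_phage_contigs(
    n_votus: int = 3,
    members_per_votu: int = 10,
    within_votu_divergence: float = 0.01,
    planted_hccds: tuple[tuple[str, float], ...] = (("AcrIIA4", 1.0),),
    contig_length: int = 4_000,
    protein_length: int = 120,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], list[SystemInstance], dict[str, str], list[ANIRecord], PhageTruth]:
    """Phage contig sets with planted vOTU structure and counter-defense systems.

    Returns (contigs, systems, proteins, ani_records, truth).  Intra-vOTU
    ANI is >= 100*(1 - 2*divergence); inter-vOTU contigs are unrelated
    random sequences (no ANI record).
    """
    if 1 - 2 * within_votu_divergence < 0.95:
        raise ValueError("within_votu_divergence breaks the 95% ANI separation")
    rng = random.Random(rng_seed)
    n_mut_nt = round(within_votu_divergence * contig_length)
    n_mut_aa = 2  # well inside the 95% protein-identity gate for L=120

    contigs: dict[str, str] = {}
    systems: list[SystemInstance] = []
    proteins: dict[str, str] = {}
    truth = PhageTruth(votu_members={}, hccds={}, system_uids={})

    for vi in range(n_votus):
        votu_key = f"planted_v{vi}"
        ancestor_nt = "".join(rng.choice(NT) for _ in range(contig_length))
        ancestors_aa = {
            fam: _random_protein(rng, protein_length) for fam, _ in planted_hccds
        }
        member_ids = [f"contig_v{vi}_m{mi:02d}" for mi in range(members_per_votu)]
        truth.votu_members[votu_key] = member_ids
        carriers = {
            fam: sorted(rng.sample(member_ids, round(frac * members_per_votu)))
            for fam, frac in planted_hccds
        }
        for contig_id in member_ids:
            contigs[contig_id] = _mutate(rng, ancestor_nt, n_mut_nt, NT)
            for fam, _frac in planted_hccds:
                if contig_id not in carriers[fam]:
                    continue
                gid = f"{contig_id}_{fam}_p0"
                proteins[gid] = _mutate(rng, ancestors_aa[fam], n_mut_aa, AA)
                uid = f"{contig_id}_sys_{fam}"
                systems.append(
                    SystemInstance(
                        system_uid=uid,
                        genome_id=contig_id,
                        replicon_id=contig_id,
                        family=fam,
                        polarity="counter_defense",
                        component_gene_ids=(gid,),
                        complete=True,
                    )
                )
                truth.system_uids[uid] = fam
        truth.hccds[votu_key] = [
            (
                fam,
                expected_classification(len(carriers[fam]), members_per_votu),
                len(carriers[fam]),
            )
            for fam, _ in planted_hccds
        ]

    ani = build_ani_table(contigs)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_proteins, write_systems

        with open(out_dir / "contigs.fna", "w") as fh:
            for cid in sorted(contigs):
                fh.write(f">{cid}\n{contigs[cid]}\n")
        write_systems(systems, out_dir / "phage_systems.tsv")
        write_proteins(proteins, out_dir / "phage_proteins.faa")
        write_ani_table(ani, out_dir / "ani.tsv")

    return contigs, systems, proteins, ani, truth
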