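"""Reciprocal-best-hit orthology between defense-system proteins.

The built-in alignment backend (Smith-Waterman, BLOSUM62, gap open 11 /
extend 1) exists for desk-scale runs and testing; production runs may
ingest a precomputed all-vs-all hit table instead.  The RBH logic itself
is always this module's.

E-values for the built-in backend use the gapped Karlin-Altschul
parameters published for BLOSUM62 with open 11 / extend 1:
lambda = 0.267, K = 0.041; bitscore = (lambda*S - ln K)/ln 2 and
E = m*n*2^-bitscore with m, n the raw sequence lengths.  In
``identity_only`` mode the e-value is set to 0 so the e-value criterion
is vacuously satisfied and oracle tests do not depend on the alignment
backend.
"""

from __future__ import annotations

import math
from collections import defaultdict
from itertools import combinations
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import PipelineConfig
from .io import Dataset, DatasetError
from .models import HitRecord, OrthologLink, RBHPair, SystemInstance

_KA_LAMBDA = 0.267
_KA_K = 0.041

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

HIT_TABLE_COLUMNS = [
    "query_gene_id",
    "subject_gene_id",
    "pct_identity",
    "query_coverage_frac",
    "subject_coverage_frac",
    "evalue",
    "bitscore",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_similarity(
    protein_a: str, protein_b: str, mode: str = "full"
) -> HitRecord:
    """Local alignment of two amino-acid sequences, summarized as a hit.

    pct_identity counts identical columns over all alignment columns
    (including gap columns); coverage is the aligned span over each
    sequence's full length.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    for seq, name in ((protein_a, "query"), (protein_b, "subject")):
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid letters: {sorted(bad)}")

    a, b = protein_a.upper(), protein_b.upper()
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    n_columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / n_columns if n_columns else 0.0

    # aligned span on each sequence
    (qstart, qend) = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    (sstart, send) = alignment.aligned[1][0][0], alignment.aligned[1][-1][1]
    qcov = (qend - qstart) / len(a)
    scov = (send - sstart) / len(b)

    raw_score = alignment.score
    bitscore = (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)
    if mode == "identity_only":
        evalue = 0.0
    else:
        evalue = len(a) * len(b) * 2.0 ** (-bitscore)
    return HitRecord(
        query_gene_id="",
        subject_gene_id="",
        pct_identity=identity,
        query_coverage_frac=qcov,
        subject_coverage_frac=scov,
        evalue=evalue,
        bitscore=bitscore,
    )


def _species_defense_proteins(
    dataset: Dataset, species_id: str, polarity: str
) -> dict[str, list[str]]:
    """genome_id -> sorted gene ids of complete-system components."""
    out: dict[str, set[str]] = defaultdict(set)
    for s in dataset.systems_of_species(species_id, polarity=polarity):
        out[s.genome_id].update(s.component_gene_ids)
    return {g: sorted(ids) for g, ids in out.items()}


def build_hit_table(
    dataset: Dataset,
    species_id: str,
    backend: str = "builtin",
    external_path: str | Path | None = None,
    polarity: str = "defense",
    mode: str = "full",
) -> list[HitRecord]:
    """All-vs-all cross-genome hits among a species' system proteins.

    ``builtin`` aligns every ordered cross-genome pair with
    :func:`pairwise_similarity`; ``external_tsv`` reads a precomputed
    table (columns :data:`HIT_TABLE_COLUMNS`) and attaches genome ids.
    Self-genome pairs are never emitted.
    """
    gene_to_genome = {g.gene_id: g.genome_id for g in dataset.genes}
    per_genome = _species_defense_proteins(dataset, species_id, polarity)

    if backend == "external_tsv":
        if external_path is None:
            raise ValueError("external_tsv backend requires external_path")
        df = pd.read_csv(external_path, sep="\t", dtype={"query_gene_id": str, "subject_gene_id": str})
        missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise DatasetError(f"hit table missing columns: {sorted(missing)}")
        species_genes = {gid for ids in per_genome.values() for gid in ids}
        hits = []
        for row in df.itertuples(index=False):
            q, s = row.query_gene_id, row.subject_gene_id
            if q not in gene_to_genome or s not in gene_to_genome:
                unknown = q if q not in gene_to_genome else s
                raise DatasetError(f"external hit table references unknown gene {unknown!r}")
            if q not in species_genes or s not in species_genes:
                continue
            qg, sg = gene_to_genome[q], gene_to_genome[s]
            if qg == sg:
                continue  # intragenome (paralog) hits are ignored
            hits.append(
                HitRecord(
                    query_gene_id=q,
                    subject_gene_id=s,
                    pct_identity=float(row.pct_identity),
                    query_coverage_frac=float(row.query_coverage_frac),
                    subject_coverage_frac=float(row.subject_coverage_frac),
                    evalue=float(row.evalue),
                    bitscore=float(row.bitscore),
                    query_genome_id=qg,
                    subject_genome_id=sg,
                )
            )
        return hits

    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")

    return all_vs_all_hits(per_genome, dataset.proteins, mode=mode)


def all_vs_all_hits(
    per_genome: dict[str, list[str]],
    proteins: dict[str, str],
    mode: str = "full",
) -> list[HitRecord]:
    """All ordered cross-genome hits for explicit genome -> gene-id sets.

    Each unordered protein pair is aligned once; the reverse hit is its
    mirror (coverages swapped), which the symmetric built-in aligner
    guarantees.
    """
    # Prescreen: pairs sharing no 4-mer cannot approach the identity gate;
    # they get a null hit row (keeps the row-count contract) without alignment.
    def kmers(seq: str, k: int = 4) -> set[str]:
        s = seq.upper()
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    kmer_cache = {
        gid: kmers(proteins[gid]) for ids in per_genome.values() for gid in ids
    }

    hits: list[HitRecord] = []
    genomes = sorted(per_genome)
    for ga, gb in combinations(genomes, 2):
        for qa in per_genome[ga]:
            for sb in per_genome[gb]:
                if kmer_cache[qa].isdisjoint(kmer_cache[sb]):
                    null_e = 0.0 if mode == "identity_only" else math.inf
                    hits.append(
                        HitRecord(qa, sb, 0.0, 0.0, 0.0, null_e, 0.0, ga, gb)
                    )
                    hits.append(
                        HitRecord(sb, qa, 0.0, 0.0, 0.0, null_e, 0.0, gb, ga)
                    )
                    continue
                base = pairwise_similarity(proteins[qa], proteins[sb], mode=mode)
                hits.append(
                    HitRecord(
                        query_gene_id=qa,
                        subject_gene_id=sb,
                        pct_identity=base.pct_identity,
                        query_coverage_frac=base.query_coverage_frac,
                        subject_coverage_frac=base.subject_coverage_frac,
                        evalue=base.evalue,
                        bitscore=base.bitscore,
                        query_genome_id=ga,
                        subject_genome_id=gb,
                    )
                )
                hits.append(
                    HitRecord(
                        query_gene_id=sb,
                        subject_gene_id=qa,
                        pct_identity=base.pct_identity,
                        query_coverage_frac=base.subject_coverage_frac,
                        subject_coverage_frac=base.query_coverage_frac,
                        evalue=base.evalue,
                        bitscore=base.bitscore,
                        query_genome_id=gb,
                        subject_genome_id=ga,
                    )
                )
    return hits


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query_gene_id": h.query_gene_id,
                "subject_gene_id": h.subject_gene_id,
                "pct_identity": h.pct_identity,
                "query_coverage_frac": h.query_coverage_frac,
                "subject_coverage_frac": h.subject_coverage_frac,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
            }
            for h in hits
        ],
        columns=HIT_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def _admissible(h: HitRecord, cfg: PipelineConfig) -> bool:
    return (
        h.pct_identity >= cfg.min_identity_pct
        and min(h.query_coverage_frac, h.subject_coverage_frac) >= cfg.min_coverage_frac
        and h.evalue <= cfg.max_evalue
    )


def compute_rbh(hits: list[HitRecord], cfg: PipelineConfig) -> list[RBHPair]:
    """Reciprocal best hits, thresholded.

    Per (gene, partner genome) the best hit -- over ALL hits, not just
    admissible ones -- maximizes bitscore, ties broken by min evalue,
    then max identity, then lexicographically smallest subject id.  A
    pair is emitted iff each gene is the other's best AND both directed
    hits are admissible: identity >= ``min_identity_pct``, min(query,
    subject coverage) >= ``min_coverage_frac``, evalue <=
    ``max_evalue``.  Filtering after the best-hit step (rather than
    before) makes the pair set shrink monotonically as any threshold is
    raised.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if not h.query_genome_id or not h.subject_genome_id:
            raise ValueError("compute_rbh requires genome ids on every hit")
        if h.query_genome_id == h.subject_genome_id:
            continue
        key = (h.query_gene_id, h.subject_genome_id)
        cur = best.get(key)
        if cur is None or _better(h, cur):
            best[key] = h

    pairs: set[RBHPair] = set()
    for (gene, partner_genome), h in best.items():
        if not _admissible(h, cfg):
            continue
        mate = best.get((h.subject_gene_id, h.query_genome_id))
        if mate is not None and mate.subject_gene_id == gene and _admissible(mate, cfg):
            pairs.add(
                RBHPair.canonical(
                    gene, h.subject_gene_id, h.query_genome_id, h.subject_genome_id
                )
            )
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def _better(a: HitRecord, b: HitRecord) -> bool:
    """Deterministic best-hit ordering: bitscore desc, evalue asc, identity desc, subject id asc."""
    ka = (-a.bitscore, a.evalue, -a.pct_identity, a.subject_gene_id)
    kb = (-b.bitscore, b.evalue, -b.pct_identity, b.subject_gene_id)
    return ka < kb


def link_systems(
    rbh: list[RBHPair],
    systems: list[SystemInstance],
    min_component_frac: float = 1.0,
) -> list[OrthologLink]:
    """Lift gene-level RBH pairs to a system-level conservation relation.

    A link between two system instances requires: same family, different
    genomes, and -- at the default ``min_component_frac=1.0`` -- every
    component of each instance having an RBH partner among the other
    instance's components.  Lower fractions relax the rule symmetrically
    (sensitivity analysis only).
    """
    partners: dict[str, set[str]] = defaultdict(set)
    for p in rbh:
        partners[p.gene_a].add(p.gene_b)
        partners[p.gene_b].add(p.gene_a)

    links: list[OrthologLink] = []
    by_family: dict[str, list[SystemInstance]] = defaultdict(list)
    for s in systems:
        if s.complete:
            by_family[s.family].append(s)

    for family, members in by_family.items():
        for sa, sb in combinations(sorted(members, key=lambda s: s.system_uid), 2):
            if sa.genome_id == sb.genome_id:
                continue
            comps_a, comps_b = set(sa.component_gene_ids), set(sb.component_gene_ids)
            matched_a = sum(1 for g in comps_a if partners[g] & comps_b)
            matched_b = sum(1 for g in comps_b if partners[g] & comps_a)
            if (
                matched_a >= min_component_frac * len(comps_a)
                and matched_b >= min_component_frac * len(comps_b)
                and matched_a > 0
            ):
                links.append(
                    OrthologLink(
                        system_uid_a=sa.system_uid,
                        system_uid_b=sb.system_uid,
                        matched_component_count=matched_a,
                        total_component_count_a=len(comps_a),
                    )
                )
    return links
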