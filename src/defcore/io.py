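"""Readers, writers, and validation for all input/output tables.

Dialects
--------
manifest
    TSV with columns ``species_id, genome_id, genome_size_bp,
    completeness, contamination``.
gene tables
    GFF3, one file per genome named ``<genome_id>.gff``; CDS features
    with an ``ID`` attribute carrying the gene id.  A ``region`` feature
    with ``Is_circular=true`` marks a circular replicon.
systems
    TSV with columns ``system_uid, genome_id, replicon_id, family,
    polarity, complete, component_gene_ids`` (comma-joined gene ids).
MGEs
    TSV with columns ``mge_uid, genome_id, replicon_id, start, end,
    mge_class``; coordinates 1-based inclusive.
proteins
    FASTA; record ids are gene ids.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .models import GeneRecord, GenomeManifest, MGEAnnotation, SystemInstance

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "species_id",
    "genome_id",
    "genome_size_bp",
    "completeness",
    "contamination",
]
SYSTEMS_COLUMNS = [
    "system_uid",
    "genome_id",
    "replicon_id",
    "family",
    "polarity",
    "complete",
    "component_gene_ids",
]
MGE_COLUMNS = ["mge_uid", "genome_id", "replicon_id", "start", "end", "mge_class"]


class DatasetError(ValueError):
    """Fatal input-validation problem (missing file, dangling reference, ...)."""


@dataclass
class Dataset:
    """All cross-validated inputs for one pipeline run."""

    manifest: list[GenomeManifest]
    genes: list[GeneRecord]
    systems: list[SystemInstance]
    mges: list[MGEAnnotation]
    proteins: dict[str, str]  # gene_id -> amino-acid sequence

    # derived indexes, built in __post_init__
    gene_index: dict[str, GeneRecord] = field(default_factory=dict, repr=False)
    genomes_by_species: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.gene_index = {}
        for g in self.genes:
            if g.gene_id in self.gene_index:
                raise DatasetError(f"duplicate gene_id {g.gene_id!r}")
            self.gene_index[g.gene_id] = g
        self.genomes_by_species = defaultdict(list)
        seen = set()
        for m in self.manifest:
            if m.genome_id in seen:
                raise DatasetError(f"duplicate genome_id {m.genome_id!r} in manifest")
            seen.add(m.genome_id)
            self.genomes_by_species[m.species_id].append(m.genome_id)
        self.genomes_by_species = dict(self.genomes_by_species)
        self._validate()

    def _validate(self) -> None:
        genome_ids = {m.genome_id for m in self.manifest}
        for g in self.genes:
            if g.genome_id not in genome_ids:
                raise DatasetError(
                    f"gene {g.gene_id!r} references unknown genome {g.genome_id!r}"
                )
        for s in self.systems:
            if s.genome_id not in genome_ids:
                raise DatasetError(
                    f"system {s.system_uid!r} references unknown genome "
                    f"{s.genome_id!r}"
                )
            for gid in s.component_gene_ids:
                gene = self.gene_index.get(gid)
                if gene is None:
                    raise DatasetError(
                        f"system {s.system_uid!r} references unknown gene {gid!r}"
                    )
                if gene.genome_id != s.genome_id:
                    raise DatasetError(
                        f"system {s.system_uid!r} component {gid!r} lies on "
                        f"genome {gene.genome_id!r}, not {s.genome_id!r}"
                    )
        for m in self.mges:
            if m.genome_id not in genome_ids:
                raise DatasetError(
                    f"MGE {m.mge_uid!r} references unknown genome {m.genome_id!r}"
                )

    # -- convenience accessors -------------------------------------------

    def genes_of_genome(self, genome_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.genome_id == genome_id]

    def systems_of_species(self, species_id: str, polarity: str = "defense"):
        genomes = set(self.genomes_by_species.get(species_id, ()))
        return [
            s
            for s in self.systems
            if s.genome_id in genomes and s.polarity == polarity and s.complete
        ]

    def species_of_genome(self) -> dict[str, str]:
        return {m.genome_id: m.species_id for m in self.manifest}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[GenomeManifest]:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"manifest missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GenomeManifest(
                species_id=row.species_id,
                genome_id=row.genome_id,
                genome_size_bp=int(row.genome_size_bp),
                completeness_pct=float(row.completeness),
                contamination_pct=float(row.contamination),
            )
        )
    return out


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path: str | Path, genome_id: str) -> list[GeneRecord]:
    """Parse one genome's GFF3 CDS features into rank-ordered gene records.

    Ranks are always recomputed from coordinates: genes are sorted per
    replicon by (start, end, gene_id) and numbered 0..n-1.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"gene table not found: {path}")
    circular: dict[str, bool] = {}
    raw: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise DatasetError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            adict = _parse_gff_attributes(attrs)
            if ftype == "region":
                circular[seqid] = adict.get("Is_circular", "false").lower() == "true"
                continue
            if ftype != "CDS":
                continue
            gene_id = adict.get("ID")
            if gene_id is None:
                raise DatasetError(f"{path}: CDS without ID attribute")
            raw.append((seqid, gene_id, int(start), int(end), strand))

    by_replicon: dict[str, list] = defaultdict(list)
    for seqid, gene_id, start, end, strand in raw:
        by_replicon[seqid].append((start, end, gene_id, strand))

    records: list[GeneRecord] = []
    for seqid in sorted(by_replicon):
        rows = sorted(by_replicon[seqid])
        for rank, (start, end, gene_id, strand) in enumerate(rows):
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=seqid,
                    gene_id=gene_id,
                    rank=rank,
                    start=start,
                    end=end,
                    strand=strand,
                    is_circular_replicon=circular.get(seqid, False),
                )
            )
    return records


def read_systems(path: str | Path) -> list[SystemInstance]:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"systems table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SYSTEMS_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"systems table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SystemInstance(
                system_uid=row.system_uid,
                genome_id=row.genome_id,
                replicon_id=row.replicon_id,
                family=row.family,
                polarity=row.polarity,
                component_gene_ids=tuple(row.component_gene_ids.split(",")),
                complete=str(row.complete).lower() in ("true", "1", "yes"),
            )
        )
    return out


def read_mges(path: str | Path) -> list[MGEAnnotation]:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"MGE table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MGE_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"MGE table missing columns: {sorted(missing)}")
    return [
        MGEAnnotation(
            mge_uid=row.mge_uid,
            genome_id=row.genome_id,
            replicon_id=row.replicon_id,
            start=int(row.start),
            end=int(row.end),
            mge_class=row.mge_class,
        )
        for row in df.itertuples(index=False)
    ]


def read_proteins(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"protein FASTA not found: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DatasetError(f"duplicate protein id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def read_dataset(input_dir: str | Path) -> Dataset:
    """Load a full input tree laid out as written by :func:`write_dataset`.

    Layout: ``manifest.tsv``, ``systems.tsv``, ``mges.tsv``,
    ``proteins.faa`` and ``genes/<genome_id>.gff``.
    """
    input_dir = Path(input_dir)
    manifest = read_manifest(input_dir / "manifest.tsv")
    genes: list[GeneRecord] = []
    for m in manifest:
        genes.extend(read_gene_table(input_dir / "genes" / f"{m.genome_id}.gff", m.genome_id))
    systems = read_systems(input_dir / "systems.tsv")
    mge_path = input_dir / "mges.tsv"
    mges = read_mges(mge_path) if mge_path.exists() else []
    proteins = read_proteins(input_dir / "proteins.faa")
    return Dataset(manifest=manifest, genes=genes, systems=systems, mges=mges, proteins=proteins)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_manifest(manifest: list[GenomeManifest], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species_id": m.species_id,
                "genome_id": m.genome_id,
                "genome_size_bp": m.genome_size_bp,
                "completeness": m.completeness_pct,
                "contamination": m.contamination_pct,
            }
            for m in manifest
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    """Write one genome's genes as GFF3 (CDS features, ID attribute)."""
    by_replicon: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_replicon[g.replicon_id].append(g)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for replicon_id in sorted(by_replicon):
            rows = sorted(by_replicon[replicon_id], key=lambda g: g.rank)
            end = max(g.end for g in rows)
            circ = "true" if rows[0].is_circular_replicon else "false"
            fh.write(
                f"{replicon_id}\tdefcore\tregion\t1\t{end}\t.\t+\t.\t"
                f"ID={replicon_id};Is_circular={circ}\n"
            )
            for g in rows:
                fh.write(
                    f"{replicon_id}\tdefcore\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )


def write_systems(systems: list[SystemInstance], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "system_uid": s.system_uid,
                "genome_id": s.genome_id,
                "replicon_id": s.replicon_id,
                "family": s.family,
                "polarity": s.polarity,
                "complete": str(s.complete).lower(),
                "component_gene_ids": ",".join(s.component_gene_ids),
            }
            for s in systems
        ],
        columns=SYSTEMS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_mges(mges: list[MGEAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "mge_uid": m.mge_uid,
                "genome_id": m.genome_id,
                "replicon_id": m.replicon_id,
                "start": m.start,
                "end": m.end,
                "mge_class": m.mge_class,
            }
            for m in mges
        ],
        columns=MGE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_proteins(proteins: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "genes").mkdir(exist_ok=True)
    write_manifest(dataset.manifest, out_dir / "manifest.tsv")
    for m in dataset.manifest:
        write_gene_table(dataset.genes_of_genome(m.genome_id), out_dir / "genes" / f"{m.genome_id}.gff")
    write_systems(dataset.systems, out_dir / "systems.tsv")
    write_mges(dataset.mges, out_dir / "mges.tsv")
    write_proteins(dataset.proteins, out_dir / "proteins.faa")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_genomes_qc(
    manifest: list[GenomeManifest], cfg: PipelineConfig
) -> list[GenomeManifest]:
    """Keep genomes with completeness >= gate and contamination <= gate (inclusive)."""
    return [
        m
        for m in manifest
        if m.completeness_pct >= cfg.qc_min_completeness
        and m.contamination_pct <= cfg.qc_max_contamination
    ]


@dataclass(frozen=True)
class SpeciesSelection:
    species_id: str
    genome_ids: tuple[str, ...]
    has_systems: bool  # False => excluded from conservation analysis (flag only)


def select_species(
    manifest: list[GenomeManifest],
    cfg: PipelineConfig,
    systems: list[SystemInstance] | None = None,
) -> list[SpeciesSelection]:
    """Species with >= ``min_genomes_per_species`` QC-passing genomes.

    Species whose genomes carry no complete defense system anywhere are
    kept but flagged ``has_systems=False`` (excluded from conservation
    calling, not deleted).  Output order is by species id, independent of
    input ordering.
    """
    by_species: dict[str, list[str]] = defaultdict(list)
    for m in manifest:
        by_species[m.species_id].append(m.genome_id)
    genomes_with_systems = {
        s.genome_id for s in (systems or []) if s.complete and s.polarity == "defense"
    }
    out = []
    for species_id in sorted(by_species):
        genome_ids = sorted(by_species[species_id])
        if len(genome_ids) < cfg.min_genomes_per_species:
            continue
        has = any(g in genomes_with_systems for g in genome_ids)
        out.append(
            SpeciesSelection(
                species_id=species_id, genome_ids=tuple(genome_ids), has_systems=has
            )
        )
    return out
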