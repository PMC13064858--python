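"""Domain records shared across pipeline stages.

Coordinates are 1-based inclusive throughout (the GFF convention of the
input tables); any half-open arithmetic is private to the operation that
needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


MGE_CLASSES = frozenset(
    {
        "plasmid",
        "prophage",
        "ICE",
        "IME",
        "integron_sedentary",
        "integron_mobile",
    }
)

POLARITIES = frozenset({"defense", "counter_defense"})


@dataclass(frozen=True)
class GenomeManifest:
    species_id: str
    genome_id: str
    genome_size_bp: int
    completeness_pct: float
    contamination_pct: float
    replicon_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError(f"{self.genome_id}: genome_size_bp must be positive")
        if not 0 <= self.completeness_pct <= 100:
            raise ValueError(f"{self.genome_id}: completeness out of [0, 100]")
        if not 0 <= self.contamination_pct <= 100:
            raise ValueError(f"{self.genome_id}: contamination out of [0, 100]")


@dataclass(frozen=True)
class GeneRecord:
    genome_id: str
    replicon_id: str
    gene_id: str
    rank: int  # 0-based position in replicon order
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    is_circular_replicon: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SystemInstance:
    """One complete defense (or counter-defense) system call in one genome."""

    system_uid: str
    genome_id: str
    replicon_id: str
    family: str
    polarity: str  # "defense" | "counter_defense"
    component_gene_ids: tuple[str, ...]
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"{self.system_uid}: empty family")
        if self.polarity not in POLARITIES:
            raise ValueError(f"{self.system_uid}: bad polarity {self.polarity!r}")
        if not self.component_gene_ids:
            raise ValueError(f"{self.system_uid}: no component genes")


@dataclass(frozen=True)
class MGEAnnotation:
    mge_uid: str
    genome_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int
    mge_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.mge_uid}: start > end")
        if self.mge_class not in MGE_CLASSES:
            raise ValueError(
                f"{self.mge_uid}: unknown mge_class {self.mge_class!r} "
                f"(expected one of {sorted(MGE_CLASSES)})"
            )


@dataclass(frozen=True)
class HitRecord:
    """One directed protein comparison (outfmt-6-like, plus both coverages)."""

    query_gene_id: str
    subject_gene_id: str
    pct_identity: float
    query_coverage_frac: float
    subject_coverage_frac: float
    evalue: float
    bitscore: float
    query_genome_id: str = ""
    subject_genome_id: str = ""


@dataclass(frozen=True)
class RBHPair:
    """Unordered reciprocal-best-hit gene pair, stored once in canonical order."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str

    @staticmethod
    def canonical(gene_a, gene_b, genome_a, genome_b) -> "RBHPair":
        if gene_a <= gene_b:
            return RBHPair(gene_a, gene_b, genome_a, genome_b)
        return RBHPair(gene_b, gene_a, genome_b, genome_a)


@dataclass(frozen=True)
class OrthologLink:
    """System-level conservation relation lifted from gene-level RBH pairs."""

    system_uid_a: str
    system_uid_b: str
    matched_component_count: int
    total_component_count_a: int


@dataclass
class HCADSBlock:
    """Equivalence class of orthologous system instances within a species."""

    block_id: str
    species_id: str
    family: str
    member_system_uids: list[str]
    presence_count: int
    genome_count: int
    classification: str  # "core" | "quasi_core" | "accessory"

    @property
    def presence_frac(self) -> float:
        return self.presence_count / self.genome_count

    @property
    def is_hcads(self) -> bool:
        return self.classification in ("core", "quasi_core")


@dataclass
class DefenseIsland:
    island_id: str
    genome_id: str
    replicon_id: str
    start_rank: int  # may exceed end_rank for wrap-around islands
    end_rank: int
    start_bp: int
    end_bp: int
    member_gene_ids: list[str]
    member_system_uids: list[str]
    distinct_family_count: int

    @property
    def member_defense_gene_count(self) -> int:
        return len(self.member_gene_ids)


@dataclass(frozen=True)
class ContextAssignment:
    system_uid: str
    context: str  # "chromosome" or an MGE class
    mge_uid: str | None = None
    partial_overlap: bool = False  # overlapped an MGE without full containment


@dataclass(frozen=True)
class DensityRecord:
    genome_id: str
    scope: str  # "whole_genome" | "islands" | per-MGE-class scope
    count: int
    span_mb: float

    @property
    def density_per_mb(self) -> float:
        return self.count / self.span_mb


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    adjusted_p: float | None = None
    label: str = ""
    estimate: float | None = None  # odds ratio / correlation, method-dependent


@dataclass(frozen=True)
class ANIRecord:
    """Directed contig comparison: coverages are per the ordered pair."""

    query_contig: str
    target_contig: str
    ani_pct: float
    query_cov_frac: float
    target_cov_frac: float

    def __post_init__(self) -> None:
        if not 0 <= self.ani_pct <= 100:
            raise ValueError(
                f"ANI out of [0, 100] for {self.query_contig}/{self.target_contig}"
            )


@dataclass
class VOTU:
    votu_id: str
    representative_contig: str
    member_contigs: list[str]
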