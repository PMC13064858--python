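"""Pipeline configuration.

All numeric thresholds used anywhere in the pipeline live here, with the
defaults the analysis is defined by.  Thresholds are read as inclusive
("at least", ">=", "<=") everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches for every pipeline stage.

    Attributes
    ----------
    min_identity_pct:
        Minimum percent identity for an admissible protein hit.
    min_coverage_frac:
        Minimum alignment coverage; applied to *both* query and subject
        (the strictest reading of an unqualified coverage threshold).
    max_evalue:
        Maximum e-value for an admissible protein hit.
    core_frac:
        Presence fraction at (and only at) which a block is "core".
    quasi_core_min_frac:
        Minimum presence fraction for "quasi-core" (inclusive).
    island_max_gap_genes:
        Maximum number of intervening non-defense genes between two
        consecutive defense genes of the same island.
    island_min_genes / island_min_families:
        Minimum defense-gene count and distinct-family count for a
        cluster to qualify as a defense island.
    min_genomes_per_species:
        Species (or vOTU) size floor for conservation analysis.
    qc_min_completeness / qc_max_contamination:
        Genome QC gates, in percent.
    votu_min_ani / votu_min_tcov / votu_min_qcov:
        Greedy centroid clustering admission thresholds.  ``tcov``
        applies to the candidate member contig, ``qcov`` to the centroid.
    link_min_component_frac:
        Fraction of system components that must have a reciprocal-best-hit
        partner in the other system for a system-level link (1.0 = all,
        the default; exposed for sensitivity analysis).
    block_linkage:
        "single" (default) or "complete" linkage when grouping linked
        system instances into blocks.
    island_gap_mode:
        "intervening" (gap = intervening non-defense genes, default) or
        "rank" (gap = rank difference) -- the two readings of the
        island gap rule.
    mge_overlap_mode:
        "both" removes both members of every overlapping MGE pair
        (default); "nested" removes only intervals fully contained in
        another.
    mww_exact_max_n:
        Largest n1+n2 for which the rank-sum test uses the exact null.
    """

    min_identity_pct: float = 95.0
    min_coverage_frac: float = 0.80
    max_evalue: float = 1e-4
    core_frac: float = 1.0
    quasi_core_min_frac: float = 0.90
    island_max_gap_genes: int = 10
    island_min_genes: int = 5
    island_min_families: int = 3
    min_genomes_per_species: int = 10
    qc_min_completeness: float = 90.0
    qc_max_contamination: float = 5.0
    votu_min_ani: float = 95.0
    votu_min_tcov: float = 0.85
    votu_min_qcov: float = 0.0
    rng_seed: int = 0

    # secondary switches
    link_min_component_frac: float = 1.0
    block_linkage: str = "single"
    island_gap_mode: str = "intervening"
    mge_overlap_mode: str = "both"
    mww_exact_max_n: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in [0, 100]")
        if not 0 <= self.min_coverage_frac <= 1:
            raise ValueError("min_coverage_frac must be in [0, 1]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be nonnegative")
        if not 0 < self.quasi_core_min_frac <= self.core_frac <= 1:
            raise ValueError("require 0 < quasi_core_min_frac <= core_frac <= 1")
        if self.island_max_gap_genes < 0 or self.island_min_genes < 1:
            raise ValueError("island thresholds out of range")
        if self.min_genomes_per_species < 1:
            raise ValueError("min_genomes_per_species must be >= 1")
        if not 0 <= self.votu_min_ani <= 100:
            raise ValueError("votu_min_ani must be in [0, 100]")
        if self.block_linkage not in ("single", "complete"):
            raise ValueError("block_linkage must be 'single' or 'complete'")
        if self.island_gap_mode not in ("intervening", "rank"):
            raise ValueError("island_gap_mode must be 'intervening' or 'rank'")
        if self.mge_overlap_mode not in ("both", "nested"):
            raise ValueError("mge_overlap_mode must be 'both' or 'nested'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
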