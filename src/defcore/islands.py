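"""Defense-island detection on gene rank order.

An island is a maximal chain of defense genes (components of complete
systems) in which consecutive defense genes are separated by at most
``island_max_gap_genes`` intervening non-defense genes, containing at
least ``island_min_genes`` defense genes from at least
``island_min_families`` distinct families.  Circular replicons are
evaluated with the wrap-around gap between the last and first defense
gene.
"""

from __future__ import annotations

from collections import defaultdict

from .config import PipelineConfig
from .models import DefenseIsland, GeneRecord, HCADSBlock, SystemInstance


def _gap_limit(cfg: PipelineConfig) -> int:
    # "intervening": <= N non-defense genes between neighbours (rank diff <= N+1)
    # "rank":        rank difference <= N
    return cfg.island_max_gap_genes + 1 if cfg.island_gap_mode == "intervening" else cfg.island_max_gap_genes


def detect_defense_islands(
    genes: list[GeneRecord],
    systems: list[SystemInstance],
    cfg: PipelineConfig,
) -> list[DefenseIsland]:
    """Detect islands on every replicon present in ``genes``."""
    gene_families: dict[str, set[str]] = defaultdict(set)
    gene_systems: dict[str, set[str]] = defaultdict(set)
    for s in systems:
        if not s.complete or s.polarity != "defense":
            continue
        for gid in s.component_gene_ids:
            gene_families[gid].add(s.family)
            gene_systems[gid].add(s.system_uid)

    by_replicon: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_replicon[(g.genome_id, g.replicon_id)].append(g)

    islands: list[DefenseIsland] = []
    for (genome_id, replicon_id) in sorted(by_replicon):
        rows = sorted(by_replicon[(genome_id, replicon_id)], key=lambda g: g.rank)
        islands.extend(
            _detect_on_replicon(
                genome_id, replicon_id, rows, gene_families, gene_systems, cfg, len(islands)
            )
        )
    return islands


def _detect_on_replicon(
    genome_id: str,
    replicon_id: str,
    genes: list[GeneRecord],
    gene_families: dict[str, set[str]],
    gene_systems: dict[str, set[str]],
    cfg: PipelineConfig,
    id_offset: int,
) -> list[DefenseIsland]:
    n_genes = len(genes)
    defense = [g for g in genes if g.gene_id in gene_families]
    if not defense:
        return []
    limit = _gap_limit(cfg)

    # greedy left-to-right chaining on rank
    clusters: list[list[GeneRecord]] = [[defense[0]]]
    for g in defense[1:]:
        if g.rank - clusters[-1][-1].rank <= limit:
            clusters[-1].append(g)
        else:
            clusters.append([g])

    wrapped = False
    if genes[0].is_circular_replicon and len(clusters) > 1:
        wrap_dist = (n_genes - clusters[-1][-1].rank) + clusters[0][0].rank
        if wrap_dist <= limit:
            clusters[0] = clusters.pop() + clusters[0]
            wrapped = True
    elif genes[0].is_circular_replicon and len(clusters) == 1:
        # single cluster may still wrap only trivially; nothing to merge
        pass

    islands: list[DefenseIsland] = []
    for members in clusters:
        families = set().union(*(gene_families[g.gene_id] for g in members))
        if len(members) < cfg.island_min_genes or len(families) < cfg.island_min_families:
            continue
        uids = sorted(set().union(*(gene_systems[g.gene_id] for g in members)))
        is_wrap = wrapped and members[0].rank > members[-1].rank
        islands.append(
            DefenseIsland(
                island_id=f"{genome_id}_{replicon_id}_I{id_offset + len(islands):03d}",
                genome_id=genome_id,
                replicon_id=replicon_id,
                start_rank=members[0].rank,
                end_rank=members[-1].rank,
                start_bp=members[0].start,
                end_bp=members[-1].end,
                member_gene_ids=[g.gene_id for g in members],
                member_system_uids=uids,
                distinct_family_count=len(families),
            )
        )
    return islands


def island_membership(
    hcads: list[HCADSBlock],
    islands: list[DefenseIsland],
    systems: list[SystemInstance],
) -> tuple[dict[str, bool], float]:
    """Flag island-colocalized blocks; fraction is instance-level.

    A block is colocalized iff at least one member instance has at least
    one component gene inside an island.  The returned fraction is
    (colocalized HCADS instances) / (total HCADS instances).
    """
    island_genes: set[str] = set()
    for isl in islands:
        island_genes.update(isl.member_gene_ids)
    system_by_uid = {s.system_uid: s for s in systems}

    flags: dict[str, bool] = {}
    total_instances = 0
    coloc_instances = 0
    for block in hcads:
        block_flag = False
        for uid in block.member_system_uids:
            total_instances += 1
            inst = system_by_uid[uid]
            if any(gid in island_genes for gid in inst.component_gene_ids):
                coloc_instances += 1
                block_flag = True
        flags[block.block_id] = block_flag
    frac = coloc_instances / total_instances if total_instances else 0.0
    return flags, frac
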