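"""Conserved-block construction and core/quasi-core classification.

Blocks are connected components (single linkage by default) of the
system-level ortholog-link graph; the presence denominator is ALL
QC-passing genomes of the species, including genomes with no systems.
Classification: core at 100% presence, quasi-core at [90%, 100%),
accessory below.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx

from .config import PipelineConfig
from .models import HCADSBlock, OrthologLink, SystemInstance

_EPS = 1e-12


def classify_presence(presence_count: int, genome_count: int, cfg: PipelineConfig) -> str:
    if genome_count <= 0:
        raise ValueError("genome_count must be positive")
    if presence_count == genome_count:
        return "core"
    if presence_count / genome_count >= cfg.quasi_core_min_frac - _EPS:
        return "quasi_core"
    return "accessory"


def build_blocks(
    links: list[OrthologLink],
    systems: list[SystemInstance],
    species_id: str,
    genome_ids: list[str] | tuple[str, ...],
    cfg: PipelineConfig,
) -> list[HCADSBlock]:
    """Group one species' complete system instances into blocks.

    Every complete instance belongs to exactly one block; instances with
    no links form singleton blocks.  With ``block_linkage="complete"``
    a component is split unless it is a clique.
    """
    genome_ids = list(genome_ids)
    genome_set = set(genome_ids)
    insts = {
        s.system_uid: s for s in systems if s.complete and s.genome_id in genome_set
    }

    graph = nx.Graph()
    graph.add_nodes_from(insts)
    for link in links:
        if link.system_uid_a in insts and link.system_uid_b in insts:
            graph.add_edge(link.system_uid_a, link.system_uid_b)

    components: list[set[str]] = [set(c) for c in nx.connected_components(graph)]
    if cfg.block_linkage == "complete":
        components = [part for comp in components for part in _split_cliques(graph, comp)]

    blocks: list[HCADSBlock] = []
    # deterministic block ids: order components by smallest member uid
    components.sort(key=lambda c: min(c))
    for i, comp in enumerate(components):
        members = sorted(comp)
        families = {insts[u].family for u in members}
        assert len(families) == 1, f"chimeric block across families: {sorted(families)}"
        presence = len({insts[u].genome_id for u in members})
        blocks.append(
            HCADSBlock(
                block_id=f"{species_id}_B{i:04d}",
                species_id=species_id,
                family=families.pop(),
                member_system_uids=members,
                presence_count=presence,
                genome_count=len(genome_ids),
                classification=classify_presence(presence, len(genome_ids), cfg),
            )
        )
    return blocks


def _split_cliques(graph: nx.Graph, component: set[str]) -> list[set[str]]:
    """Greedy clique partition of one connected component (deterministic)."""
    remaining = sorted(component)
    parts: list[set[str]] = []
    while remaining:
        seed = remaining[0]
        clique = {seed}
        for node in remaining[1:]:
            if all(graph.has_edge(node, member) for member in clique):
                clique.add(node)
        parts.append(clique)
        remaining = [n for n in remaining if n not in clique]
    return parts


@dataclass
class ConservationSummary:
    species_id: str
    n_blocks: int
    n_core: int
    n_quasi: int
    n_accessory: int
    n_instances: int
    n_hcads_instances: int
    hcads_instance_frac: float  # fraction of all complete instances in HCADS blocks
    core_frac_of_hcads: float
    quasi_frac_of_hcads: float
    per_family_hcads: dict[str, int]


def call_hcads(
    blocks: list[HCADSBlock],
) -> tuple[list[HCADSBlock], ConservationSummary]:
    """HCADS subset (core + quasi-core blocks) and the per-species summary."""
    species_id = blocks[0].species_id if blocks else ""
    hcads = [b for b in blocks if b.is_hcads]
    n_core = sum(1 for b in hcads if b.classification == "core")
    n_quasi = len(hcads) - n_core
    n_instances = sum(len(b.member_system_uids) for b in blocks)
    n_hcads_instances = sum(len(b.member_system_uids) for b in hcads)
    per_family: dict[str, int] = defaultdict(int)
    for b in hcads:
        per_family[b.family] += 1
    summary = ConservationSummary(
        species_id=species_id,
        n_blocks=len(blocks),
        n_core=n_core,
        n_quasi=n_quasi,
        n_accessory=len(blocks) - len(hcads),
        n_instances=n_instances,
        n_hcads_instances=n_hcads_instances,
        hcads_instance_frac=(n_hcads_instances / n_instances) if n_instances else 0.0,
        core_frac_of_hcads=(n_core / len(hcads)) if hcads else 0.0,
        quasi_frac_of_hcads=(n_quasi / len(hcads)) if hcads else 0.0,
        per_family_hcads=dict(per_family),
    )
    return hcads, summary


def call_hccds(
    votu_id: str,
    member_contigs: list[str] | tuple[str, ...],
    links: list[OrthologLink],
    systems: list[SystemInstance],
    cfg: PipelineConfig,
) -> list[HCADSBlock] | None:
    """Conserved counter-defense blocks over one vOTU's member contigs.

    Identical logic to defense-block calling with genomes replaced by
    member contigs.  Returns None (skip) below the member floor.
    """
    if len(member_contigs) < cfg.min_genomes_per_species:
        return None
    counter = [s for s in systems if s.polarity == "counter_defense"]
    blocks = build_blocks(links, counter, votu_id, list(member_contigs), cfg)
    return [b for b in blocks if b.is_hcads]
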