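"""End-to-end orchestration: io -> orthology -> persistence -> islands ->
colocalization -> stats (-> vOTU/HCCDS when phage inputs are given).

All result tables are plain TSV with fixed column order; the run report
is JSON.  Conservation identities (instance partition over blocks,
island disjointness, context partition) are asserted on every run, not
merely reported.
"""

from __future__ import annotations

import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import colocalization, islands as islands_mod, orthology, persistence, stats, votu as votu_mod
from .config import PipelineConfig
from .io import Dataset, filter_genomes_qc, read_dataset, select_species
from .models import DefenseIsland, HCADSBlock, SystemInstance

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    config: dict
    n_genomes_input: int = 0
    n_genomes_qc_pass: int = 0
    n_species_analyzed: int = 0
    n_species_flagged_no_systems: int = 0
    n_systems: int = 0
    n_rbh_pairs: int = 0
    n_blocks: int = 0
    n_hcads_blocks: int = 0
    n_core: int = 0
    n_quasi: int = 0
    n_islands: int = 0
    n_mges_input: int = 0
    n_mges_removed_overlap: int = 0
    n_contexts: int = 0
    hcads_island_frac: float = 0.0
    hcads_mge_instance_frac: float = 0.0
    hcads_mge_block_frac: float = 0.0
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    cfg: PipelineConfig | None = None,
    species_filter: list[str] | None = None,
    external_hits: str | Path | None = None,
    alignment_mode: str = "full",
) -> RunReport:
    """Run all stages on an input tree; write result TSVs to ``output_dir``."""
    cfg = cfg or PipelineConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.to_dict())

    t0 = time.time()
    dataset = read_dataset(input_dir)
    report.n_genomes_input = len(dataset.manifest)
    report.stage_seconds["io"] = round(time.time() - t0, 3)

    manifest = filter_genomes_qc(dataset.manifest, cfg)
    report.n_genomes_qc_pass = len(manifest)
    selections = select_species(manifest, cfg, dataset.systems)
    if species_filter:
        selections = [s for s in selections if s.species_id in set(species_filter)]
    report.n_species_flagged_no_systems = sum(1 for s in selections if not s.has_systems)
    report.n_species_analyzed = len(selections)

    all_blocks: list[HCADSBlock] = []
    all_hcads: list[HCADSBlock] = []
    summaries = []
    gene_to_genome = {g.gene_id: g.genome_id for g in dataset.genes}
    qc_genomes = {m.genome_id for m in manifest}
    analyzed_systems: list[SystemInstance] = []

    t0 = time.time()
    n_rbh_total = 0
    for sel in selections:
        systems = [
            s
            for s in dataset.systems_of_species(sel.species_id)
            if s.genome_id in qc_genomes
        ]
        analyzed_systems.extend(systems)
        if not sel.has_systems:
            logger.info("species %s has no complete systems; flagged, skipped", sel.species_id)
            continue
        if external_hits is not None:
            hits = orthology.build_hit_table(
                dataset, sel.species_id, backend="external_tsv", external_path=external_hits
            )
        else:
            hits = orthology.build_hit_table(
                dataset, sel.species_id, backend="builtin", mode=alignment_mode
            )
        rbh = orthology.compute_rbh(hits, cfg)
        n_rbh_total += len(rbh)
        links = orthology.link_systems(rbh, systems, cfg.link_min_component_frac)
        blocks = persistence.build_blocks(links, systems, sel.species_id, list(sel.genome_ids), cfg)
        hcads, summary = persistence.call_hcads(blocks)
        all_blocks.extend(blocks)
        all_hcads.extend(hcads)
        summaries.append(summary)
    report.n_rbh_pairs = n_rbh_total
    report.n_systems = len(analyzed_systems)
    report.n_blocks = len(all_blocks)
    report.n_hcads_blocks = len(all_hcads)
    report.n_core = sum(1 for b in all_hcads if b.classification == "core")
    report.n_quasi = sum(1 for b in all_hcads if b.classification == "quasi_core")
    report.stage_seconds["orthology_persistence"] = round(time.time() - t0, 3)

    # identity: every analyzed instance in exactly one block
    member_uids = [u for b in all_blocks for u in b.member_system_uids]
    assert len(member_uids) == len(set(member_uids)), "instance in two blocks"
    assert set(member_uids) == {s.system_uid for s in analyzed_systems}, (
        "block membership does not partition the system instances"
    )

    t0 = time.time()
    analyzed_genes = [g for g in dataset.genes if g.genome_id in qc_genomes]
    det_islands = islands_mod.detect_defense_islands(analyzed_genes, analyzed_systems, cfg)
    _assert_island_disjoint(det_islands)
    island_flags, island_frac = islands_mod.island_membership(
        all_hcads, det_islands, analyzed_systems
    )
    report.n_islands = len(det_islands)
    report.hcads_island_frac = island_frac
    report.stage_seconds["islands"] = round(time.time() - t0, 3)

    t0 = time.time()
    analyzed_mges = [m for m in dataset.mges if m.genome_id in qc_genomes]
    report.n_mges_input = len(analyzed_mges)
    mges_kept, mges_removed = colocalization.resolve_mge_overlaps(analyzed_mges, cfg)
    report.n_mges_removed_overlap = len(mges_removed)
    contexts = colocalization.assign_context(analyzed_systems, mges_kept, dataset.gene_index)
    report.n_contexts = len(contexts)
    assert len(contexts) == len(analyzed_systems), "context assignment lost a system"

    hcads_uids = {u for b in all_hcads for u in b.member_system_uids}
    hcads_contexts = [c for c in contexts if c.system_uid in hcads_uids]
    n_on_mge = sum(1 for c in hcads_contexts if c.context != "chromosome")
    report.hcads_mge_instance_frac = n_on_mge / len(hcads_contexts) if hcads_contexts else 0.0
    ctx_by_uid = {c.system_uid: c for c in contexts}
    n_blocks_on_mge = sum(
        1
        for b in all_hcads
        if any(ctx_by_uid[u].context != "chromosome" for u in b.member_system_uids)
    )
    report.hcads_mge_block_frac = n_blocks_on_mge / len(all_hcads) if all_hcads else 0.0

    hcads_system_genomes = {
        u: s.genome_id for s in analyzed_systems if s.system_uid in hcads_uids for u in [s.system_uid]
    }
    densities = colocalization.compute_densities(
        hcads_contexts, hcads_system_genomes, det_islands, manifest, mges_kept
    )
    report.stage_seconds["colocalization"] = round(time.time() - t0, 3)

    t0 = time.time()
    stat_rows = _run_stats(all_hcads, island_flags, densities, manifest, analyzed_systems, det_islands)
    report.stage_seconds["stats"] = round(time.time() - t0, 3)

    _write_blocks(all_blocks, island_flags, output_dir / "hcads_blocks.tsv")
    _write_islands(det_islands, output_dir / "islands.tsv")
    _write_contexts(contexts, output_dir / "context.tsv")
    _write_densities(densities, output_dir / "densities.tsv")
    _write_removed_mges(mges_removed, output_dir / "removed_mges.tsv")
    _write_stats(stat_rows, output_dir / "stats.tsv")
    _write_summaries(summaries, output_dir / "species_summary.tsv")
    report.to_json(output_dir / "run_report.json")
    return report


def _assert_island_disjoint(det_islands: list[DefenseIsland]) -> None:
    seen: dict[tuple[str, str], set[str]] = defaultdict(set)
    for isl in det_islands:
        key = (isl.genome_id, isl.replicon_id)
        overlap = seen[key] & set(isl.member_gene_ids)
        assert not overlap, f"islands share genes: {sorted(overlap)[:3]}"
        seen[key].update(isl.member_gene_ids)


def _run_stats(all_hcads, island_flags, densities, manifest, systems, det_islands):
    rows = []
    # density of conserved systems vs genome size (pooled across species)
    wg = {d.genome_id: d for d in densities if d.scope == "whole_genome"}
    sizes, dens = [], []
    for m in manifest:
        if m.genome_id in wg:
            sizes.append(m.genome_size_bp / 1e6)
            dens.append(wg[m.genome_id].density_per_mb)
    if len(sizes) >= 3 and len(set(dens)) > 1 and len(set(sizes)) > 1:
        res = stats.correlate_density_size(dens, sizes)
        rows.append(("hcads_density_vs_genome_size",) + _row(res))

    # family enrichment in islands vs outside (instance counts)
    island_genes = {g for isl in det_islands for g in isl.member_gene_ids}
    fam_counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for s in systems:
        inside = any(g in island_genes for g in s.component_gene_ids)
        fam_counts[s.family][0 if inside else 1] += 1
    table = {f: (c[0], c[1]) for f, c in fam_counts.items()}
    if table and sum(v[0] for v in table.values()) > 0:
        for res in stats.enrichment_test(table):
            rows.append((f"island_enrichment:{res.label}",) + _row(res))
    return rows


def _row(res):
    return (
        res.method,
        res.statistic,
        res.p_value,
        "" if res.adjusted_p is None else res.adjusted_p,
        res.n1,
        res.n2,
    )


def _write_blocks(blocks, island_flags, path):
    pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "species_id": b.species_id,
                "family": b.family,
                "classification": b.classification,
                "presence_count": b.presence_count,
                "genome_count": b.genome_count,
                "presence_frac": round(b.presence_frac, 6),
                "in_island": str(island_flags.get(b.block_id, False)).lower(),
                "member_system_uids": ",".join(b.member_system_uids),
            }
            for b in blocks
        ],
        columns=[
            "block_id",
            "species_id",
            "family",
            "classification",
            "presence_count",
            "genome_count",
            "presence_frac",
            "in_island",
            "member_system_uids",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_islands(det_islands, path):
    pd.DataFrame(
        [
            {
                "island_id": i.island_id,
                "genome_id": i.genome_id,
                "replicon_id": i.replicon_id,
                "start_rank": i.start_rank,
                "end_rank": i.end_rank,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "n_defense_genes": i.member_defense_gene_count,
                "n_families": i.distinct_family_count,
                "member_system_uids": ",".join(i.member_system_uids),
            }
            for i in det_islands
        ],
        columns=[
            "island_id",
            "genome_id",
            "replicon_id",
            "start_rank",
            "end_rank",
            "start_bp",
            "end_bp",
            "n_defense_genes",
            "n_families",
            "member_system_uids",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_contexts(contexts, path):
    pd.DataFrame(
        [
            {
                "system_uid": c.system_uid,
                "context": c.context,
                "mge_uid": c.mge_uid or "",
                "partial_overlap": str(c.partial_overlap).lower(),
            }
            for c in contexts
        ],
        columns=["system_uid", "context", "mge_uid", "partial_overlap"],
    ).to_csv(path, sep="\t", index=False)


def _write_densities(densities, path):
    pd.DataFrame(
        [
            {
                "genome_id": d.genome_id,
                "scope": d.scope,
                "count": d.count,
                "span_mb": round(d.span_mb, 6),
                "density_per_mb": round(d.density_per_mb, 6),
            }
            for d in densities
        ],
        columns=["genome_id", "scope", "count", "span_mb", "density_per_mb"],
    ).to_csv(path, sep="\t", index=False)


def _write_removed_mges(removed, path):
    pd.DataFrame(
        [
            {
                "mge_uid": m.mge_uid,
                "genome_id": m.genome_id,
                "replicon_id": m.replicon_id,
                "start": m.start,
                "end": m.end,
                "mge_class": m.mge_class,
            }
            for m in removed
        ],
        columns=["mge_uid", "genome_id", "replicon_id", "start", "end", "mge_class"],
    ).to_csv(path, sep="\t", index=False)


def _write_stats(rows, path):
    pd.DataFrame(
        rows, columns=["comparison", "method", "statistic", "p_value", "adjusted_p", "n1", "n2"]
    ).to_csv(path, sep="\t", index=False)


def _write_summaries(summaries, path):
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "n_blocks": s.n_blocks,
                "n_core": s.n_core,
                "n_quasi": s.n_quasi,
                "n_accessory": s.n_accessory,
                "n_instances": s.n_instances,
                "n_hcads_instances": s.n_hcads_instances,
                "hcads_instance_frac": round(s.hcads_instance_frac, 6),
                "core_frac_of_hcads": round(s.core_frac_of_hcads, 6),
                "quasi_frac_of_hcads": round(s.quasi_frac_of_hcads, 6),
            }
            for s in summaries
        ],
        columns=[
            "species_id",
            "n_blocks",
            "n_core",
            "n_quasi",
            "n_accessory",
            "n_instances",
            "n_hcads_instances",
            "hcads_instance_frac",
            "core_frac_of_hcads",
            "quasi_frac_of_hcads",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phage arm: vOTU clustering + conserved counter-defense calling
# ---------------------------------------------------------------------------


def run_votu_pipeline(
    contigs: dict[str, str],
    ani_records,
    systems: list[SystemInstance],
    proteins: dict[str, str],
    cfg: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
    alignment_mode: str = "full",
):
    """Cluster contigs into vOTUs, then call conserved counter-defense blocks.

    Returns (votus, {votu_id: hccds blocks}); vOTUs below the member
    floor are skipped (logged), not errors.
    """
    cfg = cfg or PipelineConfig()
    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    votus = votu_mod.cluster_votus(lengths, ani_records, cfg)

    systems_by_contig: dict[str, list[SystemInstance]] = defaultdict(list)
    for s in systems:
        systems_by_contig[s.genome_id].append(s)

    hccds_by_votu: dict[str, list[HCADSBlock]] = {}
    for v in votus:
        if len(v.member_contigs) < cfg.min_genomes_per_species:
            logger.info(
                "vOTU %s has %d members (< %d); skipped for conservation calling",
                v.votu_id,
                len(v.member_contigs),
                cfg.min_genomes_per_species,
            )
            continue
        member_systems = [
            s
            for c in v.member_contigs
            for s in systems_by_contig.get(c, [])
            if s.polarity == "counter_defense" and s.complete
        ]
        if not member_systems:
            hccds_by_votu[v.votu_id] = []
            continue
        per_contig: dict[str, list[str]] = defaultdict(list)
        for s in member_systems:
            per_contig[s.genome_id].extend(s.component_gene_ids)
        hits = orthology.all_vs_all_hits(
            {c: sorted(set(g)) for c, g in per_contig.items()}, proteins, mode=alignment_mode
        )
        rbh = orthology.compute_rbh(hits, cfg)
        links = orthology.link_systems(rbh, member_systems, cfg.link_min_component_frac)
        blocks = persistence.call_hccds(
            v.votu_id, v.member_contigs, links, member_systems, cfg
        )
        hccds_by_votu[v.votu_id] = blocks or []

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        votu_mod.write_votus(votus, output_dir / "votus.tsv")
        rows = []
        for votu_id, blocks in sorted(hccds_by_votu.items()):
            for b in blocks:
                rows.append(
                    {
                        "votu_id": votu_id,
                        "block_id": b.block_id,
                        "family": b.family,
                        "classification": b.classification,
                        "presence_count": b.presence_count,
                        "member_count": b.genome_count,
                        "presence_frac": round(b.presence_frac, 6),
                        "member_system_uids": ",".join(b.member_system_uids),
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "votu_id",
                "block_id",
                "family",
                "classification",
                "presence_count",
                "member_count",
                "presence_frac",
                "member_system_uids",
            ],
        ).to_csv(output_dir / "hccds.tsv", sep="\t", index=False)

    return votus, hccds_by_votu
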