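"""MGE overlap resolution, genomic-context assignment, and densities."""

from __future__ import annotations

import logging
from collections import defaultdict

from .config import PipelineConfig
from .models import (
    ContextAssignment,
    DefenseIsland,
    DensityRecord,
    GeneRecord,
    GenomeManifest,
    MGEAnnotation,
    SystemInstance,
)

logger = logging.getLogger(__name__)

MGE_DENSITY_SCOPES = ("integron_sedentary", "integron_mobile")


def _intersects(a: MGEAnnotation, b: MGEAnnotation) -> bool:
    return a.start <= b.end and b.start <= a.end


def _contained(inner: MGEAnnotation, outer: MGEAnnotation) -> bool:
    return outer.start <= inner.start and inner.end <= outer.end


def resolve_mge_overlaps(
    mges: list[MGEAnnotation], cfg: PipelineConfig | None = None
) -> tuple[list[MGEAnnotation], list[MGEAnnotation]]:
    """Drop overlapping MGE annotations; returns (kept, removed).

    Default mode removes BOTH members of every intersecting pair on the
    same replicon (e.g. an integron carried by a plasmid removes both).
    ``mge_overlap_mode="nested"`` removes only intervals fully contained
    in another.  Order-independent and idempotent.
    """
    mode = cfg.mge_overlap_mode if cfg is not None else "both"
    by_replicon: dict[tuple[str, str], list[MGEAnnotation]] = defaultdict(list)
    for m in mges:
        by_replicon[(m.genome_id, m.replicon_id)].append(m)

    removed_uids: set[str] = set()
    for group in by_replicon.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if not _intersects(a, b):
                    continue
                if mode == "both":
                    removed_uids.add(a.mge_uid)
                    removed_uids.add(b.mge_uid)
                else:  # nested: remove only fully contained intervals
                    if _contained(a, b):
                        removed_uids.add(a.mge_uid)
                    if _contained(b, a):
                        removed_uids.add(b.mge_uid)

    kept = [m for m in mges if m.mge_uid not in removed_uids]
    removed = [m for m in mges if m.mge_uid in removed_uids]
    if mges:
        logger.info(
            "MGE overlap exclusion removed %d/%d annotations (%.1f%%)",
            len(removed),
            len(mges),
            100.0 * len(removed) / len(mges),
        )
    return kept, removed


def assign_context(
    systems: list[SystemInstance],
    mges_filtered: list[MGEAnnotation],
    genes: dict[str, GeneRecord],
) -> list[ContextAssignment]:
    """One context per system instance: an MGE class or chromosome.

    A system gets an MGE context iff ALL its component genes fall within
    a single MGE interval; partial overlaps fall back to chromosome and
    are flagged.
    """
    by_replicon: dict[tuple[str, str], list[MGEAnnotation]] = defaultdict(list)
    for m in mges_filtered:
        by_replicon[(m.genome_id, m.replicon_id)].append(m)

    out: list[ContextAssignment] = []
    for s in systems:
        comp = [genes[gid] for gid in s.component_gene_ids]
        candidates = by_replicon.get((s.genome_id, s.replicon_id), [])
        assigned = None
        partial = False
        for m in candidates:
            inside = sum(1 for g in comp if m.start <= g.start and g.end <= m.end)
            touches = sum(1 for g in comp if g.start <= m.end and m.start <= g.end)
            if inside == len(comp):
                assigned = m
                break
            if touches:
                partial = True
        if assigned is not None:
            out.append(
                ContextAssignment(
                    system_uid=s.system_uid, context=assigned.mge_class, mge_uid=assigned.mge_uid
                )
            )
        else:
            if partial:
                logger.info("system %s partially overlaps an MGE; assigned chromosome", s.system_uid)
            out.append(
                ContextAssignment(
                    system_uid=s.system_uid, context="chromosome", mge_uid=None, partial_overlap=partial
                )
            )
    return out


def compute_densities(
    hcads_contexts: list[ContextAssignment],
    hcads_system_genomes: dict[str, str],
    islands: list[DefenseIsland],
    manifest: list[GenomeManifest],
    mges_filtered: list[MGEAnnotation],
) -> list[DensityRecord]:
    """Per-genome densities of conserved systems and islands, per Mb.

    Scopes: ``whole_genome`` (instances / genome Mb), ``islands``
    (islands / genome Mb), and per integron class (instances assigned to
    that class / summed class span in Mb).  Zero counts are emitted;
    zero-span scopes are omitted with a log entry.
    """
    ctx_by_uid = {c.system_uid: c for c in hcads_contexts}
    count_by_genome: dict[str, int] = defaultdict(int)
    class_count: dict[tuple[str, str], int] = defaultdict(int)
    for uid, genome_id in hcads_system_genomes.items():
        count_by_genome[genome_id] += 1
        ctx = ctx_by_uid.get(uid)
        if ctx is not None and ctx.context != "chromosome":
            class_count[(genome_id, ctx.context)] += 1

    islands_by_genome: dict[str, int] = defaultdict(int)
    for isl in islands:
        islands_by_genome[isl.genome_id] += 1

    class_span: dict[tuple[str, str], int] = defaultdict(int)
    for m in mges_filtered:
        class_span[(m.genome_id, m.mge_class)] += m.end - m.start + 1

    out: list[DensityRecord] = []
    for m in manifest:
        size_mb = m.genome_size_bp / 1e6
        out.append(
            DensityRecord(
                genome_id=m.genome_id,
                scope="whole_genome",
                count=count_by_genome.get(m.genome_id, 0),
                span_mb=size_mb,
            )
        )
        out.append(
            DensityRecord(
                genome_id=m.genome_id,
                scope="islands",
                count=islands_by_genome.get(m.genome_id, 0),
                span_mb=size_mb,
            )
        )
        for scope in MGE_DENSITY_SCOPES:
            span_bp = class_span.get((m.genome_id, scope), 0)
            if span_bp == 0:
                if class_count.get((m.genome_id, scope), 0):
                    logger.warning(
                        "genome %s: %s density undefined (zero span)", m.genome_id, scope
                    )
                continue
            out.append(
                DensityRecord(
                    genome_id=m.genome_id,
                    scope=scope,
                    count=class_count.get((m.genome_id, scope), 0),
                    span_mb=span_bp / 1e6,
                )
            )
    return out
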