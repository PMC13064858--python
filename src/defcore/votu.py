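"""Viral contig clustering into vOTUs by greedy centroid ANI clustering.

Admission rule (per ordered comparison of a candidate member against the
current centroid): ANI >= ``votu_min_ani``, coverage of the candidate
member contig >= ``votu_min_tcov``, coverage of the centroid >=
``votu_min_qcov`` (0 by default, vacuous).  The member-coverage reading
follows the convention of greedy ANI clustering scripts that sort by
length and require the shorter (member) contig to be mostly covered;
this orientation is the main compatibility risk for full-scale
reproduction and is pinned down by the tests.

The built-in ANI backend is test-grade only: it assumes
substitution-only divergence, finds the dominant shared k-mer diagonal,
and counts matching columns on that single ungapped offset.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .models import ANIRecord, VOTU


def compute_contig_ani(
    contig_a: str, contig_b: str, name_a: str = "a", name_b: str = "b", k: int = 15
) -> ANIRecord | None:
    """Ungapped single-offset ANI estimate between two nucleotide sequences.

    Shared k-mers vote for a diagonal (offset); identity is counted
    column-by-column on the winning diagonal's overlap.  Returns None
    when the sequences share no k-mer (no detectable homology).
    Coverages are overlap span over each sequence's length
    (query = ``contig_a``, target = ``contig_b``).
    """
    if not contig_a or not contig_b:
        raise ValueError("empty contig sequence")
    a, b = contig_a.upper(), contig_b.upper()
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        index[b[j : j + k]].append(j)
    votes: dict[int, int] = defaultdict(int)
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            votes[i - j] += 1
    if not votes:
        return None
    offset = max(sorted(votes), key=lambda o: votes[o])
    # overlap of a[offset:] with b on this diagonal
    a_start = max(0, offset)
    b_start = max(0, -offset)
    span = min(len(a) - a_start, len(b) - b_start)
    if span <= 0:
        return None
    matches = sum(
        1 for t in range(span) if a[a_start + t] == b[b_start + t]
    )
    return ANIRecord(
        query_contig=name_a,
        target_contig=name_b,
        ani_pct=100.0 * matches / span,
        query_cov_frac=span / len(a),
        target_cov_frac=span / len(b),
    )


def build_ani_table(
    contigs: dict[str, str], k: int = 15
) -> list[ANIRecord]:
    """All ordered-pair ANI records with the built-in backend (sparse)."""
    names = sorted(contigs)
    out: list[ANIRecord] = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            rec = compute_contig_ani(contigs[na], contigs[nb], na, nb, k=k)
            if rec is None:
                continue
            out.append(rec)
            out.append(
                ANIRecord(
                    query_contig=nb,
                    target_contig=na,
                    ani_pct=rec.ani_pct,
                    query_cov_frac=rec.target_cov_frac,
                    target_cov_frac=rec.query_cov_frac,
                )
            )
    return out


def read_ani_table(path: str | Path) -> list[ANIRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    required = {"query", "target", "ani", "qcov", "tcov"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ANI table missing columns: {sorted(missing)}")
    return [
        ANIRecord(
            query_contig=row.query,
            target_contig=row.target,
            ani_pct=float(row.ani),
            query_cov_frac=float(row.qcov),
            target_cov_frac=float(row.tcov),
        )
        for row in df.itertuples(index=False)
    ]


def write_ani_table(records: list[ANIRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query": r.query_contig,
                "target": r.target_contig,
                "ani": r.ani_pct,
                "qcov": r.query_cov_frac,
                "tcov": r.target_cov_frac,
            }
            for r in records
        ],
        columns=["query", "target", "ani", "qcov", "tcov"],
    ).to_csv(path, sep="\t", index=False)


def cluster_votus(
    contig_lengths: dict[str, int],
    ani: list[ANIRecord],
    cfg: PipelineConfig,
) -> list[VOTU]:
    """Greedy centroid clustering.

    Contigs sorted by length descending (ties: lexicographic id); the
    longest unassigned contig seeds a cluster and recruits every
    unassigned contig admissible against it; missing ANI rows mean
    below-threshold.  Every contig ends up in exactly one vOTU.
    """
    for L in contig_lengths.values():
        if L <= 0:
            raise ValueError("contig lengths must be positive")
    lookup: dict[tuple[str, str], ANIRecord] = {}
    for r in ani:
        lookup[(r.query_contig, r.target_contig)] = r

    def admissible(member: str, centroid: str) -> bool:
        rec = lookup.get((member, centroid))
        if rec is not None:
            member_cov, centroid_cov = rec.query_cov_frac, rec.target_cov_frac
        else:
            rec = lookup.get((centroid, member))
            if rec is None:
                return False
            member_cov, centroid_cov = rec.target_cov_frac, rec.query_cov_frac
        return (
            rec.ani_pct >= cfg.votu_min_ani
            and member_cov >= cfg.votu_min_tcov
            and centroid_cov >= cfg.votu_min_qcov
        )

    order = sorted(contig_lengths, key=lambda c: (-contig_lengths[c], c))
    assigned: set[str] = set()
    votus: list[VOTU] = []
    for centroid in order:
        if centroid in assigned:
            continue
        members = [centroid]
        assigned.add(centroid)
        for c in order:
            if c in assigned:
                continue
            if admissible(c, centroid):
                members.append(c)
                assigned.add(c)
        votus.append(
            VOTU(
                votu_id=f"vOTU{len(votus):04d}",
                representative_contig=centroid,
                member_contigs=members,
            )
        )
    return votus


def write_votus(votus: list[VOTU], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "votu_id": v.votu_id,
                "representative": v.representative_contig,
                "n_members": len(v.member_contigs),
                "members": ",".join(v.member_contigs),
            }
            for v in votus
        ],
        columns=["votu_id", "representative", "n_members", "members"],
    ).to_csv(path, sep="\t", index=False)
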