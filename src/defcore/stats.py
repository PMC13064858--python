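"""Statistical tests applied to pipeline outputs.

Thin, contract-stable wrappers around scipy/statsmodels routines:
two-sided rank-sum comparison (exact null for small untied samples,
normal approximation with tie and continuity corrections otherwise),
per-family Fisher exact enrichment with Benjamini-Hochberg adjustment,
and tie-aware Spearman rank correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import TestResult


def mww_test(
    sample_a: list[float],
    sample_b: list[float],
    exact_max_n: int = 16,
) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact null by enumeration when n1+n2 <= ``exact_max_n`` and there
    are no ties; otherwise normal approximation with tie correction and
    continuity correction.  The U statistic of sample_a is reported.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mww_test requires nonempty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-{method}",
        n1=int(a.size),
        n2=int(b.size),
    )


def enrichment_test(
    family_counts: dict[str, tuple[int, int]],
    alpha: float = 0.05,
) -> list[TestResult]:
    """Per-family two-sided Fisher exact enrichment with BH adjustment.

    ``family_counts`` maps family -> (count inside, count outside) the
    stratum of interest (e.g. in-island vs outside).  Each family is
    tested on the 2x2 table [family vs all others] x [in vs out].
    All-zero tables are skipped.
    """
    families = sorted(family_counts)
    total_in = sum(v[0] for v in family_counts.values())
    total_out = sum(v[1] for v in family_counts.values())
    results: list[TestResult] = []
    for fam in families:
        fin, fout = family_counts[fam]
        table = np.array([[fin, fout], [total_in - fin, total_out - fout]])
        if table.sum() == 0:
            continue
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        results.append(
            TestResult(
                statistic=float(p),  # placeholder, replaced below
                p_value=float(p),
                method="fisher-exact",
                n1=int(fin + fout),
                n2=int(table[1].sum()),
                label=fam,
                estimate=float(odds) if np.isfinite(odds) else float("inf"),
            )
        )
    if not results:
        return []
    pvals = [r.p_value for r in results]
    _, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        TestResult(
            statistic=r.p_value,
            p_value=r.p_value,
            method=r.method,
            n1=r.n1,
            n2=r.n2,
            adjusted_p=float(min(a, 1.0)),
            label=r.label,
            estimate=r.estimate,
        )
        for r, a in zip(results, adj)
    ]


def correlate_density_size(
    densities: list[float], genome_sizes: list[float]
) -> TestResult:
    """Spearman rank correlation of density vs genome size (tie-aware)."""
    d = np.asarray(densities, dtype=float)
    s = np.asarray(genome_sizes, dtype=float)
    if d.size != s.size:
        raise ValueError("paired observations required")
    if d.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.all(d == d[0]) or np.all(s == s[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(d, s)
    return TestResult(
        statistic=float(rho),
        p_value=float(p),
        method="spearman",
        n1=int(d.size),
        n2=int(s.size),
        estimate=float(rho),
    )
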