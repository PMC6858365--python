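"""Paired nonparametric comparison of segmentation conditions.

Conditions are compared per matched case with the Wilcoxon signed-rank
test: zero differences are discarded (Wilcoxon's original treatment),
ties are mid-ranked, the p-value is two-sided — exact enumeration of the
2^n sign assignments for n <= 25 pairs, normal approximation with
continuity correction beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 25


@dataclass
class ComparisonResult:
    condition_a: str
    condition_b: str
    n_pairs: int
    statistic: float
    p_value: float


def wilcoxon_signed_rank(
    paired_a,
    paired_b,
    condition_a: str = "a",
    condition_b: str = "b",
) -> ComparisonResult:
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if nz.size < 5:
        raise ValueError(f"only {nz.size} nonzero differences; need >= 5")
    method = "exact" if nz.size <= EXACT_MAX_N else "approx"
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return ComparisonResult(
        condition_a=condition_a,
        condition_b=condition_b,
        n_pairs=int(nz.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def wilcoxon_exact_enumeration(paired_a, paired_b) -> tuple[float, float]:
    """Brute-force oracle: enumerate all sign assignments of the rank sum.

    Returns (W+, two-sided p). Independent of scipy; used to validate
    :func:`wilcoxon_signed_rank` at small n.
    """
    diffs = np.asarray(paired_a, dtype=np.float64) - np.asarray(paired_b, dtype=np.float64)
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences zero")
    ranks = sps.rankdata(np.abs(diffs))  # mid-ranks for ties
    w_plus = float(ranks[diffs > 0].sum())
    total = float(ranks.sum())
    # null distribution: each rank positive or negative with prob 1/2
    stats_all = np.zeros(1)
    for r in ranks:
        stats_all = np.concatenate([stats_all, stats_all + r])
    w_min_obs = min(w_plus, total - w_plus)
    w_min_all = np.minimum(stats_all, total - stats_all)
    p = float(np.mean(w_min_all <= w_min_obs + 1e-12))
    return w_plus, min(1.0, p)
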