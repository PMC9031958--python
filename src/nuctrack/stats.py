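"""Two-sample rank-based inference.

The population comparisons in this pipeline are nonparametric throughout,
because migration and morphology features are strongly skewed:

* :func:`wilcoxon_rank_sum` — location comparison on pooled mid-ranks.
  Small, tie-free samples (n1 + n2 <= 12) use exact enumeration over all
  C(N, n1) rank assignments; otherwise the normal approximation with
  continuity correction and tie-corrected variance is used.
* :func:`fligner_killeen` — scale (variance-heterogeneity) comparison:
  absolute deviations from each group's median are jointly ranked, mapped
  to normal scores a_r = Φ⁻¹(1/2 + r / (2(N+1))), and the between-group
  dispersion of mean scores is referred to a χ² distribution with k − 1
  degrees of freedom.

Both tests are two-sided.  Reported p-values are never truncated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control, norm, rankdata

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "fligner_killeen",
    "per_frame_variance_tests",
]

#: Largest pooled sample size for which the Wilcoxon null distribution is
#: enumerated exactly (tie-free data only).
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    group_summaries: dict = field(default_factory=dict)
    alternative: str = "two_sided"
    method: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _summaries(x: np.ndarray, y: np.ndarray) -> dict:
    return {
        "median_1": float(np.median(x)),
        "median_2": float(np.median(y)),
        "variance_1": float(np.var(x, ddof=1)) if len(x) > 1 else None,
        "variance_2": float(np.var(y, ddof=1)) if len(y) > 1 else None,
    }


def _as_arrays(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < min_n or len(y) < min_n:
        raise ValueError(f"each group needs >= {min_n} values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    The statistic W is the sum of the pooled mid-ranks of the first
    sample.  Exact enumeration of all rank assignments is used for tie-free
    pooled samples of at most 12 values; otherwise the normal approximation
    with continuity correction and tie-corrected variance.
    """
    x, y = _as_arrays(x, y, min_n=1)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    nn = n1 + n2
    if np.ptp(pooled) == 0:
        return TestResult(
            "wilcoxon_rank_sum",
            statistic=n1 * (nn + 1) / 2.0,
            p_value=1.0,
            n1=n1,
            n2=n2,
            group_summaries=_summaries(x, y),
            method="degenerate",
            degenerate=True,
        )
    ranks = rankdata(pooled)  # mid-ranks for ties
    w = float(ranks[:n1].sum())
    mu = n1 * (nn + 1) / 2.0

    has_ties = len(np.unique(pooled)) < nn
    if nn <= EXACT_ENUMERATION_MAX_N and not has_ties:
        dev = abs(w - mu)
        count = 0
        total = 0
        all_ranks = np.arange(1, nn + 1)
        for subset in combinations(all_ranks, n1):
            total += 1
            if abs(sum(subset) - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (nn * (nn - 1))
        var = n1 * n2 / 12.0 * (nn + 1 - tie_term)
        if var <= 0:
            p, method = 1.0, "degenerate"
        else:
            z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(abs(z)))
            method = "normal_approx"
    return TestResult(
        "wilcoxon_rank_sum",
        statistic=w,
        p_value=p,
        n1=n1,
        n2=n2,
        group_summaries=_summaries(x, y),
        method=method,
    )


def fligner_killeen(x, y) -> TestResult:
    """Two-sided Fligner–Killeen test of equal scale for two samples.

    Median-centers each group, jointly ranks the absolute deviations
    (mid-ranks for ties), transforms ranks to normal scores
    a_r = Φ⁻¹(1/2 + r/(2(N+1))), and compares the group means of the
    scores: X² = Σ_g n_g (ā_g − ā)² / V with V the sample variance of all
    scores, referred to χ²(k−1).
    """
    x, y = _as_arrays(x, y, min_n=2)
    n1, n2 = len(x), len(y)
    dev = np.concatenate([np.abs(x - np.median(x)), np.abs(y - np.median(y))])
    nn = n1 + n2
    ranks = rankdata(dev)
    scores = norm.ppf(0.5 + ranks / (2.0 * (nn + 1)))
    grand = scores.mean()
    v = scores.var(ddof=1)
    if v <= 0:  # all deviations tied (e.g. both groups constant)
        return TestResult(
            "fligner_killeen",
            statistic=0.0,
            p_value=1.0,
            n1=n1,
            n2=n2,
            group_summaries=_summaries(x, y),
            method="degenerate",
            degenerate=True,
        )
    means = np.array([scores[:n1].mean(), scores[n1:].mean()])
    stat = float((np.array([n1, n2]) * (means - grand) ** 2).sum() / v)
    p = float(chi2.sf(stat, df=1))
    return TestResult(
        "fligner_killeen",
        statistic=stat,
        p_value=p,
        n1=n1,
        n2=n2,
        group_summaries=_summaries(x, y),
        method="chi2",
    )


def per_frame_variance_tests(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    frames,
    value_col: str = "value",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Fligner–Killeen scale comparison at each requested frame.

    ``group_a`` / ``group_b`` are long tables with ``frame`` and
    ``value_col`` columns.  Frames absent from either group are skipped
    with a warning.  With ``adjust="bh"`` and more than two frames,
    Benjamini–Hochberg-adjusted p-values are added as ``p_adj``.
    """
    rows = []
    for f in frames:
        a = group_a.loc[group_a["frame"] == f, value_col].to_numpy(float)
        b = group_b.loc[group_b["frame"] == f, value_col].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"frame {f}: insufficient data in one group, skipped")
            continue
        res = fligner_killeen(a, b)
        rows.append(
            {
                "frame": f,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "variance_1": res.group_summaries["variance_1"],
                "variance_2": res.group_summaries["variance_2"],
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out) > 2:
        out["p_adj"] = false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out
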