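"""Shared statistical primitives: rank tests, FDR, summary intervals.

All tests are two-sided. Small samples without ties use exact null
distributions; larger or tied samples fall back to the normal approximation
with tie correction (scipy's behaviour, selected explicitly here so the
policy is documented in one place).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest combined sample size for which the exact Mann-Whitney null is used.
EXACT_MWU_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    p_adjusted: float | None = None


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact p-value when the combined sample size is at most
    ``EXACT_MWU_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= EXACT_MWU_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann-whitney-u", float(res.statistic), float(res.pvalue),
                      (x.size, y.size))


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon's original rule); a degenerate
    input with all differences zero is rejected.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    if x.size != y.size:
        raise ValueError(f"paired samples differ in length: {x.size} vs {y.size}")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; test undefined")
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    n_eff = int(np.count_nonzero(d))
    return TestResult("wilcoxon-signed-rank", float(res.statistic),
                      float(res.pvalue), (n_eff,))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


def summarize(values, z: float = 1.96) -> Summary:
    """Mean, sample SD (ddof=1) and normal-approximation CI (mean +/- z*SD/sqrt(n)).

    A single observation gets SD 0 and a degenerate interval.
    """
    v = _as_sample(values, "values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    half = z * sd / np.sqrt(v.size)
    return Summary(mean, sd, mean - half, mean + half, v.size)
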