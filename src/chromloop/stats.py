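"""Shared statistical primitives: BH adjustment, KS and Mann-Whitney tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    q_value: float | None = None


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_test(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(min(1.0, res.pvalue)))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with a degenerate-tie guard."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # all observations identical: U = n1*n2/2 by tie convention, no evidence
        return TestResult(x.size * y.size / 2.0, 1.0)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(float(res.statistic), float(min(1.0, res.pvalue)))
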