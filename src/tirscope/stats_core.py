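"""Shared statistical kernel: t-tests, Bonferroni correction, Spearman.

Positional nucleotide-frequency comparisons are run as two-sample t-tests on
per-gene 0/1 indicators (gene has base b at offset k), i.e. a comparison of
two Bernoulli proportions.  The two-sample test defaults to Welch's
(unequal-variance) form; a pooled-variance form is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "StatError",
    "ZeroVarianceError",
    "two_sample_t",
    "one_sample_t",
    "bonferroni",
    "spearman",
]


class StatError(ValueError):
    pass


class ZeroVarianceError(StatError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int | None = None
    m: int | None = None  # number of tests in the Bonferroni family
    significant_bonferroni: bool | None = None

    def with_bonferroni(self, m: int, alpha: float = 0.05) -> "TestResult":
        return TestResult(
            statistic=self.statistic,
            p_value=self.p_value,
            n1=self.n1,
            n2=self.n2,
            m=m,
            significant_bonferroni=bool(self.p_value < alpha / m),
        )


def _as_array(x: Sequence[float], name: str, min_n: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise StatError(f"{name} must be one-dimensional")
    if a.size < min_n:
        raise StatError(f"{name}: need at least {min_n} observations, got {a.size}")
    return a


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> TestResult:
    """Two-sided two-sample t-test (Welch by default).

    Degenerate rule: if both samples are constant and equal the statistic is 0
    and p is 1; any other zero-variance input raises
    :class:`ZeroVarianceError`.
    """
    a = _as_array(x, "x", 2)
    b = _as_array(y, "y", 2)
    const_a = np.ptp(a) == 0
    const_b = np.ptp(b) == 0
    if const_a or const_b:
        if const_a and const_b and a[0] == b[0]:
            return TestResult(statistic=0.0, p_value=1.0, n1=a.size, n2=b.size)
        raise ZeroVarianceError("zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=a.size,
        n2=b.size,
    )


def one_sample_t(x: Sequence[float], mu0: float) -> TestResult:
    """Two-sided one-sample t-test of H0: mean(x) = mu0."""
    a = _as_array(x, "x", 2)
    if np.ptp(a) == 0:
        if a[0] == mu0:
            return TestResult(statistic=0.0, p_value=1.0, n1=a.size)
        raise ZeroVarianceError("zero variance")
    res = stats.ttest_1samp(a, popmean=mu0)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), n1=a.size
    )


def bonferroni(
    p: Sequence[float], alpha: float = 0.05
) -> tuple[float, list[float]]:
    """Bonferroni correction over m = len(p) tests.

    Returns (threshold = alpha/m, adjusted p-values min(1, p*m)).
    """
    if not 0 < alpha < 1:
        raise StatError("alpha must be in (0, 1)")
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise StatError("empty p-value list")
    if np.any((arr < 0) | (arr > 1)):
        raise StatError("p-values must lie in [0, 1]")
    m = arr.size
    return alpha / m, [float(min(1.0, v * m)) for v in arr]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = _as_array(x, "x", 3)
    b = _as_array(y, "y", 3)
    if a.size != b.size:
        raise StatError("length mismatch")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("constant input")
    return float(stats.spearmanr(a, b).statistic)
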