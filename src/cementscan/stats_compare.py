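"""Summary statistics and the equal-variance two-sample t-test.

The measurement arms (optical photograph percentages vs CT slab
percentages, HU statistics with vs without the metal prosthesis) are
compared with the classical pooled-variance independent-samples Student
t-test with two-sided p-values.  Degenerate zero-variance inputs follow an
explicit contract: identical constant samples give t = 0, p = 1; constant
samples with different means give an infinite t and p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import round_half_up
from .errors import ValidationError

__all__ = ["TTestResult", "mean_sd", "student_t_independent"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    pooled_sd: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError("t-test needs df >= 1 (n1 + n2 >= 3)")
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p_value": self.p_value,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "pooled_sd": self.pooled_sd,
        }


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a sample SD")
    return float(np.mean(values)), float(np.std(values, ddof=1))


def format_mean_sd(values) -> str:
    """Report-style rendering: mean to 2 decimals, SD to 1 (half-up)."""
    m, s = mean_sd(values)
    mr = round_half_up(m, 2)
    sr = round_half_up(s, 1)
    return f"{mr:g} ({sr:g})"


def student_t_independent(a, b) -> TTestResult:
    """Pooled-variance (equal-variance) independent two-sample t-test."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    df = a.size + b.size - 2
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled_var = ((a.size - 1) * var_a + (b.size - 1) * var_b) / df
    pooled_sd = float(math.sqrt(pooled_var))
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if pooled_sd == 0.0:
        # Documented degenerate contract for zero-variance samples.
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean_a - mean_b), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t=t, df=df, p_value=p, mean_a=mean_a, mean_b=mean_b, pooled_sd=pooled_sd)
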