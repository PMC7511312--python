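"""Two-sample significance testing with star annotation.

Group comparisons throughout the pipeline use a two-sided two-sample t-test
and the conventional star code: ``**`` for p < 0.01, ``*`` for p < 0.05,
empty string otherwise (strict inequalities). The default variant pools the
variances (classical equal-variance test); Welch's unequal-variance test is
available via ``variant="welch"``. No multiple-testing correction is applied
by default; a Benjamini-Hochberg helper is provided as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "two_sample_t_test",
    "annotate_stars",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def annotate_stars(p: float) -> str:
    """Star annotation for a p-value: ``**`` < 0.01, ``*`` < 0.05, else ''."""
    if not (0 <= p <= 1):
        raise ValidationError(f"p-value out of range: {p!r}")
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_sample_t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "pooled",
    *,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided two-sample t-test.

    ``variant`` is ``"pooled"`` (equal-variance, default) or ``"welch"``.
    Each sample needs at least two observations. The sign of ``t`` follows
    ``mean(a) - mean(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if variant == "pooled":
        equal_var = True
        df = a.size + b.size - 2
    elif variant == "welch":
        equal_var = False
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        denom = va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        df = (va + vb) ** 2 / denom if denom > 0 else a.size + b.size - 2
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both samples, identical means
        t, p = 0.0, 1.0
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        t_statistic=t,
        degrees_of_freedom=float(df),
        p_value=p,
        stars=annotate_stars(p),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (extension; off by default)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values out of range")
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
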