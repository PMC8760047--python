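"""Effect sizes derived from model coefficients.

Group contrasts are expressed as Cohen's d computed from the coefficient's
t statistic with the unequal-group-size correction,

    d = t * (n1 + n2) / (sqrt(DF) * sqrt(n1 * n2)),

and continuous associations as the partial correlation recovered from t and
the denominator DF, r = t / sqrt(t^2 + DF). Confidence intervals follow the
standard large-sample forms: for d, a normal interval with
SE_d = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))); for r, the Fisher
z-transform with effective sample size DF + 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class EffectSize:
    kind: str  # "cohens_d" | "partial_r"
    value: float
    ci_low: float
    ci_high: float
    b: float
    se_b: float
    df: float
    n1: int | None = None
    n2: int | None = None

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Report-style half-up rounding of (value, ci_low, ci_high)."""
        q = Decimal(10) ** -ndigits
        return tuple(
            float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))
            for v in (self.value, self.ci_low, self.ci_high)
        )


def cohens_d(b: float, se_b: float, df: float, n1: int, n2: int) -> EffectSize:
    """Cohen's d for a two-group contrast coefficient."""
    if se_b <= 0:
        raise ValueError("se_b must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes n1, n2 must be >= 2")
    t = b / se_b
    d = t * (n1 + n2) / (np.sqrt(df) * np.sqrt(n1 * n2))
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    return EffectSize(
        kind="cohens_d", value=float(d),
        ci_low=float(d - 1.96 * se_d), ci_high=float(d + 1.96 * se_d),
        b=b, se_b=se_b, df=df, n1=n1, n2=n2,
    )


def partial_r(b: float, se_b: float, df: float) -> EffectSize:
    """Partial correlation recovered from a coefficient's t statistic."""
    if se_b <= 0:
        raise ValueError("se_b must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = b / se_b
    r = t / np.sqrt(t * t + df)
    n_eff = df + 2.0
    z = np.arctanh(r)
    se_z = 1.0 / np.sqrt(n_eff - 3.0)
    return EffectSize(
        kind="partial_r", value=float(r),
        ci_low=float(np.tanh(z - 1.96 * se_z)),
        ci_high=float(np.tanh(z + 1.96 * se_z)),
        b=b, se_b=se_b, df=df,
    )
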