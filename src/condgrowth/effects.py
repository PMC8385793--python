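"""Balance diagnostics between cohort subgroups.

Cohort studies with incomplete follow-up routinely compare children with
and without complete measurements.  Rather than p-values (meaningless at
n ~ 10^4), the comparison is summarized by effect sizes: the phi
coefficient for 2x2 tables, Cramér's V for r x c tables (Pearson
chi-square, no continuity correction) and the point-biserial r derived
from a pooled-variance Student t for numeric variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeResult",
    "phi_from_2x2",
    "cramers_v",
    "r_from_summaries",
    "balance_table",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EffectSizeResult:
    variable: str
    kind: str  # "phi" | "cramers_v" | "r"
    value: float
    n1: int
    n2: int

    @property
    def rounded(self) -> float:
        return round_half_up(self.value, 2)


def phi_from_2x2(a, b, c, d) -> float:
    """Phi coefficient of the 2x2 table [[a, b], [c, d]].

    Equals sqrt(chi2 / n) for the uncorrected Pearson chi-square:
    |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = (float(v) for v in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("phi undefined: a margin of the 2x2 table is zero")
    return abs(a * d - b * c) / np.sqrt(margins)


def cramers_v(table) -> float:
    """Cramér's V of an r x c count table: sqrt(chi2 / (n * min(r-1, c-1))).

    Pearson chi-square without continuity correction; reduces to phi for a
    2x2 table.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("Cramér's V undefined: zero margin")
    chi2 = stats.chi2_contingency(arr, correction=False)[0]
    n = arr.sum()
    k = min(arr.shape[0] - 1, arr.shape[1] - 1)
    return float(np.sqrt(chi2 / (n * k)))


def r_from_summaries(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Point-biserial r from two groups' summary statistics.

    Classic pooled-variance Student t; r = sqrt(t^2 / (t^2 + df)) with
    df = n1 + n2 - 2.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("zero pooled variance")
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return float(np.sqrt(t**2 / (t**2 + df)))


#: (column, kind) pairs of the default balance table; kind "binary" and
#: "categorical" use phi/Cramér's V, "numeric" uses r.
BALANCE_VARIABLES = [
    ("gestational_age", "numeric"),
    ("birth_length", "numeric"),
    ("birth_weight", "numeric"),
    ("parity", "binary"),
    ("maternal_age", "numeric"),
    ("maternal_smoking", "binary"),
    ("maternal_education", "categorical"),
    ("paternal_education", "categorical"),
    ("family_income", "categorical"),
    ("home_speech_stimulation", "binary"),
    ("delay_6", "binary"),
    ("delay_12", "binary"),
]


def balance_table(df: pd.DataFrame, split: pd.Series, variables=None) -> pd.DataFrame:
    """Compare the two groups defined by boolean ``split`` on each variable.

    Missing values are excluded per variable (group sizes therefore vary by
    row, as in published baseline tables).  Returns a frame with the group
    summaries, per-group missing counts and the two-decimal effect size.
    """
    if variables is None:
        variables = [(v, k) for v, k in BALANCE_VARIABLES if v in df.columns]
    split = split.astype(bool)
    g1, g2 = df[split], df[~split]
    rows = []
    for var, kind in variables:
        s1, s2 = g1[var], g2[var]
        a1, a2 = s1.dropna(), s2.dropna()
        if kind == "numeric":
            value = r_from_summaries(a1.mean(), a1.std(ddof=1), len(a1), a2.mean(), a2.std(ddof=1), len(a2))
            summary1 = f"{a1.mean():.1f} ({a1.std(ddof=1):.1f})"
            summary2 = f"{a2.mean():.1f} ({a2.std(ddof=1):.1f})"
            es_kind = "r"
        else:
            levels = sorted(set(a1.unique()) | set(a2.unique()))
            counts = np.array([[(a1 == lev).sum() for lev in levels], [(a2 == lev).sum() for lev in levels]]).T
            if counts.shape[0] == 2:
                value = phi_from_2x2(*counts.T.ravel())
                es_kind = "phi"
            else:
                value = cramers_v(counts.T)
                es_kind = "cramers_v"
            summary1 = "; ".join(f"{lev}: {(a1 == lev).sum()}" for lev in levels)
            summary2 = "; ".join(f"{lev}: {(a2 == lev).sum()}" for lev in levels)
        rows.append(
            {
                "variable": var,
                "kind": es_kind,
                "group1": summary1,
                "group2": summary2,
                "missing1": int(s1.isna().sum()),
                "missing2": int(s2.isna().sum()),
                "n1": int(len(a1)),
                "n2": int(len(a2)),
                "effect_size": round_half_up(value, 2),
            }
        )
    return pd.DataFrame(rows)
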