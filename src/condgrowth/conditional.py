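"""Conditional growth variables by sequential residualization.

Length and weight trajectories are strongly autocorrelated, so raw interval
gains cannot separate linear growth from weight gain.  Conditional growth
modelling removes the overlap by regression: the *conditional length* at an
age is the child's length z-score residualized on every earlier length and
weight z-score, and the *conditional relative weight* is the weight z-score
residualized on the concurrent length plus every earlier size.  Birth
length and weight z-scores act as the conditional variables at birth (there
is nothing earlier to regress on).  Each residual is standardized to unit
variance within the estimation sample, so downstream relative risks are per
1 SD.  By construction the variables are mutually uncorrelated, which lets
them enter one multivariable model without collinearity.

Timepoint sets ("model variants") reflect which checkups a child attended:

========  ======================  =========================================
variant   timepoints (months)     note
========  ======================  =========================================
1         0, 4, 7, 10             full trajectory
2         0, 4, 7                 no 10-month checkup
3         0, 4, 10                no 7-month checkup; the 10-month
                                  conditionals regress on birth and 4 months
"birth4"  0, 4                    used for the 6-month outcome models
========  ======================  =========================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError

__all__ = [
    "VARIANT_TIMEPOINTS",
    "conditional_length",
    "conditional_relative_weight",
    "build_conditional_set",
    "ConditionalGrowthModel",
    "ConditionalGrowthResults",
]

VARIANT_TIMEPOINTS = {1: (0, 4, 7, 10), 2: (0, 4, 7), 3: (0, 4, 10), "birth4": (0, 4)}


def zcol(measure: str, month: int) -> str:
    return f"z_{measure}_{month}"


def conditional_name(measure: str, month: int) -> str:
    if month == 0:
        return "length0" if measure == "length" else "weight0"
    return (f"cLength{month}" if measure == "length" else f"crWeight{month}")


def _residualize(y: np.ndarray, X: np.ndarray, standardize: bool = True):
    """OLS residuals of ``y`` on ``[1, X]``, optionally scaled to unit SD.

    Returns ``(residuals, coef)``.  Raises :class:`EstimationError` on a
    rank-deficient design or too small a sample; a perfect fit (zero
    residual variance) yields all-zero residuals with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if n <= p + 1:
        raise EstimationError(f"estimation sample has {n} rows for {p} regressors")
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise EstimationError("rank-deficient design in residualization")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    if standardize:
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            warnings.warn("degenerate residualization: zero residual variance", stacklevel=2)
            return np.zeros_like(resid), coef
        resid = resid / sd
    return resid, coef


def conditional_length(current_length_z, previous):
    """Standardized residual of current length z on all earlier sizes.

    ``previous`` is an ``(n, p)`` array (or sequence of columns) of every
    earlier length and weight z-score.  A positive value means linear
    growth faster than predicted from the child's history.
    """
    prev = np.column_stack(previous) if isinstance(previous, (list, tuple)) else np.asarray(previous)
    resid, _ = _residualize(np.asarray(current_length_z, dtype=float), prev)
    return resid


def conditional_relative_weight(current_weight_z, current_length_z, previous):
    """Standardized residual of current weight z on concurrent length plus
    all earlier sizes — weight gain net of linear growth."""
    prev = np.column_stack(previous) if isinstance(previous, (list, tuple)) else np.asarray(previous)
    if prev.ndim == 1:
        prev = prev[:, None]
    X = np.column_stack([np.asarray(current_length_z, dtype=float), prev])
    resid, _ = _residualize(np.asarray(current_weight_z, dtype=float), X)
    return resid


def _regressor_sets(variant):
    """Yield (target measure, month, list of regressor (measure, month))."""
    timepoints = VARIANT_TIMEPOINTS[variant]
    for k, month in enumerate(timepoints):
        if month == 0:
            continue
        previous = [(m, t) for t in timepoints[:k] for m in ("length", "weight")]
        yield "length", month, previous
        yield "weight", month, [("length", month)] + previous


def build_conditional_set(zscores: pd.DataFrame, variant, standardize_birth: bool = True) -> pd.DataFrame:
    """Compute the conditional variables for one estimation sample.

    ``zscores`` must hold complete columns ``z_length_<m>`` / ``z_weight_<m>``
    for every timepoint of the variant (complete cases; callers subset by
    sex stratum first — the residualizations are meant to be fit within
    sex).  Returns a frame indexed like ``zscores`` with columns
    ``length0, weight0`` and ``cLength<m>/crWeight<m>`` per later timepoint.
    """
    if variant not in VARIANT_TIMEPOINTS:
        raise ValueError(f"unknown model variant {variant!r}")
    needed = [zcol(m, t) for t in VARIANT_TIMEPOINTS[variant] for m in ("length", "weight")]
    missing = [c for c in needed if c not in zscores.columns]
    if missing:
        raise ValueError(f"zscores missing columns: {missing}")
    if len(zscores) == 0:
        raise EstimationError("empty estimation sample")
    if zscores[needed].isna().any().any():
        raise ValueError("conditional variables require complete cases; drop missing rows first")

    out = pd.DataFrame(index=zscores.index)
    for measure in ("length", "weight"):
        z = zscores[zcol(measure, 0)].to_numpy(dtype=float)
        if standardize_birth:
            sd = z.std(ddof=1)
            if sd < 1e-12:
                raise EstimationError("zero variance in birth z-scores")
            z = (z - z.mean()) / sd
        out[conditional_name(measure, 0)] = z
    for measure, month, previous in _regressor_sets(variant):
        y = zscores[zcol(measure, month)].to_numpy(dtype=float)
        X = np.column_stack([zscores[zcol(m, t)].to_numpy(dtype=float) for m, t in previous])
        if measure == "weight":
            # concurrent length is already the first entry of `previous`
            resid, _ = _residualize(y, X)
        else:
            resid, _ = _residualize(y, X)
        out[conditional_name(measure, month)] = resid
    return out


@dataclass
class ConditionalGrowthResults:
    """Fitted conditional growth variables for one stratum/variant."""

    conditionals: pd.DataFrame
    variant: object
    sex: str | None
    n_obs: int

    def summary(self) -> pd.DataFrame:
        """Means, SDs and the maximum absolute pairwise correlation —
        diagnostics that the residualization behaved (means ~0, SDs ~1,
        post-birth conditionals uncorrelated; only length0-weight0, the
        raw birth z-scores, retain their natural correlation)."""
        desc = self.conditionals.agg(["mean", "std"]).T
        corr = self.conditionals.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        desc["max_abs_corr"] = np.abs(corr).max(axis=1)
        desc.index.name = "variable"
        return desc


class ConditionalGrowthModel:
    """Sequential residualization model over a cohort's z-score frame.

    Parameters
    ----------
    zscores : DataFrame with ``z_length_<m>`` / ``z_weight_<m>`` columns.
    variant : 1, 2, 3 or "birth4" — which timepoints are available.
    sex : optional stratum label carried through to the results.

    Rows with any missing required column are dropped (complete-case fit).
    """

    def __init__(self, zscores: pd.DataFrame, variant=1, sex: str | None = None):
        if variant not in VARIANT_TIMEPOINTS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self.sex = sex
        needed = [zcol(m, t) for t in VARIANT_TIMEPOINTS[variant] for m in ("length", "weight")]
        missing = [c for c in needed if c not in zscores.columns]
        if missing:
            raise ValueError(f"zscores missing columns: {missing}")
        self.data = zscores.dropna(subset=needed)

    def fit(self) -> ConditionalGrowthResults:
        conditionals = build_conditional_set(self.data, self.variant)
        return ConditionalGrowthResults(
            conditionals=conditionals, variant=self.variant, sex=self.sex, n_obs=len(conditionals)
        )
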