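"""LMS growth-reference z-scores for infant length and weight.

A growth reference parameterizes the distribution of a body measurement at
each age by three numbers: the Box-Cox power ``L`` (skewness), the median
``M`` and the coefficient of variation ``S``.  A raw measurement ``x`` is
converted to a z-score by

    z = ((x / M)**L - 1) / (L * S)        (L != 0)
    z = ln(x / M) / S                     (L == 0)

Birth rows may additionally be stratified by the mother's parity and the
child's completed gestational week, mirroring national newborn standards
that condition birth size on both; post-natal rows are stratified by sex
and age only.

The published national standards are not redistributable, so the package
generates a *synthetic* reference table (:func:`synthetic_reference`) with
smooth, plausible median curves.  Any user-supplied table in the same CSV
schema (columns ``sex, measure, age_days, parity, gestational_week, L, M,
S``; the literal ``any`` marks unstratified rows) is accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "lms_zscore",
    "lms_inverse",
    "GrowthReference",
    "synthetic_reference",
    "zscore_child",
]

# Below this |L| the power form is numerically unstable; use the log limit.
_L_EPS = 1e-7

SEXES = ("boy", "girl")
MEASURES = ("length", "weight")
PARITIES = ("primipara", "multipara")
#: completed gestational weeks covered by the birth strata of the synthetic table
GESTATIONAL_WEEKS = (37, 38, 39, 40, 41)

REFERENCE_COLUMNS = [
    "sex",
    "measure",
    "age_days",
    "parity",
    "gestational_week",
    "L",
    "M",
    "S",
]


def lms_zscore(x, L, M, S):
    """Convert a measurement to an LMS z-score.

    Parameters may be scalars or broadcastable arrays.  ``x``, ``M`` and
    ``S`` must be strictly positive.  The transform is continuous in ``L``
    at zero: for ``|L| < 1e-7`` the logarithmic limit is used.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("lms_zscore requires x > 0, M > 0 and S > 0")
    log_ratio = np.log(x / M)
    # expm1 keeps the power form accurate down to L -> 0 (no cancellation)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = np.expm1(L * log_ratio) / (L * S)
    log_form = log_ratio / S
    z = np.where(np.abs(L) < _L_EPS, log_form, power)
    return z if z.ndim else float(z)


def lms_inverse(z, L, M, S):
    """Invert :func:`lms_zscore`: map a z-score back to the raw scale.

    For ``L != 0`` the inverse ``M * (1 + L*S*z)**(1/L)`` exists only while
    ``1 + L*S*z > 0``; arguments outside that range raise ``ValueError``.
    """
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("lms_inverse requires M > 0 and S > 0")
    base = L * S * z
    power_valid = (np.abs(L) < _L_EPS) | (base > -1.0)
    if not np.all(power_valid):
        raise ValueError("z outside the invertible range of the LMS transform")
    with np.errstate(divide="ignore", invalid="ignore"):
        power = M * np.exp(np.log1p(np.where(power_valid, base, 0.0)) / L)
    log_form = M * np.exp(S * z)
    x = np.where(np.abs(L) < _L_EPS, log_form, power)
    return x if x.ndim else float(x)


def _check_reference(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    table = table.copy()
    table["gestational_week"] = table["gestational_week"].astype(str)
    if (table["M"] <= 0).any() or (table["S"] <= 0).any():
        raise ValueError("reference table requires M > 0 and S > 0")
    stratified = (table["parity"] != "any") | (table["gestational_week"] != "any")
    if (stratified & (table["age_days"] != 0)).any():
        raise ValueError("parity/gestational_week stratification is allowed only at age 0")
    keys = ["sex", "measure", "age_days", "parity", "gestational_week"]
    if table.duplicated(keys).any():
        raise ValueError("duplicate reference rows on " + ", ".join(keys))
    return table


class GrowthReference:
    """Lookup of LMS parameters by sex, measure, age and birth stratum.

    Age lookup: the row nearest in age wins if it lies within
    ``age_tolerance_days`` (default 15) of the requested age; otherwise
    ``L``, ``M`` and ``S`` are linearly interpolated between the flanking
    tabulated ages.  Requests outside the tabulated range use the nearest
    edge row (no extrapolation of the curves).
    """

    def __init__(self, table: pd.DataFrame, age_tolerance_days: float = 15.0):
        self.table = _check_reference(table)
        self.age_tolerance_days = float(age_tolerance_days)
        # pre-split per (sex, measure, parity, gestational_week) with sorted ages
        self._grids: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, grp in self.table.groupby(["sex", "measure", "parity", "gestational_week"], sort=False):
            grp = grp.sort_values("age_days")
            self._grids[key] = (
                grp["age_days"].to_numpy(dtype=float),
                grp["L"].to_numpy(dtype=float),
                grp["M"].to_numpy(dtype=float),
                grp["S"].to_numpy(dtype=float),
            )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GrowthReference":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def _grid(self, sex, measure, parity, gestational_week):
        key = (sex, measure, str(parity), str(gestational_week))
        if key not in self._grids:
            raise KeyError(
                "no reference rows for stratum "
                f"(sex={sex!r}, measure={measure!r}, parity={parity!r}, "
                f"gestational_week={gestational_week!r})"
            )
        return self._grids[key]

    def lookup(self, sex, measure, age_days, parity="any", gestational_week="any"):
        """Return arrays ``(L, M, S)`` for the requested ages.

        ``age_days`` may be a scalar or an array.  Birth strata are
        addressed with ``parity`` and ``gestational_week``; post-natal rows
        with the default ``"any"``.
        """
        ages, L, M, S = self._grid(sex, measure, parity, gestational_week)
        q = np.atleast_1d(np.asarray(age_days, dtype=float))
        idx = np.searchsorted(ages, q)
        lo = np.clip(idx - 1, 0, len(ages) - 1)
        hi = np.clip(idx, 0, len(ages) - 1)
        nearest = np.where(np.abs(ages[lo] - q) <= np.abs(ages[hi] - q), lo, hi)
        use_nearest = np.abs(ages[nearest] - q) <= self.age_tolerance_days
        outL = np.interp(q, ages, L)
        outM = np.interp(q, ages, M)
        outS = np.interp(q, ages, S)
        outL = np.where(use_nearest, L[nearest], outL)
        outM = np.where(use_nearest, M[nearest], outM)
        outS = np.where(use_nearest, S[nearest], outS)
        if np.isscalar(age_days) or np.ndim(age_days) == 0:
            return float(outL[0]), float(outM[0]), float(outS[0])
        return outL, outM, outS

    def zscore(self, x, sex, measure, age_days, parity="any", gestational_week="any"):
        L, M, S = self.lookup(sex, measure, age_days, parity, gestational_week)
        return lms_zscore(x, L, M, S)

    def inverse(self, z, sex, measure, age_days, parity="any", gestational_week="any"):
        L, M, S = self.lookup(sex, measure, age_days, parity, gestational_week)
        return lms_inverse(z, L, M, S)


# ---------------------------------------------------------------------------
# synthetic reference table
# ---------------------------------------------------------------------------

# Median growth curves: M(t) = a + b * (1 - exp(-t / tau)) with t in days.
# Values chosen to resemble first-year growth of Japanese term infants
# (birth ~49 cm / ~3.0 kg, ~63 cm / ~6.9 kg at 4 months).
_LENGTH_CURVE = {"boy": (49.0, 26.0, 160.0), "girl": (48.4, 25.2, 160.0)}
_WEIGHT_CURVE = {"boy": (3050.0, 6500.0, 140.0), "girl": (2960.0, 6000.0, 140.0)}

#: fixed Box-Cox powers of the synthetic table
_L_LENGTH = 1.0
_L_WEIGHT = 0.35

# per completed gestational week relative change in the birth median
_GW_LENGTH_SLOPE = 0.009
_GW_WEIGHT_SLOPE = 0.055
# multipara newborns run slightly larger
_PARITY_LENGTH = {"primipara": -0.0015, "multipara": 0.0015}
_PARITY_WEIGHT = {"primipara": -0.008, "multipara": 0.008}

_AGE_GRID = (0, 30, 61, 91, 122, 152, 183, 213, 244, 274, 304, 335, 365)


def _median(measure: str, sex: str, age_days: float) -> float:
    a, b, tau = (_LENGTH_CURVE if measure == "length" else _WEIGHT_CURVE)[sex]
    return a + b * (1.0 - np.exp(-age_days / tau))


def _cv(measure: str, age_days: float) -> float:
    if measure == "length":
        return 0.034 + 0.006 * np.exp(-age_days / 100.0)
    return 0.105 + 0.013 * np.exp(-age_days / 150.0)


def synthetic_reference() -> GrowthReference:
    """Build the package's synthetic LMS reference table.

    This is a stand-in with smooth plausible curves, not the published
    national standards.  Birth rows (age 0) are stratified by parity and
    completed gestational week 37-41; later ages carry the ``any`` stratum.
    """
    rows = []
    for sex in SEXES:
        for measure in MEASURES:
            L = _L_LENGTH if measure == "length" else _L_WEIGHT
            for age in _AGE_GRID:
                M = _median(measure, sex, age)
                S = _cv(measure, age)
                if age == 0:
                    gw_slope = _GW_LENGTH_SLOPE if measure == "length" else _GW_WEIGHT_SLOPE
                    par_eff = _PARITY_LENGTH if measure == "length" else _PARITY_WEIGHT
                    for parity in PARITIES:
                        for gw in GESTATIONAL_WEEKS:
                            # gw + 0.5 centres the stratum on the middle of the week
                            m = M * (1.0 + gw_slope * (gw + 0.5 - 39.5)) * (1.0 + par_eff[parity])
                            rows.append((sex, measure, age, parity, str(gw), L, m, S))
                else:
                    rows.append((sex, measure, age, "any", "any", L, M, S))
    table = pd.DataFrame(rows, columns=REFERENCE_COLUMNS)
    return GrowthReference(table)


def zscore_child(sex, parity, gestational_age_weeks, values_by_age, ref: GrowthReference):
    """Z-score one child's (length, weight) values at a set of ages.

    ``values_by_age`` maps age in days to a ``(length_cm, weight_g)`` pair
    where either element may be ``None``.  Birth (age 0) is scored in the
    parity x completed-gestational-week stratum; other ages in the sex x
    age stratum.  Returns ``{age: (z_length, z_weight)}`` with ``None``
    propagated for absent inputs.
    """
    gw = int(np.floor(gestational_age_weeks))
    out = {}
    for age, (length, weight) in values_by_age.items():
        zs = []
        for measure, value in (("length", length), ("weight", weight)):
            if value is None or (isinstance(value, float) and np.isnan(value)):
                zs.append(None)
                continue
            if age == 0:
                L, M, S = ref.lookup(sex, measure, 0, parity, gw)
            else:
                L, M, S = ref.lookup(sex, measure, age)
            zs.append(float(lms_zscore(value, L, M, S)))
        out[age] = tuple(zs)
    return out


def zscore_frame(df: pd.DataFrame, x: pd.DataFrame, ref: GrowthReference, month_days=None) -> pd.DataFrame:
    """Cohort-wide z-scoring of the timeline output.

    ``df`` supplies ``sex``, ``parity`` and ``gestational_age``; ``x`` the
    ``x_<measure>_<month>`` columns from the timeline stage; ``month_days``
    maps month label to the age in days used for reference lookup
    (default {0: 0, 4: 122, 7: 213, 10: 304}).  Birth columns are scored
    within the parity x completed-week stratum.  Returns
    ``z_<measure>_<month>`` columns with NaN propagated.
    """
    if month_days is None:
        month_days = {0: 0, 4: 122, 7: 213, 10: 304}
    sex = df["sex"].to_numpy()
    parity = df["parity"].to_numpy()
    gw = np.floor(df["gestational_age"].to_numpy(dtype=float)).astype(int)
    out = pd.DataFrame(index=df.index)
    for col in x.columns:
        _, measure, month = col.split("_")
        month = int(month)
        vals = x[col].to_numpy(dtype=float)
        z = np.full(len(vals), np.nan)
        present = ~np.isnan(vals)
        if month == 0:
            for s in np.unique(sex):
                for p in np.unique(parity):
                    for week in np.unique(gw):
                        m = present & (sex == s) & (parity == p) & (gw == week)
                        if not m.any():
                            continue
                        L, M, S = ref.lookup(s, measure, 0, p, week)
                        z[m] = lms_zscore(vals[m], L, M, S)
        else:
            age = month_days[month]
            for s in np.unique(sex):
                m = present & (sex == s)
                if not m.any():
                    continue
                L, M, S = ref.lookup(s, measure, age)
                z[m] = lms_zscore(vals[m], L, M, S)
        out[f"z_{measure}_{month}"] = z
    return out
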