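"""Align irregularly timed checkup measurements to target ages.

Infant checkups happen near, not at, the nominal 4-, 7- and 10-month ages,
so each measurement series is carried to the target ages by piecewise
linear interpolation between the two observations flanking the target, or
linear extrapolation from the nearest two observations when the target
falls outside the observed range.  A value is produced only when the
nearest observation lies within an admissibility window of the target
(default 92 days), which stops e.g. a birth-only child from being
extrapolated to 10 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TargetAges", "measurement_at_age", "build_timeline", "timeline_frame"]

#: mean calendar month length used to place the default target ages
MONTH_DAYS = 30.4375

DEFAULT_WINDOW_DAYS = 92.0


def _month_to_days(months: float, month_length: float = MONTH_DAYS) -> int:
    return int(round(months * month_length))


@dataclass(frozen=True)
class TargetAges:
    """Ordered target ages in days; the first is birth (0)."""

    ages: tuple = (0, _month_to_days(4), _month_to_days(7), _month_to_days(10))

    def __post_init__(self):
        ages = tuple(self.ages)
        if len(ages) == 0 or ages[0] != 0:
            raise ValueError("target ages must start at birth (0 days)")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("target ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)

    @classmethod
    def from_months(cls, months=(0, 4, 7, 10), month_length: float = MONTH_DAYS):
        return cls(tuple(_month_to_days(m, month_length) for m in months))


def measurement_at_age(observations, target, window=DEFAULT_WINDOW_DAYS):
    """Interpolate/extrapolate a measurement series to ``target`` days.

    ``observations`` is a sequence of ``(age_days, value)`` with strictly
    increasing ages and positive values.  Returns ``None`` when no
    admissible estimate exists: fewer than two observations (unless a lone
    observation sits within one day of the target) or nearest observation
    farther than ``window`` days from the target.
    """
    obs = [(float(a), float(v)) for a, v in observations if v is not None and not np.isnan(v)]
    ages = np.array([a for a, _ in obs])
    vals = np.array([v for _, v in obs])
    if np.any(np.diff(ages) <= 0):
        raise ValueError("observation ages must be strictly increasing")
    if len(obs) == 0:
        return None
    nearest = np.abs(ages - target).min()
    if len(obs) == 1:
        return float(vals[0]) if nearest <= 1.0 else None
    if nearest > window:
        return None
    if target <= ages[0]:
        i, j = 0, 1
    elif target >= ages[-1]:
        i, j = len(ages) - 2, len(ages) - 1
    else:
        j = int(np.searchsorted(ages, target))
        i = j - 1
    slope = (vals[j] - vals[i]) / (ages[j] - ages[i])
    return float(vals[i] + slope * (target - ages[i]))


def build_timeline(record, targets: TargetAges = TargetAges(), window=DEFAULT_WINDOW_DAYS):
    """Carry one child's length/weight series to the target ages.

    ``record`` needs ``birth_length``, ``birth_weight`` and ``checkups``
    (list of ``(age_days, length_cm, weight_g)``, either measurement
    possibly ``None``).  Birth values pass through untouched.  Returns
    ``{age: (length, weight)}`` with ``None`` for inadmissible targets.
    """
    lengths = [(0.0, record.birth_length)] if record.birth_length is not None else []
    weights = [(0.0, record.birth_weight)] if record.birth_weight is not None else []
    for age, length, weight in sorted(record.checkups):
        if length is not None and not (isinstance(length, float) and np.isnan(length)):
            lengths.append((age, length))
        if weight is not None and not (isinstance(weight, float) and np.isnan(weight)):
            weights.append((age, weight))
    out = {}
    for t in targets.ages:
        if t == 0:
            out[0] = (record.birth_length, record.birth_weight)
        else:
            out[t] = (
                measurement_at_age(lengths, t, window),
                measurement_at_age(weights, t, window),
            )
    return out


# month label -> default target age in days, aligned with TargetAges()
TARGET_MONTHS = (0, 4, 7, 10)


def _interp_rows(ages: np.ndarray, vals: np.ndarray, target: float, window: float) -> np.ndarray:
    """Vectorized measurement_at_age over rows of (n, k) observation arrays.

    Columns must be in increasing-age order per row; missing observations
    are NaN in either array.  Returns an (n,) array with NaN where no
    admissible estimate exists.  Semantics match measurement_at_age row by
    row (tested against it).
    """
    ages = np.asarray(ages, dtype=float)
    vals = np.asarray(vals, dtype=float)
    mask = ~np.isnan(ages) & ~np.isnan(vals)
    a = np.where(mask, ages, np.nan)
    out = np.full(len(a), np.nan)
    count = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        nearest = np.nanmin(np.abs(a - target), axis=1, initial=np.inf, where=mask)
    # lone observation: pass through only at the target (+-1 day)
    lone = count == 1
    if lone.any():
        idx = np.argmax(mask[lone], axis=1)
        ok = nearest[lone] <= 1.0
        res = vals[lone, idx]
        res[~ok] = np.nan
        out[lone] = res
    multi = (count >= 2) & (nearest <= window)
    if multi.any():
        rows = np.flatnonzero(multi)
        am, vm, mm = a[rows], vals[rows], mask[rows]
        # number of existing obs strictly below target, clipped to [1, m-1]
        below = ((am < target) & mm).sum(axis=1)
        m = mm.sum(axis=1)
        j_rank = np.clip(below, 1, m - 1)  # rank among existing obs
        i_rank = j_rank - 1
        order = np.argsort(np.where(mm, am, np.inf), axis=1, kind="stable")
        ridx = np.arange(len(rows))
        ci = order[ridx, i_rank]
        cj = order[ridx, j_rank]
        ai, aj = am[ridx, ci], am[ridx, cj]
        vi, vj = vm[ridx, ci], vm[ridx, cj]
        out[rows] = vi + (vj - vi) * (target - ai) / (aj - ai)
    return out


def timeline_frame(df: pd.DataFrame, targets: TargetAges = TargetAges(), window=DEFAULT_WINDOW_DAYS) -> pd.DataFrame:
    """Cohort-wide timeline: raw length/weight at the target ages.

    ``df`` uses the wide cohort schema (``birth_length``, ``birth_weight``,
    ``age_d_k``/``length_cm_k``/``weight_g_k`` for k = 1..3).  Returns
    columns ``x_length_<m>`` / ``x_weight_<m>`` per target month label
    (0, 4, 7, 10 for the default targets).
    """
    n = len(df)
    zeros = np.zeros(n)
    ages = np.column_stack([zeros, df["age_d_1"], df["age_d_2"], df["age_d_3"]])
    months = TARGET_MONTHS[: len(targets.ages)]
    out = pd.DataFrame(index=df.index)
    for measure, birth_col, cols in (
        ("length", "birth_length", ["length_cm_1", "length_cm_2", "length_cm_3"]),
        ("weight", "birth_weight", ["weight_g_1", "weight_g_2", "weight_g_3"]),
    ):
        vals = np.column_stack([df[birth_col], df[cols[0]], df[cols[1]], df[cols[2]]])
        for month, target in zip(months, targets.ages):
            if target == 0:
                out[f"x_{measure}_0"] = df[birth_col].to_numpy(dtype=float)
            else:
                out[f"x_{measure}_{month}"] = _interp_rows(ages, vals, float(target), window)
    return out
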