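"""Sex-stratified relative-risk regression of developmental delay.

The outcome (screened developmental delay) is common (~9-17 %), so odds
ratios would overstate the association; relative risks are estimated
directly with a log-link Poisson-family GLM on the binary outcome.  Point
estimates equal Poisson maximum likelihood; standard errors are inflated
by the square root of the Pearson dispersion (quasi-Poisson), and 95 %
Wald intervals use z = 1.96.  Exponentiated coefficients are adjusted
relative risks (aRR) — per 1 SD for the standardized conditional growth
exposures.

:class:`DelayRiskModel` follows the model/results idiom: construct from a
DataFrame, ``fit()`` returns :class:`DelayRiskResults` carrying estimates,
intervals, the dispersion and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .asq3 import DOMAINS
from .conditional import VARIANT_TIMEPOINTS, ConditionalGrowthModel, conditional_name
from .errors import EstimationError

__all__ = [
    "COVARIATES",
    "CATEGORY_LEVELS",
    "ModelSpec",
    "RRResult",
    "DelayRiskModel",
    "DelayRiskResults",
    "fit_rr_model",
    "run_model_grid",
]

Z_CRIT = 1.96

#: the six fixed adjustment covariates
COVARIATES = (
    "maternal_age",
    "maternal_smoking",
    "maternal_education",
    "paternal_education",
    "family_income",
    "home_speech_stimulation",
)

#: category orders; the first level is the dummy-coding reference
CATEGORY_LEVELS = {
    "maternal_education": ("junior_high", "high_school", "university_or_grad"),
    "paternal_education": ("junior_high", "high_school", "university_or_grad"),
    "family_income": ("low", "mid", "high"),
}
_BINARY_COVARIATES = ("maternal_smoking", "home_speech_stimulation")


@dataclass(frozen=True)
class ModelSpec:
    """One outcome model: which delay column, stratum and exposure set."""

    outcome: str
    exposures: tuple
    sex: str | None = None
    variant: object = None
    covariates: tuple = COVARIATES


@dataclass(frozen=True)
class RRResult:
    term: str
    aRR: float
    ci_low: float
    ci_high: float
    dispersion: float
    n_used: int
    events: int

    def formatted(self) -> str:
        return f"{self.aRR:.2f} ({self.ci_low:.2f}–{self.ci_high:.2f})"


def _design_matrix(data: pd.DataFrame, exposures, covariates) -> pd.DataFrame:
    """Numeric design matrix: exposures as-is, binaries as 0/1, categoricals
    dummy-coded against their declared reference level."""
    cols = {}
    for term in exposures:
        cols[term] = data[term].astype(float)
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[cov]
            observed = set(data[cov].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"{cov}: unknown levels {sorted(unknown)}")
            for lev in levels[1:]:
                if lev not in observed:
                    warnings.warn(f"{cov}: level {lev!r} absent from data; dropped", stacklevel=3)
                    continue
                cols[f"{cov}[{lev}]"] = (data[cov] == lev).astype(float)
        elif cov in _BINARY_COVARIATES:
            cols[cov] = data[cov].astype(float)
        else:
            cols[cov] = data[cov].astype(float)
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "intercept", 1.0)
    return X


class DelayRiskModel:
    """Quasi-Poisson relative-risk model for a binary delay outcome.

    Parameters
    ----------
    data : per-child analysis table containing the outcome column, the
        exposure columns and the six covariates.
    outcome : name of the 0/1 (or boolean) delay column.
    exposures : conditional growth variable columns entering the model.
    covariates : adjustment set (defaults to the fixed six).

    Rows with any missing value among outcome, exposures or covariates are
    dropped (complete-case); the count of dropped rows is kept on the model.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, exposures, covariates=COVARIATES):
        self.outcome = outcome
        self.exposures = tuple(exposures)
        self.covariates = tuple(covariates)
        needed = [outcome, *self.exposures, *self.covariates]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"analysis table missing columns: {missing}")
        complete = data[needed].notna().all(axis=1)
        self.n_dropped = int((~complete).sum())
        self.data = data.loc[complete]
        y = self.data[outcome]
        vals = set(pd.unique(y.astype(float)))
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"outcome {outcome!r} must be binary 0/1")

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: ModelSpec) -> "DelayRiskModel":
        if spec.sex is not None:
            data = data[data["sex"] == spec.sex]
        return cls(data, spec.outcome, spec.exposures, spec.covariates)

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "DelayRiskResults":
        y = self.data[self.outcome].astype(float).to_numpy()
        X = _design_matrix(self.data, self.exposures, self.covariates)
        n, p = X.shape
        if n <= p:
            raise EstimationError(f"{n} complete cases for {p} parameters")
        if np.linalg.matrix_rank(X.to_numpy()) < p:
            raise EstimationError("rank-deficient design matrix")
        glm = sm.GLM(y, X, family=sm.families.Poisson())
        with warnings.catch_warnings():
            # binary endog in a Poisson family triggers a benign warning
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=maxiter, tol=tol, scale="X2")
        if not res.converged:
            raise EstimationError(f"IRLS did not converge in {maxiter} iterations")
        mu = res.fittedvalues
        if np.any(mu > 1 - 1e-10) or np.any(mu < 1e-12):
            warnings.warn("fitted risks at the 0/1 boundary; possible separation", stacklevel=2)
        return DelayRiskResults(model=self, _glm_results=res)


@dataclass
class DelayRiskResults:
    """Fit results: aRRs with quasi-Poisson Wald intervals and diagnostics."""

    model: DelayRiskModel
    _glm_results: object

    @property
    def params(self) -> pd.Series:
        return self._glm_results.params

    @property
    def bse(self) -> pd.Series:
        """Standard errors on the log scale, already scaled by sqrt(dispersion)."""
        return self._glm_results.bse

    @property
    def dispersion(self) -> float:
        """Pearson chi-square / residual df."""
        return float(self._glm_results.scale)

    @property
    def n_used(self) -> int:
        return int(len(self.model.data))

    @property
    def events(self) -> int:
        return int(self.model.data[self.model.outcome].astype(float).sum())

    @property
    def arr(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self) -> pd.DataFrame:
        # near-separated terms have enormous SEs; an infinite upper bound
        # is the honest Wald answer, so let exp overflow to inf quietly
        with np.errstate(over="ignore"):
            lo = np.exp(self.params - Z_CRIT * self.bse)
            hi = np.exp(self.params + Z_CRIT * self.bse)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary(self) -> pd.DataFrame:
        """Tidy table: one row per term with aRR, 95 % CI and diagnostics."""
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "term": self.params.index,
                "aRR": self.arr.to_numpy(),
                "ci_low": ci["ci_low"].to_numpy(),
                "ci_high": ci["ci_high"].to_numpy(),
            }
        )
        out["dispersion"] = self.dispersion
        out["n_used"] = self.n_used
        out["events"] = self.events
        return out

    def results_for(self, terms=None) -> list:
        """RRResult records for the requested terms (default: exposures)."""
        if terms is None:
            terms = self.model.exposures
        ci = self.conf_int()
        return [
            RRResult(
                term=t,
                aRR=float(self.arr[t]),
                ci_low=float(ci.loc[t, "ci_low"]),
                ci_high=float(ci.loc[t, "ci_high"]),
                dispersion=self.dispersion,
                n_used=self.n_used,
                events=self.events,
            )
            for t in terms
        ]


def fit_rr_model(data: pd.DataFrame, spec: ModelSpec) -> list:
    """Fit one model and return the exposure terms' RRResult records."""
    return DelayRiskModel.from_spec(data, spec).fit().results_for()


# ---------------------------------------------------------------------------
# the full table layout: per sex, 6-month model + three 12-month variants
# ---------------------------------------------------------------------------

#: (label, outcome age months, conditional-variable variant) per table
TABLE_LAYOUT = (
    ("6mo", 6, "birth4"),
    ("12mo_model1", 12, 1),
    ("12mo_model2", 12, 2),
    ("12mo_model3", 12, 3),
)


def exposure_names(variant) -> list:
    names = []
    for month in VARIANT_TIMEPOINTS[variant]:
        names.append(conditional_name("length", month))
        names.append(conditional_name("weight", month))
    return names


def run_model_grid(analysis: pd.DataFrame, sexes=("boy", "girl")) -> dict:
    """Fit the full grid: 2 sexes x 4 tables x (total + 5 domains).

    ``analysis`` is the merged per-child table with ``sex``, z-score
    columns ``z_length_<m>``/``z_weight_<m>``, the six covariates and delay
    columns ``delayed_<age>_total`` / ``delayed_<age>_<Domain>``.  For each
    sex and variant the conditional variables are fit on that stratum's
    complete-anthropometry sample, then each outcome column is modelled on
    its own complete cases.  Returns ``{(sex, label): tidy DataFrame}``
    with one row per term per outcome.
    """
    outcomes_by_age = {age: ["total", *DOMAINS] for _, age, _ in TABLE_LAYOUT}
    results = {}
    for sex in sexes:
        stratum = analysis[analysis["sex"] == sex]
        for label, age, variant in TABLE_LAYOUT:
            cg = ConditionalGrowthModel(stratum, variant=variant, sex=sex).fit()
            merged = cg.conditionals.join(stratum[[c for c in stratum.columns if c not in cg.conditionals.columns]])
            rows = []
            for outcome_name in outcomes_by_age[age]:
                col = f"delayed_{age}_{outcome_name}"
                if col not in merged.columns:
                    raise ValueError(f"analysis table missing outcome column {col!r}")
                spec = ModelSpec(outcome=col, exposures=tuple(exposure_names(variant)), sex=sex, variant=variant)
                res = DelayRiskModel(merged, col, spec.exposures).fit()
                for rr in res.results_for():
                    rows.append(
                        {
                            "sex": sex,
                            "table": label,
                            "outcome": outcome_name,
                            "term": rr.term,
                            "aRR": rr.aRR,
                            "ci_low": rr.ci_low,
                            "ci_high": rr.ci_high,
                            "dispersion": rr.dispersion,
                            "n_used": rr.n_used,
                            "events": rr.events,
                            "formatted": rr.formatted(),
                        }
                    )
            results[(sex, label)] = pd.DataFrame(rows)
    return results


def format_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy result table into the printed layout: terms x outcomes,
    cells like ``0.85 (0.82–0.88)``; the header row carries events/n."""
    pivot = tidy.pivot(index="term", columns="outcome", values="formatted")
    header = tidy.groupby("outcome").first()
    rates = {
        o: f"{int(r.events):,}/{int(r.n_used):,} ({100 * r.events / r.n_used:.1f} %)"
        for o, r in header.iterrows()
    }
    pivot.loc["events/n"] = [rates[c] for c in pivot.columns]
    order = ["events/n"] + [t for t in tidy["term"].unique()]
    return pivot.loc[order]
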