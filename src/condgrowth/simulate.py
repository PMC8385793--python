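"""Seeded synthetic birth-cohort generator.

The cohort the analysis was designed for is not publicly distributable, so
this module generates cohorts with the statistical structure the pipeline
assumes: correlated latent length/weight z-score trajectories at birth and
4/7/10 months, Japanese-cohort-like covariate marginals, delay outcomes
linked *log-linearly* to the true conditional growth variables (so the
quasi-Poisson estimand equals the configured relative risk exactly),
questionnaire items sampled to be score-consistent with the drawn delay
flag, and missing-at-random missingness that skews the incomplete group
toward multiparity, smoking and lower education.

One integer seed governs everything through a fixed `SeedSequence` split
(one child stream per generation stage, in the order listed in
``_STREAMS``), so equal seeds give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .asq3 import DOMAINS, ITEMS_PER_DOMAIN
from .errors import ConfigurationError
from .reference import GrowthReference, lms_inverse, synthetic_reference

__all__ = [
    "Z_ORDER",
    "CONDITIONAL_ORDER",
    "SimulationConfig",
    "MissingnessConfig",
    "ChildRecord",
    "Cohort",
    "default_config",
    "default_growth_corr",
    "simulate_cohort",
    "population_conditional_transform",
]

#: latent z-score order: (measure, month)
Z_ORDER = (
    ("length", 0),
    ("weight", 0),
    ("length", 4),
    ("weight", 4),
    ("length", 7),
    ("weight", 7),
    ("length", 10),
    ("weight", 10),
)
CONDITIONAL_ORDER = (
    "length0",
    "weight0",
    "cLength4",
    "crWeight4",
    "cLength7",
    "crWeight7",
    "cLength10",
    "crWeight10",
)

#: nominal checkup ages in days per month label
CHECKUP_DAYS = {4: 122, 7: 213, 10: 304}

OUTCOME_AGES = (6, 12)

_STREAMS = (
    "demographics",
    "covariates",
    "latent",
    "checkup_ages",
    "delay",
    "asq",
    "missingness",
    "eligibility",
)


def default_growth_corr() -> np.ndarray:
    """Plausible correlation matrix of the eight latent z-scores.

    Length/weight track strongly after birth (autocorrelations rising with
    age) and correlate ~0.55-0.7 with each other at the same visit; birth
    size correlates ~0.3-0.55 with infancy size.  Not estimated from any
    cohort — a documented default.
    """
    corr = np.eye(8)
    vals = {
        # within-length
        (0, 2): 0.55, (0, 4): 0.45, (0, 6): 0.40, (2, 4): 0.80, (2, 6): 0.70, (4, 6): 0.85,
        # within-weight
        (1, 3): 0.55, (1, 5): 0.45, (1, 7): 0.40, (3, 5): 0.80, (3, 7): 0.70, (5, 7): 0.85,
        # length-weight, same visit
        (0, 1): 0.55, (2, 3): 0.70, (4, 5): 0.72, (6, 7): 0.72,
        # length-weight, different visits
        (0, 3): 0.40, (0, 5): 0.35, (0, 7): 0.30,
        (1, 2): 0.40, (1, 4): 0.33, (1, 6): 0.30,
        (2, 5): 0.60, (2, 7): 0.55,
        (3, 4): 0.60, (3, 6): 0.55,
        (4, 7): 0.62, (5, 6): 0.62,
    }
    for (i, j), v in vals.items():
        corr[i, j] = corr[j, i] = v
    return corr


@dataclass(frozen=True)
class MissingnessConfig:
    """Missing-at-random missingness given covariates.

    ``checkup`` / ``asq`` hold marginal missingness probabilities per
    checkup month and questionnaire age; the per-child probability tilts
    along ``logodds`` (log-odds increments for covariate features), with
    the intercept calibrated on the generated sample so the marginal rate
    matches the configured value.
    """

    checkup: dict = field(default_factory=lambda: {4: 0.161, 7: 0.633, 10: 0.421})
    asq: dict = field(default_factory=lambda: {6: 0.044, 12: 0.090})
    item_prob: float = 0.002
    covariate: dict = field(
        default_factory=lambda: {
            "maternal_age": 0.0001,
            "maternal_smoking": 0.024,
            "maternal_education": 0.021,
            "paternal_education": 0.027,
            "family_income": 0.089,
            "home_speech_stimulation": 0.023,
        }
    )
    logodds: dict = field(
        default_factory=lambda: {
            "multipara": 0.40,
            "maternal_smoking": 0.30,
            "maternal_education_junior_high": 0.25,
            "maternal_education_university_or_grad": -0.25,
            "family_income_low": 0.15,
            "family_income_high": -0.15,
        }
    )
    p_missing_basic: float = 0.003


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults from :func:`default_config`."""

    n_children: int = 86805
    sex_ratio: float = 0.510  # proportion of boys
    seed: int = 0
    growth_corr: np.ndarray = field(default_factory=default_growth_corr)
    true_log_rr: dict = field(default_factory=dict)
    baseline_delay_prob: dict = field(
        default_factory=lambda: {
            (6, "boy"): 0.089,
            (6, "girl"): 0.085,
            (12, "boy"): 0.169,
            (12, "girl"): 0.126,
        }
    )
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    covariate_dists: dict = field(
        default_factory=lambda: {
            "multipara": 0.517,
            "maternal_smoking": 0.145,
            "maternal_education": {"junior_high": 0.032, "high_school": 0.728, "university_or_grad": 0.240},
            "paternal_education": {"junior_high": 0.053, "high_school": 0.596, "university_or_grad": 0.351},
            "family_income": {"low": 0.369, "mid": 0.340, "high": 0.291},
            "home_speech_stimulation": 0.814,
            "maternal_age_mean": 31.4,
            "maternal_age_sd": 4.8,
            "gestational_age_mean": 39.4,
            "gestational_age_sd": 1.1,
        }
    )
    checkup_jitter_days: int = 10
    p_malformation: float = 0.035
    p_multiple_birth: float = 0.010
    # score-sampling knobs: unimpaired domain scores are 60 - 5*Bin(4, .35)
    # (support 40-60); the forced low domain of a delayed child scores
    # 5*Bin(2, .3) (support 0-10), leaving a hard gap for the cutoff.
    asq_high_binom: tuple = (4, 0.35)
    asq_low_binom: tuple = (2, 0.30)

    def to_yaml(self) -> str:
        """Serialize the configuration (numpy arrays as nested lists)."""
        import yaml

        d = {
            "n_children": self.n_children,
            "sex_ratio": self.sex_ratio,
            "seed": self.seed,
            "growth_corr": np.asarray(self.growth_corr, dtype=float).tolist(),
            "true_log_rr": {k: float(v) for k, v in self.true_log_rr.items()},
            "baseline_delay_prob": {f"{a}mo_{s}": p for (a, s), p in self.baseline_delay_prob.items()},
            "missingness": {
                "checkup": dict(self.missingness.checkup),
                "asq": dict(self.missingness.asq),
                "item_prob": self.missingness.item_prob,
                "covariate": dict(self.missingness.covariate),
                "logodds": dict(self.missingness.logodds),
                "p_missing_basic": self.missingness.p_missing_basic,
            },
            "covariate_dists": self.covariate_dists,
            "checkup_jitter_days": self.checkup_jitter_days,
            "p_malformation": self.p_malformation,
            "p_multiple_birth": self.p_multiple_birth,
            "asq_high_binom": list(self.asq_high_binom),
            "asq_low_binom": list(self.asq_low_binom),
        }
        return yaml.safe_dump(d, sort_keys=True)

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigurationError("n_children must be >= 1")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigurationError("sex_ratio must be in [0, 1]")
        corr = np.asarray(self.growth_corr, dtype=float)
        if corr.shape != (8, 8):
            raise ConfigurationError("growth_corr must be 8x8 over " + str(Z_ORDER))
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigurationError("growth_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigurationError("growth_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigurationError("growth_corr must be positive definite")
        unknown = set(self.true_log_rr) - set(CONDITIONAL_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown conditional variables in true_log_rr: {sorted(unknown)}")
        for key, p in self.baseline_delay_prob.items():
            if not 0 < p < 1:
                raise ConfigurationError(f"baseline_delay_prob{key} must be in (0, 1)")
        for d in (self.missingness.checkup, self.missingness.asq, self.missingness.covariate):
            for k, p in d.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"missingness probability {k}={p} outside [0, 1]")


def default_config(**overrides) -> SimulationConfig:
    """The generator's standard conditions.

    Marginals (sex ratio, parity, smoking, education, income, speech
    stimulation, delay rates, per-checkup availability) follow the
    complete-data column of a large Japanese term-birth cohort; the true
    log relative risks default to the magnitudes such a cohort reports
    (protective conditional length at 4 months, ~0.85 per SD).
    """
    cfg = SimulationConfig(
        true_log_rr={
            "length0": np.log(0.99),
            "weight0": np.log(0.91),
            "cLength4": np.log(0.85),
            "crWeight4": np.log(1.03),
            "cLength7": np.log(1.07),
            "crWeight7": np.log(0.98),
            "cLength10": np.log(0.98),
            "crWeight10": np.log(0.94),
        }
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class ChildRecord:
    """One child's raw data, mirroring a single CSV row."""

    child_id: str
    sex: str
    gestational_age: float
    parity: str
    birth_length: float | None
    birth_weight: float | None
    checkups: list
    maternal_age: float | None
    maternal_smoking: bool | None
    maternal_education: str | None
    paternal_education: str | None
    family_income: str | None
    home_speech_stimulation: bool | None
    asq_items: dict
    singleton: bool = True
    malformation: bool = False


class Cohort:
    """A simulated cohort: wide DataFrame plus generation-time truths.

    ``data`` is the public wide table (one row per child; the CSV schema).
    ``latent_z``, ``true_conditionals`` and ``true_delay_prob`` retain the
    latent quantities for diagnostics and tests; they are not written to
    CSV.
    """

    def __init__(self, data: pd.DataFrame, config: SimulationConfig, latent_z=None, true_conditionals=None, true_delay_prob=None):
        self.data = data
        self.config = config
        self.latent_z = latent_z
        self.true_conditionals = true_conditionals
        self.true_delay_prob = true_delay_prob

    def __len__(self) -> int:
        return len(self.data)

    def to_dataframe(self) -> pd.DataFrame:
        return self.data

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @staticmethod
    def _opt(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return value

    def records(self):
        """Yield :class:`ChildRecord` objects (lazy; the frame is the fast path)."""
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            checkups = []
            for k in (1, 2, 3):
                age = self._opt(d[f"age_d_{k}"])
                if age is None:
                    continue
                checkups.append((float(age), self._opt(d[f"length_cm_{k}"]), self._opt(d[f"weight_g_{k}"])))
            asq_items = {}
            for age in OUTCOME_AGES:
                for domain in DOMAINS:
                    items = [self._opt(d[f"{domain}_item{i}_{age}"]) for i in range(1, ITEMS_PER_DOMAIN + 1)]
                    asq_items[(age, domain)] = None if all(v is None for v in items) else items
            yield ChildRecord(
                child_id=d["child_id"],
                sex=d["sex"],
                gestational_age=float(d["gestational_age"]),
                parity=d["parity"],
                birth_length=self._opt(d["birth_length"]),
                birth_weight=self._opt(d["birth_weight"]),
                checkups=checkups,
                maternal_age=self._opt(d["maternal_age"]),
                maternal_smoking=self._opt(d["maternal_smoking"]),
                maternal_education=self._opt(d["maternal_education"]),
                paternal_education=self._opt(d["paternal_education"]),
                family_income=self._opt(d["family_income"]),
                home_speech_stimulation=self._opt(d["home_speech_stimulation"]),
                asq_items=asq_items,
                singleton=bool(d["singleton"]),
                malformation=bool(d["malformation"]),
            )


def population_conditional_transform(corr: np.ndarray) -> np.ndarray:
    """Matrix ``A`` with ``conditionals = A @ z`` under the population law.

    Row order is :data:`CONDITIONAL_ORDER`; each post-birth row encodes the
    population regression residual of the current size on its regressor
    set, scaled to unit variance.  Used to generate delay probabilities
    that match the estimand of the sample residualization exactly.
    """
    corr = np.asarray(corr, dtype=float)
    A = np.zeros((8, 8))
    A[0, 0] = 1.0
    A[1, 1] = 1.0
    specs = {
        2: (2, [0, 1]),          # cLength4 ~ birth sizes
        3: (3, [2, 0, 1]),       # crWeight4 ~ length4 + birth sizes
        4: (4, [0, 1, 2, 3]),    # cLength7
        5: (5, [4, 0, 1, 2, 3]), # crWeight7
        6: (6, [0, 1, 2, 3, 4, 5]),
        7: (7, [6, 0, 1, 2, 3, 4, 5]),
    }
    for row, (y, R) in specs.items():
        beta = np.linalg.solve(corr[np.ix_(R, R)], corr[R, y])
        resid_var = 1.0 - corr[y, R] @ beta
        if resid_var <= 0:
            raise ConfigurationError("growth_corr implies non-positive conditional variance")
        A[row, y] = 1.0
        A[row, R] -= beta
        A[row] /= np.sqrt(resid_var)
    return A


def _sample_categorical(rng, probs: dict, n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _calibrate_intercept(target: float, lp: np.ndarray) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) == target, by bisection."""
    lo, hi = -15.0, 15.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + lp).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _missingness_lp(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    lp = np.zeros(len(df))
    lp += coefs.get("multipara", 0.0) * (df["parity"] == "multipara").to_numpy(float)
    lp += coefs.get("maternal_smoking", 0.0) * df["maternal_smoking"].astype("float64").to_numpy()
    for var in ("maternal_education", "family_income"):
        for lev in ("junior_high", "high_school", "university_or_grad", "low", "mid", "high"):
            key = f"{var}_{lev}"
            if key in coefs:
                lp += coefs[key] * (df[var] == lev).to_numpy(float)
    return lp


# item-token patterns per score step u = points/5 (0..12): u//2 "yes",
# u%2 "sometimes", rest "not_yet" — a fixed decomposition of each score
_ITEM_PATTERNS = {}
for _u in range(13):
    _y, _m = _u // 2, _u % 2
    _ITEM_PATTERNS[_u] = ["yes"] * _y + ["sometimes"] * _m + ["not_yet"] * (ITEMS_PER_DOMAIN - _y - _m)


def simulate_cohort(config: SimulationConfig, ref: GrowthReference | None = None, seed: int | None = None) -> Cohort:
    """Generate one cohort under ``config``.

    ``seed`` overrides ``config.seed``; ``ref`` the LMS reference used for
    the z-to-raw inverse transform (default: the synthetic table).
    Generation order: demographics -> covariates -> latent z trajectories
    -> raw anthropometry -> delay indicators (log-linear in the true
    conditionals) -> score-consistent questionnaire items -> missingness
    -> eligibility flags.
    """
    config.validate()
    if ref is None:
        ref = synthetic_reference()
    n = config.n_children
    streams = dict(zip(_STREAMS, np.random.SeedSequence(config.seed if seed is None else seed).spawn(len(_STREAMS))))
    rngs = {k: np.random.default_rng(ss) for k, ss in streams.items()}
    dists = config.covariate_dists

    # --- demographics ---
    rng = rngs["demographics"]
    sex = np.where(rng.random(n) < config.sex_ratio, "boy", "girl")
    parity = np.where(rng.random(n) < dists["multipara"], "multipara", "primipara")
    ga_mean, ga_sd = dists["gestational_age_mean"], dists["gestational_age_sd"]
    a, b = (37.0 - ga_mean) / ga_sd, (42.0 - ga_mean) / ga_sd
    ga = truncnorm.rvs(a, b, loc=ga_mean, scale=ga_sd, size=n, random_state=rng)
    ga = np.clip(np.round(ga, 1), 37.0, 41.9)

    # --- covariates ---
    rng = rngs["covariates"]
    maternal_age = np.round(np.clip(rng.normal(dists["maternal_age_mean"], dists["maternal_age_sd"], n), 16, 50), 1)
    maternal_smoking = rng.random(n) < dists["maternal_smoking"]
    maternal_education = _sample_categorical(rng, dists["maternal_education"], n)
    paternal_education = _sample_categorical(rng, dists["paternal_education"], n)
    family_income = _sample_categorical(rng, dists["family_income"], n)
    speech = rng.random(n) < dists["home_speech_stimulation"]

    # --- latent z trajectories and true conditionals ---
    rng = rngs["latent"]
    corr = np.asarray(config.growth_corr, dtype=float)
    z = rng.standard_normal((n, 8)) @ np.linalg.cholesky(corr).T
    A = population_conditional_transform(corr)
    cond = z @ A.T  # columns follow CONDITIONAL_ORDER

    # --- raw anthropometry ---
    gw = np.floor(ga).astype(int)
    birth_length = np.empty(n)
    birth_weight = np.empty(n)
    for s in ("boy", "girl"):
        for p in ("primipara", "multipara"):
            for week in np.unique(gw):
                m = (sex == s) & (parity == p) & (gw == week)
                if not m.any():
                    continue
                for col, (out, zi) in {"length": (birth_length, 0), "weight": (birth_weight, 1)}.items():
                    L, M, S = ref.lookup(s, col, 0, p, week)
                    out[m] = lms_inverse(z[m, zi], L, M, S)
    birth_length = np.round(birth_length, 1)
    birth_weight = np.round(birth_weight, 0)

    rng = rngs["checkup_ages"]
    jitter = config.checkup_jitter_days
    checkup_age = {}
    checkup_val = {}
    month_to_z = {4: (2, 3), 7: (4, 5), 10: (6, 7)}
    for month, nominal in CHECKUP_DAYS.items():
        ages = nominal + rng.integers(-jitter, jitter + 1, size=n)
        checkup_age[month] = ages.astype(float)
        li, wi = month_to_z[month]
        lv = np.empty(n)
        wv = np.empty(n)
        for s in ("boy", "girl"):
            m = sex == s
            for measure, zi, out in (("length", li, lv), ("weight", wi, wv)):
                L, M, S = ref.lookup(s, measure, ages[m])
                out[m] = lms_inverse(z[m, zi], L, M, S)
        checkup_val[month] = (np.round(lv, 1), np.round(wv, 0))

    # --- delay indicators ---
    rng = rngs["delay"]
    logrr = np.array([config.true_log_rr.get(name, 0.0) for name in CONDITIONAL_ORDER])
    shift = cond @ logrr
    delay = {}
    prob = {}
    for age in OUTCOME_AGES:
        p_age = np.empty(n)
        for s in ("boy", "girl"):
            m = sex == s
            p_age[m] = config.baseline_delay_prob[(age, s)] * np.exp(shift[m])
        bad = (p_age <= 0) | (p_age >= 1)
        if bad.any():
            i = int(np.argmax(bad))
            raise ConfigurationError(
                f"delay probability {p_age[i]:.3f} outside (0, 1) at outcome age {age} mo, "
                f"sex {sex[i]} (true_log_rr too large for the baseline)"
            )
        prob[age] = p_age
        delay[age] = rng.random(n) < p_age

    # --- questionnaire items, score-consistent with the delay flag ---
    rng = rngs["asq"]
    hi_n, hi_p = config.asq_high_binom
    lo_n, lo_p = config.asq_low_binom
    item_cols = {}
    for age in OUTCOME_AGES:
        scores = 60 - 5 * rng.binomial(hi_n, hi_p, size=(n, len(DOMAINS)))
        forced = rng.integers(0, len(DOMAINS), size=n)
        low_scores = 5 * rng.binomial(lo_n, lo_p, size=n)
        d = delay[age]
        scores[d, forced[d]] = low_scores[d]
        pattern_arr = np.array([_ITEM_PATTERNS[u] for u in range(13)], dtype=object)
        for j, domain in enumerate(DOMAINS):
            items = pattern_arr[scores[:, j] // 5]  # (n, 6) tokens
            for i in range(1, ITEMS_PER_DOMAIN + 1):
                item_cols[f"{domain}_item{i}_{age}"] = items[:, i - 1]

    df = pd.DataFrame(
        {
            "child_id": [f"C{i:07d}" for i in range(n)],
            "sex": sex,
            "gestational_age": ga,
            "parity": parity,
            "birth_length": birth_length,
            "birth_weight": birth_weight,
            "age_d_1": checkup_age[4],
            "length_cm_1": checkup_val[4][0],
            "weight_g_1": checkup_val[4][1],
            "age_d_2": checkup_age[7],
            "length_cm_2": checkup_val[7][0],
            "weight_g_2": checkup_val[7][1],
            "age_d_3": checkup_age[10],
            "length_cm_3": checkup_val[10][0],
            "weight_g_3": checkup_val[10][1],
            "maternal_age": maternal_age,
            "maternal_smoking": pd.array(maternal_smoking, dtype="boolean"),
            "maternal_education": maternal_education,
            "paternal_education": paternal_education,
            "family_income": family_income,
            "home_speech_stimulation": pd.array(speech, dtype="boolean"),
            **item_cols,
        }
    )

    # --- missingness (last, so latent truths stay intact) ---
    rng = rngs["missingness"]
    mc = config.missingness
    lp = _missingness_lp(df, mc.logodds)
    checkup_cols = {4: ("age_d_1", "length_cm_1", "weight_g_1"), 7: ("age_d_2", "length_cm_2", "weight_g_2"), 10: ("age_d_3", "length_cm_3", "weight_g_3")}
    for month, target in mc.checkup.items():
        if target <= 0:
            continue
        b0 = _calibrate_intercept(target, lp)
        miss = rng.random(n) < expit(b0 + lp)
        for col in checkup_cols[month]:
            df.loc[miss, col] = np.nan
    for age, target in mc.asq.items():
        if target <= 0:
            continue
        b0 = _calibrate_intercept(target, lp)
        miss = rng.random(n) < expit(b0 + lp)
        cols = [f"{d}_item{i}_{age}" for d in DOMAINS for i in range(1, ITEMS_PER_DOMAIN + 1)]
        df.loc[miss, cols] = None
        if mc.item_prob > 0:
            item_miss = rng.random((n, len(cols))) < mc.item_prob
            for k, col in enumerate(cols):
                df.loc[item_miss[:, k] & ~miss, col] = None
    for cov, p in mc.covariate.items():
        if p <= 0:
            continue
        df.loc[rng.random(n) < p, cov] = np.nan
    if mc.p_missing_basic > 0:
        miss = rng.random(n) < mc.p_missing_basic
        df.loc[miss, ["birth_length", "birth_weight"]] = np.nan

    # --- eligibility flags ---
    rng = rngs["eligibility"]
    df["singleton"] = rng.random(n) >= config.p_multiple_birth
    df["malformation"] = rng.random(n) < config.p_malformation

    latent = pd.DataFrame(z, columns=[f"z_{m}_{t}" for m, t in Z_ORDER])
    conditionals = pd.DataFrame(cond, columns=list(CONDITIONAL_ORDER))
    probs = pd.DataFrame({f"p_delay_{age}": prob[age] for age in OUTCOME_AGES})
    for age in OUTCOME_AGES:
        probs[f"delay_{age}"] = delay[age]
    return Cohort(df, config, latent_z=latent, true_conditionals=conditionals, true_delay_prob=probs)
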