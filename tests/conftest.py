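import numpy as np
import pandas as pd
import pytest

from condgrowth import default_config, simulate_cohort
from condgrowth.conditional import ConditionalGrowthModel
from condgrowth.pipeline import apply_eligibility, build_analysis_table
from condgrowth.risk import DelayRiskModel, exposure_names

RECOVERY_SEEDS = tuple(range(100, 120))
NULL_SEEDS = tuple(range(200, 220))
SIM_N = 50_000


def fit_boys_6mo(seed: int, true_log_rr: dict) -> dict:
    """Full pipeline on one synthetic cohort; boys' 6-month total-delay model.

    Returns {exposure: (aRR, ci_low, ci_high)}.
    """
    cfg = default_config(n_children=SIM_N, true_log_rr=true_log_rr)
    cohort = simulate_cohort(cfg, seed=seed)
    eligible, _ = apply_eligibility(cohort.data)
    analysis, _ = build_analysis_table(eligible)
    boys = analysis[analysis["sex"] == "boy"]
    cg = ConditionalGrowthModel(boys, variant="birth4", sex="boy").fit()
    merged = cg.conditionals.join(boys[[c for c in boys.columns if c not in cg.conditionals.columns]])
    res = DelayRiskModel(merged, "delayed_6_total", exposure_names("birth4")).fit()
    ci = res.conf_int()
    return {t: (float(res.arr[t]), float(ci.loc[t, "ci_low"]), float(ci.loc[t, "ci_high"])) for t in res.model.exposures}


@pytest.fixture(scope="session")
def recovery_runs():
    """20 pipeline fits with a true protective cLength4 effect of RR 0.85."""
    true = {"cLength4": float(np.log(0.85))}
    return [fit_boys_6mo(seed, true) for seed in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def null_runs():
    """20 pipeline fits with every true log-RR zero."""
    return [fit_boys_6mo(seed, {}) for seed in NULL_SEEDS]


@pytest.fixture(scope="session")
def small_cohort():
    """One modest default-configuration cohort shared by cheap tests."""
    cfg = default_config(n_children=8000)
    return simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    eligible, flow = apply_eligibility(small_cohort.data)
    analysis, cutoffs = build_analysis_table(eligible)
    return {"analysis": analysis, "cutoffs": cutoffs, "flow": flow, "eligible": eligible}
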