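"""End-to-end orchestration: cohort -> z-scores -> conditionals -> outcomes
-> risk models -> balance table.

Every stage writes its intermediate CSV into the run directory so a run is
auditable and partially re-runnable; a manifest records the seed, a config
hash and per-stage row counts (selection flow conservation is asserted:
eligible = analyzed + excluded at every filter).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asq3 import DOMAINS, ITEMS_PER_DOMAIN, derive_cutoffs, flag_delay, score_frame
from .effects import balance_table
from .reference import GrowthReference, synthetic_reference, zscore_frame
from .risk import format_table, run_model_grid
from .simulate import OUTCOME_AGES, SimulationConfig, default_config, simulate_cohort
from .timeline import DEFAULT_WINDOW_DAYS, TargetAges, timeline_frame

__all__ = ["RunConfig", "apply_eligibility", "asq_outcomes", "build_analysis_table", "run_all"]


def apply_eligibility(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Apply the selection cascade and log counts at each step.

    Order: live singleton birth; term window (gestational age >= 37 and
    < 42 weeks); complete basic information (parity, sex, birth length,
    birth weight); no malformation/severe disease.  Returns the analysis
    cohort and a list of ``(step, n_before, n_excluded)``.
    """
    log = []

    def step(frame, name, keep):
        kept = frame[keep]
        log.append((name, int(len(frame)), int(len(frame) - len(kept))))
        return kept

    out = df
    if "singleton" in out.columns:
        out = step(out, "singleton_live_birth", out["singleton"].astype(bool))
    ga = out["gestational_age"].astype(float)
    out = step(out, "term_window_37_to_42", (ga >= 37.0) & (ga < 42.0))
    basic = out[["parity", "sex", "birth_length", "birth_weight"]].notna().all(axis=1)
    out = step(out, "complete_basic_information", basic)
    if "malformation" in out.columns:
        out = step(out, "no_malformation_severe_disease", ~out["malformation"].astype(bool))
    return out, log


def asq_items_for_age(df: pd.DataFrame, age: int) -> pd.DataFrame:
    cols = {f"{d}_item{i}_{age}": f"{d}_item{i}" for d in DOMAINS for i in range(1, ITEMS_PER_DOMAIN + 1)}
    return df[list(cols)].rename(columns=cols)


def asq_outcomes(df: pd.DataFrame, prorate: bool = False):
    """Score the questionnaire columns and flag delay per outcome age.

    Cutoffs (mean - 2 SD) are derived per domain from all children with a
    score at that age, pooled across sexes.  Returns ``(outcomes, cutoffs,
    scores)`` where ``outcomes`` holds ``delayed_<age>_<Domain>`` and
    ``delayed_<age>_total`` columns (1.0/0.0/NaN).
    """
    outcomes = pd.DataFrame(index=df.index)
    cutoff_sets = {}
    score_frames = {}
    for age in OUTCOME_AGES:
        scores = score_frame(asq_items_for_age(df, age), prorate=prorate)
        cutoffs = derive_cutoffs({d: scores[d] for d in DOMAINS}, outcome_age=age)
        cutoff_sets[age] = cutoffs
        score_frames[age] = scores
        any_known = scores.notna().any(axis=1)
        flags = pd.DataFrame(index=df.index)
        for d in DOMAINS:
            f = (scores[d] <= cutoffs[d]).astype(float)
            f[scores[d].isna()] = np.nan
            flags[d] = f
            outcomes[f"delayed_{age}_{d}"] = f
        total = (flags.fillna(0.0).sum(axis=1) > 0).astype(float)
        total[~any_known] = np.nan
        outcomes[f"delayed_{age}_total"] = total
    return outcomes, cutoff_sets, score_frames


def build_analysis_table(
    df: pd.DataFrame,
    ref: GrowthReference | None = None,
    targets: TargetAges = TargetAges(),
    window: float = DEFAULT_WINDOW_DAYS,
    prorate: bool = False,
):
    """Assemble the per-child analysis table from an eligible cohort frame.

    Adds raw target-age measurements (``x_*``), z-scores (``z_*``) and
    delay outcome columns to the cohort's identifier/covariate columns.
    Returns ``(analysis, cutoff_sets)``.
    """
    if ref is None:
        ref = synthetic_reference()
    x = timeline_frame(df, targets=targets, window=window)
    z = zscore_frame(df, x, ref, month_days=dict(zip((0, 4, 7, 10), targets.ages)))
    outcomes, cutoff_sets, _ = asq_outcomes(df, prorate=prorate)
    keep = [c for c in df.columns if not any(d in c for d in DOMAINS)]
    analysis = pd.concat([df[keep], x, z, outcomes], axis=1)
    return analysis, cutoff_sets


@dataclass
class RunConfig:
    """Configuration of one reproducible end-to-end run."""

    seed: int = 0
    output_dir: str = "condgrowth_run"
    n_children: int | None = 20000
    cohort_csv: str | None = None  # load instead of simulating
    reference_csv: str | None = None
    simulation: SimulationConfig | None = None
    window_days: float = DEFAULT_WINDOW_DAYS
    target_ages_days: tuple = TargetAges().ages
    prorate_missing_items: bool = False

    def to_yaml(self) -> str:
        d = {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "n_children": self.n_children,
            "cohort_csv": self.cohort_csv,
            "reference_csv": self.reference_csv,
            "window_days": self.window_days,
            "target_ages_days": list(self.target_ages_days),
            "prorate_missing_items": self.prorate_missing_items,
        }
        return yaml.safe_dump(d, sort_keys=True)


def run_all(config: RunConfig) -> dict:
    """Execute every stage, write intermediates and results, return the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = GrowthReference.from_csv(config.reference_csv) if config.reference_csv else synthetic_reference()
    ref.to_csv(outdir / "lms_reference.csv")

    if config.cohort_csv:
        raw = pd.read_csv(config.cohort_csv)
    else:
        sim = config.simulation or default_config()
        if config.n_children is not None:
            from dataclasses import replace

            sim = replace(sim, n_children=config.n_children)
        cohort = simulate_cohort(sim, ref=ref, seed=config.seed)
        (outdir / "simulation_config.yaml").write_text(sim.to_yaml())
        raw = cohort.data
    raw.to_csv(outdir / "cohort_raw.csv", index=False)

    eligible, flow = apply_eligibility(raw)
    eligible.to_csv(outdir / "cohort_eligible.csv", index=False)

    targets = TargetAges(tuple(config.target_ages_days))
    analysis, cutoff_sets = build_analysis_table(
        eligible, ref=ref, targets=targets, window=config.window_days, prorate=config.prorate_missing_items
    )
    zcols = [c for c in analysis.columns if c.startswith(("x_", "z_", "delayed_"))]
    analysis[["child_id", *zcols]].to_csv(outdir / "analysis_table.csv", index=False)
    pd.DataFrame(
        [
            {"outcome_age": age, "domain": d, "cutoff": cs[d], "reference_n": cs.reference_n[d]}
            for age, cs in cutoff_sets.items()
            for d in DOMAINS
        ]
    ).to_csv(outdir / "asq_cutoffs.csv", index=False)

    complete = analysis[[f"z_{m}_{t}" for t in (4, 7, 10) for m in ("length", "weight")]].notna().all(axis=1)
    bal_df = analysis.rename(columns={"delayed_6_total": "delay_6", "delayed_12_total": "delay_12"})
    bal = balance_table(bal_df, complete)
    bal.to_csv(outdir / "balance_table.csv", index=False)

    tables = run_model_grid(analysis)
    table_files = []
    for (sex, label), tidy in tables.items():
        path = outdir / f"rr_{sex}_{label}.csv"
        tidy.to_csv(path, index=False)
        format_table(tidy).to_csv(outdir / f"rr_{sex}_{label}_formatted.csv")
        table_files.append(path.name)

    flow_log = [
        {"step": name, "n_before": before, "n_excluded": excluded, "n_after": before - excluded}
        for name, before, excluded in flow
    ]
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "n_raw": int(len(raw)),
        "n_eligible": int(len(eligible)),
        "selection_flow": flow_log,
        "n_complete_anthropometry": int(complete.sum()),
        "result_tables": sorted(table_files),
    }
    (outdir / "run_config.yaml").write_text(config.to_yaml())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
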