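"""ASQ-3 developmental screening: domain scores, cutoffs, delay flags.

The Ages & Stages Questionnaires (3rd edition) screen five developmental
domains — Communication, Gross Motor, Fine Motor, Problem Solving,
Personal-Social — with six parent-reported items each.  Items score
10 ("yes"), 5 ("sometimes") or 0 ("not yet"); a domain score is the item
sum, 0-60 in steps of 5.  A domain's cutoff is two standard deviations
below the mean domain score of a reference sample, and a child screens as
having a neurodevelopmental delay when any domain score is at or below its
cutoff.

Missing items: by default a domain with any unanswered item is treated as
absent (no prorating).  ``prorate=True`` enables the instrument-manual
style adjustment instead (mean of answered items times six).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "RESPONSE_POINTS",
    "DomainScore",
    "CutoffSet",
    "DelayOutcome",
    "score_domain",
    "derive_cutoffs",
    "flag_delay",
    "score_frame",
]

DOMAINS = ("Communication", "GrossMotor", "FineMotor", "ProblemSolving", "PersonalSocial")
ITEMS_PER_DOMAIN = 6
RESPONSE_POINTS = {"yes": 10, "sometimes": 5, "not_yet": 0}


@dataclass(frozen=True)
class DomainScore:
    domain: str
    points: float | None
    n_answered: int

    @property
    def absent(self) -> bool:
        return self.points is None


@dataclass(frozen=True)
class CutoffSet:
    """Per-domain cutoffs (mean - 2 SD of the reference sample)."""

    outcome_age: int
    cutoffs: dict
    reference_n: dict

    def __getitem__(self, domain: str) -> float:
        return self.cutoffs[domain]


@dataclass(frozen=True)
class DelayOutcome:
    outcome_age: int
    domain_delayed: dict  # domain -> bool or None (absent)
    any_delay: bool | None


def score_domain(responses, domain: str = "", prorate: bool = False) -> DomainScore:
    """Sum one domain's six item responses into a 0-60 score.

    ``responses`` holds six tokens from {"yes", "sometimes", "not_yet"};
    ``None``/NaN marks an unanswered item.  With any item missing the
    domain is absent unless ``prorate`` is set, in which case the mean of
    the answered items is scaled to six items (a fully unanswered domain is
    absent either way).
    """
    if len(responses) != ITEMS_PER_DOMAIN:
        raise ValueError(f"expected {ITEMS_PER_DOMAIN} item responses, got {len(responses)}")
    points = []
    for r in responses:
        if r is None or (isinstance(r, float) and np.isnan(r)):
            points.append(None)
            continue
        if r not in RESPONSE_POINTS:
            raise ValueError(f"unknown ASQ-3 response token {r!r}")
        points.append(RESPONSE_POINTS[r])
    answered = [p for p in points if p is not None]
    n = len(answered)
    if n == ITEMS_PER_DOMAIN:
        return DomainScore(domain, float(sum(answered)), n)
    if prorate and n > 0:
        return DomainScore(domain, float(np.mean(answered) * ITEMS_PER_DOMAIN), n)
    return DomainScore(domain, None, n)


def derive_cutoffs(scores_by_domain: dict, outcome_age: int) -> CutoffSet:
    """Cutoff per domain: reference-sample mean minus two sample SDs.

    ``scores_by_domain`` maps domain to an array of reference scores (NaN
    allowed, ignored).  SD uses the n-1 denominator; cutoffs are not
    floored at zero.  A zero-variance domain falls back to its mean with a
    warning.
    """
    cutoffs, ns = {}, {}
    for domain, scores in scores_by_domain.items():
        arr = np.asarray(scores, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            raise ValueError(f"domain {domain}: need >= 2 reference scores, got {len(arr)}")
        mean, sd = arr.mean(), arr.std(ddof=1)
        if sd == 0:
            warnings.warn(f"domain {domain}: zero variance in reference sample; cutoff = mean", stacklevel=2)
            cutoffs[domain] = float(mean)
        else:
            cutoffs[domain] = float(mean - 2.0 * sd)
        ns[domain] = int(len(arr))
    return CutoffSet(outcome_age=outcome_age, cutoffs=cutoffs, reference_n=ns)


def flag_delay(scores: dict, cutoffs: CutoffSet) -> DelayOutcome:
    """Apply the at-or-below rule per domain and OR them into ``any_delay``.

    ``scores`` maps domain to points or ``None``.  Absent domains
    contribute no flag; with every domain absent ``any_delay`` is ``None``.
    """
    flags = {}
    for domain, cutoff in cutoffs.cutoffs.items():
        pts = scores.get(domain)
        if pts is None or (isinstance(pts, float) and np.isnan(pts)):
            flags[domain] = None
        else:
            flags[domain] = bool(pts <= cutoff)
    known = [f for f in flags.values() if f is not None]
    any_delay = any(known) if known else None
    return DelayOutcome(outcome_age=cutoffs.outcome_age, domain_delayed=flags, any_delay=any_delay)


def score_frame(items: pd.DataFrame, prorate: bool = False) -> pd.DataFrame:
    """Score a cohort's item columns into domain-score columns.

    ``items`` holds columns ``<Domain>_item<k>`` (k = 1..6) with tokens or
    NaN.  Vectorized; returns one ``<Domain>`` score column per domain with
    NaN for absent domains.
    """
    out = pd.DataFrame(index=items.index)
    point_map = {**RESPONSE_POINTS}
    for domain in DOMAINS:
        cols = [f"{domain}_item{k}" for k in range(1, ITEMS_PER_DOMAIN + 1)]
        missing = [c for c in cols if c not in items.columns]
        if missing:
            raise ValueError(f"item frame missing columns: {missing}")
        block = items[cols]
        bad = block.notna() & ~block.isin(list(point_map))
        if bad.any().any():
            tok = block.where(bad).stack().iloc[0]
            raise ValueError(f"unknown ASQ-3 response token {tok!r}")
        pts = block.apply(lambda s: s.map(point_map))
        n_answered = pts.notna().sum(axis=1)
        if prorate:
            scores = pts.mean(axis=1) * ITEMS_PER_DOMAIN
            scores[n_answered == 0] = np.nan
        else:
            scores = pts.sum(axis=1)
            scores[n_answered < ITEMS_PER_DOMAIN] = np.nan
        out[domain] = scores
    return out
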