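"""Observation-time density statistics for longitudinal record streams.

Quantifies how much longitudinal signal a corpus actually carries: per-patient
observation time (first to last visit), the follow-up category distribution
(none / up to 5 y / 5-10 y / 10-15 y / 15-20 y / >20 y), diagnoses-per-patient
counts, and first-to-kth visit interval summaries with normal-approximation
95% confidence intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .change_classifier import PatientTimeline

DAYS_PER_YEAR = 365.25
_Z95 = 1.96


class FollowUpCategory(str, enum.Enum):
    NONE = "none"
    LE5Y = "le5y"
    GT5_LE10Y = "gt5_le10y"
    GT10_LE15Y = "gt10_le15y"
    GT15_LE20Y = "gt15_le20y"
    GT20Y = "gt20y"


_CATEGORY_UPPER_YEARS = [
    (FollowUpCategory.LE5Y, 5.0),
    (FollowUpCategory.GT5_LE10Y, 10.0),
    (FollowUpCategory.GT10_LE15Y, 15.0),
    (FollowUpCategory.GT15_LE20Y, 20.0),
]

_CATEGORY_DESC = {
    FollowUpCategory.NONE: "No follow-up",
    FollowUpCategory.LE5Y: "Up to 5 years",
    FollowUpCategory.GT5_LE10Y: ">5 and <=10 years",
    FollowUpCategory.GT10_LE15Y: ">10 and <=15 years",
    FollowUpCategory.GT15_LE20Y: ">15 and <=20 years",
    FollowUpCategory.GT20Y: "More than 20 years",
}


def observation_time(tl: PatientTimeline) -> int:
    """Days between a patient's first and last visit; 0 for a single visit."""
    if not tl.diagnoses:
        raise ValueError(f"patient {tl.patient_id!r}: empty timeline has no observation time")
    return (tl.diagnoses[-1].diagnosis_date - tl.diagnoses[0].diagnosis_date).days


def follow_up_category(obs_days: float) -> FollowUpCategory:
    """Bucket an observation time; upper bounds inclusive ("up to 5 years").

    Zero observation time (single visit, or same-day visits only) is the
    no-follow-up category.  Years are days / 365.25.
    """
    if obs_days < 0:
        raise ValueError("observation time cannot be negative")
    if obs_days == 0:
        return FollowUpCategory.NONE
    years = obs_days / DAYS_PER_YEAR
    for cat, upper in _CATEGORY_UPPER_YEARS:
        if years <= upper:
            return cat
    return FollowUpCategory.GT20Y


def interval_to_kth(tl: PatientTimeline, k: int) -> Optional[int]:
    """Days from the first to the k-th visit, or None with fewer than k visits."""
    if k < 2:
        raise ValueError("k must be at least 2 (the first-to-kth interval)")
    if len(tl.diagnoses) < k:
        return None
    return (tl.diagnoses[k - 1].diagnosis_date - tl.diagnoses[0].diagnosis_date).days


@dataclass(frozen=True)
class IntervalSummary:
    n: int
    mean_days: float
    median_days: float
    sd_days: float
    ci95_lo: float
    ci95_hi: float

    @property
    def mean_years(self) -> float:
        return self.mean_days / DAYS_PER_YEAR

    @property
    def mean_months(self) -> float:
        return self.mean_days / (DAYS_PER_YEAR / 12)


def summarize(values: Sequence[float]) -> IntervalSummary:
    """Mean, median, sample SD and normal-approximation 95% CI of the mean.

    SD uses the n-1 denominator; a single observation reports SD 0 and a
    degenerate CI equal to the point estimate.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of durations")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    half = _Z95 * sd / np.sqrt(arr.size)
    return IntervalSummary(
        n=int(arr.size),
        mean_days=mean,
        median_days=float(np.median(arr)),
        sd_days=sd,
        ci95_lo=mean - half,
        ci95_hi=mean + half,
    )


def follow_up_table(timelines: Iterable[PatientTimeline]) -> pd.DataFrame:
    """Patient counts by follow-up category (layout: category, N, %)."""
    cats = [follow_up_category(observation_time(tl)) for tl in timelines]
    n_total = len(cats)
    rows = []
    for cat in FollowUpCategory:
        n = sum(c is cat for c in cats)
        rows.append(
            {
                "category": cat.value,
                "description": _CATEGORY_DESC[cat],
                "n": n,
                "percent": 100.0 * n / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def diagnoses_per_patient(timelines: Iterable[PatientTimeline]) -> pd.DataFrame:
    """Distribution of diagnosis counts: exclusively 1 / 2 / 3 / 4 or more."""
    counts = [len(tl) for tl in timelines]
    n_total = len(counts)
    buckets = [("1", lambda c: c == 1), ("2", lambda c: c == 2),
               ("3", lambda c: c == 3), ("4+", lambda c: c >= 4)]
    rows = []
    for name, pred in buckets:
        n = sum(pred(c) for c in counts)
        rows.append({"n_diagnoses": name, "n_patients": n,
                     "percent": 100.0 * n / n_total if n_total else 0.0})
    return pd.DataFrame(rows)


def interval_summaries(
    timelines: Iterable[PatientTimeline], ks: Sequence[int] = (2, 3, 4)
) -> dict[int, IntervalSummary]:
    """First-to-kth visit interval summaries over patients with >= k visits."""
    tls = list(timelines)
    out: dict[int, IntervalSummary] = {}
    for k in ks:
        vals = [v for tl in tls if (v := interval_to_kth(tl, k)) is not None]
        if vals:
            out[k] = summarize(vals)
    return out
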