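"""Longitudinal disease-change classification.

Orders each patient's structured diagnoses in time, applies the minimum-gap
rule (two visits must be at least 90 days apart to count as a transition),
and classifies disease change into progression / improvement / no-change /
unknown.  Two views are produced:

* a consecutive-pair scan that walks the timeline, skipping identical states
  and visits closer than the minimum gap to the current anchor, emitting
  labelled :class:`Transition` objects; and
* the headline per-patient cohort label, a first-versus-last comparison of
  the earliest and latest classifiable diagnoses.

Patients with fewer than two classifiable diagnoses at an eligible gap, or
whose states cannot be ordered (partial states tying on their shared prefix),
fall into the ``unknown`` cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .diagnosis_model import (
    ChangeLabel,
    Comparison,
    PDDiagnosis,
    compare_states,
    state_of,
)

DEFAULT_MIN_GAP_DAYS = 90

_LABEL_OF = {
    Comparison.WORSE: ChangeLabel.PROGRESSION,
    Comparison.BETTER: ChangeLabel.IMPROVEMENT,
    Comparison.SAME: ChangeLabel.NO_CHANGE,
    Comparison.INCOMPARABLE: ChangeLabel.UNKNOWN,
}


@dataclass(frozen=True)
class PatientTimeline:
    """Date-ordered diagnoses for one patient."""

    patient_id: str
    diagnoses: tuple[PDDiagnosis, ...]

    def __post_init__(self) -> None:
        if isinstance(self.diagnoses, list):
            object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        dates = [d.diagnosis_date for d in self.diagnoses]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("timeline dates must be non-decreasing")
        if any(d.patient_id != self.patient_id for d in self.diagnoses):
            raise ValueError("all records must share the timeline's patient_id")

    def __len__(self) -> int:
        return len(self.diagnoses)


@dataclass(frozen=True)
class Transition:
    """One From/To visit pair with its gap and (optionally) its label."""

    from_diag: PDDiagnosis
    to_diag: PDDiagnosis
    gap_days: int
    label: Optional[ChangeLabel] = None

    def __post_init__(self) -> None:
        if self.gap_days != (self.to_diag.diagnosis_date - self.from_diag.diagnosis_date).days:
            raise ValueError("gap_days inconsistent with the two dates")
        if self.gap_days < 0:
            raise ValueError("transitions must run forward in time")


def build_timeline(records: Sequence[PDDiagnosis]) -> PatientTimeline:
    """Stable-sort one patient's records by date and collapse same-day visits.

    Same-day duplicates keep the last-documented complete record: a record
    with a full (type, severity, extent) state is preferred; among equally
    complete records the later one in input order wins.
    """
    ids = {r.patient_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix patient ids: {sorted(ids)}")
    ordered = sorted(records, key=lambda r: r.diagnosis_date)  # stable

    def _completeness(r: PDDiagnosis) -> int:
        if r.disease_type is None:
            return 0
        if r.severity is not None and r.extent is not None:
            return 2
        return 1

    collapsed: list[PDDiagnosis] = []
    for rec in ordered:
        if collapsed and collapsed[-1].diagnosis_date == rec.diagnosis_date:
            if _completeness(rec) >= _completeness(collapsed[-1]):
                collapsed[-1] = rec
        else:
            collapsed.append(rec)
    pid = next(iter(ids)) if ids else ""
    return PatientTimeline(patient_id=pid, diagnoses=tuple(collapsed))


def classify_pair(from_diag: PDDiagnosis, to_diag: PDDiagnosis) -> ChangeLabel:
    """Label the change between two diagnoses taken in time order.

    A missing disease type on either side, or states that tie only on a
    partial prefix, give ``UNKNOWN``.
    """
    if from_diag.disease_type is None or to_diag.disease_type is None:
        return ChangeLabel.UNKNOWN
    return _LABEL_OF[compare_states(state_of(from_diag), state_of(to_diag))]


def eligible_pairs(
    tl: PatientTimeline, min_gap_days: int = DEFAULT_MIN_GAP_DAYS
) -> list[Transition]:
    """Consecutive From/To scan under the minimum-gap rule.

    The scan keeps an anchor ("From") visit and walks forward: a visit closer
    than ``min_gap_days`` to the anchor is ignored (anchor retained); a visit
    with a state identical to the anchor's is skipped and becomes the new
    anchor; otherwise the pair is emitted unlabelled and the "To" visit
    becomes the new anchor.  Records without a disease type cannot be
    compared and are passed over.
    """
    usable = [d for d in tl.diagnoses if d.disease_type is not None]
    if len(usable) < 2:
        return []
    out: list[Transition] = []
    anchor = usable[0]
    for nxt in usable[1:]:
        gap = (nxt.diagnosis_date - anchor.diagnosis_date).days
        if gap < min_gap_days:
            continue
        if compare_states(state_of(anchor), state_of(nxt)) is Comparison.SAME:
            anchor = nxt
            continue
        out.append(Transition(anchor, nxt, gap))
        anchor = nxt
    return out


def label_pairs(transitions: Iterable[Transition]) -> list[Transition]:
    """Attach a change label to each unlabelled transition."""
    return [
        Transition(t.from_diag, t.to_diag, t.gap_days, classify_pair(t.from_diag, t.to_diag))
        for t in transitions
    ]


def classify_patient(
    tl: PatientTimeline, min_gap_days: int = DEFAULT_MIN_GAP_DAYS
) -> ChangeLabel:
    """Headline cohort label: first versus last classifiable diagnosis.

    Intermediate excursions are ignored by definition.  Fewer than two
    classifiable diagnoses, or a first-to-last gap below ``min_gap_days``,
    give ``UNKNOWN``.
    """
    usable = [d for d in tl.diagnoses if d.disease_type is not None]
    if len(usable) < 2:
        return ChangeLabel.UNKNOWN
    first, last = usable[0], usable[-1]
    if (last.diagnosis_date - first.diagnosis_date).days < min_gap_days:
        return ChangeLabel.UNKNOWN
    return classify_pair(first, last)


@dataclass
class CohortPartition:
    """Cohort counts, per-patient labels, and per-(from,to) transition tallies."""

    labels: dict[str, ChangeLabel]
    counts: Counter = field(default_factory=Counter)
    transition_tallies: Counter = field(default_factory=Counter)

    @property
    def n_patients(self) -> int:
        return len(self.labels)

    def count(self, label: ChangeLabel) -> int:
        return self.counts.get(label, 0)


def generate_cohorts(
    timelines: Iterable[PatientTimeline],
    min_gap_days: int = DEFAULT_MIN_GAP_DAYS,
) -> CohortPartition:
    """Assign every patient to exactly one cohort and tally transitions.

    The four counts (progression / improvement / no-change / unknown) always
    sum to the number of input patients.  Transition tallies record
    ``(from_state, to_state, label)`` for each labelled consecutive pair,
    supporting an appendix-style category breakdown.
    """
    labels: dict[str, ChangeLabel] = {}
    tallies: Counter = Counter()
    for tl in timelines:
        labels[tl.patient_id] = classify_patient(tl, min_gap_days)
        for t in label_pairs(eligible_pairs(tl, min_gap_days)):
            key = (
                str(state_of(t.from_diag)),
                str(state_of(t.to_diag)),
                t.label.value,
            )
            tallies[key] += 1
    counts = Counter(labels.values())
    for lab in ChangeLabel:
        counts.setdefault(lab, 0)
    return CohortPartition(labels=labels, counts=counts, transition_tallies=tallies)
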