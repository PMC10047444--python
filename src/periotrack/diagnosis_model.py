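"""Controlled vocabularies, the structured diagnosis record, and the ordinal
disease-state lattice.

Clinician-written periodontal diagnoses combine up to five attributes: disease
type (gingivitis or periodontitis), severity (five ordinal grades from mild to
severe, including the intermediate "mild to moderate" and "moderate to severe"),
extent (localized or generalized), onset (acute or chronic), and location
(maxilla, mandible, tooth numbers).  Type, severity and extent induce a strict
ordinal lattice used to decide whether a patient's disease got worse, got
better, or stayed the same between two visits; location and onset are carried
as metadata only.

The ordering is lexicographic with type dominating severity dominating extent:
a change of type (gingivitis -> periodontitis) is progression regardless of
severity, a severity change decides when type ties, and an extent change
(localized -> generalized) decides when both type and severity tie.  States
with a missing severity or extent are *partial* and compare only on their
shared non-missing prefix; when that prefix ties the comparison is
``INCOMPARABLE`` and downstream classification reports "unknown".
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


class DiseaseType(str, enum.Enum):
    GINGIVITIS = "gingivitis"
    PERIODONTITIS = "periodontitis"


class Severity(str, enum.Enum):
    MILD = "mild"
    MILD_TO_MODERATE = "mild_to_moderate"
    MODERATE = "moderate"
    MODERATE_TO_SEVERE = "moderate_to_severe"
    SEVERE = "severe"


class Extent(str, enum.Enum):
    LOCALIZED = "localized"
    GENERALIZED = "generalized"


class Onset(str, enum.Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"


#: Ordinal ranks.  Intermediate severities interleave strictly between their
#: neighbours.
TYPE_RANK = {DiseaseType.GINGIVITIS: 1, DiseaseType.PERIODONTITIS: 2}
SEVERITY_RANK = {
    Severity.MILD: 1,
    Severity.MILD_TO_MODERATE: 2,
    Severity.MODERATE: 3,
    Severity.MODERATE_TO_SEVERE: 4,
    Severity.SEVERE: 5,
}
EXTENT_RANK = {Extent.LOCALIZED: 1, Extent.GENERALIZED: 2}


class ChangeLabel(str, enum.Enum):
    """Per-patient / per-pair disease-change category."""

    PROGRESSION = "progression"
    IMPROVEMENT = "improvement"
    NO_CHANGE = "no_change"
    UNKNOWN = "unknown"


class Comparison(str, enum.Enum):
    """Outcome of comparing two disease states in time order (a then b)."""

    WORSE = "worse"
    BETTER = "better"
    SAME = "same"
    INCOMPARABLE = "incomparable"


class UnclassifiableRecordError(ValueError):
    """Raised when a record without a disease type is asked for its state."""


@dataclass(frozen=True)
class PDDiagnosis:
    """One structured periodontal diagnosis extracted from a clinical note.

    Any attribute except ``patient_id`` and ``diagnosis_date`` may be missing
    (``None`` / empty list); a record whose ``disease_type`` is missing is the
    "missing / no disease mentioned / algorithm error" bucket and carries no
    severity, extent or onset.
    """

    patient_id: str
    diagnosis_date: _dt.date
    disease_type: Optional[DiseaseType] = None
    severity: Optional[Severity] = None
    extent: Optional[Extent] = None
    location: tuple[str, ...] = ()
    onset: Optional[Onset] = None
    source_text: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.diagnosis_date, _dt.date):
            raise TypeError("diagnosis_date must be a datetime.date")
        if isinstance(self.location, list):
            object.__setattr__(self, "location", tuple(self.location))
        if self.disease_type is None and (
            self.severity is not None
            or self.extent is not None
            or self.onset is not None
        ):
            raise ValueError(
                "a record with missing disease_type must not carry "
                "severity/extent/onset"
            )

    @property
    def is_missing_bucket(self) -> bool:
        return self.disease_type is None


@dataclass(frozen=True, order=False)
class DiseaseState:
    """Ordinal position of a diagnosis on the (type, severity, extent) lattice.

    ``severity_rank`` / ``extent_rank`` are ``None`` for partial states.
    """

    type_rank: int
    severity_rank: Optional[int] = None
    extent_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.type_rank not in (1, 2):
            raise ValueError("type_rank must be 1 (gingivitis) or 2 (periodontitis)")
        if self.severity_rank is not None and not 1 <= self.severity_rank <= 5:
            raise ValueError("severity_rank must be in 1..5")
        if self.extent_rank is not None and self.extent_rank not in (1, 2):
            raise ValueError("extent_rank must be 1 (localized) or 2 (generalized)")

    @property
    def completeness(self) -> str:
        return "full" if self.is_full else "partial"

    @property
    def is_full(self) -> bool:
        return self.severity_rank is not None and self.extent_rank is not None

    def ranks(self) -> tuple[Optional[int], Optional[int], Optional[int]]:
        return (self.type_rank, self.severity_rank, self.extent_rank)

    def __str__(self) -> str:
        parts = []
        if self.extent_rank is not None:
            parts.append(
                {1: Extent.LOCALIZED, 2: Extent.GENERALIZED}[self.extent_rank].value
            )
        if self.severity_rank is not None:
            sev = {v: k for k, v in SEVERITY_RANK.items()}[self.severity_rank]
            parts.append(sev.value.replace("_", " "))
        parts.append(
            {1: DiseaseType.GINGIVITIS, 2: DiseaseType.PERIODONTITIS}[
                self.type_rank
            ].value
        )
        return " ".join(parts)


def state_of(diag: PDDiagnosis) -> DiseaseState:
    """Canonicalize a diagnosis record into its lattice state.

    Location and onset never influence the state.  Raises
    :class:`UnclassifiableRecordError` for missing-bucket records.
    """
    if diag.disease_type is None:
        raise UnclassifiableRecordError(
            f"record for patient {diag.patient_id!r} on {diag.diagnosis_date} "
            "has no disease type and cannot be placed on the lattice"
        )
    return DiseaseState(
        type_rank=TYPE_RANK[diag.disease_type],
        severity_rank=SEVERITY_RANK[diag.severity] if diag.severity else None,
        extent_rank=EXTENT_RANK[diag.extent] if diag.extent else None,
    )


def compare_states(a: DiseaseState, b: DiseaseState) -> Comparison:
    """Compare two states in time order: did the disease get worse from a to b?

    Full states compare lexicographically on (type, severity, extent); ``b``
    greater means ``WORSE`` (the progression direction).  If either state is
    partial, only the longest shared non-missing prefix is compared; a tie on
    that prefix with a missing compared-out field on either side is
    ``INCOMPARABLE``.
    """
    for ra, rb in zip(a.ranks(), b.ranks()):
        if ra is None or rb is None:
            return Comparison.INCOMPARABLE
        if rb > ra:
            return Comparison.WORSE
        if rb < ra:
            return Comparison.BETTER
    return Comparison.SAME


def all_full_states() -> Iterator[DiseaseState]:
    """Enumerate the 20 full states in ascending lattice order."""
    for t in sorted(TYPE_RANK.values()):
        for s in sorted(SEVERITY_RANK.values()):
            for e in sorted(EXTENT_RANK.values()):
                yield DiseaseState(t, s, e)


# ---------------------------------------------------------------------------
# JSON serialization of the vocabularies / rank tables, so deployments can
# extend synonyms without code change.

def rank_tables() -> dict:
    return {
        "disease_type": {k.value: v for k, v in TYPE_RANK.items()},
        "severity": {k.value: v for k, v in SEVERITY_RANK.items()},
        "extent": {k.value: v for k, v in EXTENT_RANK.items()},
        "onset": [o.value for o in Onset],
    }


def dump_rank_tables(path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rank_tables(), fh, indent=2)
        fh.write("\n")
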