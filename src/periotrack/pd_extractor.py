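"""Fuzzy-matching extraction of structured periodontal diagnoses from
free-text clinical notes.

The extractor works bottom-up: it tokenizes the note, runs approximate string
matching (Levenshtein distance via :mod:`edlib`) of token n-grams against a
controlled lexicon, then assembles one structured :class:`PDDiagnosis` per
disease-type mention by attaching nearby severity / extent / onset / location
modifiers.  When attributes are absent the extractor degrades gracefully and
emits the fields it did find with explicit missing markers; a note with no
recognizable disease type yields a single "missing bucket" record so that the
record stream stays aligned with the note stream.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib

from .diagnosis_model import (
    DiseaseType,
    Extent,
    Onset,
    PDDiagnosis,
    Severity,
)

# Fields a lexicon entry may target.
_FIELDS = ("disease_type", "severity", "extent", "onset", "location")

#: How far (in tokens) a modifier may sit from the disease-type token it
#: attaches to.
ATTACH_WINDOW = 6


@dataclass(frozen=True)
class ClinicalNote:
    """One dated free-text note for one patient."""

    patient_id: str
    visit_date: _dt.date
    text: str = ""


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # character offset in the original text
    end: int


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> list[Token]:
    """Lowercase and split on any non-alphanumeric run, preserving order.

    Hyphens and other punctuation split tokens, so ``"mod-severe perio"``
    yields ``[mod, severe, perio]``.
    """
    lowered = text.lower()
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(lowered)]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (insert / delete / substitute)."""
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class LexiconEntry:
    term: str  # lowercase surface form; may be multi-word
    target_field: str  # one of _FIELDS
    canonical_value: str

    def __post_init__(self) -> None:
        if self.target_field not in _FIELDS:
            raise ValueError(f"unknown target field {self.target_field!r}")
        if self.term != self.term.lower():
            raise ValueError("lexicon surface terms must be lowercase")


def default_max_distance(term: str) -> int:
    """Default per-term edit-distance budget: ``max(1, len//5)`` capped at 2.

    Tolerates a single typo on short terms without letting ``mild`` collapse
    into ``moderate`` (distance 6).
    """
    return min(2, max(1, len(term) // 5))


@dataclass
class Lexicon:
    """Surface-term -> (field, canonical value) map with fuzzy thresholds.

    ``max_distances`` overrides the per-term default budget for a whole field;
    ``global_cap`` (e.g. from the CLI ``--max-dist``) caps every budget.
    """

    entries: list[LexiconEntry]
    max_distances: dict[str, int] = field(default_factory=dict)
    global_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon must be non-empty")
        # token-count buckets for n-gram matching
        self._by_len: dict[int, list[tuple[int, LexiconEntry]]] = {}
        for idx, e in enumerate(self.entries):
            n = len(e.term.split())
            self._by_len.setdefault(n, []).append((idx, e))
        self.max_ngram = max(self._by_len)

    def threshold(self, entry: LexiconEntry) -> int:
        t = self.max_distances.get(entry.target_field, default_max_distance(entry.term))
        if self.global_cap is not None:
            t = min(t, self.global_cap)
        return t

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "entries": [
                {"term": e.term, "field": e.target_field, "value": e.canonical_value}
                for e in self.entries
            ],
            "max_distances": self.max_distances,
            "global_cap": self.global_cap,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        entries = [
            LexiconEntry(d["term"], d["field"], d["value"])
            for d in payload["entries"]
        ]
        return cls(
            entries,
            max_distances=dict(payload.get("max_distances", {})),
            global_cap=payload.get("global_cap"),
        )


def default_lexicon(max_dist: Optional[int] = None) -> Lexicon:
    """The built-in vocabulary: canonical terms plus common chart shorthand.

    Compound severities are listed before their single-word components so that
    on a distance tie the longer span wins ("mild to moderate" is never
    shadowed by "mild").
    """
    raw: list[tuple[str, str, str]] = [
        # compound severities first (longest spans, matched as 3-grams)
        ("mild to moderate", "severity", Severity.MILD_TO_MODERATE.value),
        ("moderate to severe", "severity", Severity.MODERATE_TO_SEVERE.value),
        # disease type
        ("periodontitis", "disease_type", DiseaseType.PERIODONTITIS.value),
        ("gingivitis", "disease_type", DiseaseType.GINGIVITIS.value),
        ("perio", "disease_type", DiseaseType.PERIODONTITIS.value),
        # severity
        ("mild", "severity", Severity.MILD.value),
        ("slight", "severity", Severity.MILD.value),
        ("moderate", "severity", Severity.MODERATE.value),
        ("mod", "severity", Severity.MODERATE.value),
        ("severe", "severity", Severity.SEVERE.value),
        ("advanced", "severity", Severity.SEVERE.value),
        # extent
        ("localized", "extent", Extent.LOCALIZED.value),
        ("local", "extent", Extent.LOCALIZED.value),
        ("generalized", "extent", Extent.GENERALIZED.value),
        ("general", "extent", Extent.GENERALIZED.value),
        # onset
        ("acute", "onset", Onset.ACUTE.value),
        ("chronic", "onset", Onset.CHRONIC.value),
        # location
        ("maxilla", "location", "maxilla"),
        ("maxillary", "location", "maxilla"),
        ("mandible", "location", "mandible"),
        ("mandibular", "location", "mandible"),
    ]
    return Lexicon(
        [LexiconEntry(t, f, v) for t, f, v in raw],
        global_cap=max_dist,
    )


@dataclass(frozen=True)
class Match:
    """One lexicon hit: a token span resolved to a canonical field value."""

    target_field: str
    canonical_value: str
    matched_span: str
    distance: int
    token_start: int  # index of first token of the span
    token_end: int  # exclusive


def fuzzy_match(tokens: Sequence[Token], lex: Lexicon) -> list[Match]:
    """Approximate-match token n-grams against the lexicon.

    Every n-gram within its entry's edit-distance budget is a candidate; for
    overlapping candidates the lowest distance wins, ties broken by longest
    span, then earliest lexicon entry, then earliest position — fully
    deterministic.
    """
    candidates: list[tuple[int, int, int, int, int, LexiconEntry]] = []
    for n, bucket in lex._by_len.items():
        for start in range(len(tokens) - n + 1):
            gram = " ".join(t.text for t in tokens[start : start + n])
            for entry_idx, entry in bucket:
                d = edit_distance(gram, entry.term)
                if d <= lex.threshold(entry):
                    # sort key: distance, longer span first, entry order, position
                    candidates.append((d, -n, entry_idx, start, n, entry))
    candidates.sort(key=lambda c: c[:4])

    taken = [False] * len(tokens)
    out: list[Match] = []
    for d, _neg_n, _idx, start, n, entry in candidates:
        if any(taken[start : start + n]):
            continue
        for i in range(start, start + n):
            taken[i] = True
        out.append(
            Match(
                target_field=entry.target_field,
                canonical_value=entry.canonical_value,
                matched_span=" ".join(t.text for t in tokens[start : start + n]),
                distance=d,
                token_start=start,
                token_end=start + n,
            )
        )
    out.sort(key=lambda m: m.token_start)
    return out


# tooth-number locations: "tooth 3", "teeth 3 and 14", "#12"
_TOOTH_WORDS = {"tooth", "teeth"}


def _tooth_number_matches(tokens: Sequence[Token], claimed: set[int]) -> list[Match]:
    out = []
    i = 0
    while i < len(tokens):
        if tokens[i].text in _TOOTH_WORDS and i not in claimed:
            j = i + 1
            while j < len(tokens):
                if tokens[j].text.isdigit() and len(tokens[j].text) <= 2:
                    out.append(
                        Match("location", f"tooth {tokens[j].text}",
                              f"{tokens[i].text} {tokens[j].text}", 0, i, j + 1)
                    )
                    j += 1
                elif tokens[j].text == "and":
                    j += 1
                else:
                    break
            i = j
        else:
            i += 1
    return out


def _attach_target(mod_start: int, type_positions: list[int]) -> Optional[int]:
    """Pick the disease-type token a modifier binds to.

    Prefer the nearest type token *following* the modifier within the window
    (natural "generalized mild periodontitis" order); otherwise the nearest
    preceding one within the window ("periodontitis of the mandible").
    """
    following = [p for p in type_positions if p >= mod_start and p - mod_start <= ATTACH_WINDOW]
    if following:
        return min(following)
    preceding = [p for p in type_positions if p < mod_start and mod_start - p <= ATTACH_WINDOW]
    if preceding:
        return max(preceding)
    return None


def extract_diagnoses(note: ClinicalNote, lex: Optional[Lexicon] = None) -> list[PDDiagnosis]:
    """Bottom-up extraction: one structured record per disease-type mention.

    Modifiers bind to the nearest disease-type token within ``ATTACH_WINDOW``
    tokens (the following one preferred); unattached modifiers are dropped.
    Absent attributes are reported as explicit missing markers rather than
    errors.  A note without a disease-type match yields one missing-bucket
    record.
    """
    if lex is None:
        lex = default_lexicon()
    tokens = normalize(note.text)
    matches = fuzzy_match(tokens, lex)
    claimed = {i for m in matches for i in range(m.token_start, m.token_end)}
    matches = matches + _tooth_number_matches(tokens, claimed)
    matches.sort(key=lambda m: m.token_start)

    type_matches = [m for m in matches if m.target_field == "disease_type"]
    if not type_matches:
        return [
            PDDiagnosis(
                patient_id=note.patient_id,
                diagnosis_date=note.visit_date,
                source_text=note.text,
            )
        ]

    type_positions = [m.token_start for m in type_matches]
    by_pos = {m.token_start: m for m in type_matches}
    fields: dict[int, dict] = {
        p: {"severity": None, "extent": None, "onset": None, "location": []}
        for p in type_positions
    }
    for m in matches:
        if m.target_field == "disease_type":
            continue
        target = _attach_target(m.token_start, type_positions)
        if target is None:
            continue
        slot = fields[target]
        if m.target_field == "location":
            slot["location"].append(m.canonical_value)
        elif slot[m.target_field] is None:  # first (nearest-scan) modifier wins
            slot[m.target_field] = m.canonical_value

    records = []
    for p in type_positions:
        tm = by_pos[p]
        f = fields[p]
        records.append(
            PDDiagnosis(
                patient_id=note.patient_id,
                diagnosis_date=note.visit_date,
                disease_type=DiseaseType(tm.canonical_value),
                severity=Severity(f["severity"]) if f["severity"] else None,
                extent=Extent(f["extent"]) if f["extent"] else None,
                onset=Onset(f["onset"]) if f["onset"] else None,
                location=tuple(f["location"]),
                source_text=note.text,
            )
        )
    return records


def extract_corpus(
    notes: Iterable[ClinicalNote], lex: Optional[Lexicon] = None
) -> list[PDDiagnosis]:
    """Extract every note in a corpus, preserving note order."""
    if lex is None:
        lex = default_lexicon()
    out: list[PDDiagnosis] = []
    for note in notes:
        out.extend(extract_diagnoses(note, lex))
    return out
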