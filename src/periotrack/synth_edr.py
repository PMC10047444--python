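"""Seeded synthetic longitudinal EDR corpora.

Real periodontal-diagnosis notes cannot be shared (they are identifiable
clinical text), so this module generates corpora that emulate their structure:
short free-text diagnosis statements of the form extent + severity + onset +
type + location with field dropout, misspellings, multi-visit timelines with
heavy-tailed inter-visit gaps, and a large single-visit fraction.  Each
corpus ships with gold structured labels and a planted per-patient trajectory
(progress / improve / static), so extraction and change classification are
testable end to end with the truth known by construction.

Default condition parameters mirror the documentation-density profile of a
large dental-school record system: 58% of patients with exactly one
documented diagnosis, 24% with two, 8% with three and 10% with four or more;
lognormal inter-visit gaps with a median of 346 days; and a trajectory mix of
75% static, 13% progressing, 12% improving patients.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import string as _string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diagnosis_model import (
    ChangeLabel,
    DiseaseState,
    DiseaseType,
    Extent,
    Onset,
    PDDiagnosis,
    Severity,
    all_full_states,
    SEVERITY_RANK,
)
from .pd_extractor import ClinicalNote

TRAJECTORIES = ("static", "progress", "improve")

#: Planted trajectory -> the cohort label a perfect pipeline should recover.
PLANTED_TO_LABEL = {
    "static": ChangeLabel.NO_CHANGE,
    "progress": ChangeLabel.PROGRESSION,
    "improve": ChangeLabel.IMPROVEMENT,
}

#: Diagnosis-statement patterns; fields drop out cleanly when missing.
DEFAULT_TEMPLATES = (
    "{extent} {severity} {onset} {type} {location}.",
    "Patient presents with {extent} {severity} {onset} {type} {location}.",
    "Diagnosis: {extent} {severity} {onset} {type} {location}.",
    "Exam completed. Impression: {extent} {severity} {onset} {type} {location}.",
    "{severity} {onset} {type}, {extent} {location}.",
)

NO_DIAGNOSIS_TEXT = "Patient seen for routine prophylaxis; no diagnosis documented."


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic corpus generator."""

    n_patients: int = 100
    seed: int = 0
    entry_window: tuple[str, str] = ("2009-01-01", "2014-12-31")
    #: probability of exactly 1 / 2 / 3 / 4-or-more documented diagnoses
    visit_count_probs: dict = field(
        default_factory=lambda: {"1": 0.58, "2": 0.24, "3": 0.08, "4+": 0.10}
    )
    gap_median_days: float = 346.0
    gap_log_sd: float = 0.9
    trajectory_probs: dict = field(
        default_factory=lambda: {"static": 0.75, "progress": 0.13, "improve": 0.12}
    )
    #: lattice-step sizes for one trajectory move
    step_magnitude_probs: dict = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    #: per-field probability that a note omits the field.  disease_type
    #: dropout is drawn per visit (an occasional unparseable note); the other
    #: fields are a per-patient documentation habit, constant across visits.
    missingness: dict = field(
        default_factory=lambda: {
            "disease_type": 0.02,
            "severity": 0.14,
            "extent": 0.10,
            "onset": 0.80,
            "location": 0.70,
        }
    )
    typo_rate: float = 0.05
    templates: tuple[str, ...] = DEFAULT_TEMPLATES

    def __post_init__(self) -> None:
        for name, probs in (
            ("visit_count_probs", self.visit_count_probs),
            ("trajectory_probs", self.trajectory_probs),
            ("step_magnitude_probs", self.step_magnitude_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0 <= self.typo_rate <= 1:
            raise ValueError("typo_rate must be a probability")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["entry_window"] = list(self.entry_window)
        d["templates"] = list(self.templates)
        return d

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if "entry_window" in d:
            d["entry_window"] = tuple(d["entry_window"])
        if "templates" in d:
            d["templates"] = tuple(d["templates"])
        if "step_magnitude_probs" in d:
            d["step_magnitude_probs"] = {
                int(k): v for k, v in d["step_magnitude_probs"].items()
            }
        return cls(**d)


@dataclass(frozen=True)
class GoldRecord:
    """One emitted note plus its ground truth."""

    note: ClinicalNote
    diagnosis: PDDiagnosis
    trajectory: str


_STATES: list[DiseaseState] = list(all_full_states())
_SEV_BY_RANK = {v: k for k, v in SEVERITY_RANK.items()}


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # one stream per patient so corpora reproduce under any generation order
    return np.random.default_rng([seed, patient_index])


def _sample_n_visits(cfg: SimConfig, rng: np.random.Generator) -> int:
    keys = list(cfg.visit_count_probs)
    probs = np.array([cfg.visit_count_probs[k] for k in keys])
    choice = keys[rng.choice(len(keys), p=probs)]
    if choice == "4+":
        return int(min(28, 3 + rng.geometric(0.5)))
    return int(choice)


def simulate_trajectory(
    cfg: SimConfig, rng: np.random.Generator, n_visits: int, trajectory: str
) -> list[DiseaseState]:
    """Monotone lattice walk over the 20 full states.

    ``static`` repeats one state; ``progress`` walks non-decreasing with a
    strictly worse last-versus-first state; ``improve`` is the mirror image.
    """
    if trajectory not in TRAJECTORIES:
        raise ValueError(f"unknown trajectory {trajectory!r}")
    top = len(_STATES) - 1
    if trajectory == "static":
        idx = int(rng.integers(0, top + 1))
        return [_STATES[idx]] * n_visits
    sign = 1 if trajectory == "progress" else -1
    # leave room for at least one step in the trajectory's direction
    start = int(rng.integers(0, top)) if sign == 1 else int(rng.integers(1, top + 1))
    mags = list(cfg.step_magnitude_probs)
    mag_p = np.array([cfg.step_magnitude_probs[m] for m in mags])
    idxs = [start]
    for _ in range(n_visits - 1):
        step = 0
        if rng.random() < 0.5:
            step = sign * int(mags[rng.choice(len(mags), p=mag_p)])
        idxs.append(int(np.clip(idxs[-1] + step, 0, top)))
    if n_visits > 1 and idxs[-1] == start:  # force a net change
        mag = int(mags[rng.choice(len(mags), p=mag_p)])
        idxs[-1] = int(np.clip(start + sign * mag, 0, top))
        if idxs[-1] == start:
            idxs[-1] = start + sign
    return [_STATES[i] for i in idxs]


def _apply_typo(word: str, rng: np.random.Generator) -> str:
    """One random character edit (substitute / insert / delete)."""
    letters = _string.ascii_lowercase
    op = rng.choice(3) if len(word) > 1 else rng.choice(2)  # no delete to empty
    pos = int(rng.integers(0, len(word)))
    if op == 0:  # substitute with a different letter
        repl = letters[int(rng.integers(0, 26))]
        while repl == word[pos]:
            repl = letters[int(rng.integers(0, 26))]
        return word[:pos] + repl + word[pos + 1 :]
    if op == 1:  # insert
        ins = letters[int(rng.integers(0, 26))]
        return word[:pos] + ins + word[pos:]
    return word[:pos] + word[pos + 1 :]  # delete


def _perturb(phrase_words: list[tuple[str, bool]], rate: float,
             rng: np.random.Generator) -> str:
    out = []
    for word, is_content in phrase_words:
        if is_content and rate > 0 and rng.random() < rate:
            core = word.strip(".,:;")
            lead = word[: len(word) - len(word.lstrip(".,:;"))]
            trail = word[len(lead) + len(core) :]
            word = lead + _apply_typo(core, rng) + trail
        out.append(word)
    return " ".join(out)


def render_note(
    diag: PDDiagnosis, cfg: SimConfig, rng: np.random.Generator
) -> ClinicalNote:
    """Render a structured diagnosis into free text.

    The template slot for each missing field collapses cleanly; content
    tokens (the diagnosis terms themselves) each receive at most one random
    character edit at ``cfg.typo_rate``.  Records with no disease type render
    a fixed no-diagnosis note.
    """
    if diag.disease_type is None:
        return ClinicalNote(diag.patient_id, diag.diagnosis_date, NO_DIAGNOSIS_TEXT)
    template = cfg.templates[int(rng.integers(0, len(cfg.templates)))]
    parts = {
        "extent": diag.extent.value if diag.extent else "",
        "severity": diag.severity.value.replace("_", " ") if diag.severity else "",
        "onset": diag.onset.value if diag.onset else "",
        "type": diag.disease_type.value,
        "location": ("of the " + " and ".join(diag.location)) if diag.location else "",
    }
    filled = template.format(**parts)
    content_words = {
        w for key in ("extent", "severity", "onset", "type") for w in parts[key].split()
    } | set(diag.location)
    words: list[tuple[str, bool]] = []
    for raw in filled.split():
        words.append((raw, raw.strip(".,:;").lower() in content_words))
    text = _perturb(words, cfg.typo_rate, rng)
    # tidy artifacts left by empty slots
    text = " ".join(text.split())
    text = text.replace(" ,", ",").replace(" .", ".").replace(",.", ".")
    if text.startswith(",") or text.startswith("."):
        text = text.lstrip(",. ")
    return ClinicalNote(diag.patient_id, diag.diagnosis_date, text)


def _documentation_habit(cfg: SimConfig, rng: np.random.Generator) -> dict[str, bool]:
    """Which optional fields this patient's clinician habitually documents."""
    return {
        f: rng.random() >= cfg.missingness.get(f, 0.0)
        for f in ("severity", "extent", "onset", "location")
    }


def _diagnosis_from_state(
    pid: str,
    date: _dt.date,
    state: DiseaseState,
    cfg: SimConfig,
    habit: dict[str, bool],
    rng: np.random.Generator,
) -> PDDiagnosis:
    """Apply field dropout and sample the metadata fields."""
    if rng.random() < cfg.missingness.get("disease_type", 0.0):
        return PDDiagnosis(pid, date)
    severity = None
    if habit["severity"]:
        severity = _SEV_BY_RANK[state.severity_rank]
    extent = None
    if habit["extent"]:
        extent = Extent.LOCALIZED if state.extent_rank == 1 else Extent.GENERALIZED
    onset = None
    if habit["onset"]:
        onset = Onset.CHRONIC if rng.random() < 0.8 else Onset.ACUTE
    location: tuple[str, ...] = ()
    if habit["location"]:
        location = (("maxilla",), ("mandible",), ("maxilla", "mandible"))[
            rng.choice(3, p=[0.4, 0.4, 0.2])
        ]
    dtype = DiseaseType.GINGIVITIS if state.type_rank == 1 else DiseaseType.PERIODONTITIS
    return PDDiagnosis(
        patient_id=pid,
        diagnosis_date=date,
        disease_type=dtype,
        severity=severity,
        extent=extent,
        location=location,
        onset=onset,
    )


def simulate_patient(cfg: SimConfig, patient_index: int) -> list[GoldRecord]:
    """Generate one patient's full visit history (deterministic per index)."""
    rng = _patient_rng(cfg.seed, patient_index)
    pid = f"P{patient_index:06d}"
    n_visits = _sample_n_visits(cfg, rng)
    keys = list(cfg.trajectory_probs)
    probs = np.array([cfg.trajectory_probs[k] for k in keys])
    trajectory = keys[rng.choice(len(keys), p=probs)]
    states = simulate_trajectory(cfg, rng, n_visits, trajectory)
    habit = _documentation_habit(cfg, rng)

    start, end = (_dt.date.fromisoformat(d) for d in cfg.entry_window)
    date = start + _dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))
    mu = np.log(cfg.gap_median_days)
    records = []
    for i, state in enumerate(states):
        if i > 0:
            gap = max(1, int(round(rng.lognormal(mu, cfg.gap_log_sd))))
            date = date + _dt.timedelta(days=gap)
        diag = _diagnosis_from_state(pid, date, state, cfg, habit, rng)
        note = render_note(diag, cfg, rng)
        diag = dataclasses.replace(diag, source_text=note.text)
        records.append(GoldRecord(note=note, diagnosis=diag, trajectory=trajectory))
    return records


def generate_corpus(
    cfg: SimConfig, out_dir: Optional[Path | str] = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the full corpus: notes table, gold table, manifest.

    Re-running with the same config reproduces byte-identical CSV/JSON files.
    """
    note_rows, gold_rows = [], []
    for i in range(cfg.n_patients):
        for rec in simulate_patient(cfg, i):
            note_rows.append(
                {
                    "patient_id": rec.note.patient_id,
                    "visit_date": rec.note.visit_date.isoformat(),
                    "text": rec.note.text,
                }
            )
            d = rec.diagnosis
            gold_rows.append(
                {
                    "patient_id": d.patient_id,
                    "visit_date": d.diagnosis_date.isoformat(),
                    "disease_type": d.disease_type.value if d.disease_type else "",
                    "severity": d.severity.value if d.severity else "",
                    "extent": d.extent.value if d.extent else "",
                    "onset": d.onset.value if d.onset else "",
                    "location": ";".join(d.location),
                    "trajectory": rec.trajectory,
                }
            )
    cols_notes = ["patient_id", "visit_date", "text"]
    cols_gold = [
        "patient_id", "visit_date", "disease_type", "severity",
        "extent", "onset", "location", "trajectory",
    ]
    notes = pd.DataFrame(note_rows, columns=cols_notes)
    gold = pd.DataFrame(gold_rows, columns=cols_gold)
    manifest = {
        "config": cfg.to_dict(),
        "n_patients": cfg.n_patients,
        "n_notes": len(notes),
        "files": {"notes": "notes.csv", "gold": "gold.csv"},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        notes.to_csv(out / "notes.csv", index=False)
        gold.to_csv(out / "gold.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return notes, gold, manifest
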