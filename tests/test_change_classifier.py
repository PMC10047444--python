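"""Timeline construction, the 90-day rule, and cohort assignment."""

import datetime as dt
import itertools

import pytest

from periotrack.change_classifier import (
    PatientTimeline,
    build_timeline,
    classify_pair,
    classify_patient,
    eligible_pairs,
    generate_cohorts,
)
from periotrack.diagnosis_model import (
    ChangeLabel,
    Comparison,
    all_full_states,
    compare_states,
    state_of,
)

from conftest import make_diag

D0 = dt.date(2010, 1, 1)


def at_day(day, **kw):
    return make_diag(date=D0 + dt.timedelta(days=day), **kw)


def mild_perio(day, extent="generalized"):
    return at_day(day, disease_type="periodontitis", severity="mild", extent=extent)


class TestBuildTimeline:
    def test_sorts_by_date(self):
        recs = [
            make_diag("gingivitis", "mild", "localized", date=dt.date(2010, 1, 1)),
            make_diag("gingivitis", "mild", "localized", date=dt.date(2009, 6, 1)),
            make_diag("gingivitis", "mild", "localized", date=dt.date(2012, 3, 1)),
        ]
        tl = build_timeline(recs)
        assert [d.diagnosis_date.year for d in tl.diagnoses] == [2009, 2010, 2012]

    def test_same_day_collapse_prefers_complete_record(self):
        partial = make_diag("periodontitis", "mild")
        full = make_diag("periodontitis", "mild", "generalized")
        for order in ([partial, full], [full, partial]):
            tl = build_timeline(order)
            assert len(tl) == 1 and tl.diagnoses[0].extent is not None

    def test_same_day_equal_completeness_keeps_last_documented(self):
        a = make_diag("gingivitis", "mild", "localized", source_text="first")
        b = make_diag("gingivitis", "moderate", "localized", source_text="second")
        tl = build_timeline([a, b])
        assert tl.diagnoses[0].source_text == "second"

    def test_empty_and_mixed_ids(self):
        assert len(build_timeline([])) == 0
        with pytest.raises(ValueError):
            build_timeline([make_diag(patient_id="a"), make_diag(patient_id="b")])

    def test_timeline_rejects_unsorted_dates(self):
        with pytest.raises(ValueError):
            PatientTimeline("p1", (mild_perio(10), mild_perio(0)))


class TestEligiblePairs:
    @pytest.mark.parametrize("gap, n_pairs", [(89, 0), (90, 1), (91, 1), (200, 1)])
    def test_minimum_gap_inclusive(self, gap, n_pairs):
        tl = build_timeline([mild_perio(0), at_day(gap, disease_type="periodontitis",
                                                   severity="moderate", extent="generalized")])
        assert len(eligible_pairs(tl)) == n_pairs

    def test_single_visit_yields_nothing(self):
        assert eligible_pairs(build_timeline([mild_perio(0)])) == []

    def test_close_visit_ignored_anchor_retained(self):
        # day 0 -> day 30 (too close, ignored) -> day 120 pairs with day 0
        tl = build_timeline([
            mild_perio(0),
            at_day(30, disease_type="periodontitis", severity="severe", extent="generalized"),
            at_day(120, disease_type="periodontitis", severity="moderate", extent="generalized"),
        ])
        pairs = eligible_pairs(tl)
        assert len(pairs) == 1
        assert pairs[0].from_diag.diagnosis_date == D0
        assert pairs[0].gap_days == 120

    def test_identical_states_skipped_and_scan_advances(self):
        tl = build_timeline([
            mild_perio(0), mild_perio(200),
            at_day(400, disease_type="periodontitis", severity="moderate", extent="generalized"),
        ])
        pairs = eligible_pairs(tl)
        assert len(pairs) == 1
        # the anchor moved to day 200 when the identical pair was skipped
        assert pairs[0].gap_days == 200

    def test_min_gap_monotonicity(self):
        tl = build_timeline([
            mild_perio(0),
            at_day(100, disease_type="periodontitis", severity="moderate", extent="generalized"),
            at_day(250, disease_type="periodontitis", severity="severe", extent="generalized"),
            at_day(500, disease_type="gingivitis", severity="mild", extent="localized"),
        ])
        counts = [len(eligible_pairs(tl, g)) for g in range(0, 600, 25)]
        assert counts == sorted(counts, reverse=True)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "frm, to, label",
        [
            # the published worked transitions
            (("periodontitis", "mild", "generalized"),
             ("periodontitis", "moderate", "localized"), ChangeLabel.PROGRESSION),
            (("periodontitis", "moderate", "generalized"),
             ("periodontitis", "severe", "localized"), ChangeLabel.PROGRESSION),
            (("periodontitis", "mild", "generalized"),
             ("periodontitis", "moderate", "generalized"), ChangeLabel.PROGRESSION),
            (("periodontitis", "moderate", "generalized"),
             ("periodontitis", "mild", "generalized"), ChangeLabel.IMPROVEMENT),
            (("periodontitis", "mild", "generalized"),
             ("gingivitis", "mild", "generalized"), ChangeLabel.IMPROVEMENT),
            (("periodontitis", "mild", "generalized"),
             ("periodontitis", "mild", "localized"), ChangeLabel.IMPROVEMENT),
            (("gingivitis", "mild", "generalized"),
             ("periodontitis", "mild", "generalized"), ChangeLabel.PROGRESSION),
            (("gingivitis", "mild", "localized"),
             ("gingivitis", "mild", "localized"), ChangeLabel.NO_CHANGE),
        ],
    )
    def test_examples(self, frm, to, label):
        assert classify_pair(make_diag(*frm), make_diag(*to)) is label

    def test_bare_type_within_type_is_unknown(self):
        assert classify_pair(
            make_diag("periodontitis"), make_diag("periodontitis", "mild", "localized")
        ) is ChangeLabel.UNKNOWN

    def test_missing_type_is_unknown(self):
        assert classify_pair(make_diag(), make_diag("gingivitis", "mild", "localized")) \
            is ChangeLabel.UNKNOWN

    def test_oracle_equivalence_over_all_pairs(self, enumerated_full_order):
        """classify_pair agrees with the enumerated-order oracle on all 400
        ordered full-state pairs."""
        pos = {t: i for i, t in enumerate(enumerated_full_order)}
        sev = {1: "mild", 2: "mild_to_moderate", 3: "moderate",
               4: "moderate_to_severe", 5: "severe"}

        def diag_of(t):
            return make_diag(
                "gingivitis" if t[0] == 1 else "periodontitis",
                sev[t[1]],
                "localized" if t[2] == 1 else "generalized",
            )

        for a, b in itertools.product(enumerated_full_order, repeat=2):
            got = classify_pair(diag_of(a), diag_of(b))
            ia, ib = pos[a], pos[b]
            want = (
                ChangeLabel.NO_CHANGE if ia == ib
                else ChangeLabel.PROGRESSION if ib > ia
                else ChangeLabel.IMPROVEMENT
            )
            assert got is want


class TestClassifyPatient:
    def test_first_vs_last(self):
        tl = build_timeline([
            at_day(0, disease_type="periodontitis", severity="moderate", extent="generalized"),
            at_day(5 * 365, disease_type="periodontitis", severity="mild", extent="generalized"),
        ])
        assert classify_patient(tl) is ChangeLabel.IMPROVEMENT

    def test_single_diagnosis_is_unknown(self):
        assert classify_patient(build_timeline([mild_perio(0)])) is ChangeLabel.UNKNOWN

    def test_intermediate_excursions_ignored(self):
        visits = [mild_perio(0)]
        for i, sev in enumerate(["severe", "moderate", "mild_to_moderate", "severe", "moderate"]):
            visits.append(at_day(100 * (i + 1), disease_type="periodontitis",
                                 severity=sev, extent="generalized"))
        visits.append(mild_perio(1000))
        assert classify_patient(build_timeline(visits)) is ChangeLabel.NO_CHANGE

    def test_short_first_to_last_gap_is_unknown(self):
        tl = build_timeline([mild_perio(0), at_day(60, disease_type="gingivitis",
                                                   severity="mild", extent="localized")])
        assert classify_patient(tl) is ChangeLabel.UNKNOWN


def _reverse_timeline(tl):
    """Mirror a timeline in time: visit k gets visit n-1-k's state."""
    dates = [d.diagnosis_date for d in tl.diagnoses]
    rev = [
        make_diag(
            d.disease_type.value if d.disease_type else None,
            d.severity.value if d.severity else None,
            d.extent.value if d.extent else None,
            patient_id=tl.patient_id,
            date=dates[i],
        )
        for i, d in enumerate(reversed(tl.diagnoses))
    ]
    return build_timeline(rev)


class TestGenerateCohorts:
    def _tl(self, pid, *states_days):
        recs = [
            at_day(day, patient_id=pid, disease_type=t, severity=s, extent=e)
            for day, (t, s, e) in states_days
        ]
        return build_timeline(recs)

    def test_known_mix_recovered(self):
        tls = []
        for i in range(3):  # worse
            tls.append(self._tl(f"w{i}", (0, ("periodontitis", "mild", "generalized")),
                                (200, ("periodontitis", "severe", "generalized"))))
        for i in range(2):  # better
            tls.append(self._tl(f"b{i}", (0, ("periodontitis", "moderate", "generalized")),
                                (200, ("periodontitis", "mild", "generalized"))))
        for i in range(5):  # static
            tls.append(self._tl(f"s{i}", (0, ("gingivitis", "mild", "localized")),
                                (200, ("gingivitis", "mild", "localized"))))
        part = generate_cohorts(tls)
        assert part.count(ChangeLabel.PROGRESSION) == 3
        assert part.count(ChangeLabel.IMPROVEMENT) == 2
        assert part.count(ChangeLabel.NO_CHANGE) == 5
        assert part.count(ChangeLabel.UNKNOWN) == 0

    def test_empty_input(self):
        part = generate_cohorts([])
        assert part.n_patients == 0
        assert all(part.count(lab) == 0 for lab in ChangeLabel)

    def test_all_single_visit_patients_unknown(self):
        tls = [build_timeline([mild_perio(0, extent="generalized")])]
        tls[0] = PatientTimeline("p1", tls[0].diagnoses)
        part = generate_cohorts(tls)
        assert part.count(ChangeLabel.UNKNOWN) == part.n_patients == 1

    def test_partition_conservation_and_reversal_on_random_corpus(self):
        import numpy as np

        from periotrack.synth_edr import SimConfig, simulate_patient
        from periotrack.io import timelines_from_records

        cfg = SimConfig(
            n_patients=120, seed=42, typo_rate=0.0,
            missingness={"disease_type": 0, "severity": 0, "extent": 0,
                         "onset": 0.8, "location": 0.7},
        )
        recs = [r.diagnosis for i in range(cfg.n_patients) for r in simulate_patient(cfg, i)]
        tls = timelines_from_records(recs)
        part = generate_cohorts(tls)
        assert sum(part.count(lab) for lab in ChangeLabel) == len(tls) == part.n_patients

        rev = generate_cohorts([_reverse_timeline(tl) for tl in tls])
        assert rev.count(ChangeLabel.PROGRESSION) == part.count(ChangeLabel.IMPROVEMENT)
        assert rev.count(ChangeLabel.IMPROVEMENT) == part.count(ChangeLabel.PROGRESSION)
        assert rev.count(ChangeLabel.NO_CHANGE) == part.count(ChangeLabel.NO_CHANGE)
        assert rev.count(ChangeLabel.UNKNOWN) == part.count(ChangeLabel.UNKNOWN)

    def test_transition_tallies_cover_labelled_pairs(self):
        tl = self._tl("p1", (0, ("periodontitis", "mild", "generalized")),
                      (200, ("periodontitis", "moderate", "generalized")),
                      (500, ("periodontitis", "mild", "generalized")))
        part = generate_cohorts([tl])
        assert sum(part.transition_tallies.values()) == 2
        labels = {k[2] for k in part.transition_tallies}
        assert labels == {"progression", "improvement"}
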