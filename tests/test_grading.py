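"""Ordinal grading, agreement, and backsliding detection vs a literal oracle."""

import numpy as np
import pytest

from neolus.grading import (
    BackslidingEvent,
    GradeRuleConfig,
    LambTimeline,
    LUSGrade,
    count_backsliding,
    detect_backsliding,
    extract_clip_features,
    median_grade,
    percent_agreement,
    rule_based_grade,
)
from neolus.synthetic import ClipGeometry, epa_to_grade, synthesize_lus_clip

GRADE_SET = [0.0, 0.5, 1.0, 2.0, 3.0]


def make_timeline(lamb_id="L1", group="control", times=None, grades=None, epa=None):
    times = np.asarray(times if times is not None else [0.0, 5.0, 10.0], dtype=float)
    return LambTimeline(
        lamb_id=lamb_id,
        group=group,
        timepoints_min=times,
        grades={k: np.asarray(v, dtype=float) for k, v in (grades or {}).items()},
        epa={k: np.asarray(v, dtype=float) for k, v in (epa or {}).items()},
    )


class TestMedianAndAgreement:
    @pytest.mark.parametrize(
        "grades,expected",
        [([2, 2, 3], 2.0), ([0.5, 1], 0.75), ([0, 0.5, 1, 2, 3], 1.0)],
    )
    def test_median_conventions(self, grades, expected):
        med, (q1, q3) = median_grade(grades)
        assert med == pytest.approx(expected)
        assert q1 <= med <= q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_grade([])
        with pytest.raises(ValueError):
            LUSGrade(1.7)

    def test_percent_agreement(self):
        a = [0, 1, 2, 3]
        assert percent_agreement(a, a) == 100.0
        assert percent_agreement([0, 1], [1, 0]) == 0.0
        # 75 matches out of 92 images -> 81.5%
        b = [2.0] * 92
        c = [2.0] * 75 + [3.0] * 17
        assert percent_agreement(b, c) == pytest.approx(100 * 75 / 92)
        with pytest.raises(ValueError):
            percent_agreement([0, 1], [0])


# ---------------------------------------------------------------------------
# Literal-rule oracle: an independent double loop over consecutive pairs
# ---------------------------------------------------------------------------


def oracle_backsliding(timeline, thr=0.2, severe_epa=0.6, severe_grade=1.0):
    """Naive restatement of the definitions, evaluated pair by pair."""
    events = []
    t = timeline.timepoints_min
    for i in range(len(t) - 1):
        j = i + 1

        def vals(mapping, k):
            return {s: mapping[s][k] for s in mapping if np.isfinite(mapping[s][k])}

        gi, gj = vals(timeline.grades, i), vals(timeline.grades, j)
        ei, ej = vals(timeline.epa, i), vals(timeline.epa, j)
        if not (gi or ei) or not (gj or ej):
            continue
        # (i) a reduction in the grade, in either lung
        for s in gi:
            if s in gj and gj[s] < gi[s]:
                events.append(("grade", t[i], t[j], gj[s] <= severe_grade))
        # (ii) a reduction in EPA by > thr in either lung
        dropped = [s for s in ei if s in ej and (ei[s] - ej[s]) > thr]
        if dropped:
            mean_after = np.mean(list(ej.values()))
            events.append(("epa", t[i], t[j], mean_after < severe_epa))
    return events


def random_timeline(rng, lamb_id="L"):
    n = int(rng.integers(2, 9))
    times = np.cumsum(rng.uniform(1, 10, size=n)) - 5.0
    sides = ["left", "right"][: int(rng.integers(1, 3))]
    grades = {}
    epa = {}
    for s in sides:
        g = rng.choice(GRADE_SET, size=n)
        e = np.round(rng.uniform(0, 1, size=n), 3)
        # sprinkle missingness but keep each timepoint observable somewhere
        g[rng.random(n) < 0.2] = np.nan
        e[rng.random(n) < 0.2] = np.nan
        grades[s] = g
        epa[s] = e
    return make_timeline(lamb_id=lamb_id, times=times, grades=grades, epa=epa)


class TestDetectBacksliding:
    def test_monotone_timeline_no_events(self):
        tl = make_timeline(
            grades={"left": [0, 1, 2], "right": [0.5, 2, 3]},
            epa={"left": [0.2, 0.5, 0.9], "right": [0.1, 0.6, 0.8]},
        )
        assert detect_backsliding(tl) == []

    def test_epa_drop_not_severe(self):
        tl = make_timeline(
            times=[0, 5],
            epa={"left": [0.9, 0.65], "right": [0.9, 0.9]},
        )
        events = detect_backsliding(tl)
        assert len(events) == 1
        ev = events[0]
        assert ev.trigger == "epa_drop"
        assert ev.delta_epa == pytest.approx(0.25)
        assert not ev.severe  # mean EPA after = 0.775 >= 0.6

    def test_grade_drop_to_one_is_severe(self):
        tl = make_timeline(times=[0, 5], grades={"left": [2, 1]})
        events = detect_backsliding(tl)
        assert len(events) == 1
        assert events[0].trigger == "grade_drop"
        assert events[0].severe

    def test_exact_threshold_drop_not_an_event(self):
        # the definition is a drop strictly greater than 0.2
        tl = make_timeline(times=[0, 5], epa={"left": [1.0, 0.8]})
        assert detect_backsliding(tl) == []

    def test_half_step_grade_drop_counts(self):
        tl = make_timeline(times=[0, 5], grades={"left": [1, 0.5]})
        events = detect_backsliding(tl)
        assert len(events) == 1 and events[0].severe

    def test_pair_can_trigger_both_criteria(self):
        tl = make_timeline(
            times=[0, 5],
            grades={"left": [3, 2]},
            epa={"left": [0.9, 0.6]},
        )
        triggers = {e.trigger for e in detect_backsliding(tl)}
        assert triggers == {"grade_drop", "epa_drop"}

    def test_infinite_threshold_and_no_grades_is_silent(self):
        tl = make_timeline(epa={"left": [0.9, 0.1, 0.8]})
        assert detect_backsliding(tl, epa_drop_threshold=np.inf) == []

    def test_time_shift_invariance_and_severe_subset(self, rng):
        for _ in range(50):
            tl = random_timeline(rng)
            events = detect_backsliding(tl)
            shifted = make_timeline(
                times=tl.timepoints_min + 37.0,
                grades=tl.grades,
                epa=tl.epa,
            )
            assert len(detect_backsliding(shifted)) == len(events)
            for ev in events:
                if ev.trigger == "epa_drop" and ev.severe:
                    j = np.searchsorted(tl.timepoints_min, ev.time_to_min)
                    after = [
                        tl.epa[s][j] for s in tl.epa if np.isfinite(tl.epa[s][j])
                    ]
                    assert np.mean(after) < 0.6

    def test_oracle_equivalence_on_random_timelines(self, rng):
        for _ in range(1000):
            tl = random_timeline(rng)
            got = detect_backsliding(tl)
            want = oracle_backsliding(tl)
            got_keys = sorted(
                ("grade" if e.trigger == "grade_drop" else "epa", e.time_from_min, e.time_to_min, e.severe)
                for e in got
            )
            want_keys = sorted((k, float(a), float(b), bool(s)) for k, a, b, s in want)
            assert got_keys == want_keys


class TestCountBacksliding:
    def test_empty_cohort_counts(self):
        table = count_backsliding([], {"a": "control", "b": "elevated"})
        assert (table["mean_occurrences"] == 0).all()
        assert (table["pct_with_event"] == 0).all()

    def test_single_lamb_mean(self):
        events = [
            BackslidingEvent("a", 0.0, 5.0, "grade_drop", False, "left", grade_after=2.0)
        ] * 3
        groups = {"a": "control", "b": "control", "c": "elevated"}
        table = count_backsliding(events, groups)
        row = table.query("group == 'control' and trigger == 'grade_drop' and severity == 'any'")
        assert row["mean_occurrences"].iloc[0] == pytest.approx(3 / 2)
        assert row["pct_with_event"].iloc[0] == pytest.approx(50.0)

    def test_counts_match_oracle_on_random_cohort(self, rng):
        timelines = [random_timeline(rng, lamb_id=f"L{i}") for i in range(12)]
        groups = {tl.lamb_id: ("control" if i < 6 else "elevated") for i, tl in enumerate(timelines)}
        events = [ev for tl in timelines for ev in detect_backsliding(tl)]
        table = count_backsliding(events, groups)
        n_any = table.query("severity == 'any'")[["group", "trigger", "mean_occurrences", "n_lambs"]]
        total_from_table = float((n_any["mean_occurrences"] * n_any["n_lambs"]).sum())
        total_oracle = sum(len(oracle_backsliding(tl)) for tl in timelines)
        assert total_from_table == pytest.approx(total_oracle)


class TestRuleBasedGrade:
    def test_liquid_field_grades_zero(self, geometry, rng):
        clip, info = synthesize_lus_clip(0.0, geometry, seed=rng)
        f = extract_clip_features(clip.frames, info["pleural_row"], info["shadow_mask"])
        assert float(rule_based_grade(f)) == 0.0

    def test_aerated_field_grades_three(self, geometry, rng):
        clip, info = synthesize_lus_clip(1.0, geometry, seed=rng)
        f = extract_clip_features(clip.frames, info["pleural_row"], info["shadow_mask"])
        assert float(rule_based_grade(f)) == 3.0

    def test_grid_accuracy_within_half_step(self, geometry):
        rng = np.random.default_rng(0)
        hits = total = 0
        for e in np.linspace(0, 1, 21):
            for _ in range(3):
                clip, info = synthesize_lus_clip(float(e), geometry, seed=rng)
                f = extract_clip_features(clip.frames, info["pleural_row"], info["shadow_mask"])
                hits += abs(float(rule_based_grade(f)) - epa_to_grade(float(e))) <= 0.5
                total += 1
        assert hits / total >= 0.8
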