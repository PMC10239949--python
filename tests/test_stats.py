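"""Statistical plan: gating, rank tests vs brute force, models, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neolus.stats import (
    blocks_vs_baseline,
    bonferroni,
    lamb_adjusted_regression,
    normality_gate,
    paired_compare,
    paired_mdd,
    paired_t_power,
    repeated_measures_group_model,
    timepoint_group_tests,
)


class TestNormalityGate:
    def test_normal_samples_choose_parametric(self):
        rng = np.random.default_rng(0)
        chosen = sum(
            normality_gate(rng.standard_normal(50))[0] == "parametric"
            for _ in range(100)
        )
        assert chosen >= 90

    def test_exponential_samples_choose_rank(self):
        rng = np.random.default_rng(1)
        chosen = sum(
            normality_gate(rng.exponential(size=50))[0] == "rank" for _ in range(100)
        )
        assert chosen >= 90

    def test_degenerate_forces_rank(self):
        assert normality_gate(np.array([2.0, 2.0, 2.0, 2.0]))[0] == "rank"
        assert normality_gate(np.array([1.0, 2.0]))[0] == "rank"

    def test_summary_styles(self):
        choice, summary = normality_gate(np.random.default_rng(2).standard_normal(40))
        if choice == "parametric":
            assert {"mean", "sem"} <= summary.keys()
        else:
            assert {"median", "iqr"} <= summary.keys()


def brute_force_u(a, b):
    """Mann-Whitney U of sample a by literal pair counting with ties."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestTimepointGroupTests:
    def test_identical_distributions_give_high_p(self, rng):
        rows = []
        for t in (5.0, 10.0, 15.0):
            for g in ("control", "elevated"):
                for v in (1.0, 2.0, 2.0, 3.0):
                    rows.append({"time_min": t, "group": g, "grade": v})
        out = timepoint_group_tests(pd.DataFrame(rows))
        assert (out["p_value"] > 0.8).all()
        assert (out["p_adjusted"] >= out["p_value"]).all()

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.04, 20) == pytest.approx(0.8)
        assert bonferroni(0.2, 10) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    def test_u_statistic_matches_brute_force(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 9), rng.integers(2, 9)
            a = rng.integers(0, 6, size=n1) / 2.0  # tied ordinal-like data
            b = rng.integers(0, 6, size=n2) / 2.0
            got = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
            assert got == pytest.approx(brute_force_u(a, b))

    def test_adjustment_counts_tested_timepoints_only(self):
        rows = [
            {"time_min": 1.0, "group": "control", "grade": 1.0},
            {"time_min": 1.0, "group": "elevated", "grade": 2.0},
            {"time_min": 2.0, "group": "control", "grade": 1.0},  # elevated missing
        ]
        out = timepoint_group_tests(pd.DataFrame(rows))
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_value"].iloc[0])


def epa_long_table(rng, n_per_group=8, n_times=6, group_shift=0.0, lamb_sd=0.1):
    rows = []
    for g, shift in (("control", 0.0), ("elevated", -group_shift)):
        for k in range(n_per_group):
            lamb = f"{g}{k}"
            u = rng.normal(0, lamb_sd)
            for t in range(n_times):
                rows.append(
                    {
                        "lamb_id": lamb,
                        "group": g,
                        "time_min": float(5 * (t + 1)),
                        "epa": 0.5 + 0.05 * t + u + shift + rng.normal(0, 0.05),
                    }
                )
    return pd.DataFrame(rows)


class TestRepeatedMeasuresModel:
    def test_detects_group_shift(self, rng):
        table = epa_long_table(rng, group_shift=0.25)
        res = repeated_measures_group_model(table)
        assert res["group"] < 0.01
        assert res["time"] < 0.01

    def test_duplicated_lambs_preserve_estimates(self, rng):
        table = epa_long_table(rng, group_shift=0.1)
        dup = table.copy()
        dup["lamb_id"] = dup["lamb_id"] + "_copy"
        res1 = repeated_measures_group_model(table)
        res2 = repeated_measures_group_model(pd.concat([table, dup], ignore_index=True))
        assert res2["group_estimate"] == pytest.approx(res1["group_estimate"], abs=1e-6)

    def test_tolerates_missing_cells(self, rng):
        table = epa_long_table(rng, group_shift=0.25)
        table = table.drop(table.sample(n=8, random_state=1).index)
        res = repeated_measures_group_model(table)
        assert res["group"] < 0.05

    def test_too_small_design_rejected(self):
        df = pd.DataFrame(
            {
                "lamb_id": ["a", "a", "b", "b"],
                "group": ["control", "control", "elevated", "elevated"],
                "time_min": [1.0, 2.0, 1.0, 2.0],
                "epa": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.raises(ValueError):
            repeated_measures_group_model(df)


def aado2_table(rng, n_lambs=6, n_points=8, slope=-300.0, noise=5.0):
    rows = []
    for k in range(n_lambs):
        icept = 400.0 + rng.normal(0, 30)
        for _ in range(n_points):
            epa = rng.uniform(0, 1)
            rows.append(
                {
                    "lamb_id": f"L{k}",
                    "epa": epa,
                    "aado2": icept + slope * epa + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestLambAdjustedRegression:
    def test_exact_linear_data(self, rng):
        table = aado2_table(rng, noise=0.0)
        res = lamb_adjusted_regression(table, outcome="aado2", predictor="epa")
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(-300.0, abs=1e-8)

    def test_slope_recovery_with_noise(self, rng):
        res = lamb_adjusted_regression(aado2_table(rng), outcome="aado2", predictor="epa")
        assert res.slope == pytest.approx(-300.0, rel=0.1)
        assert res.p_value < 1e-6

    def test_permuted_predictor_is_null(self, rng):
        table = aado2_table(rng, slope=-200.0)
        hits = 0
        n_perm = 40
        for _ in range(n_perm):
            shuffled = table.copy()
            shuffled["epa"] = (
                shuffled.groupby("lamb_id")["epa"].transform(rng.permutation)
            )
            res = lamb_adjusted_regression(shuffled, outcome="aado2", predictor="epa")
            hits += res.p_value < 0.05
        assert hits <= 0.2 * n_perm  # ~5% nominal; loose bound

    def test_insufficient_data_rejected(self, rng):
        table = aado2_table(rng, n_lambs=1)
        with pytest.raises(ValueError):
            lamb_adjusted_regression(table, outcome="aado2", predictor="epa")


class TestPairedCompare:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(x, x)
        assert res.p_value == 1.0
        assert "no test" in res.note

    def test_constant_shift_degenerate_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_compare(x, x + 1.0)
        # zero-variance differences: rank branch with a degeneracy note
        assert res.test_name == "wilcoxon"
        assert res.note != ""

    def test_power_at_unit_effect(self, rng):
        hits = 0
        for _ in range(200):
            before = rng.standard_normal(17)
            after = before + 1.0 + rng.standard_normal(17)
            hits += paired_compare(before, after).p_value < 0.05
        assert hits >= 0.9 * 200


class TestBlocksVsBaseline:
    def _blocks_table(self, rng, effect=0.0, n_lambs=8):
        rows = []
        for k in range(n_lambs):
            u = rng.normal(0, 2)
            for blk in ["pre", "post1", "post2", "post3"]:
                shift = effect if blk == "post2" else 0.0
                rows.append(
                    {
                        "lamb_id": f"L{k}",
                        "block": blk,
                        "rate_bpm": 60 + u + shift + rng.normal(0, 2),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_family_mostly_quiet(self, rng):
        out = blocks_vs_baseline(self._blocks_table(rng), metric="rate_bpm")
        assert (out["p_adjusted"] > 0.05).all()

    def test_large_effect_detected_in_target_block(self, rng):
        out = blocks_vs_baseline(
            self._blocks_table(rng, effect=-20.0), metric="rate_bpm"
        ).set_index("block")
        assert out.loc["post2", "p_adjusted"] < 0.01
        assert out.loc["post2", "estimate"] == pytest.approx(-20.0, abs=4.0)

    def test_missing_baseline_rejected(self, rng):
        table = self._blocks_table(rng).query("block != 'pre'")
        with pytest.raises(ValueError, match="baseline"):
            blocks_vs_baseline(table, metric="rate_bpm")

    def test_adjusted_never_below_raw(self, rng):
        out = blocks_vs_baseline(self._blocks_table(rng, effect=-5.0), metric="rate_bpm")
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


class TestPairedMdd:
    def test_scale_equivariance(self):
        d1 = paired_mdd(17, 0.1)
        d2 = paired_mdd(17, 0.2)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_power_at_mdd_is_target(self):
        for n, sd in [(10, 1.0), (17, 0.1), (40, 2.5)]:
            delta = paired_mdd(n, sd, power=0.80, alpha=0.05)
            assert paired_t_power(delta, n, sd) == pytest.approx(0.80, abs=0.005)

    def test_mdd_decreases_with_n(self):
        assert paired_mdd(30, 0.1) < paired_mdd(17, 0.1) < paired_mdd(8, 0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            paired_mdd(1, 0.1)
        with pytest.raises(ValueError):
            paired_mdd(17, -1.0)
        with pytest.raises(ValueError):
            paired_mdd(17, 0.1, power=1.5)
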