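"""Shadow-attribute selection and the two-condition stability protocol."""

import numpy as np
import pandas as pd
import pytest

from lipidlens.cohort import CohortDesign, EffectSpec, generate
from lipidlens.diffabund import preprocess
from lipidlens.stability import (
    StabilityResult,
    _stratified_subsample,
    ferns_importance_backend,
    shadow_ratios,
    shadow_run,
    stability_protocol,
)


def noise_frame(rng, n=30, p=20):
    frame = pd.DataFrame(rng.normal(size=(n, p)))
    frame.columns = [f"f{i}" for i in range(p)]
    return frame


class TestShadowRun:
    def test_label_like_feature_is_confirmed(self, rng):
        confirmed = 0
        for seed in range(5):
            local = np.random.default_rng(seed)
            y = np.array([1] * 15 + [0] * 15)
            X = noise_frame(local)
            X["signal"] = y + local.normal(0, 0.05, size=30)
            result = shadow_run(X, y, seed=seed)
            decided = result.decisions["signal"]
            confirmed += decided == "confirmed"
            assert result.n_iter <= 100
        assert confirmed == 5

    def test_zero_iterations_leave_everything_tentative(self, rng):
        X = noise_frame(rng)
        y = rng.integers(0, 2, size=30)
        result = shadow_run(X, y, seed=0, max_iter=0)
        assert set(result.decisions.values()) == {"tentative"}

    def test_non_binary_labels_rejected(self, rng):
        X = noise_frame(rng)
        with pytest.raises(ValueError, match="binary"):
            shadow_run(X, np.arange(30), seed=0)

    def test_constant_table_rejects_all_with_warning(self):
        X = pd.DataFrame(np.ones((20, 4)), columns=list("abcd"))
        y = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            result = shadow_run(X, y, seed=0)
        assert set(result.decisions.values()) == {"rejected"}

    def test_same_seed_is_bit_reproducible(self, rng):
        X = noise_frame(rng)
        X["signal"] = np.array([1] * 15 + [0] * 15) + rng.normal(0, 0.2, 30)
        y = np.array([1] * 15 + [0] * 15)
        a = shadow_run(X, y, seed=42, max_iter=20)
        b = shadow_run(X, y, seed=42, max_iter=20)
        assert a.decisions == b.decisions
        assert a.shadow_max == b.shadow_max
        assert a.importance_history == b.importance_history


@pytest.fixture(scope="module")
def small_result():
    """Reduced protocol on a small implanted cohort."""
    rng = np.random.default_rng(8)
    y = np.array([1] * 20 + [0] * 10)
    X = pd.DataFrame(rng.normal(size=(30, 15)))
    X.columns = [f"f{i}" for i in range(15)]
    X["signal"] = y * 1.5 + rng.normal(0, 0.5, size=30)
    return stability_protocol(X, y, R1=8, R2=8, base_seed=1, max_iter=40), X, y


class TestStabilityProtocol:
    def test_stable_rule_is_majority_in_both_conditions(self, small_result):
        result, _, _ = small_result
        tab = result.table
        expected = (tab["confirmed_count_subsample"] > result.r1 / 2) & (
            tab["confirmed_count_full"] > result.r2 / 2
        )
        assert (tab["stable"] == expected).all()
        assert result.table.loc["signal", "stable"]

    def test_counts_bounded_by_run_numbers(self, small_result):
        result, _, _ = small_result
        tab = result.table
        assert tab["confirmed_count_subsample"].between(0, result.r1).all()
        assert tab["confirmed_count_full"].between(0, result.r2).all()

    def test_ranks_follow_median_importance(self, small_result):
        result, _, _ = small_result
        stable = result.table[result.table["stable"]]
        ordered = stable.sort_values("medianImp", ascending=False)
        assert list(ordered["rank"]) == sorted(ordered["rank"])

    def test_protocol_is_reproducible(self, small_result):
        result, X, y = small_result
        again = stability_protocol(X, y, R1=8, R2=8, base_seed=1, max_iter=40)
        pd.testing.assert_frame_equal(result.table, again.table)

    def test_majority_thresholds_on_paper_scale_counts(self):
        # 60/100 and 70/100 -> stable; 60/100 and 40/100 -> not
        assert (60 > 50) and (70 > 50)
        table = pd.DataFrame(
            {
                "confirmed_count_subsample": [60, 60],
                "confirmed_count_full": [70, 40],
            },
            index=["kept", "dropped"],
        )
        stable = (table["confirmed_count_subsample"] > 50) & (
            table["confirmed_count_full"] > 50
        )
        assert stable.tolist() == [True, False]

    def test_subsample_preserves_group_proportion(self, rng):
        groups = np.array(["case"] * 30 + ["control"] * 11)
        for _ in range(20):
            idx = _stratified_subsample(groups, 0.70, rng)
            sub = groups[idx]
            assert (sub == "case").sum() == 21
            assert (sub == "control").sum() == 8

    def test_subsample_that_empties_a_group_errors(self, rng):
        groups = np.array(["case"] * 30 + ["control"] * 2)
        with pytest.raises(ValueError, match="control"):
            _stratified_subsample(groups, 0.70, rng)

    def test_label_permuted_cohort_yields_no_stable_features(self):
        """Shuffling the group labels of a structured cohort should leave
        the two-condition vote empty (reduced-scale protocol)."""
        from lipidlens.cohort import cll_like_effects

        table = generate(CohortDesign(seed=3), cll_like_effects())
        X, _ = preprocess(table)
        rng = np.random.default_rng(17)
        total_stable = 0
        for rep in range(3):
            y = np.array(table.groups.values, copy=True)
            rng.shuffle(y)
            result = stability_protocol(X, y, R1=6, R2=6, base_seed=rep, max_iter=50)
            total_stable += len(result.stable_features())
        assert total_stable <= 1

    def test_monotone_power_in_effect_size(self):
        """Confirmation frequency never decreases with the implanted shift."""
        panel = [
            "CAR 12:0", "CAR 10:0", "LPC 16:0", "LPC 18:0", "LPC 18:1",
            "PC 34:1", "PC 36:0", "PC 36:2", "PC 38:4", "PC O-34:2",
            "PC O-36:5", "SM 18:1;O2/16:0", "SM 18:1;O2/24:1", "PC 32:0",
            "LPC 20:4", "PC 40:6", "PC 34:2", "SM 18:1;O2/22:0", "PC 36:4",
            "CAR 14:0",
        ]
        freqs = []
        for shift in (0.5, 1.0, 2.0):
            effects = EffectSpec(shifts={"CAR 12:0": shift}, noise_sigma=0.5)
            # common random numbers: same design seed, same run seeds
            t = generate(CohortDesign(panel=tuple(panel), seed=12), effects)
            X, _ = preprocess(t)
            confirmed = 0
            for run_seed in range(8):
                result = shadow_run(X, t.groups.values, seed=run_seed, max_iter=60)
                confirmed += result.decisions["CAR 12:0"] == "confirmed"
            freqs.append(confirmed)
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] >= 6  # a standardized effect of 4 is reliably confirmed


class TestShadowRatios:
    @staticmethod
    def synthetic_result(median_imp, shadow_max, shadow_mean):
        table = pd.DataFrame(
            {
                "confirmed_count_subsample": [5],
                "confirmed_count_full": [5],
                "stable": [True],
                "medianImp": [median_imp],
            },
            index=pd.Index(["feat"], name="feature"),
        )
        return StabilityResult(
            table=table, r1=6, r2=6, subsample_fraction=0.7, base_seed=0,
            run_shadow_max=shadow_max, run_shadow_mean=shadow_mean,
        )

    def test_ratio_arithmetic(self):
        result = self.synthetic_result(0.08, [0.01, 0.02, 0.015], [0.004, 0.004, 0.004])
        ratios = shadow_ratios(result)
        rmax, rmean = ratios["feat"]
        assert rmax == pytest.approx(0.08 / 0.015)
        assert rmean == pytest.approx(20.0)

    def test_mean_ratio_dominates_max_ratio(self):
        result = self.synthetic_result(0.08, [0.02, 0.03], [0.005, 0.006])
        rmax, rmean = shadow_ratios(result)["feat"]
        assert rmean >= rmax

    def test_feature_tracking_shadow_max_has_unit_ratio(self):
        result = self.synthetic_result(0.015, [0.01, 0.02, 0.015], [0.004] * 3)
        rmax, _ = shadow_ratios(result)["feat"]
        assert rmax == pytest.approx(1.0)

    def test_no_stable_features_is_an_error(self):
        result = self.synthetic_result(0.08, [0.01], [0.004])
        result.table["stable"] = False
        with pytest.raises(ValueError, match="stable"):
            shadow_ratios(result)

    def test_zero_shadow_statistics_are_an_error(self):
        result = self.synthetic_result(0.08, [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ZeroDivisionError):
            shadow_ratios(result)
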