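"""Differential abundance: Wilcoxon, BH, pseudo fold changes, PCA, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidlens.cohort import (
    AbundanceTable,
    CohortDesign,
    EffectSpec,
    cll_like_effects,
    generate,
    null_effects,
)
from lipidlens.diffabund import (
    InsufficientDataError,
    UndefinedFoldChangeError,
    bh_adjust,
    de_by_level,
    hier_cluster,
    pca,
    preprocess,
    pseudo_fold_change,
    wilcoxon_mw,
)


def brute_force_bh(p):
    """Direct min-over-tail definition: adj_i = min_{p_j >= p_i} m p_j / rank_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        tail = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(tail))
    return adj


def permutation_wilcoxon(x, y):
    """Exact two-sided p by enumerating all group assignments of the pool."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    u_obs = min(u_obs, len(x) * len(y) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = stats.mannwhitneyu(pooled[mask], pooled[~mask], alternative="two-sided").statistic
        u = min(u, len(x) * len(y) - u)
        total += 1
        count += u <= u_obs
    return count / total


def small_table(values, groups):
    frame = pd.DataFrame(values)
    frame.index = [f"S{i}" for i in range(len(frame))]
    return AbundanceTable(
        abundance=frame,
        groups=pd.Series(groups, index=frame.index),
    )


class TestPreprocess:
    def test_all_positive_uses_plain_log2(self):
        t = small_table({"PC 34:1": [1.0, 2.0, 4.0, 8.0]}, ["case", "case", "control", "control"])
        log2, deltas = preprocess(t)
        assert deltas == {"PC 34:1": 0.0}
        np.testing.assert_allclose(log2["PC 34:1"], [0, 1, 2, 3])

    def test_zero_column_gets_half_min_positive_offset(self):
        t = small_table({"PC 34:1": [0.0, 2.0, 6.0, 1.0]}, ["case", "case", "control", "control"])
        log2, deltas = preprocess(t)
        assert deltas["PC 34:1"] == 0.5
        np.testing.assert_allclose(log2["PC 34:1"], np.log2(np.array([0, 2, 6, 1]) + 0.5))

    def test_all_zero_species_dropped_with_warning(self):
        t = small_table(
            {"PC 34:1": [1.0, 1.0, 2.0, 2.0], "CAR 12:0": [0.0, 0.0, 0.0, 0.0]},
            ["case", "case", "control", "control"],
        )
        with pytest.warns(UserWarning, match="CAR 12:0"):
            log2, _ = preprocess(t)
        assert list(log2.columns) == ["PC 34:1"]


class TestWilcoxon:
    def test_fully_separated_triples(self):
        assert wilcoxon_mw([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_mw([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_exact_path_equals_permutation_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 9, size=2)
            pool = rng.choice(np.arange(1000), size=n1 + n2, replace=False).astype(float)
            x, y = pool[:n1], pool[n1:]
            assert wilcoxon_mw(x, y) == pytest.approx(permutation_wilcoxon(x, y))

    def test_insufficient_group_size_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_mw([1.0], [2.0, 3.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_uniformly_spaced_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 25))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.4])


class TestPseudoFoldChange:
    def test_plain_median_ratio(self):
        fc, log2fc = pseudo_fold_change([4, 4, 4], [1, 1, 1])
        assert fc == pytest.approx(4.0)
        assert log2fc == pytest.approx(2.0)

    def test_equal_medians_give_zero_log2fc(self):
        _, log2fc = pseudo_fold_change([2, 3, 4], [3, 3, 3])
        assert log2fc == pytest.approx(0.0)

    def test_swapping_groups_negates_log2fc(self, rng):
        for _ in range(20):
            x, y = rng.random(9) + 0.1, rng.random(7) + 0.1
            _, forward = pseudo_fold_change(x, y)
            _, backward = pseudo_fold_change(y, x)
            assert forward == pytest.approx(-backward)

    def test_zero_median_uses_half_min_positive(self):
        fc, _ = pseudo_fold_change([0, 0, 4], [2, 2, 2])
        # epsilon = half of the smallest positive pooled value (2) = 1
        assert fc == pytest.approx((0 + 1) / (2 + 1))

    def test_all_zero_inputs_undefined(self):
        with pytest.raises(UndefinedFoldChangeError):
            pseudo_fold_change([0, 0], [0, 0])


class TestDEByLevel:
    def test_implanted_species_detected_with_correct_sign(self, panel_annotation):
        hits = 0
        for seed in range(5):
            t = generate(CohortDesign(seed=seed), cll_like_effects())
            de = de_by_level(t, panel_annotation, "species")
            row = de.set_index("feature_id").loc["CAR 12:0"]
            hits += bool(row["significant"] and row["log2fc"] > 0)
        assert hits == 5

    def test_null_class_level_rarely_significant(self, panel_annotation):
        seeds_with_hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            t = generate(CohortDesign(seed=1000 + seed), null_effects())
            de = de_by_level(t, panel_annotation, "class")
            assert len(de) == 5
            seeds_with_hits += bool(de["significant"].any())
        assert seeds_with_hits <= 0.10 * n_seeds + 1

    def test_single_member_stratum_matches_species_record(self):
        t = small_table(
            {"CAR 12:0": [1.0, 2.0, 9.0, 8.0, 7.0], "LPC 18:0": [5.0, 6.0, 5.5, 6.5, 6.0]},
            ["case", "case", "control", "control", "control"],
        )
        annot = pd.DataFrame(
            {"lipid_class": ["CAR", "LPC"]}, index=["CAR 12:0", "LPC 18:0"]
        )
        species = de_by_level(t, annot, "species").set_index("feature_id")
        by_class = de_by_level(t, annot, "class").set_index("feature_id")
        assert by_class.loc["CAR", "p_value"] == pytest.approx(
            species.loc["CAR 12:0", "p_value"]
        )
        assert by_class.loc["CAR", "log2fc"] == pytest.approx(
            species.loc["CAR 12:0", "log2fc"]
        )

    def test_unknown_level_lists_valid_levels(self, panel_annotation):
        t = generate(CohortDesign(seed=0), null_effects())
        with pytest.raises(ValueError, match="species"):
            de_by_level(t, panel_annotation, "banana")

    def test_class_aggregation_conserves_total_mass(self, panel_annotation):
        from lipidlens.diffabund import _stratum_values

        t = generate(CohortDesign(seed=4), cll_like_effects())
        strata = _stratum_values(t, panel_annotation, "class")
        np.testing.assert_allclose(
            strata.sum(axis=1).values, t.abundance.sum(axis=1).values
        )

    def test_group_swap_negates_log2fc_and_keeps_p(self, panel_annotation):
        t = generate(CohortDesign(seed=6), cll_like_effects())
        swapped = AbundanceTable(
            abundance=t.abundance.copy(),
            groups=t.groups.map({"case": "control", "control": "case"}),
        )
        de = de_by_level(t, panel_annotation, "species").set_index("feature_id")
        de_swapped = de_by_level(swapped, panel_annotation, "species").set_index("feature_id")
        np.testing.assert_allclose(de["log2fc"], -de_swapped.loc[de.index, "log2fc"])
        np.testing.assert_allclose(de["p_value"], de_swapped.loc[de.index, "p_value"])

    def test_raw_p_null_calibration(self, panel_annotation):
        """With zero effects the raw p < 0.05 rate stays near 5%."""
        flagged = 0
        total = 0
        for seed in range(20):
            t = generate(CohortDesign(seed=2000 + seed), null_effects())
            de = de_by_level(t, panel_annotation, "species")
            flagged += int((de["p_value"] < 0.05).sum())
            total += len(de)
        low, high = stats.binom.interval(0.99, total, 0.05)
        assert low <= flagged <= high


class TestPCA:
    def test_single_varying_species_explains_everything(self):
        values = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]},
            index=list("wxyz"),
        )
        with pytest.warns(UserWarning, match="constant"):
            result = pca(values)
        assert result.explained_fraction[0] == pytest.approx(1.0)

    def test_two_feature_correlation_oracle(self, rng):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        data = rng.multivariate_normal([0, 0], cov, size=400)
        frame = pd.DataFrame(data, columns=["a", "b"])
        result = pca(frame, n_components=2)
        eigvals = np.linalg.eigvalsh(np.corrcoef(data.T))[::-1]
        np.testing.assert_allclose(
            result.explained_fraction, eigvals / eigvals.sum(), atol=1e-8
        )

    def test_explained_fractions_non_increasing_and_bounded(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 8)))
        frame.columns = [f"f{i}" for i in range(8)]
        result = pca(frame, n_components=5)
        frac = result.explained_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert np.all((frac >= 0) & (frac <= 1))
        assert frac.sum() <= 1 + 1e-9


class TestHierCluster:
    def test_identical_samples_merge_first_at_zero_distance(self):
        frame = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 8.0]],
            index=["dup1", "dup2", "far"],
            columns=["a", "b"],
        )
        result = hier_cluster(frame)
        first = result.sample_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_separated_groups_form_contiguous_leaf_blocks(self, panel_annotation):
        blocks = 0
        for seed in range(5):
            shifts = {s: 3.0 for s in panel_annotation.index[:40]}
            t = generate(
                CohortDesign(seed=seed),
                EffectSpec(shifts=shifts, noise_sigma=0.3),
            )
            log2, _ = preprocess(t)
            result = hier_cluster(log2)
            labels = [t.groups[s] for s in result.sample_order]
            switches = sum(a != b for a, b in zip(labels, labels[1:]))
            blocks += switches == 1
        assert blocks >= 4

    def test_row_permutation_equivariance(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 6)))
        frame.index = [f"s{i}" for i in range(10)]
        frame.columns = [f"f{i}" for i in range(6)]
        shuffled = frame.sample(frac=1.0, random_state=3)
        a = hier_cluster(frame)
        b = hier_cluster(shuffled)
        assert sorted(a.sample_order) == sorted(b.sample_order)
        # same merge heights regardless of input row order
        np.testing.assert_allclose(
            np.sort(a.sample_linkage[:, 2]), np.sort(b.sample_linkage[:, 2])
        )
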