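"""Evaluation metrics: hand-derived values, metric axioms, null behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otubench import (
    CountMatrix,
    aitchison_per_sample,
    alpha_indices,
    benjamini_hochberg,
    bray_curtis_matrix,
    cohens_d,
    da_features,
    jaccard,
    magnitude_label,
    nmds_embed,
    smape_per_sample,
    total_sparsity,
    whittaker_matrix,
    zero_confusion,
)
from otubench.evaluation import (
    alpha_error_tests,
    alpha_group_comparisons,
    comparison_disagreement,
    evaluate_all,
)


def cm(arr, groups=None, layer="raw") -> CountMatrix:
    arr = np.asarray(arr, dtype=float)
    samples = [f"S{j}" for j in range(arr.shape[1])]
    g = None if groups is None else pd.Series(list(groups), index=samples)
    return CountMatrix(
        pd.DataFrame(arr, index=[f"F{i}" for i in range(arr.shape[0])], columns=samples),
        groups=g,
        layer=layer,
    )


def aitchison_double_loop(x, y):
    """Literal double-sum over log-ratio differences (independent oracle)."""
    m = len(x)
    total = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            total += (np.log(x[i] / x[j]) - np.log(y[i] / y[j])) ** 2
    return np.sqrt(total / m)


class TestSparsityAndConfusion:
    def test_quarter_zero(self):
        assert total_sparsity(np.array([[0.0, 1.0], [2.0, 3.0]])) == 25.0

    def test_all_zero_and_empty(self):
        assert total_sparsity(np.zeros((3, 3))) == 100.0
        with pytest.raises(ValueError):
            total_sparsity(np.empty((0, 0)))

    def test_oracle_imputer_scores_perfectly(self):
        truth = np.array([[5.0, 0.0], [0.0, 3.0], [2.0, 2.0]])
        raw = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0]])
        oracle = np.where((truth > 0) & (raw == 0), 9.0, raw)
        conf = zero_confusion(truth, raw, oracle)
        assert conf.sensitivity == 100.0 and conf.specificity == 100.0

    def test_identity_pipeline_recovers_nothing(self):
        truth = np.array([[5.0, 0.0], [0.0, 3.0]])
        raw = np.zeros((2, 2))
        conf = zero_confusion(truth, raw, raw)
        assert conf.sensitivity == 0.0 and conf.specificity == 100.0

    def test_impute_everything_kills_specificity(self):
        truth = np.array([[5.0, 0.0], [0.0, 3.0]])
        raw = np.zeros((2, 2))
        conf = zero_confusion(truth, raw, np.ones((2, 2)))
        assert conf.sensitivity == 100.0 and conf.specificity == 0.0

    def test_counts_partition_raw_zeros(self, reduced_dataset):
        raw = reduced_dataset.raw
        conf = zero_confusion(reduced_dataset.ground_truth, raw, raw)
        n_zeros = int((raw.to_numpy() == 0).sum())
        assert conf.tp + conf.fp + conf.fn + conf.tn == n_zeros


class TestSMAPE:
    def test_hand_value(self):
        assert smape_per_sample([1.0, 3.0], [3.0, 1.0]) == pytest.approx(50.0)

    def test_identical_and_double_zero(self):
        assert smape_per_sample([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert smape_per_sample([0.0, 0.0], [0.0, 0.0]) == 0.0

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=30),
        st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, x, data):
        y = data.draw(
            st.lists(
                st.floats(0, 1e6, allow_nan=False),
                min_size=len(x),
                max_size=len(x),
            )
        )
        a = smape_per_sample(x, y)
        assert a == pytest.approx(smape_per_sample(y, x))
        assert 0.0 <= a <= 100.0


class TestAitchison:
    def test_hand_value_two_parts(self):
        assert aitchison_per_sample([1.0, np.e], [1.0, 1.0]) == pytest.approx(
            np.sqrt(0.5), abs=1e-6
        )
        assert aitchison_per_sample([1.0, np.e], [1.0, 1.0]) == pytest.approx(
            0.70711, abs=1e-5
        )

    def test_identity_and_scale_invariance(self):
        x = np.array([1.0, 2.0, 7.0])
        y = np.array([3.0, 1.0, 4.0])
        assert aitchison_per_sample(x, x) == pytest.approx(0.0, abs=1e-12)
        assert aitchison_per_sample(5.0 * x, y) == pytest.approx(
            aitchison_per_sample(x, y), rel=1e-10
        )

    @given(st.integers(2, 200), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_clr_form_equals_double_loop(self, m, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 100.0, size=m)
        y = rng.uniform(0.1, 100.0, size=m)
        assert aitchison_per_sample(x, y, zero_rule="none") == pytest.approx(
            aitchison_double_loop(x, y), abs=1e-8
        )

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y, z = rng.uniform(0.5, 50.0, size=(3, 10))
            dxy = aitchison_per_sample(x, y, zero_rule="none")
            dyz = aitchison_per_sample(y, z, zero_rule="none")
            dxz = aitchison_per_sample(x, z, zero_rule="none")
            assert dxy >= 0
            assert dxy == pytest.approx(aitchison_per_sample(y, x, zero_rule="none"))
            assert dxz <= dxy + dyz + 1e-9


class TestAlpha:
    def test_uniform_community_has_unit_evenness(self):
        a = alpha_indices(cm([[10.0], [10.0], [10.0], [10.0]]))
        assert a["richness"].iloc[0] == 4
        assert a["pielou"].iloc[0] == pytest.approx(1.0)

    def test_single_species_evenness_undefined(self):
        a = alpha_indices(cm([[10.0], [0.0]]))
        assert np.isnan(a["pielou"].iloc[0])

    def test_hand_values(self):
        a = alpha_indices(cm([[2.0], [1.0], [1.0]]))  # p = 0.5, 0.25, 0.25
        assert a["shannon"].iloc[0] == pytest.approx(1.03972, abs=1e-5)
        assert a["pielou"].iloc[0] == pytest.approx(0.94640, abs=1e-5)

    def test_richness_untouched_by_normalization(self, reduced_dataset):
        from otubench import normalize

        raw = reduced_dataset.raw
        for method in ("tss", "gmpr"):
            out = normalize(raw, method)
            pd.testing.assert_series_equal(
                alpha_indices(out)["richness"], alpha_indices(raw)["richness"]
            )


class TestAlphaTests:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        truth = rng.integers(1, 60, size=(30, 10)).astype(float)
        raw = truth.copy()
        raw[rng.random(truth.shape) < 0.3] = 0.0
        raw[0] += 1
        return cm(truth, layer="ground_truth"), cm(raw)

    def test_perfect_pipeline_has_zero_errors(self):
        truth, raw = self._toy()
        res = alpha_error_tests(truth, raw, {"perfect": truth})
        assert (res["median_rel_error"] == 0).all()
        assert (res["p_value"] < 0.05).all()

    def test_identity_pipeline_is_not_an_improvement(self):
        truth, raw = self._toy()
        res = alpha_error_tests(truth, raw, {"same": raw})
        assert (res["p_value"] == 1.0).all()

    def test_halved_errors_detected_with_large_effect(self):
        # construct a pipeline whose index values sit exactly halfway
        # between raw's and the truth's -> halved relative errors
        truth, raw = self._toy(seed=3)
        half = cm((truth.to_numpy() + raw.to_numpy()) / 2)
        res = alpha_error_tests(truth, raw, {"half": half}, indices=("richness",))
        row = res.iloc[0]
        assert row["p_adjusted"] < 0.05
        assert row["cohens_d"] < 0  # smaller errors
        assert abs(row["cohens_d"]) > 0.8


class TestGroupComparisons:
    def test_identical_groups_ns(self):
        rng = np.random.default_rng(1)
        block = rng.integers(1, 50, size=(20, 4)).astype(float)
        arr = np.column_stack([block, block])
        labels = alpha_group_comparisons(cm(arr, groups="AAAABBBB"))
        assert (labels["label"] == "ns").all()

    def test_disjoint_richness_up(self):
        arr = np.zeros((30, 8))
        arr[:25, :4] = 5.0  # group A: rich
        arr[:3, 4:] = 5.0   # group B: poor
        labels = alpha_group_comparisons(cm(arr, groups="AAAABBBB"),
                                         indices=("richness",))
        assert labels["label"].iloc[0] == "up"

    def test_truth_vs_itself_zero_disagreement(self, reduced_dataset):
        lab = alpha_group_comparisons(reduced_dataset.ground_truth)
        assert comparison_disagreement(lab, lab) == 0.0


class TestBeta:
    def test_whittaker_hand_cases(self):
        identical = cm([[1.0, 2.0], [3.0, 1.0]])
        assert whittaker_matrix(identical).iloc[0, 1] == pytest.approx(1.0)
        disjoint = cm([[1.0, 0.0], [0.0, 1.0]])
        assert whittaker_matrix(disjoint).iloc[0, 1] == pytest.approx(2.0)
        # S_a=3, S_b=1, overlap 1 -> union 3, mean richness 2 -> 1.5
        partial = cm([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        assert whittaker_matrix(partial).iloc[0, 1] == pytest.approx(1.5)

    def test_bray_curtis_hand_cases(self):
        assert bray_curtis_matrix(cm([[2.0, 2.0], [3.0, 3.0]])).iloc[0, 1] == 0.0
        assert bray_curtis_matrix(cm([[2.0, 0.0], [0.0, 2.0]])).iloc[0, 1] == 1.0
        m = cm([[2.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        assert m is not None
        assert bray_curtis_matrix(m).iloc[0, 1] == pytest.approx(0.5)

    def test_nmds_equilateral_and_exact_recovery(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, stress = nmds_embed(D, seed=0)
        d01 = np.linalg.norm(coords.iloc[0] - coords.iloc[1])
        d02 = np.linalg.norm(coords.iloc[0] - coords.iloc[2])
        assert d01 == pytest.approx(d02, rel=0.05)
        assert stress < 0.02

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        D2 = squareform(pdist(pts))
        _, stress2 = nmds_embed(D2, seed=0)
        assert stress2 < 0.01

    def test_nmds_label_permutation(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        coords, _ = nmds_embed(pd.DataFrame(D, index=list("abcdef"),
                                            columns=list("abcdef")), seed=1)
        perm = [3, 1, 0, 5, 4, 2]
        Dp = D[np.ix_(perm, perm)]
        labels = [list("abcdef")[i] for i in perm]
        coords_p, stress_p = nmds_embed(
            pd.DataFrame(Dp, index=labels, columns=labels), seed=1
        )
        # a non-metric embedding is defined only up to monotone transforms of
        # the distances, so compare rank structure and fit quality, not
        # coordinates: both runs must reproduce the dissimilarity ranks
        from scipy.spatial.distance import pdist as pd_
        from scipy.stats import spearmanr

        _, stress_o = nmds_embed(pd.DataFrame(D, index=list("abcdef"),
                                              columns=list("abcdef")), seed=1)
        for c, dm in ((coords.loc[labels], Dp), (coords_p, Dp)):
            rho = spearmanr(pd_(c.to_numpy()), squareform(dm)).statistic
            assert rho > 0.95
        assert stress_p == pytest.approx(stress_o, abs=0.02)


class TestDA:
    def test_identical_groups_empty(self):
        rng = np.random.default_rng(2)
        block = rng.integers(0, 40, size=(25, 5)).astype(float)
        arr = np.column_stack([block, block])
        arr[0] += 1
        out = da_features(cm(arr, groups="AAAAABBBBB"))
        assert out[("A", "B")] == set()

    def test_single_separated_feature_found(self):
        # one feature with completely disjoint high/low values (10 vs 10),
        # everything else identical between groups
        rng = np.random.default_rng(4)
        base = rng.integers(5, 30, size=(20, 10)).astype(float)
        arr = np.column_stack([base, base])
        arr[0, :10] = np.arange(100.0, 110.0)
        arr[0, 10:] = np.arange(1.0, 11.0)
        out = da_features(cm(arr, groups="A" * 10 + "B" * 10))
        assert out[("A", "B")] == {"F0"}
        # exact MW p for complete separation: 2/C(20,10) before correction;
        # permutation oracle confirms the test statistic is extreme
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(arr[0, :10], arr[0, 10:], alternative="two-sided",
                         method="exact").pvalue
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_zero_alpha_level_empty(self):
        rng = np.random.default_rng(6)
        arr = rng.integers(0, 50, size=(15, 8)).astype(float)
        arr[0] += 1
        out = da_features(cm(arr, groups="AAAABBBB"), alpha_level=0.0)
        assert all(len(s) == 0 for s in out.values())

    def test_null_false_positive_rate_controlled(self):
        # identical-groups simulation: BH at 0.05 keeps the false-positive
        # proportion within 0.05 + 3 binomial SEs
        rng = np.random.default_rng(11)
        n_feat = 500
        arr = rng.negative_binomial(5, 0.1, size=(n_feat, 20)).astype(float)
        arr[0] += 1
        out = da_features(cm(arr, groups="A" * 10 + "B" * 10))
        fp = len(out[("A", "B")]) / n_feat
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_feat)
        assert fp <= bound


class TestJaccardBHCohen:
    def test_jaccard_cases(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard(set(), set()) == 1.0

    def test_bh_hand_case(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(benjamini_hochberg([0.7]), [0.7])

    def test_bh_rejects_bad_input(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_cohens_d_and_labels(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(a, a) == 0.0
        assert magnitude_label(0.0) == "Negligible"
        assert magnitude_label(0.005) == "Negligible"
        assert magnitude_label(0.01) == "Very small"
        assert magnitude_label(0.2) == "Small"
        assert magnitude_label(0.5) == "Medium"
        assert magnitude_label(0.8) == "Large"
        assert magnitude_label(1.2) == "Very large"
        assert magnitude_label(2.0) == "Huge"
        assert magnitude_label(-2.5) == "Huge"


class TestEvaluateAll:
    def test_perfect_pipeline_and_report_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        truth_arr = rng.integers(1, 80, size=(40, 12)).astype(float)
        truth_arr[rng.random(truth_arr.shape) < 0.2] = 0.0
        truth_arr[0] += 1
        raw_arr = truth_arr.copy()
        raw_arr[rng.random(truth_arr.shape) < 0.2] = 0.0
        groups = "AAAABBBBCCCC"
        truth = cm(truth_arr, groups=groups, layer="ground_truth")
        raw = cm(raw_arr, groups=groups, layer="raw")
        perfect = cm(truth_arr, groups=groups, layer="processed")
        report = evaluate_all(truth, raw, {"perfect": perfect}, with_beta=False)
        sc = report.tables["sparsity_confusion"].loc["perfect"]
        assert sc["sensitivity"] == 100.0 and sc["specificity"] == 100.0
        ab = report.tables["abundance_error"].loc["perfect"]
        assert ab["median_smape"] == 0.0
        assert ab["median_aitchison"] == 0.0
        da = report.tables["da_concordance"].loc["perfect"]
        assert da["median_jaccard"] == 1.0

        report.write(tmp_path / "rep")
        from otubench import EvalReport

        back = EvalReport.read(tmp_path / "rep")
        assert back.summary == report.summary
        for name, table in report.tables.items():
            pd.testing.assert_frame_equal(
                back.tables[name].reset_index(drop=True).round(12),
                table.reset_index(drop=True).round(12),
                check_dtype=False,
            )
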