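"""Peptidome pipeline: baseline subtraction, binning, scaling, PCA/dPCA,
differential testing and pattern calls."""

import numpy as np
import pytest

from hypothesis import given, settings, strategies as st

from thermopept.peptidomics import (
    FeatureMatrix,
    bin_spectrum,
    average_replicates,
    build_feature_matrix,
    classify_pattern,
    differential_f_test,
    differential_t_test,
    discriminant_pca,
    group_bin_means,
    pca,
    scale_features,
    subtract_spectrum_baseline,
)
from thermopept.synthetic import Spectrum


def make_spectrum(mz, intensity, **kw):
    defaults = dict(sample_id="s", group="Control", fraction="FX2",
                    replicate=1)
    defaults.update(kw)
    return Spectrum(mz=np.asarray(mz, float),
                    intensity=np.asarray(intensity, float), **defaults)


def flat_grid(start=900.0, stop=1100.0, step=0.5):
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


def make_matrix(values, groups, centers=None, scaling="raw"):
    values = np.asarray(values, float)
    if centers is None:
        centers = 900.5 + np.arange(values.shape[1])
    return FeatureMatrix(
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        groups=tuple(groups),
        bin_centers=np.asarray(centers, float),
        values=values,
        scaling_state=scaling,
    )


class TestBaselineSubtraction:
    def test_constant_intensity_removed(self):
        mz = flat_grid()
        sp = make_spectrum(mz, np.full_like(mz, 7.0))
        out = subtract_spectrum_baseline(sp, window_width=20.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_peaks_on_zero_baseline_preserved(self):
        mz = flat_grid()
        intensity = np.zeros_like(mz)
        for center in (950.0, 1000.0, 1050.0):
            intensity += 80.0 * np.exp(-0.5 * ((mz - center) / 0.3) ** 2)
        out = subtract_spectrum_baseline(make_spectrum(mz, intensity),
                                         window_width=30.0)
        assert np.max(np.abs(out.intensity - intensity)) < 0.01 * 80.0

    def test_peak_apex_survives_decaying_baseline(self):
        mz = flat_grid()
        baseline = 50.0 * np.exp(-(mz - 900.0) / 150.0)
        peak = 100.0 * np.exp(-0.5 * ((mz - 1000.0) / 0.3) ** 2)
        out = subtract_spectrum_baseline(make_spectrum(mz, baseline + peak),
                                         window_width=30.0)
        apex = out.intensity[np.argmin(np.abs(mz - 1000.0))]
        assert apex == pytest.approx(100.0, rel=0.05)

    def test_invalid_window_rejected(self):
        sp = make_spectrum([900.0, 901.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            subtract_spectrum_baseline(sp, window_width=0.0)


class TestBinning:
    def test_nearby_peaks_share_one_bin(self):
        sp = make_spectrum([1000.0, 1000.4], [3.0, 4.0])
        vec = bin_spectrum(sp, bin_width=1.0)
        idx = 1000 - 900
        assert vec[idx] == pytest.approx(7.0)
        assert vec.sum() == pytest.approx(7.0)

    def test_point_on_edge_goes_to_higher_bin(self):
        sp = make_spectrum([1001.0], [5.0])
        vec = bin_spectrum(sp, bin_width=1.0)
        assert vec[1001 - 900] == 5.0
        assert vec[1000 - 900] == 0.0

    def test_matches_per_point_assignment_oracle(self):
        rng = np.random.default_rng(9)
        mz = np.sort(rng.uniform(850, 3100, size=500))
        intensity = rng.exponential(scale=10, size=500)
        vec = bin_spectrum(make_spectrum(mz, intensity), bin_width=1.0)
        oracle = np.zeros(2100)
        for m, i in zip(mz, intensity):
            if 900.0 <= m < 3000.0:
                oracle[int(np.floor(m - 900.0))] += i
        np.testing.assert_allclose(vec, oracle, rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_binning_conserves_in_range_intensity(self, seed):
        rng = np.random.default_rng(seed)
        mz = np.sort(rng.uniform(900.0, 3000.0 - 1e-6, size=100))
        mz = np.unique(mz)
        intensity = rng.exponential(scale=5, size=mz.size)
        vec = bin_spectrum(make_spectrum(mz, intensity), bin_width=1.0)
        assert vec.sum() == pytest.approx(intensity.sum(), rel=1e-12)

    def test_vector_length_follows_bin_width(self):
        sp = make_spectrum([1000.0], [1.0])
        assert bin_spectrum(sp, bin_width=1.0).size == 2100
        assert bin_spectrum(sp, bin_width=2.5).size == int(np.ceil(2100 / 2.5))


class TestReplicateAveraging:
    def test_identity_and_mean(self):
        np.testing.assert_array_equal(
            average_replicates([np.array([1.0, 2.0])]), [1.0, 2.0]
        )
        np.testing.assert_array_equal(
            average_replicates([np.array([0.0]), np.array([2.0])]), [1.0]
        )

    def test_matches_oracle(self):
        rng = np.random.default_rng(10)
        reps = [rng.exponential(size=30) for _ in range(3)]
        np.testing.assert_allclose(
            average_replicates(reps), (reps[0] + reps[1] + reps[2]) / 3.0
        )

    def test_inconsistent_grids_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([np.zeros(3), np.zeros(4)])
        with pytest.raises(ValueError):
            average_replicates([])


class TestScaling:
    def test_pareto_divides_by_sqrt_sd(self):
        col = np.array([[0.0], [4.0], [8.0], [4.0]])  # sd = sqrt(32/3)
        m = make_matrix(np.hstack([col, col * 0 + 1]), ["a"] * 4)
        out = scale_features(m, "pareto")
        sd = np.std(col, ddof=1)
        expected = (col[:, 0] - col.mean()) / np.sqrt(sd)
        np.testing.assert_allclose(out.values[:, 0], expected)

    def test_mean_centering_zeroes_column_means(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(6, 9)), ["a"] * 6)
        out = scale_features(m, "mean_center")
        assert np.max(np.abs(out.values.mean(axis=0))) < 1e-12

    def test_zero_variance_column_left_centered(self):
        m = make_matrix(np.zeros((3, 2)), ["a"] * 3)
        out = scale_features(m, "pareto")
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_sample_rejected(self):
        m = make_matrix(np.ones((1, 4)), ["a"])
        with pytest.raises(ValueError):
            scale_features(m)


class TestPCA:
    def test_one_dimensional_data_explained_by_pc1(self):
        t = np.linspace(-1, 1, 8)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        m = make_matrix(np.outer(t, direction), ["a"] * 8)
        res = pca(scale_features(m, "mean_center"), n_components=3)
        total = res.explained_variance.sum()
        assert res.explained_variance[0] / total == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(12)
        m = scale_features(make_matrix(rng.normal(size=(6, 10)), ["a"] * 6),
                           "mean_center")
        res = pca(m, n_components=5)
        recon = res.scores @ res.loadings.T
        assert np.max(np.abs(recon - m.values)) < 1e-8

    def test_explained_variance_matches_covariance_eigenvalues(self):
        rng = np.random.default_rng(13)
        m = scale_features(make_matrix(rng.normal(size=(10, 50)), ["a"] * 10),
                           "pareto")
        res = pca(m, n_components=9)
        eig = np.sort(np.linalg.eigvalsh(np.cov(m.values.T)))[::-1]
        np.testing.assert_allclose(res.explained_variance, eig[:9], atol=1e-8)

    def test_score_variance_equals_matrix_variance(self):
        rng = np.random.default_rng(14)
        m = scale_features(make_matrix(rng.normal(size=(8, 20)), ["a"] * 8),
                           "mean_center")
        res = pca(m, n_components=7)
        total_scores = res.scores.var(axis=0, ddof=1).sum()
        total_matrix = m.values.var(axis=0, ddof=1).sum()
        assert total_scores == pytest.approx(total_matrix, rel=1e-8)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(15)
        m = scale_features(make_matrix(rng.normal(size=(7, 12)), ["a"] * 7),
                           "mean_center")
        res = pca(m, n_components=4)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        peak_loadings = res.loadings[
            np.argmax(np.abs(res.loadings), axis=0), np.arange(4)
        ]
        assert np.all(peak_loadings > 0)

    def test_raw_matrix_and_oversized_rank_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(4, 6)),
                        ["a"] * 4)
        with pytest.raises(ValueError):
            pca(m, n_components=2)
        scaled = scale_features(m, "mean_center")
        with pytest.raises(ValueError):
            pca(scaled, n_components=4)


def three_group_matrix(n_per_group=4, n_bins=40, sep=6.0, seed=16):
    rng = np.random.default_rng(seed)
    groups, rows = [], []
    for g_idx, g in enumerate(("Control", "CIN 2", "Cerv Ca")):
        center = np.zeros(n_bins)
        center[g_idx * 3:g_idx * 3 + 3] = sep
        for _ in range(n_per_group):
            rows.append(center + rng.normal(size=n_bins))
            groups.append(g)
    return make_matrix(np.array(rows), groups)


class TestDiscriminantPCA:
    def test_separated_groups_fully_sorted(self):
        m = scale_features(three_group_matrix(), "pareto")
        res = discriminant_pca(m, n_pcs=5)
        assert res.purity == 1.0
        assert res.scores.shape == (12, 2)
        assert not res.degenerate

    def test_shuffled_labels_drop_to_chance(self):
        # leave-one-out purity is the chance-level control; in-sample
        # purity overfits random labels at n = 12
        m = scale_features(three_group_matrix(), "pareto")
        rng = np.random.default_rng(17)
        labels = np.array(m.groups)
        purities = []
        for _ in range(100):
            purities.append(
                discriminant_pca(m, labels=rng.permutation(labels),
                                 n_pcs=5, cross_validate=True).purity
            )
        assert np.mean(purities) == pytest.approx(1 / 3, abs=0.25)

    def test_true_labels_survive_cross_validation(self):
        m = scale_features(three_group_matrix(), "pareto")
        res = discriminant_pca(m, n_pcs=5, cross_validate=True)
        assert res.purity == 1.0

    def test_identical_groups_flagged_degenerate(self):
        rng = np.random.default_rng(18)
        block = rng.normal(size=(4, 20))
        values = np.vstack([block, block])
        m = scale_features(
            make_matrix(values, ["a"] * 4 + ["b"] * 4), "mean_center"
        )
        with pytest.warns(UserWarning):
            res = discriminant_pca(m, n_pcs=3)
        assert res.degenerate

    def test_preconditions(self):
        m = scale_features(three_group_matrix(), "pareto")
        with pytest.raises(ValueError):
            discriminant_pca(m, n_pcs=9)  # >= n_samples - n_groups
        tiny = scale_features(
            make_matrix(np.random.default_rng(0).normal(size=(3, 5)),
                        ["a", "a", "b"]),
            "mean_center",
        )
        with pytest.raises(ValueError):
            discriminant_pca(tiny, n_pcs=1)  # group b has a single sample


class TestDifferentialTests:
    def test_identical_groups_yield_no_hits(self):
        block = np.tile(np.arange(4.0), (4, 1))
        m = make_matrix(np.vstack([block, block]), ["a"] * 4 + ["b"] * 4)
        res = differential_t_test(m, group_pair=("a", "b"))
        assert not any(r.significant for r in res)
        assert all(r.p_value == 1.0 for r in res)

    def test_hand_computed_t_statistic(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
                        ["a"] * 3 + ["b"] * 3)
        res = differential_t_test(m, group_pair=("a", "b"))[0]
        assert res.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.0214, abs=1e-3)
        assert res.significant

    def test_p_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(19)
        vals = rng.exponential(size=(8, 15))
        labels = ["a"] * 4 + ["b"] * 4
        p1 = [r.p_value for r in
              differential_t_test(make_matrix(vals, labels),
                                  group_pair=("a", "b"))]
        p2 = [r.p_value for r in
              differential_t_test(make_matrix(vals * 37.5, labels),
                                  group_pair=("a", "b"))]
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_f_test_agrees_with_t_for_two_groups(self):
        rng = np.random.default_rng(20)
        vals = rng.normal(size=(8, 10))
        labels = ["a"] * 4 + ["b"] * 4
        m = make_matrix(vals, labels)
        p_t = np.array([r.p_value for r in
                        differential_t_test(m, group_pair=("a", "b"))])
        p_f = np.array([r.p_value for r in differential_f_test(m)])
        np.testing.assert_allclose(p_t, p_f, atol=1e-10)

    def test_small_groups_rejected(self):
        m = make_matrix(np.ones((3, 4)), ["a", "a", "b"])
        with pytest.raises(ValueError):
            differential_t_test(m, group_pair=("a", "b"))


class TestPatternClassification:
    def test_absent_control_equal_disease(self):
        call = classify_pattern(
            {"Control": 0.0, "Cerv Ca": 100.0, "CIN 2": 98.0},
            fold_tolerance=0.5,
        )
        assert call == "Absent in Control; Cerv Ca = CIN 2"

    def test_three_way_ordering(self):
        call = classify_pattern(
            {"CIN 2": 100.0, "Cerv Ca": 40.0, "Control": 10.0}
        )
        assert call == "CIN 2>Cerv Ca>Control"

    def test_all_equal_means_single_chain(self):
        call = classify_pattern(
            {"Control": 50.0, "CIN 2": 52.0, "Cerv Ca": 49.0}
        )
        assert call == "Cerv Ca = CIN 2 = Control"

    def test_all_absent_flagged(self):
        with pytest.warns(UserWarning):
            call = classify_pattern(
                {"Control": 0.0, "CIN 2": 0.0, "Cerv Ca": 0.0},
                absence_threshold=1.0,
            )
        assert call.count("Absent in") == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern({"Control": 1.0})


class TestFeatureMatrixConstruction:
    def test_replicates_collapse_to_one_row_per_sample(self):
        mz = flat_grid(900, 1000, 0.5)
        spectra = []
        for sid in ("s1", "s2"):
            for rep in (1, 2, 3):
                peak = 60.0 * np.exp(-0.5 * ((mz - 950.0) / 0.3) ** 2)
                spectra.append(
                    make_spectrum(mz, peak, sample_id=sid, replicate=rep)
                )
        fm = build_feature_matrix(spectra, mz_range=(900.0, 1000.0))
        assert fm.values.shape[0] == 2
        assert fm.scaling_state == "raw"
        means = group_bin_means(fm, 950.0)
        assert means["Control"] > 50.0
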