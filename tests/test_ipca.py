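"""Incremental PCA core: moment updates, SVD updates, fit/transform contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import msipca
from msipca import (
    FitState,
    default_batch_size,
    exact_pca,
    finalize_explained_variance,
    fit,
    load_model,
    partial_fit,
    principal_angles,
    read_matrix,
    save_model,
    transform_incremental,
    update_mean_var,
)
from msipca.ipca import _fit_bounds, apply_sign_convention


class TestDefaultBatchSize:
    @pytest.mark.parametrize(
        "n_peaks,n_spectra,expected",
        [
            (310, 262_144, 5890),  # 19x heuristic at scale
            (199, 35_000, 3781),
            (33, 100, 100),  # clipped to cube length
            (100, 50, 50),
        ],
    )
    def test_heuristic_and_clip(self, n_peaks, n_spectra, expected):
        assert default_batch_size(n_peaks, n_spectra) == expected

    def test_never_below_peak_count_when_feasible(self):
        for f in (1, 7, 33, 500):
            n = 100 * f
            assert default_batch_size(f, n) >= f

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            default_batch_size(0, 10)


class TestRunningMoments:
    def test_pooled_update_matches_one_pass(self):
        # state from rows {1, 3}; batch {5, 7}; oracle over {1, 3, 5, 7}
        n, mu, m2 = update_mean_var(0, None, None, np.array([[1.0], [3.0]]))
        assert (n, mu[0], m2[0]) == (2, 2.0, 2.0)
        n, mu, m2 = update_mean_var(n, mu, m2, np.array([[5.0], [7.0]]))
        assert (n, mu[0], m2[0]) == (4, 4.0, 20.0)

    def test_initialization_from_empty_state(self):
        batch = np.array([[1.0, 2.0], [3.0, 6.0]])
        n, mu, m2 = update_mean_var(0, None, None, batch)
        np.testing.assert_allclose(mu, [2.0, 4.0])
        np.testing.assert_allclose(m2, [2.0, 8.0])

    def test_identical_batches_cancel_correction(self):
        batch = np.array([[1.0, -1.0], [5.0, 3.0]])
        n, mu, m2 = update_mean_var(0, None, None, batch)
        n, mu2, m2_2 = update_mean_var(n, mu, m2, batch)
        np.testing.assert_allclose(mu2, batch.mean(axis=0))
        np.testing.assert_allclose(m2_2, 2 * m2)

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=40),
        st.integers(1, 39),
    )
    def test_any_split_agrees_with_one_pass(self, xs, cut):
        cut = min(cut, len(xs) - 1)
        col = np.array(xs)[:, None]
        n, mu, m2 = update_mean_var(0, None, None, col[:cut])
        n, mu, m2 = update_mean_var(n, mu, m2, col[cut:])
        assert n == len(xs)
        np.testing.assert_allclose(mu, col.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(m2, ((col - col.mean(0)) ** 2).sum(0), atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            update_mean_var(0, None, None, np.array([[np.inf]]))


class TestPartialFit:
    def test_hand_svd_of_orthogonal_columns(self):
        x = np.array([[2, 0], [-2, 0], [0, 1], [0, -1]], dtype=np.float32)
        state = partial_fit(FitState(n_features=2, k=2), x)
        np.testing.assert_allclose(
            state.singular_values, [np.sqrt(8), np.sqrt(2)], rtol=1e-6
        )
        np.testing.assert_allclose(np.abs(state.components), np.eye(2), atol=1e-6)
        ev, ratio = finalize_explained_variance(state)
        np.testing.assert_allclose(ev, [8 / 3, 2 / 3], rtol=1e-6)
        np.testing.assert_allclose(ratio, [0.8, 0.2], rtol=1e-6)

    def test_rank_one_cube_has_unit_leading_ratio(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=6)
        x = np.outer(rng.normal(size=50), v).astype(np.float32)
        state = FitState(n_features=6, k=6)
        for i in range(0, 50, 10):
            partial_fit(state, x[i : i + 10])
        _, ratio = finalize_explained_variance(state)
        assert ratio[0] == pytest.approx(1.0, abs=1e-5)
        assert ratio[1:].max() < 1e-5

    def test_batched_fit_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 10)).astype(np.float32)
        state = FitState(n_features=10, k=10)
        for i in range(0, 200, 50):
            partial_fit(state, x[i : i + 50])
        xc = x - x.mean(axis=0)
        s_oracle = np.linalg.svd(xc.astype(np.float64), compute_uv=False)
        np.testing.assert_allclose(state.singular_values[:5], s_oracle[:5], rtol=1e-3)
        vt = np.linalg.svd(xc.astype(np.float64))[2]
        angles = principal_angles(_orthonormalize(state.components[:5]), vt[:5])
        assert angles.max() < 1e-3

    def test_first_batch_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="first batch"):
            partial_fit(FitState(n_features=4, k=4), np.zeros((3, 4), dtype=np.float32))

    def test_loadings_stay_orthonormal(self):
        rng = np.random.default_rng(5)
        state = FitState(n_features=12, k=12)
        for _ in range(6):
            partial_fit(state, rng.normal(size=(40, 12)).astype(np.float32))
        gram = state.components.astype(np.float64) @ state.components.T.astype(np.float64)
        assert np.max(np.abs(gram - np.eye(12))) <= 1e-4

    def test_sign_convention_largest_entry_positive(self):
        comp = np.array([[0.1, -0.9, 0.2], [0.5, 0.4, 0.3]])
        fixed = apply_sign_convention(comp)
        np.testing.assert_allclose(fixed[0], [-0.1, 0.9, -0.2])
        np.testing.assert_allclose(fixed[1], comp[1])


def _orthonormalize(rows):
    rows = rows.astype(np.float64)
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


class TestFit:
    def test_single_batch_fit_equals_exact_pca(self, make_cube):
        cube, _ = make_cube(n_spectra=300, n_peaks=12, rank=4, seed=3)
        inc = fit(cube, batch_size=300)
        ref = exact_pca(cube)
        np.testing.assert_allclose(inc.singular_values, ref.singular_values, rtol=1e-5)
        np.testing.assert_allclose(inc.components, ref.components, atol=1e-5)

    def test_final_mean_matches_one_pass(self, make_cube):
        cube, _ = make_cube(n_spectra=1000, n_peaks=8, seed=9)
        model = fit(cube, batch_size=170)
        full = cube.read_all()
        assert model.n_seen == 1000
        np.testing.assert_allclose(model.mean, full.mean(axis=0, dtype=np.float64), rtol=1e-5)

    def test_zero_variance_cube_yields_zero_ratios(self, tmp_path):
        spec = msipca.SyntheticSpec(
            n_spectra=200, n_peaks=6, rank=0, noise_sd=0.0, baseline=1.0, seed=0
        )
        cube, _ = msipca.generate_datacube(spec, tmp_path / "flat")
        model = fit(cube, batch_size=50)
        assert np.all(model.singular_values < 1e-3)
        np.testing.assert_array_equal(model.explained_variance_ratio, 0.0)

    def test_batch_size_permutation_robustness(self, make_cube):
        cube, _ = make_cube(n_spectra=2000, n_peaks=25, rank=6, seed=11)
        f, n = 25, 2000
        models = [fit(cube, batch_size=d) for d in (f, 5 * f, 19 * f, n)]
        ref = models[-1].singular_values
        for m in models[:-1]:
            np.testing.assert_allclose(m.singular_values, ref, rtol=1e-3)

    def test_variance_conservation_at_full_rank(self, make_cube):
        cube, _ = make_cube(n_spectra=1500, n_peaks=20, rank=5, seed=2)
        model = fit(cube)  # k = F
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(
            model.explained_variance.sum(), model.total_variance.sum(), rtol=1e-3
        )

    def test_small_batch_size_enlarges_first_batch_only(self, make_cube):
        bounds = _fit_bounds(n_spectra=100, batch_size=10, k=33)
        assert bounds[0] == (0, 33)
        assert bounds[1] == (33, 10)
        assert sum(r for _, r in bounds) == 100
        cube, _ = make_cube(n_spectra=100, n_peaks=33, rank=3, seed=4)
        model = fit(cube, batch_size=10)  # k=33 > 10: must still fit fine
        assert model.k == 33

    def test_cross_check_against_sklearn_incremental_pca(self, make_cube):
        sklearn_dec = pytest.importorskip("sklearn.decomposition")
        cube, _ = make_cube(n_spectra=1200, n_peaks=15, rank=5, seed=21)
        x = cube.read_all()
        ours = fit(cube, k=15, batch_size=300)
        theirs = sklearn_dec.IncrementalPCA(n_components=15, batch_size=300)
        theirs.fit(x)
        np.testing.assert_allclose(
            ours.singular_values, theirs.singular_values_, rtol=1e-4
        )
        np.testing.assert_allclose(
            ours.explained_variance_ratio, theirs.explained_variance_ratio_, rtol=1e-3
        )
        aligned = msipca.align_signs(ours.components, theirs.components_.astype(np.float32))
        np.testing.assert_allclose(ours.components[:5], aligned[:5], atol=1e-3)


class TestTransform:
    def test_identity_projection_returns_cube(self, make_cube, tmp_path):
        cube, _ = make_cube(n_spectra=120, n_peaks=6, rank=2, seed=1)
        model = fit(cube, batch_size=120)
        ident = msipca.IPCAModel(
            n_seen=model.n_seen,
            n_features=6,
            k=6,
            mean=np.zeros(6),
            total_variance=model.total_variance,
            singular_values=model.singular_values,
            components=np.eye(6, dtype=np.float32),
            explained_variance=model.explained_variance,
            explained_variance_ratio=model.explained_variance_ratio,
        )
        mf = transform_incremental(cube, ident, tmp_path / "ident", batch_size=50)
        np.testing.assert_array_equal(read_matrix(mf), cube.read_all())

    def test_scores_are_centered(self, make_cube, tmp_path):
        cube, _ = make_cube(n_spectra=3000, n_peaks=10, rank=3, seed=8)
        model = fit(cube)
        mf = transform_incremental(cube, model, tmp_path / "s")
        scores = read_matrix(mf)
        lim = 1e-3 * scores.std(axis=0) + 1e-9
        assert np.all(np.abs(scores.mean(axis=0)) <= lim)

    def test_full_rank_reconstruction(self, make_cube, tmp_path):
        cube, _ = make_cube(n_spectra=500, n_peaks=12, rank=4, seed=6)
        model = fit(cube)  # k = F
        mf = transform_incremental(cube, model, tmp_path / "s")
        scores = read_matrix(mf).astype(np.float64)
        x = cube.read_all().astype(np.float64)
        xc = x - model.mean
        recon = scores @ model.components.astype(np.float64)
        data_range = x.max() - x.min()
        assert np.max(np.abs(recon - xc)) <= 1e-3 * data_range

    @pytest.mark.parametrize("workers", [2, 4])
    def test_concurrency_bitwise_identity(self, make_cube, tmp_path, workers):
        cube, _ = make_cube(n_spectra=2100, n_peaks=16, rank=4, seed=12)
        model = fit(cube)
        seq = transform_incremental(cube, model, tmp_path / "seq", batch_size=250)
        par = transform_incremental(
            cube, model, tmp_path / f"par{workers}", batch_size=250, concurrency=workers
        )
        np.testing.assert_array_equal(read_matrix(seq), read_matrix(par))

    def test_feature_mismatch_rejected(self, make_cube, tmp_path):
        cube, _ = make_cube(n_spectra=100, n_peaks=5, rank=2)
        other, _ = make_cube(n_spectra=100, n_peaks=6, rank=2)
        model = fit(other)
        with pytest.raises(ValueError, match="features"):
            transform_incremental(cube, model, tmp_path / "x")


class TestModelPersistence:
    def test_save_load_round_trip(self, make_cube, tmp_path):
        cube, _ = make_cube(n_spectra=400, n_peaks=9, rank=3, seed=5)
        model = fit(cube)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.n_seen == model.n_seen and back.k == model.k
        np.testing.assert_array_equal(back.components, model.components)
        np.testing.assert_allclose(back.mean, model.mean)
        np.testing.assert_allclose(back.singular_values, model.singular_values)

    def test_explained_variance_requires_two_rows(self):
        state = FitState(n_features=2, k=1)
        partial_fit(state, np.array([[1.0, 2.0]], dtype=np.float32))
        with pytest.raises(ValueError, match="2 rows"):
            finalize_explained_variance(state)
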