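"""Covariance analysis, projections, cosine content, porcupine extraction."""

import numpy as np
import pytest

from mdcompare.essential_dynamics import (
    ProjectionSeries,
    build_covariance,
    cosine_content,
    cumulative_contribution,
    porcupine_extremes,
    project,
)
from mdcompare.superpose_metrics import FitSpec, rmsf_profile
from mdcompare.synthetic_data import (
    ca_chain_topology,
    diffusion_trajectory,
    gaussian_ensemble,
)

from conftest import make_trajectory


def _no_fit_spec(traj):
    ca = traj.topology.ca_indices()
    return FitSpec(fit_indices=ca, measure_indices=ca, superpose=False)


class TestBuildCovariance:
    def test_static_trajectory_has_zero_tmsf(self):
        rng = np.random.default_rng(0)
        ref = rng.standard_normal((8, 3))
        traj = make_trajectory(np.repeat(ref[None], 5, axis=0),
                               ca_chain_topology(ref * 10.0))
        model = build_covariance(traj)
        assert model.tmsf_nm2 <= 1e-20
        np.testing.assert_allclose(model.covariance_nm2, 0.0, atol=1e-18)

    def test_trace_equals_eigenvalue_sum(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        assert model.eigenvalues_nm2.sum() == pytest.approx(
            model.tmsf_nm2, rel=1e-12)

    def test_eigenvectors_orthonormal(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        gram = model.eigenvectors.T @ model.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_rigid_fit_annihilates_six_modes(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        # fitting removes 3 translations + 3 rotations
        assert np.all(model.eigenvalues_nm2[-6:] <= 1e-8 * model.tmsf_nm2)

    def test_prescribed_diagonal_spectrum_recovered_without_fitting(self):
        # heteroscedastic diagonal covariance, compared against the raw
        # sample covariance eigenvalues (independent oracle) and the truth
        n = 15
        rng = np.random.default_rng(42)
        variances = rng.uniform(0.5, 2.0, 3 * n) * 1e-3
        traj, truth = gaussian_ensemble(10_000, seed=43, n_atoms=n,
                                        variances_nm2=variances)
        model = build_covariance(traj, _no_fit_spec(traj))
        x = traj.coords.reshape(traj.n_frames, -1)
        oracle_cov = np.cov(x, rowvar=False, ddof=0)
        oracle_eigs = np.sort(np.linalg.eigvalsh(oracle_cov))[::-1]
        np.testing.assert_allclose(model.eigenvalues_nm2, oracle_eigs,
                                   rtol=1e-8, atol=1e-16)
        expected = np.sort(truth.payload["variances_nm2"])[::-1]
        np.testing.assert_allclose(model.eigenvalues_nm2[:3], expected[:3],
                                   rtol=0.05)

    def test_low_rank_mode_variances_recovered(self):
        # 3 orthogonal modes above an isotropic floor; top-3 eigenvalues
        # must land within 5% of the prescribed variances at 1e4 frames
        n = 20
        rng = np.random.default_rng(7)
        modes = rng.standard_normal((3, 3 * n))
        mode_var = np.array([0.05, 0.02, 0.01])
        traj, truth = gaussian_ensemble(
            10_000, seed=8, n_atoms=n, modes=modes,
            mode_variances_nm2=mode_var, sigma_nm=0.005)
        model = build_covariance(traj, _no_fit_spec(traj))
        floor = truth.payload["isotropic_floor_nm2"]
        np.testing.assert_allclose(model.eigenvalues_nm2[:3],
                                   mode_var + floor, rtol=0.05)

    def test_rank_one_ensemble_has_single_mode(self):
        n = 10
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((n, 3))
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction)
        amplitudes = np.linspace(-0.5, 0.5, 50)
        coords = ref[None] + amplitudes[:, None, None] * direction[None]
        traj = make_trajectory(coords, ca_chain_topology(ref * 10.0))
        model = build_covariance(traj, _no_fit_spec(traj))
        assert model.eigenvalues_nm2[0] > 0
        assert model.eigenvalues_nm2[1] <= 1e-12 * model.eigenvalues_nm2[0]
        cum = cumulative_contribution(model.eigenvalues_nm2)
        assert cum[0] == pytest.approx(100.0)

    def test_single_frame_rejected(self):
        ref = np.zeros((4, 3))
        traj = make_trajectory(ref[None] + 0.0, ca_chain_topology(ref))
        with pytest.raises(ValueError, match="2 frames"):
            build_covariance(traj)

    def test_sign_convention_largest_component_positive(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        for j in range(model.eigenvectors.shape[1]):
            col = model.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] >= 0


class TestTraceConsistency:
    def test_tmsf_equals_sum_of_squared_rmsf(self, small_gaussian):
        # computed on identical (unfitted) frames by two independent paths
        traj, _ = small_gaussian
        spec = _no_fit_spec(traj)
        model = build_covariance(traj, spec)
        profile = rmsf_profile(traj, spec)
        assert np.sum(profile.values_nm**2) == pytest.approx(
            model.tmsf_nm2, rel=1e-10)


class TestCumulativeContribution:
    def test_hand_arithmetic_four_eigenvalues(self):
        cum = cumulative_contribution(np.array([4.0, 3.0, 2.0, 1.0]))
        np.testing.assert_allclose(cum, [40.0, 70.0, 90.0, 100.0])

    def test_equal_eigenvalues_are_linear(self):
        cum = cumulative_contribution(np.ones(5))
        np.testing.assert_allclose(cum, [20.0, 40.0, 60.0, 80.0, 100.0])

    def test_monotone_and_ends_at_100(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        cum = cumulative_contribution(model.eigenvalues_nm2)
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(100.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            cumulative_contribution(np.array([1.0, 2.0]))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cumulative_contribution(np.array([1.0, -0.5]))


class TestProjection:
    def test_mean_is_zero_and_variance_matches_eigenvalue(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        for j in (0, 1, 2):
            series = project(traj, model, j)
            assert abs(series.values_nm.mean()) <= 1e-10
            assert series.values_nm.var() == pytest.approx(
                model.eigenvalues_nm2[j], rel=1e-8)

    def test_reconstruction_from_all_projections(self):
        traj, _ = gaussian_ensemble(40, seed=5, n_atoms=6, sigma_nm=0.05)
        spec = _no_fit_spec(traj)
        model = build_covariance(traj, spec)
        dim = 3 * traj.n_atoms
        projections = np.stack(
            [project(traj, model, j, spec).values_nm for j in range(dim)],
            axis=1)
        rebuilt = (projections @ model.eigenvectors.T).reshape(
            traj.n_frames, traj.n_atoms, 3) + model.mean_nm
        assert np.abs(rebuilt - traj.coords).max() <= 1e-8

    def test_index_out_of_range(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        with pytest.raises(IndexError):
            project(traj, model, 3 * traj.n_atoms)


class TestCosineContent:
    def _series(self, values, times=None):
        t = np.linspace(0.0, 1000.0, len(values)) if times is None else times
        return ProjectionSeries(times_ps=t, values_nm=np.asarray(values),
                                eigenvector_index=0)

    def test_half_period_cosine_scores_near_one(self):
        t = np.linspace(0.0, 1.0, 1000)
        c = cosine_content(self._series(np.cos(np.pi * t), times=t * 1000.0))
        assert c >= 0.999

    def test_orthogonal_harmonic_scores_near_zero(self):
        t = np.linspace(0.0, 1.0, 1000)
        c = cosine_content(self._series(np.cos(2 * np.pi * t), times=t * 1000.0),
                           harmonic=1)
        assert c <= 0.001

    def test_second_harmonic_picks_up_full_period_cosine(self):
        t = np.linspace(0.0, 1.0, 1000)
        c = cosine_content(self._series(np.cos(2 * np.pi * t), times=t * 1000.0),
                           harmonic=2)
        assert c >= 0.999

    def test_random_walk_first_pc_is_diffusive(self):
        # the hallmark of unconverged sampling: projections of free
        # diffusion onto the first principal component look like a
        # half-period cosine (content near 1)
        contents = []
        for seed in range(50):
            traj, _ = diffusion_trajectory(10, 200, 0.02, seed=seed)
            model = build_covariance(traj, _no_fit_spec(traj))
            series = project(traj, model, 0, _no_fit_spec(traj))
            contents.append(cosine_content(series))
        assert np.median(contents) >= 0.8

    def test_invariant_to_amplitude_and_time_scaling(self):
        rng = np.random.default_rng(9)
        values = np.cumsum(rng.standard_normal(300))
        t = np.linspace(0.0, 500.0, 300)
        base = cosine_content(self._series(values, times=t))
        scaled = cosine_content(self._series(5.0 * values, times=t * 7.0))
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cosine_content(self._series(np.zeros(10)))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            cosine_content(self._series(np.array([1.0, 2.0])))


class TestPorcupine:
    def test_rank_one_oscillation_extremes_match_endpoints(self):
        n = 8
        rng = np.random.default_rng(11)
        ref = rng.standard_normal((n, 3))
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction)
        amplitudes = np.sin(np.linspace(0, 2 * np.pi, 60))
        coords = ref[None] + 0.3 * amplitudes[:, None, None] * direction[None]
        traj = make_trajectory(coords, ca_chain_topology(ref * 10.0))
        spec = _no_fit_spec(traj)
        model = build_covariance(traj, spec)
        series = project(traj, model, 0, spec)
        conf_min, conf_max, vectors = porcupine_extremes(model, series, traj)
        lo = coords[np.argmin(series.values_nm)]
        hi = coords[np.argmax(series.values_nm)]
        extremes = {tuple(np.round(c.ravel(), 8).tolist())
                    for c in (conf_min, conf_max)}
        targets = {tuple(np.round(c.ravel(), 8).tolist()) for c in (lo, hi)}
        assert extremes == targets

    def test_vector_norms_square_to_projection_range(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        series = project(traj, model, 0)
        _, _, vectors = porcupine_extremes(model, series, traj)
        total = np.sum(vectors["length_nm"] ** 2)
        assert total == pytest.approx(np.ptp(series.values_nm) ** 2, rel=1e-10)

    def test_symmetric_series_gives_symmetric_extremes(self):
        traj, _ = gaussian_ensemble(100, seed=13, n_atoms=6, sigma_nm=0.05)
        spec = _no_fit_spec(traj)
        model = build_covariance(traj, spec)
        series = project(traj, model, 0, spec)
        sym = ProjectionSeries(times_ps=np.arange(4.0),
                               values_nm=np.array([-0.2, 0.1, -0.1, 0.2]),
                               eigenvector_index=0)
        conf_min, conf_max, _ = porcupine_extremes(model, sym, traj)
        np.testing.assert_allclose(conf_min + conf_max, 2 * model.mean_nm,
                                   atol=1e-12)

    def test_constant_series_rejected(self, small_gaussian):
        traj, _ = small_gaussian
        model = build_covariance(traj)
        flat = ProjectionSeries(times_ps=np.arange(3.0),
                                values_nm=np.zeros(3), eigenvector_index=0)
        with pytest.raises(ValueError, match="constant"):
            porcupine_extremes(model, flat, traj)
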