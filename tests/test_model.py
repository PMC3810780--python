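"""Memory-walk model: angular density, turn distribution, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from femdrift._kernels import accumulate_angular_density
from femdrift.errors import ParameterError
from femdrift.model import (
    AngularDensity,
    ModelParams,
    WalkState,
    angular_density,
    angular_density_closed,
    grid_angles,
    history_density_at,
    model_H_curve,
    simulate_ensemble,
    simulate_walk,
    step,
    turn_probability,
)
from femdrift.scaling import fit_loglog_slope, msd_curve, scaling_curve


def quadrature_angular_density(r_m, theta_m, sigma, angle):
    """Oracle: radial integral of the planar Gaussian-mixture density."""

    def integrand(r):
        x, y = r * np.cos(angle), r * np.sin(angle)
        total = 0.0
        for rm, tm in zip(r_m, theta_m):
            xm, ym = rm * np.cos(tm), rm * np.sin(tm)
            total += np.exp(-((x - xm) ** 2 + (y - ym) ** 2) / (2 * sigma**2))
        return r * total / (2 * np.pi * sigma**2)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


class TestPlanarDensity:
    def test_peak_value_at_isolated_remembered_point(self):
        val = history_density_at([2.0, 0.0], [[2.0, 0.0]], sigma=0.5)
        assert val == pytest.approx(1.0 / (2 * np.pi * 0.25))

    def test_total_mass_is_memory_length(self):
        rng = np.random.default_rng(0)
        hist = rng.normal(0, 1.5, size=(4, 2))
        sigma = 0.8
        val, _ = integrate.dblquad(
            lambda y, x: history_density_at([x, y], hist, sigma),
            -12, 12, -12, 12, epsabs=1e-8,
        )
        assert val == pytest.approx(len(hist), abs=1e-5)

    def test_distant_point_contributes_negligibly(self):
        sigma = 0.3
        near = history_density_at([0.0, 0.0], [[0.0, 0.0]], sigma)
        far = history_density_at([10 * sigma, 0.0], [[0.0, 0.0]], sigma)
        assert far < 1e-20 * near


class TestAngularDensityClosedForm:
    def test_coincident_point_gives_uniform_density(self):
        angles = grid_angles(64)
        n = angular_density_closed([0.0], [0.0], sigma=1.0, angles=angles)
        assert np.allclose(n, 1.0 / (2 * np.pi))

    def test_single_point_matches_quadrature_everywhere(self):
        angles = grid_angles(32)
        n = angular_density_closed([2.0], [np.pi], sigma=1.0, angles=angles)
        oracle = [quadrature_angular_density([2.0], [np.pi], 1.0, a) for a in angles]
        assert np.max(np.abs(n - oracle)) <= 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_configurations_match_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 5)
        r_m = rng.uniform(0.0, 5.0, m)
        theta_m = rng.uniform(0.0, 2 * np.pi, m)
        sigma = rng.uniform(0.1, 3.0)
        angles = rng.uniform(0.0, 2 * np.pi, 4)
        n = angular_density_closed(r_m, theta_m, sigma, angles)
        oracle = [quadrature_angular_density(r_m, theta_m, sigma, a) for a in angles]
        assert np.max(np.abs(n - oracle)) <= 1e-6

    def test_angular_mass_equals_buffer_length(self):
        rng = np.random.default_rng(3)
        hist = rng.normal(0, 2.0, size=(7, 2))
        state = WalkState(position=np.array([0.3, -0.2]), history=hist)
        dens = angular_density(state, sigma=0.7, grid_size=2048)
        mass = np.sum(dens.n) * dens.bin_width
        assert mass == pytest.approx(len(hist), rel=1e-6)

    def test_extreme_concentration_is_finite(self):
        angles = grid_angles(512)
        n = angular_density_closed([100.0], [0.0], sigma=0.05, angles=angles)
        assert np.isfinite(n).all()
        assert (n >= 0).all()

    def test_kernel_fast_path_matches_exact_form(self):
        rng = np.random.default_rng(5)
        hist = rng.normal(0, 2.0, size=(8, 2))
        cx, cy, sigma = 0.3, -0.2, 0.7
        G = 1024
        angles = grid_angles(G)
        n = np.zeros(G)
        accumulate_angular_density(n, cx, cy, hist, sigma, np.cos(angles), np.sin(angles))
        rel = hist - [cx, cy]
        exact = angular_density_closed(
            np.hypot(rel[:, 0], rel[:, 1]), np.arctan2(rel[:, 1], rel[:, 0]),
            sigma, angles,
        )
        assert np.max(np.abs(n - exact)) <= 2e-6

    def test_rotational_equivariance(self):
        rng = np.random.default_rng(6)
        hist = rng.normal(0, 1.5, size=(5, 2))
        G = 256
        shift = 17  # rotate by an integer number of grid bins
        phi = shift * 2 * np.pi / G
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        d1 = angular_density(WalkState(position=np.zeros(2), history=hist),
                             sigma=0.9, grid_size=G)
        d2 = angular_density(WalkState(position=np.zeros(2), history=hist @ rot.T),
                             sigma=0.9, grid_size=G)
        p1 = turn_probability(d1, alpha=2.0).p
        p2 = turn_probability(d2, alpha=2.0).p
        assert np.max(np.abs(np.roll(p1, shift) - p2)) <= 1e-9


class TestTurnProbability:
    def _density(self, seed=1, G=512):
        rng = np.random.default_rng(seed)
        hist = rng.normal(0, 1.0, size=(6, 2))
        return angular_density(WalkState(position=np.zeros(2), history=hist),
                               sigma=0.8, grid_size=G)

    def test_zero_penalty_is_uniform(self):
        dens = turn_probability(self._density(), alpha=0.0)
        assert np.allclose(dens.p, 1.0 / (2 * np.pi))

    def test_normalization(self):
        dens = turn_probability(self._density(), alpha=3.0)
        assert np.sum(dens.p) * dens.bin_width == pytest.approx(1.0, abs=1e-9)

    def test_penalty_is_strictly_monotone_in_density(self):
        dens = turn_probability(self._density(), alpha=2.0)
        order = np.argsort(dens.n)
        p_sorted = dens.p[order]
        n_sorted = dens.n[order]
        strict = np.diff(n_sorted) > 1e-12
        assert (np.diff(p_sorted)[strict] < 0).all()

    def test_negative_alpha_rejected(self):
        with pytest.raises(ParameterError):
            turn_probability(self._density(), alpha=-1.0)


class TestStep:
    def test_memoryless_headings_are_uniform(self):
        rng = np.random.default_rng(7)
        state = WalkState(position=np.zeros(2), history=np.empty((0, 2)))
        params = ModelParams(tau=0)
        headings = []
        for _ in range(2000):
            new = step(state, params, rng)
            d = new.position - state.position
            headings.append(np.arctan2(d[1], d[0]))
        counts, _ = np.histogram(headings, bins=16, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_strong_penalty_avoids_history_direction(self):
        hist = np.array([[1.0, 0.0]])  # remembered point due +x
        state = WalkState(position=np.zeros(2), history=hist)
        dens = turn_probability(angular_density(state, sigma=1.0, grid_size=1024),
                                alpha=1000.0)
        arc = np.abs((dens.angles + np.pi) % (2 * np.pi) - np.pi) <= np.pi / 8
        mass = np.sum(dens.p[arc]) * dens.bin_width
        assert mass < 1e-3

    def test_buffer_grows_then_saturates(self):
        rng = np.random.default_rng(8)
        params = ModelParams(tau=3)
        state = WalkState(position=np.zeros(2), history=np.empty((0, 2)))
        for j in range(6):
            assert len(state.history) == min(j, params.tau)
            state = step(state, params, rng)


class TestSimulation:
    def test_same_seed_is_bit_for_bit_reproducible(self):
        p = ModelParams(tau=10, sigma=1.0, alpha=1.0)
        a = simulate_walk(p, 200, seed=42)
        b = simulate_walk(p, 200, seed=42)
        assert (a == b).all()
        c = simulate_walk(p, 200, seed=43)
        assert not (a == c).all()

    def test_unit_step_lengths(self):
        w = simulate_walk(ModelParams(tau=5), 100, seed=1)
        assert np.allclose(np.hypot(*np.diff(w, axis=0).T), 1.0)

    def test_memoryless_limit_is_diffusive(self):
        walks = simulate_ensemble(ModelParams(tau=0), 50, 300, seed=2)
        slope = fit_loglog_slope(msd_curve(walks, m_max=50))
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_zero_penalty_limit_is_diffusive(self):
        walks = simulate_ensemble(ModelParams(tau=10, sigma=1.0, alpha=0.0),
                                  50, 300, seed=3)
        slope = fit_loglog_slope(msd_curve(walks, m_max=50))
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_very_broad_memory_approaches_diffusion(self):
        """The directional bias decays as O(r/sigma): by sigma = 100 px a
        unit-step walk is diffusive again."""
        walks = simulate_ensemble(ModelParams(tau=10, sigma=100.0, alpha=1.0),
                                  50, 300, seed=9)
        slope = fit_loglog_slope(msd_curve(walks, m_max=50))
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_grid_sampler_matches_continuous_rejection_sampler(self):
        """Ensemble H1 from inverse-CDF grid sampling agrees with a
        rejection sampler drawing theta continuously from the exact
        closed-form density."""

        def sim_rejection(params, n_steps, rng):
            pos = np.zeros((n_steps + 1, 2))
            probe = grid_angles(256)
            for j in range(n_steps):
                nh = min(j, params.tau)
                if nh == 0:
                    theta = rng.uniform(0, 2 * np.pi)
                else:
                    rel = pos[j - nh : j] - pos[j]
                    r = np.hypot(rel[:, 0], rel[:, 1])
                    tm = np.arctan2(rel[:, 1], rel[:, 0])
                    nmin = angular_density_closed(r, tm, params.sigma, probe).min()
                    while True:
                        theta = rng.uniform(0, 2 * np.pi)
                        nv = angular_density_closed(r, tm, params.sigma,
                                                    np.array([theta]))[0]
                        if rng.random() < np.exp(-params.alpha * (nv - nmin)):
                            break
                pos[j + 1] = pos[j] + [np.cos(theta), np.sin(theta)]
            return pos

        params = ModelParams(tau=10, sigma=1.0, alpha=1.0)
        rng = np.random.default_rng(21)
        rej = [sim_rejection(params, 150, rng) for _ in range(15)]
        h_rej = scaling_curve(msd_curve(rej, m_max=15)).h1
        grid = simulate_ensemble(params, 60, 150, seed=22)
        h_grid = scaling_curve(msd_curve(grid, m_max=15)).h1
        assert h_grid == pytest.approx(h_rej, abs=0.25)

    def test_strong_penalty_is_ballistic_at_short_lags(self):
        curve = model_H_curve(ModelParams(tau=10, sigma=1.0, alpha=100.0),
                              n_walks=30, n_steps=300, seed=4, m_max=25)
        assert np.mean(curve.h[:3]) == pytest.approx(2.0, abs=0.2)

    def test_grid_refinement_converges(self):
        """Doubling the angle grid leaves ensemble H1 within MC noise."""
        p = ModelParams(tau=10, sigma=1.0, alpha=1.0)
        h_a = model_H_curve(p, n_walks=40, n_steps=300, seed=5, grid_size=512).h1
        h_b = model_H_curve(p, n_walks=40, n_steps=300, seed=5, grid_size=1024).h1
        assert h_a == pytest.approx(h_b, abs=0.08)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            ModelParams(tau=-1)
        with pytest.raises(ParameterError):
            ModelParams(tau=5, sigma=0.0)
        with pytest.raises(ParameterError):
            ModelParams(tau=5, alpha=-0.5)
        with pytest.raises(ParameterError):
            simulate_walk(ModelParams(tau=1), 0, seed=0)
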