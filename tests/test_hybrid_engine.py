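"""Hybrid engine: coupling sampler, renormalization, toy forces, Langevin
integration, and the PMF-enriched run contract."""

import math

import numpy as np
import pytest

from pmfrich import fixture_gen, pmf_builder as pb
from pmfrich import hybrid_engine as he
from pmfrich.experiments import make_escape_system
from pmfrich.units import KB

KT = KB * 300.0


class _FixedRng:
    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        return self.value if size is None else np.full(size, self.value)


class TestSampleAlpha:
    def test_off_mode_is_constant(self):
        c = he.HybridCoupling(alpha=1e-5, epsilon=20.0, mode="off")
        assert he.sample_alpha(c, np.random.default_rng(0)) == 1e-5

    def test_literal_mode_vanishes_at_xi_one(self):
        c = he.HybridCoupling(alpha=1e-5, epsilon=20.0, mode="literal")
        assert he.sample_alpha(c, _FixedRng(1.0)) == 0.0

    def test_literal_mode_mean_is_alpha_epsilon_half(self):
        c = he.HybridCoupling(alpha=2.0, epsilon=10.0, mode="literal")
        draws = he.sample_alpha(c, np.random.default_rng(1), size=200_000)
        assert draws.mean() == pytest.approx(2.0 * 10.0 / 2, rel=0.01)

    @pytest.mark.parametrize("epsilon", [1.0, 10.0, 20.0, 25.0])
    def test_mean_preserving_long_run_mean_is_alpha(self, epsilon):
        alpha = 1e-5
        c = he.HybridCoupling(alpha=alpha, epsilon=epsilon)
        draws = he.sample_alpha(c, np.random.default_rng(7), size=1_000_000)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - alpha) < 3 * se
        assert np.all(draws >= 0)

    def test_epsilon_zero_degenerates_to_alpha(self):
        c = he.HybridCoupling(alpha=3e-6, epsilon=0.0)
        assert he.sample_alpha(c, np.random.default_rng(0)) == 3e-6


class TestRenormalization:
    def test_alpha_zero_returns_reference_bitwise(self, rng):
        gA = rng.normal(size=(6, 3))
        gB = rng.normal(size=(6, 3))
        out = he.renormalize_gradient(gA, gB, gB, 0.0)
        assert out is gA or np.array_equal(out, gA)

    def test_zero_bias_guard(self, rng):
        gA = rng.normal(size=(5, 3))
        z = np.zeros_like(gA)
        np.testing.assert_allclose(he.renormalize_gradient(gA, z, z, 1e-3),
                                   gA / (1 + 1e-3), atol=1e-15)

    def test_matches_direct_formula_and_term_norms(self, rng):
        alpha = 1e-5
        gA = rng.normal(size=(8, 3))
        gr = rng.normal(size=(8, 3))
        ga = rng.normal(size=(8, 3))
        out = he.renormalize_gradient(gA, gr, ga, alpha)
        nA = np.linalg.norm(gA)
        want = (gA / (1 + alpha)
                + alpha * nA / np.linalg.norm(gr) * gr
                + alpha * nA / np.linalg.norm(ga) * ga)
        np.testing.assert_allclose(out, want, rtol=1e-12)
        _, (tr, ta) = he.renormalize_terms(gA, [gr, ga], alpha)
        assert np.linalg.norm(tr) == pytest.approx(alpha * nA, rel=1e-12)
        assert np.linalg.norm(ta) == pytest.approx(alpha * nA, rel=1e-12)

    def test_non_finite_rejected(self, rng):
        gA = rng.normal(size=(3, 3))
        bad = gA.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            he.renormalize_terms(gA, [bad], 1e-3)


class TestToyForces:
    def test_bond_at_rest_length_is_force_free(self):
        top = fixture_gen.make_toy_chain(2, bond_r0=0.153, repulsion_eps=0.0)
        pos = np.array([[0.0, 0, 0], [0.153, 0, 0]])
        energy, grad = he.toy_forces(top, pos)
        assert energy == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_gradient_matches_finite_difference(self, double_well_chain, rng):
        pos = double_well_chain.initial_positions() + 0.02 * rng.normal(size=(5, 3))
        _, grad = he.toy_forces(double_well_chain, pos)
        h = 1e-6
        for a in range(5):
            for x in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[a, x] += h
                pm[a, x] -= h
                fd = (he.toy_forces(double_well_chain, pp)[0]
                      - he.toy_forces(double_well_chain, pm)[0]) / (2 * h)
                assert grad[a, x] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_energy_invariant_under_rigid_motion(self, double_well_chain, rng):
        from scipy.spatial.transform import Rotation

        pos = double_well_chain.initial_positions() + 0.02 * rng.normal(size=(5, 3))
        e0, _ = he.toy_forces(double_well_chain, pos)
        moved = pos @ Rotation.random(random_state=3).as_matrix().T + [1.0, -2.0, 0.5]
        e1, _ = he.toy_forces(double_well_chain, moved)
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_numba_and_numpy_paths_agree(self, double_well_chain, rng):
        pos = double_well_chain.initial_positions() + 0.05 * rng.normal(size=(5, 3))
        e1, g1 = he.toy_forces(double_well_chain, pos)
        e2, g2 = he._toy_forces_numpy(double_well_chain, pos)
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(g1, g2, atol=1e-12)


class TestLangevin:
    def test_zero_force_zero_temperature_is_static(self):
        state = he.EngineState(positions=np.ones((2, 3)),
                               momenta=np.zeros((2, 3)), temperature=0.0)
        out = he.langevin_step(state, np.zeros((2, 3)), 0.002, 2.0,
                               np.ones(2), np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, state.positions)

    def test_harmonic_equipartition(self):
        # friction 8/ps keeps the position autocorrelation short, so the
        # variance estimate concentrates well inside the 5% band
        k, mass, T = 800.0, 12.0, 300.0
        rng_t = np.random.default_rng(99)
        state = he.EngineState(positions=np.zeros((1, 3)),
                               momenta=np.zeros((1, 3)), temperature=T)
        xs = np.empty((300_000, 3))
        for i in range(len(xs)):
            grad = k * state.positions
            state = he.langevin_step(state, grad, 0.002, 8.0,
                                     np.array([mass]), rng_t)
            xs[i] = state.positions[0]
        var = xs[30_000:].var(axis=0).mean()
        assert var == pytest.approx(KB * T / k, rel=0.05)

    def test_two_seeds_same_statistics_different_paths(self):
        k, mass = 800.0, 12.0

        def run(seed):
            rng_t = np.random.default_rng(seed)
            state = he.EngineState(positions=np.zeros((1, 3)),
                                   momenta=np.zeros((1, 3)), temperature=300.0)
            xs = []
            for _ in range(120_000):
                state = he.langevin_step(state, k * state.positions, 0.002,
                                         2.0, np.array([mass]), rng_t)
                xs.append(state.positions[0, 0])
            return np.array(xs[12_000:])

        a, b = run(1), run(2)
        assert not np.array_equal(a[:100], b[:100])
        assert np.var(a) == pytest.approx(np.var(b), rel=0.1)

    def test_non_finite_force_halts(self):
        state = he.EngineState(positions=np.zeros((1, 3)),
                               momenta=np.zeros((1, 3)))
        with pytest.raises(FloatingPointError):
            he.langevin_step(state, np.full((1, 3), np.nan), 0.002, 2.0,
                             np.ones(1), np.random.default_rng(0))


class TestRunPmfEnriched:
    def test_alpha_zero_bitwise_identical_to_unbiased(self):
        topology, library = make_escape_system()
        biased = he.run_pmf_enriched(topology, library,
                                     he.HybridCoupling(alpha=0.0, epsilon=20.0),
                                     400, 0.004, seed=5)
        unbiased = he.run_pmf_enriched(topology, pb.PmfLibrary(),
                                       he.HybridCoupling(alpha=0.0),
                                       400, 0.004, seed=5)
        np.testing.assert_array_equal(biased.final_state.positions,
                                      unbiased.final_state.positions)
        np.testing.assert_array_equal(biased.trajectory, unbiased.trajectory)

    def test_zero_steps_returns_initial_state(self):
        topology, library = make_escape_system()
        out = he.run_pmf_enriched(topology, library,
                                  he.HybridCoupling(alpha=1e-3), 0, 0.004,
                                  seed=1)
        np.testing.assert_array_equal(out.trajectory[0],
                                      topology.initial_positions())
        assert out.final_state.step == 0

    def test_bias_magnitude_bound_and_term_norms(self):
        """Every logged step obeys ‖∇H(C) − ∇H(A)/(1+α)‖ ≤ 2α(t)‖∇H(A)‖ and
        each rescaled term has norm exactly α(t)·‖∇H(A)‖."""
        topology, library = make_escape_system()
        out = he.run_pmf_enriched(topology, library,
                                  he.HybridCoupling(alpha=1e-2, epsilon=20.0),
                                  800, 0.004, seed=3)
        log = out.log
        active = log[log.alpha_t > 0]
        assert len(active) > 100
        bound = 2 * active.alpha_t * active.norm_grad_A
        assert np.all(active.norm_delta <= bound * (1 + 1e-9))
        for col in ("norm_term_rad", "norm_term_ang"):
            nz = active[active[col] > 0]
            np.testing.assert_allclose(nz[col],
                                       nz.alpha_t * nz.norm_grad_A, rtol=1e-12)

    def test_tiny_alpha_preserves_unbiased_observable(self):
        """α → 0 limit: a 1e-9 coupling leaves equilibrium averages intact
        (mean bond length within 2%, averaged over seeds)."""
        topology, library = make_escape_system()

        def mean_bond(lib, alpha, seed):
            out = he.run_pmf_enriched(topology, lib,
                                      he.HybridCoupling(alpha=alpha,
                                                        epsilon=1.0),
                                      30_000, 0.004, seed=seed)
            traj = out.trajectory
            d = np.linalg.norm(traj[:, 0] - traj[:, 1], axis=1)
            return np.mean(d[len(d) // 5:])

        biased = np.mean([mean_bond(library, 1e-9, s) for s in (11, 12, 13)])
        unbiased = np.mean([mean_bond(pb.PmfLibrary(), 0.0, s)
                            for s in (11, 12, 13)])
        assert biased == pytest.approx(unbiased, rel=0.02)

    def test_trajectory_and_log_shapes(self):
        topology, library = make_escape_system()
        out = he.run_pmf_enriched(topology, library,
                                  he.HybridCoupling(alpha=1e-3, epsilon=20.0),
                                  100, 0.004, seed=2, log_interval=10)
        assert out.log.shape[0] == 10
        assert {"energy_A", "alpha_t", "norm_grad_A"} <= set(out.log.columns)
        assert out.trajectory.shape[1:] == (5, 3)
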