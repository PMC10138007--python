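"""Bioheat solver: stencil correctness, boundaries, stability, convergence."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanotherm as nt
from nanotherm.solver import StabilityError, SolverError


def _healthy(**overrides):
    base = dict(k=0.51, omega_b=5e-4, rho=1000.0, rho_b=1000.0,
                Q_m=420.0, c=4200.0, c_b=4200.0)
    base.update(overrides)
    return nt.TissueParameters(**base)


class TestFaceConductivity:
    def test_table_values(self):
        assert nt.face_conductivity(0.51, 0.51) == pytest.approx(0.51)
        assert nt.face_conductivity(0.51, 0.64) == pytest.approx(
            2 * 0.51 * 0.64 / (0.51 + 0.64)
        )
        assert nt.face_conductivity(0.51, 0.64) == pytest.approx(0.56765, abs=1e-5)

    @given(
        k1=st.floats(1e-3, 1e3, allow_nan=False),
        k2=st.floats(1e-3, 1e3, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, k1, k2):
        kh = nt.face_conductivity(k1, k2)
        assert kh == nt.face_conductivity(k2, k1)
        assert min(k1, k2) - 1e-12 <= kh <= max(k1, k2) + 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nt.face_conductivity(0.0, 0.5)


class TestStabilityLimit:
    def test_benchmark_value(self):
        """With the standard tissue pair at N=128 the bound is ~0.667 s, so
        the 0.1 s session step is comfortably stable."""
        sc = nt.build_scenario(nt.builtin_scenario(1, N=128))
        limit = nt.stability_limit(sc)
        h2 = (0.1 / 128) ** 2
        expected = h2 * 4.2e6 / (6 * 0.64 + h2 * 1.25e-3 * 4.2e6)
        assert limit == pytest.approx(expected)
        assert limit == pytest.approx(0.667, abs=0.01)
        assert 0.1 < limit

    def test_scaling_with_conductivity(self):
        cfg = nt.builtin_scenario(1, N=32)
        base = nt.stability_limit(nt.build_scenario(cfg))
        cfg2 = dataclasses.replace(
            cfg,
            healthy=_healthy(k=2 * 0.51),
            tumor=dataclasses.replace(cfg.tumor, k=2 * 0.64),
        )
        doubled = nt.stability_limit(nt.build_scenario(cfg2))
        assert doubled == pytest.approx(base / 2, rel=0.01)

    def test_scaling_with_grid(self):
        lim32 = nt.stability_limit(nt.build_scenario(nt.builtin_scenario(1, N=32)))
        lim64 = nt.stability_limit(nt.build_scenario(nt.builtin_scenario(1, N=64)))
        assert lim64 == pytest.approx(lim32 / 4, rel=0.01)

    def test_simulate_refuses_unstable_step(self, scenario1_coarse):
        with pytest.raises(StabilityError):
            nt.simulate(scenario1_coarse, None, ht=20.0, t_end=100.0)

    def test_forced_unstable_step_aborts_with_diagnostic(self, scenario1_coarse):
        pts = nt.naive_injection_points(scenario1_coarse.config)
        with pytest.raises(SolverError):
            nt.simulate(scenario1_coarse, pts, ht=20.0, t_end=3000.0, force=True)


from conftest import reference_ftcs_step as _reference_ftcs


class TestStepAgainstOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_heterogeneous_5cubed(self, seed):
        """One step on a 5^3 grid matches the literal stencil to round-off,
        for random heterogeneous property fields."""
        rng = np.random.default_rng(seed)
        cfg = nt.ScenarioConfig(
            domain=nt.Domain(0.02, 4),
            tumors=(nt.TumorSphere(center=(0.01, 0.01, 0.01), radius=0.004),),
        )
        sc = nt.build_scenario(cfg)
        shape = cfg.domain.shape
        # arbitrary heterogeneous medium (not just two materials)
        sc.k = rng.uniform(0.2, 1.0, shape)
        sc.omega_b = rng.uniform(1e-4, 2e-3, shape)
        sc.Q_m = rng.uniform(100.0, 5000.0, shape)
        sc.rho_c = rng.uniform(2e6, 5e6, shape)
        qr = rng.uniform(0.0, 1e5, shape)
        T0 = nt.TemperatureField(rng.uniform(36.0, 45.0, shape))

        ht = 1e-4  # small enough for any of the random media
        got = nt.step(T0, sc, qr, ht=ht, engine="general").values
        want = _reference_ftcs(
            T0.values, sc.k, sc.rho_c, sc.perfusion_field,
            sc.Q_m + qr, ht, cfg.domain.spacing, cfg.treatment.T_a,
        )
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_fast_engine_matches_general(self):
        """The production two-material stepper agrees with the reference
        per-node-field stepper over a full run with an off-centre tumor."""
        cfg = nt.ScenarioConfig(
            domain=nt.Domain(0.1, 16),
            tumors=(nt.TumorSphere(center=(0.03, 0.04, 0.05), radius=0.012),),
        )
        sc = nt.build_scenario(cfg)
        pts = [(0.032, 0.041, 0.048)]
        fast = nt.simulate(sc, pts, ht=1.0, t_end=200.0, engine="fast")
        gen = nt.simulate(sc, pts, ht=1.0, t_end=200.0, engine="general")
        np.testing.assert_allclose(fast.values, gen.values, atol=1e-10)

    def test_tumor_touching_boundary_engines_agree(self):
        cfg = nt.ScenarioConfig(
            domain=nt.Domain(0.1, 12),
            tumors=(nt.TumorSphere(center=(0.012, 0.05, 0.05), radius=0.012),),
        )
        sc = nt.build_scenario(cfg)
        fast = nt.simulate(sc, [(0.012, 0.05, 0.05)], ht=2.0, t_end=100.0, engine="fast")
        gen = nt.simulate(sc, [(0.012, 0.05, 0.05)], ht=2.0, t_end=100.0, engine="general")
        np.testing.assert_allclose(fast.values, gen.values, atol=1e-10)


class TestStepBasics:
    def test_uniform_healthy_hand_value(self, homogeneous_healthy_small):
        """From uniform 37 °C with no SAR, one 0.1 s step raises every node
        by ht*Q_m/ρc = 1e-5 °C."""
        sc = homogeneous_healthy_small
        T0 = nt.TemperatureField.uniform(sc)
        T1 = nt.step(T0, sc, ht=0.1)
        np.testing.assert_allclose(T1.values, 37.00001, rtol=0, atol=1e-12)

    def test_steady_state_fixed_point(self, homogeneous_healthy_small):
        """The uniform steady state 37 + Q_m/(ω_b ρ_b c_b) = 37.2 °C is a
        fixed point of the update."""
        sc = homogeneous_healthy_small
        T0 = nt.TemperatureField(np.full(sc.domain.shape, 37.2))
        T1 = nt.step(T0, sc, ht=0.1)
        np.testing.assert_allclose(T1.values, 37.2, rtol=0, atol=1e-12)

    def test_zero_step_identity(self, homogeneous_healthy_small):
        sc = homogeneous_healthy_small
        T0 = nt.TemperatureField(np.full(sc.domain.shape, 40.0))
        T1 = nt.step(T0, sc, ht=0.0)
        assert T1.values is not T0.values
        np.testing.assert_array_equal(T1.values, T0.values)


class TestSimulate:
    def test_space_uniform_exponential_solution(self, homogeneous_healthy_small):
        """Uniform healthy tissue with no SAR follows
        T(t) = 37.2 − 0.2·e^(−t/2000) (time constant ρc/(ω_b ρ_b c_b))."""
        final = nt.simulate(homogeneous_healthy_small, None, ht=0.1, t_end=3000.0)
        exact = 37.2 - 0.2 * np.exp(-3000.0 / 2000.0)
        assert np.ptp(final.values) < 1e-12
        assert final.values[0, 0, 0] == pytest.approx(exact, abs=1e-3)

    def test_steady_states_reached_at_five_time_constants(self):
        # healthy: tau = 2000 s -> 37.2 C; tumor-valued medium: tau = 800 s -> 37.8 C
        for params, steady, tau in (
            (nt.HEALTHY_TISSUE, 37.2, 2000.0),
            (nt.TUMOR_TISSUE, 37.8, 800.0),
        ):
            cfg = nt.ScenarioConfig(
                domain=nt.Domain(0.1, 8), tumors=(), healthy=params, tumor=params
            )
            sc = nt.build_scenario(cfg)
            final = nt.simulate(sc, None, ht=0.5, t_end=5 * tau)
            assert final.values[4, 4, 4] == pytest.approx(steady, abs=1e-2)

    def test_cube_symmetry_of_central_injection(self):
        """Scenario 1 with the central injection is invariant under all 48
        symmetries of the cube."""
        sc = nt.build_scenario(nt.builtin_scenario(1, N=32))
        final = nt.simulate(sc, [(0.05, 0.05, 0.05)], ht=2.0).values
        for perm in ((0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0), (2, 0, 1), (0, 2, 1)):
            v = np.transpose(final, perm)
            assert np.abs(v - final).max() < 1e-9
            for axis in range(3):
                assert np.abs(np.flip(v, axis) - final).max() < 1e-9

    def test_monotone_heating(self, scenario1_coarse):
        """Starting below every local equilibrium, nodal temperatures only
        increase; the run-time monitor accepts the whole session."""
        pts = nt.naive_injection_points(scenario1_coarse.config)
        final, snaps = nt.simulate(
            scenario1_coarse, pts, ht=2.0, t_end=600.0,
            snapshot_stride=100, check_monotone=True,
        )
        for a, b in zip(snaps, snaps[1:]):
            assert np.all(b.values >= a.values - 1e-12)
        assert final.values.min() >= 37.0 - 1e-12

    def test_step_count_and_time(self, homogeneous_healthy_small):
        final = nt.simulate(homogeneous_healthy_small, None, ht=0.4, t_end=100.0)
        assert final.time == pytest.approx(0.4 * round(100.0 / 0.4))

    def test_determinism(self, scenario1_coarse):
        pts = nt.naive_injection_points(scenario1_coarse.config)
        a = nt.simulate(scenario1_coarse, pts, ht=2.0, t_end=100.0)
        b = nt.simulate(scenario1_coarse, pts, ht=2.0, t_end=100.0)
        np.testing.assert_array_equal(a.values, b.values)


class TestConvergenceOrder:
    """The damped cosine eigenmode has a closed-form solution; refining the
    grid (or the step) must shrink the error at the scheme's order."""

    @staticmethod
    def _run_mode(N, ht, t_final):
        cfg = nt.ScenarioConfig(domain=nt.Domain(0.1, N), tumors=())
        sc = nt.build_scenario(cfg)
        c = cfg.domain.node_coordinates()
        mode = (
            np.cos(np.pi * c / 0.1)[:, None, None]
            * np.cos(np.pi * c / 0.1)[None, :, None]
            * np.cos(np.pi * c / 0.1)[None, None, :]
        )
        T = nt.TemperatureField(37.0 + mode)
        n_steps = int(round(t_final / ht))
        for _ in range(n_steps):
            T = nt.step(T, sc, ht=ht, engine="fast")
        return T.values, mode

    @staticmethod
    def _exact(mode, t):
        lam = (3 * 0.51 * (np.pi / 0.1) ** 2 + 2100.0) / 4.2e6
        uniform = 37.2 - 0.2 * np.exp(-t / 2000.0)
        return uniform + np.exp(-lam * t) * mode

    def test_second_order_in_space(self):
        t_final, ht = 200.0, 0.05
        errs = []
        for N in (8, 16):
            vals, mode = self._run_mode(N, ht, t_final)
            errs.append(np.abs(vals - self._exact(mode, t_final)).max())
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0  # ~4x per halving of h

    def test_first_order_in_time(self):
        # Richardson against a near-exact small-step run on the same grid:
        # the spatial error cancels, leaving the O(ht) component.
        t_final, N = 200.0, 8
        ref, _ = self._run_mode(N, 0.01, t_final)
        errs = [
            np.abs(self._run_mode(N, ht, t_final)[0] - ref).max() for ht in (2.0, 1.0)
        ]
        ratio = errs[0] / errs[1]
        assert 1.7 < ratio < 2.3  # ~2x per halving of ht
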