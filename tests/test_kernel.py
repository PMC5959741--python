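import math

import numpy as np
import pytest

from mcrelease import (
    ConfigError,
    CurveError,
    MCSModel,
    ParticleCloud,
    ReleaseCurve,
    ShellExhaustedError,
    SimulationConfig,
    fraction_released,
    mcs_diffusion,
    mcs_erosion,
    mcs_hybrid,
    remove_leak_shell,
    sample_cylinder_points,
    simulate_release,
)
from mcrelease.kernel import (
    ESCAPED,
    MOVED,
    REJECTED,
    WalkState,
    quantize_cloud,
    random_walk_step,
)


class TestMCSDiffusion:
    def test_reciprocal_identity(self):
        assert mcs_diffusion(1) == 1.0

    def test_arithmetic(self):
        assert mcs_diffusion(200) == pytest.approx(0.005)

    def test_zero_guarded(self):
        with pytest.raises(ValueError):
            mcs_diffusion(0)

    def test_strictly_decreasing(self):
        assert mcs_diffusion(10) > mcs_diffusion(11)


class TestMCSErosion:
    def test_u_one_gives_zero(self):
        assert mcs_erosion(0.3, 1.0) == 0.0

    def test_arithmetic(self):
        assert mcs_erosion(0.1, math.exp(-1)) == pytest.approx(10.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mcs_erosion(0.0, 0.5)
        with pytest.raises(ValueError):
            mcs_erosion(0.1, 0.0)
        with pytest.raises(ValueError):
            mcs_erosion(0.1, 1.5)

    def test_sample_mean_oracle(self, rng):
        # exponential with rate lambda has mean 1/lambda
        lam = 0.1
        u = rng.random(100_000)
        u = u[u > 0]
        draws = np.abs(np.log(u)) / lam
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 10.0) < 3 * se


class TestMCSHybrid:
    def test_reduces_to_diffusion(self):
        model = MCSModel(mode="hybrid", nu=1.0, lambda1=1.0,
                         A_form="constant", A=1.0, B_form="constant", B=0.0)
        for N in (1, 7, 200):
            assert mcs_hybrid(N, 3, model, 0.5) == pytest.approx(mcs_diffusion(N))

    def test_reduces_to_erosion(self):
        model = MCSModel(mode="hybrid", lambda2=0.1,
                         A_form="constant", A=0.0, B_form="constant", B=1.0)
        for u in (0.2, 0.9, math.exp(-1)):
            assert mcs_hybrid(50, 2, model, u) == pytest.approx(mcs_erosion(0.1, u))

    def test_step_indexed_hand_value(self):
        # k=2, N=100, nu=1, lambda1=1, lambda2=0.1, u=e^-1:
        # (1/2)*(1/100) + 2*10 = 20.005
        model = MCSModel(mode="hybrid", nu=1.0, lambda1=1.0, lambda2=0.1,
                         A_form="1/k", B_form="k")
        assert mcs_hybrid(100, 2, model, math.exp(-1)) == pytest.approx(20.005)

    def test_domain_errors(self):
        model = MCSModel(mode="hybrid", lambda1=1.0, lambda2=1.0)
        with pytest.raises(ValueError):
            mcs_hybrid(0, 1, model, 0.5)
        with pytest.raises(ValueError):
            mcs_hybrid(10, 0, model, 0.5)

    def test_model_validation(self):
        with pytest.raises(ConfigError):
            MCSModel(mode="hybrid")  # missing rates with live terms
        with pytest.raises(ConfigError):
            MCSModel(mode="erosion")
        with pytest.raises(ConfigError):
            MCSModel(mode="sublimation")
        with pytest.raises(ConfigError):
            MCSModel(mode="hybrid", lambda1=1, lambda2=1, A_form="k^2")


class TestRemoveLeakShell:
    def test_empty_shell(self):
        cloud = ParticleCloud([[0, 0, 0], [1, 0, 5], [0, 2, 3]])
        out, removed, r_new = remove_leak_shell(cloud, 10.0)
        assert removed == 0
        assert r_new == 9.0
        assert out == cloud

    def test_shell_member_removed(self):
        cloud = ParticleCloud([[9.5, 0, 1], [0, 0, 1]])
        out, removed, _ = remove_leak_shell(cloud, 10.0)
        assert removed == 1
        assert out.n == 1
        assert out.points[0, 0] == 0

    def test_brute_force_oracle(self, rng):
        pts = np.column_stack([rng.uniform(-10, 10, 300),
                               rng.uniform(-10, 10, 300),
                               rng.uniform(0, 5, 300)])
        R = 8.0
        expected = sum(
            1 for x, y, _ in pts if (R - 1) ** 2 <= x * x + y * y <= R * R
        )
        out, removed, _ = remove_leak_shell(ParticleCloud(pts), R)
        assert removed == expected
        assert removed + out.n == 300

    def test_exhausted_shell(self):
        with pytest.raises(ShellExhaustedError):
            remove_leak_shell(ParticleCloud([[0, 0, 0]]), 1.0)


class TestReleaseCurve:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(CurveError):
            ReleaseCurve(t=[0, 2, 1], N=[5, 4, 3], n0=5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(CurveError):
            ReleaseCurve(t=[0, 1], N=[5, 4, 3], n0=5)

    def test_fraction_released_elementwise(self, rng):
        N = np.sort(rng.uniform(0, 100, 20))[::-1]
        curve = ReleaseCurve(t=np.arange(20.0), N=N, n0=100.0)
        frac = fraction_released(curve)
        # loop oracle
        for i in range(20):
            assert frac.N[i] == pytest.approx(1.0 - N[i] / 100.0)
        assert frac.kind == "fraction"

    def test_fraction_endpoints(self):
        curve = ReleaseCurve(t=[0.0, 1.0], N=[50.0, 0.0], n0=50.0)
        frac = fraction_released(curve)
        assert frac.N[0] == 0.0
        assert frac.N[1] == 1.0

    def test_fraction_requires_positive_n0(self):
        curve = ReleaseCurve(t=[0.0, 1.0], N=[0.0, 0.0], n0=0.0)
        with pytest.raises(ValueError):
            fraction_released(curve)


class TestSimulateShell:
    def test_all_in_shell_full_release(self):
        # every molecule sits in the leak shell [R-1, R]: one step empties it
        radii = np.linspace(4.0, 5.0, 5)
        cloud = ParticleCloud(np.column_stack([radii, np.zeros(5), np.ones(5)]))
        out, removed, r_new = remove_leak_shell(cloud, 5.0)
        assert removed == 5
        assert out.n == 0
        assert r_new == 4.0

    def test_small_cylinder_stops_at_radius_floor(self):
        curve = simulate_release(SimulationConfig(n0=5, R0=2.5, H=4, seed=1))
        assert curve.N[0] == 5
        assert curve.meta["stop"] in ("exhausted", "R_floor")

    def test_time_is_sum_of_reciprocals(self, small_diffusion_config):
        curve = simulate_release(small_diffusion_config)
        # re-summation oracle over the logged N sequence
        expected = np.concatenate(
            [[0.0], np.cumsum(1.0 / np.maximum(curve.N[1:], 1.0))]
        )
        np.testing.assert_allclose(curve.t, expected, rtol=1e-12)

    def test_conservation_every_step(self, small_diffusion_config):
        curve = simulate_release(small_diffusion_config)
        released = small_diffusion_config.n0 - curve.N
        assert np.all(released >= 0)
        assert np.all(released + curve.N == small_diffusion_config.n0)

    def test_shell_terminates_within_R0_steps(self, small_diffusion_config):
        curve = simulate_release(small_diffusion_config)
        assert curve.meta["steps"] <= math.ceil(small_diffusion_config.R0)

    def test_seed_determinism(self, small_diffusion_config):
        a = simulate_release(small_diffusion_config)
        b = simulate_release(small_diffusion_config)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.N, b.N)

    def test_monotone_invariants(self, small_erosion_config):
        curve = simulate_release(small_erosion_config)
        assert np.all(np.diff(curve.t) > 0)
        assert np.all(np.diff(curve.N) <= 0)
        assert curve.N[0] == small_erosion_config.n0

    def test_per_molecule_accounting(self, small_diffusion_config):
        config = small_diffusion_config.replace(per_molecule=True)
        curve = simulate_release(config)
        curve.check_monotone()
        assert np.all(np.diff(curve.t) > 0)
        # per-molecule time increments are harmonic partial sums over N
        n_seq = curve.N.astype(int)
        t = 0.0
        for k in range(1, len(n_seq)):
            removed = n_seq[k - 1] - n_seq[k]
            if removed > 0:
                for j in range(removed):
                    t += 1.0 / max(n_seq[k - 1] - 1 - j, 1)
            else:
                t += 1.0 / max(n_seq[k], 1)
            assert curve.t[k] == pytest.approx(t)

    def test_hybrid_reduction_step_for_step(self, small_diffusion_config):
        hybrid = MCSModel(mode="hybrid", nu=1.0, lambda1=1.0,
                          A_form="constant", A=1.0, B_form="constant", B=0.0)
        a = simulate_release(small_diffusion_config)
        b = simulate_release(small_diffusion_config.replace(mcs=hybrid))
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.N, b.N)

    def test_hybrid_reduces_to_erosion_trajectory(self, small_erosion_config):
        hybrid = MCSModel(mode="hybrid", lambda2=0.1,
                          A_form="constant", A=0.0, B_form="constant", B=1.0)
        a = simulate_release(small_erosion_config)
        b = simulate_release(small_erosion_config.replace(mcs=hybrid))
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.N, b.N)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n0=0, R0=10, H=10)
        with pytest.raises(ConfigError):
            SimulationConfig(n0=10, R0=0.5, H=10)
        with pytest.raises(ConfigError):
            SimulationConfig(n0=10, R0=10, H=10, kernel="teleport")
        with pytest.raises(ConfigError):
            SimulationConfig(n0=10, R0=10, H=10, max_steps=0)


class _ScriptedRNG:
    """Deterministic stand-in for a Generator: pops scripted integer draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def integers(self, n):
        return self.draws.pop(0)

    def random(self):
        return 0.5


class TestRandomWalk:
    def test_all_neighbours_occupied_rejects(self):
        # molecule 0 at the origin-ish interior site, all 6 neighbours taken
        centre = (0, 0, 3)
        neighbours = [(1, 0, 3), (-1, 0, 3), (0, 1, 3), (0, -1, 3),
                      (0, 0, 4), (0, 0, 2)]
        sites = [centre] + neighbours
        positions = np.array(sites)
        occupied = {s: i for i, s in enumerate(sites)}
        state = WalkState(positions=positions, occupied=occupied, R=10.0, H=6.0)
        for direction in range(6):
            rng = _ScriptedRNG([0, direction])
            assert random_walk_step(state, rng) == REJECTED
        assert state.n == 7

    def test_step_onto_leak_site_escapes(self):
        # site (8, 0, 2) with R=10: moving +x reaches rho=9 >= R-1 -> leak
        positions = np.array([[8, 0, 2]])
        state = WalkState(positions=positions,
                          occupied={(8, 0, 2): 0}, R=10.0, H=4.0)
        rng = _ScriptedRNG([0, 0])  # molecule 0, +x direction
        assert random_walk_step(state, rng) == ESCAPED
        assert state.n == 0
        assert state.occupied == {}

    def test_move_into_free_site(self):
        positions = np.array([[0, 0, 2]])
        state = WalkState(positions=positions,
                          occupied={(0, 0, 2): 0}, R=10.0, H=4.0)
        rng = _ScriptedRNG([0, 2])  # +y
        assert random_walk_step(state, rng) == MOVED
        assert (0, 1, 2) in state.occupied

    def test_occupancy_audit_over_many_steps(self):
        cloud = sample_cylinder_points(30, R=6, H=10, seed=3)
        state = quantize_cloud(cloud, 6.0, 10.0)
        rng = np.random.default_rng(99)
        n0 = state.n
        escaped = 0
        for _ in range(10_000):
            if state.n == 0:
                break
            event = random_walk_step(state, rng)
            if event == ESCAPED:
                escaped += 1
            # full-state audit: occupancy map consistent with positions
            assert len(state.occupied) == state.n
            for site, idx in state.occupied.items():
                assert tuple(state.positions[idx]) == site
            assert escaped + state.n == n0

    def test_quantize_unique_interior_sites(self):
        cloud = sample_cylinder_points(50, R=8, H=10, seed=5)
        state = quantize_cloud(cloud, 8.0, 10.0)
        assert len(state.occupied) == 50
        rho2 = state.positions[:, 0] ** 2 + state.positions[:, 1] ** 2
        assert np.all(rho2 < 49.0)

    def test_walk_simulation_invariants(self, small_walk_config):
        curve = simulate_release(small_walk_config)
        assert np.all(np.diff(curve.t) > 0)
        assert np.all(np.diff(curve.N) <= 0)
        assert curve.meta["escaped"] + curve.N[-1] == small_walk_config.n0

    def test_walk_seed_determinism(self, small_walk_config):
        a = simulate_release(small_walk_config)
        b = simulate_release(small_walk_config)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.N, b.N)
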