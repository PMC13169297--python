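"""Langevin integrator, well-tempered hill deposition, FES reconstruction."""

import math

import numpy as np
import pytest

from puckerpath.constants import KB
from puckerpath.errors import IntegrationError, PuckerPathError
from puckerpath.potentials import (
    DoubleWell1D,
    GaussianComponent,
    GaussianLandscape,
    Harmonic,
    check_gradient,
)
from puckerpath.sampler import (
    BiasState,
    MetadParams,
    count_basin_transitions,
    deposit_hill,
    reconstruct_fes,
    run_langevin,
    run_metadynamics,
)


class TestPotentials:
    def test_analytic_gradients_match_finite_differences(self, rng, reaction_landscape,
                                                         pucker_landscape, pmf1d):
        pts2 = rng.uniform([-2, -0.5], [3, 4.5], size=(20, 2))
        assert check_gradient(reaction_landscape.potential, pts2) < 1e-5
        ppts = rng.uniform([0.1, 1.0], [6.2, 3.2], size=(20, 2))
        assert check_gradient(pucker_landscape.potential, ppts) < 1e-5
        pts1 = rng.uniform(-1.3, 1.7, size=(20, 1))
        assert check_gradient(pmf1d.potential, pts1) < 1e-5
        assert check_gradient(DoubleWell1D(barrier=4.0, a=1.0), pts1) < 1e-5


class TestLangevin:
    def test_equipartition_in_harmonic_well(self):
        k = 10.0
        traj = run_langevin(Harmonic(k=k, center=(0.0,)), temperature=300.0,
                            friction=1.0, dt=0.005, n_steps=400000, seed=42)
        var = np.var(traj[2000:, 0])
        assert var == pytest.approx(KB * 300.0 / k, rel=0.05)

    def test_zero_temperature_relaxes_monotonically(self):
        traj = run_langevin(Harmonic(k=5.0, center=(0.0,)), temperature=0.0,
                            friction=5.0, dt=0.002, n_steps=5000, seed=0, x0=(2.0,))
        d = np.abs(traj[::100, 0])
        assert d[-1] < 1e-3
        assert np.all(np.diff(d) < 1e-6)  # essentially monotone decay

    def test_same_seed_reproduces_bitwise(self):
        pot = DoubleWell1D(barrier=3.0)
        a = run_langevin(pot, n_steps=2000, seed=7, x0=(1.0,))
        b = run_langevin(pot, n_steps=2000, seed=7, x0=(1.0,))
        assert np.array_equal(a, b)

    def test_unstable_timestep_raises_naming_dt(self):
        with pytest.raises(IntegrationError, match="dt"):
            run_langevin(Harmonic(k=1e6, center=(0.0,)), dt=0.5, n_steps=5000,
                         seed=0, x0=(3.0,))

    def test_boltzmann_histogram_matches_potential(self):
        # unbiased sampling of a double well with a small barrier
        pot = DoubleWell1D(barrier=1.0, a=0.8)
        traj = run_langevin(pot, temperature=300.0, friction=1.0, dt=0.005,
                            n_steps=600000, seed=3, x0=(0.8,))
        x = traj[5000:, 0]
        hist, edges = np.histogram(x, bins=31, range=(-1.3, 1.3), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        f_emp = -KB * 300.0 * np.log(hist + 1e-12)
        f_ref = pot.energy(centers[:, None])
        mask = hist > 0.02
        diff = (f_emp - f_ref)[mask]
        assert np.std(diff - diff.mean()) < 0.15  # kcal/mol

    def test_input_validation(self):
        with pytest.raises(PuckerPathError):
            run_langevin(Harmonic(), dt=-0.1)
        with pytest.raises(PuckerPathError):
            run_langevin(Harmonic(), n_steps=0)


class TestHillsAndBias:
    def make_bias(self, **kw):
        args = dict(sigma=(0.1,), delta_T=15.0, stride=100, temperature=300.0)
        args.update(kw)
        return BiasState(**args)

    def test_first_hill_has_nominal_height(self):
        bias = self.make_bias()
        h = deposit_hill(bias, (0.0,), h0=0.5)
        assert h.height == pytest.approx(0.5)

    def test_height_halves_when_bias_equals_deltaT_ln2(self):
        bias = self.make_bias()
        target = 15.0 * math.log(2.0)
        # stack hills at the same point until the accumulated bias is ΔT·ln2
        bias.add_hill((0.0,), target, step=0)
        h = deposit_hill(bias, (0.0,), h0=1.0)
        assert h.height == pytest.approx(0.5, rel=1e-12)

    def test_heights_nonincreasing_at_revisited_point(self):
        bias = self.make_bias()
        heights = [deposit_hill(bias, (0.0,), h0=1.0).height for _ in range(30)]
        assert np.all(np.diff(heights) < 0)

    def test_height_decay_follows_exp_minus_v_over_deltaT(self):
        bias = self.make_bias(delta_T=5.0)
        for _ in range(50):
            deposit_hill(bias, (0.0,), h0=1.0)
        v = bias.bias_energy((0.0,))
        h_next = deposit_hill(bias, (0.0,), h0=1.0).height
        assert h_next == pytest.approx(math.exp(-v / 5.0), rel=1e-12)

    def test_bias_energy_at_center_and_far_away(self):
        bias = self.make_bias(sigma=(0.1, 0.2))
        bias.add_hill((1.0, 2.0), 0.7)
        assert bias.bias_energy((1.0, 2.0)) == pytest.approx(0.7)
        assert bias.bias_energy((1.0 + 15 * 0.1, 2.0)) < 1e-10

    def test_periodic_minimum_image(self):
        bias = BiasState(sigma=(math.radians(5.7),), delta_T=15.0,
                         periods=(2 * math.pi,))
        bias.add_hill((math.radians(359.0),), 1.0)
        near = bias.bias_energy((math.radians(1.0),))
        ref = bias.bias_energy((math.radians(357.0),))
        assert near == pytest.approx(ref, rel=1e-12)

    def test_bias_factor_and_bookkeeping(self):
        bias = BiasState(sigma=(0.1,), delta_T=15.0, stride=100,
                         temperature=300.0, dt=0.001)
        for i in range(854):
            bias.add_hill((0.0,), 0.5, step=i * 100)
        assert bias.total_time == pytest.approx(85.4)
        assert bias.bias_factor == pytest.approx(1 + 15.0 / (KB * 300.0))

    def test_invalid_hills_rejected(self):
        bias = self.make_bias()
        with pytest.raises(PuckerPathError):
            bias.add_hill((0.0,), -1.0)
        with pytest.raises(PuckerPathError):
            BiasState(sigma=(0.0,), delta_T=15.0)
        with pytest.raises(PuckerPathError):
            BiasState(sigma=(0.1,), delta_T=-2.0)


class TestMetadynamics:
    def test_deterministic_replay(self):
        pot = DoubleWell1D(barrier=4.0, a=1.0)
        params = MetadParams(sigma=(0.1,), height=0.3, delta_T=10.0, stride=20,
                             x0=(-1.0,))
        t1, b1 = run_metadynamics(pot, params, n_hills=50, seed=5)
        t2, b2 = run_metadynamics(pot, params, n_hills=50, seed=5)
        assert np.array_equal(t1, t2)
        assert np.array_equal(b1._centers[:50], b2._centers[:50])
        assert np.array_equal(b1._heights[:50], b2._heights[:50])

    def test_double_well_crossings_and_recovery(self):
        pot = DoubleWell1D(barrier=4.0, a=1.0)
        params = MetadParams(sigma=(0.1,), height=0.25, delta_T=10.0, stride=50,
                             x0=(-1.0,), dt=0.005)
        traj, bias = run_metadynamics(pot, params, n_hills=1200, seed=11)
        basins = {"L": ((-1.4,), (-0.6,)), "R": ((0.6,), (1.4,))}
        assert count_basin_transitions(traj, basins) >= 2
        fes = reconstruct_fes(bias, [(-1.3, 1.3, 201)], average_from=0.5)
        x = fes.axes[0]
        ref = pot.energy(x[:, None])
        mask = np.abs(x) <= 1.05  # the two basins and the barrier top
        err = np.abs((fes.values - fes.values[mask].min()) - (ref - ref[mask].min()))
        assert err[mask].max() < 1.0

    def test_flat_walled_potential_gives_flat_fes(self):
        pot = GaussianLandscape(components=[], const=0.0, ndim=1,
                                walls=[(0, -1.0, 1.0, 100.0)])
        params = MetadParams(sigma=(0.2,), height=0.1, delta_T=10.0, stride=20, x0=(0.0,))
        _, bias = run_metadynamics(pot, params, n_hills=1000, seed=2)
        fes = reconstruct_fes(bias, [(-0.8, 0.8, 81)], average_from=0.5)
        # no structure beyond diffusion ripple: bounded max and small spread
        assert fes.values.max() < 1.0
        assert fes.values.std() < 0.35

    def test_large_deltaT_is_standard_metadynamics_limit(self):
        bias = BiasState(sigma=(0.1,), delta_T=1e9, temperature=300.0)
        bias.add_hill((0.0,), 1.0)
        fes = reconstruct_fes(bias, [(-0.5, 0.5, 101)])
        # scale (kBT + ΔT)/ΔT → 1: depth of the inverted hill equals its height
        # (up to the far-field tail of the hill at the grid edge)
        assert fes.values.max() == pytest.approx(1.0, abs=1e-4)

    def test_single_hill_reconstruction_is_scaled_inverted_gaussian(self):
        bias = BiasState(sigma=(0.1,), delta_T=15.0, temperature=300.0)
        bias.add_hill((0.0,), 1.0)
        fes = reconstruct_fes(bias, [(-0.5, 0.5, 101)])
        scale = (KB * 300 + 15.0) / 15.0
        x = fes.axes[0]
        expected = scale * (1.0 - np.exp(-x**2 / (2 * 0.01)))
        assert np.allclose(fes.values, expected, atol=1e-9)
        assert fes.values.min() == 0.0

    def test_empty_bias_cannot_reconstruct(self):
        bias = BiasState(sigma=(0.1,), delta_T=15.0)
        with pytest.raises(PuckerPathError):
            reconstruct_fes(bias, [(-1, 1, 11)])


class TestBasinTransitions:
    BASINS = {"MC": ((-2.0,), (-0.5,)), "PC": ((0.5,), (2.0,))}

    def test_full_round_trip_counts_two(self):
        series = [-1.0, -0.2, 0.9, 0.3, -1.2]
        assert count_basin_transitions(series, self.BASINS) == 2

    def test_grazing_the_gap_counts_zero(self):
        series = [-1.0, -0.4, 0.2, 0.4, -1.0]
        assert count_basin_transitions(series, self.BASINS) == 0

    def test_constant_series_counts_zero(self):
        assert count_basin_transitions([-1.0] * 10, self.BASINS) == 0

    def test_overlapping_basins_rejected(self):
        with pytest.raises(PuckerPathError, match="overlap"):
            count_basin_transitions([0.0], {"A": ((-1.0,), (0.5,)), "B": ((0.0,), (1.0,))})
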