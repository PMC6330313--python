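"""Toy landscape, Langevin sampler, Markov-chain oracle, quadrature FES."""

import numpy as np
import pytest

import loopflex as lf
from loopflex.angles import wrap_angle
from loopflex.errors import (CapabilityError, DimensionError,
                             ValidationError)


def boltzmann_probabilities(spec, edges, pts=4000):
    """Quadrature bin probabilities for a 1D system (independent oracle)."""
    x = -np.pi + (np.arange(pts) + 0.5) * 2 * np.pi / pts
    U = np.array([lf.potential_energy(spec, [v]) for v in x])
    w = np.exp(-(U - U.min()) / spec.kT)
    hist, _ = np.histogram(x, bins=edges, weights=w)
    return hist / hist.sum()


class TestPotential:
    def test_minimum_at_well_center(self):
        spec = lf.ToySystemSpec(1, [lf.Well((0.0,), 4.0, 0.5)])
        grid = np.linspace(-np.pi, np.pi, 721)
        vals = [lf.potential_energy(spec, [g]) for g in grid]
        assert lf.potential_energy(spec, [0.0]) <= min(vals) + 1e-12

    def test_exact_periodicity(self):
        spec = lf.ToySystemSpec(2, [lf.Well((0.5, -1.0), 3.0, 0.6)])
        x = np.array([0.3, 1.1])
        for j in range(2):
            shifted = x.copy()
            shifted[j] += 2 * np.pi
            assert lf.potential_energy(spec, shifted) == pytest.approx(
                lf.potential_energy(spec, x), abs=1e-12)

    def test_equal_wells_symmetry(self, symmetric_double_well_1d):
        spec = symmetric_double_well_1d
        assert lf.potential_energy(spec, [np.pi / 2]) == pytest.approx(
            lf.potential_energy(spec, [-np.pi / 2]), abs=1e-12)

    def test_dimension_mismatch(self):
        spec = lf.ToySystemSpec(2, [lf.Well((0.0, 0.0), 3.0, 0.5)])
        with pytest.raises(DimensionError):
            lf.potential_energy(spec, [0.0])

    def test_gradient_matches_finite_difference(self):
        spec = lf.ToySystemSpec(2, [lf.Well((0.5, -1.0), 3.0, 0.6),
                                    lf.Well((-2.0, 1.5), 2.0, 0.4)])
        rng = np.random.default_rng(4)
        h = 1e-6
        for _ in range(20):
            x = rng.uniform(-np.pi, np.pi, 2)
            g = lf.potential_gradient(spec, x)
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fd = (lf.potential_energy(spec, x + e)
                      - lf.potential_energy(spec, x - e)) / (2 * h)
                assert g[j] == pytest.approx(fd, abs=1e-6)


class TestLangevin:
    def test_zero_temperature_flat_is_constant(self):
        spec = lf.ToySystemSpec(1, [lf.Well((0.0,), 1.0, 0.5)], kT=0.0)
        traj = lf.langevin_trajectory(spec, [0.7], 100, 10)
        assert np.all(traj.angles == traj.angles[0])
        assert traj.angles[0, 0] == pytest.approx(0.7, abs=1e-12)

    def test_seed_determinism_bitwise(self, double_well_1d):
        t1 = lf.langevin_trajectory(double_well_1d, [0.0], 5000, 10, seed=3)
        t2 = lf.langevin_trajectory(double_well_1d, [0.0], 5000, 10, seed=3)
        assert np.array_equal(t1.angles, t2.angles)

    def test_frame_count_and_interval(self, double_well_1d):
        traj = lf.langevin_trajectory(double_well_1d, [0.0], 1000, 25)
        assert traj.n_frames == 41
        assert traj.frame_interval == pytest.approx(
            double_well_1d.dt * 25)

    def test_wrapping_closure(self, double_well_1d):
        traj = lf.langevin_trajectory(double_well_1d, [3.0], 20000, 5,
                                      seed=9)
        assert np.all(traj.angles > -np.pi)
        assert np.all(traj.angles <= np.pi)

    def test_deep_well_narrower_than_two_wells(self):
        """Circular variance ordering matches the Boltzmann quadrature."""
        deep = lf.ToySystemSpec(1, [lf.Well((0.0,), 8.0, 0.5)], seed=2)
        two = lf.ToySystemSpec(1, [lf.Well((-np.pi / 2,), 2.0, 0.5),
                                   lf.Well((np.pi / 2,), 2.0, 0.5)], seed=2)

        def circ_var_sampled(spec):
            t = lf.langevin_trajectory(spec, [0.0], 100_000, 10)
            return 1 - np.abs(np.mean(np.exp(1j * t.angles[:, 0])))

        def circ_var_quadrature(spec):
            x = np.linspace(-np.pi, np.pi, 4001, endpoint=False)
            U = np.array([lf.potential_energy(spec, [v]) for v in x])
            p = np.exp(-(U - U.min()))
            p /= p.sum()
            return 1 - np.abs(np.sum(p * np.exp(1j * x)))

        assert circ_var_quadrature(deep) < circ_var_quadrature(two)
        assert circ_var_sampled(deep) < circ_var_sampled(two)

    def test_boltzmann_consistency(self, double_well_1d):
        """Long unbiased sampling reproduces quadrature probabilities."""
        traj = lf.langevin_trajectory(double_well_1d, [np.pi / 2],
                                      1_000_000, 10, seed=13)
        edges = np.linspace(-np.pi, np.pi, 37)
        hist, _ = np.histogram(traj.angles[:, 0], bins=edges)
        p_sim = hist / hist.sum()
        p_ref = boltzmann_probabilities(double_well_1d, edges)
        tv = 0.5 * np.abs(p_sim - p_ref).sum()
        assert tv <= 0.05


class TestMarkovChain:
    def test_identity_is_absorbing(self):
        traj = lf.sample_markov_chain(np.eye(3), 50, start=2, seed=0)
        assert np.all(traj.states == 2)

    def test_symmetric_chain_uniform_occupancy(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        traj = lf.sample_markov_chain(T, 1_000_000, start=0, seed=21)
        frac0 = np.mean(traj.states == 0)
        assert frac0 == pytest.approx(0.5, abs=0.005)

    def test_determinism(self):
        T = np.array([[0.5, 0.5], [0.2, 0.8]])
        a = lf.sample_markov_chain(T, 1000, 0, seed=5)
        b = lf.sample_markov_chain(T, 1000, 0, seed=5)
        assert np.array_equal(a.states, b.states)

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValidationError):
            lf.sample_markov_chain(np.array([[0.5, 0.4], [0.1, 0.9]]),
                                   10, 0, seed=0)


class TestReferenceFreeEnergy:
    def test_flat_potential_constant(self):
        # near-flat landscape: a vanishing well of enormous width
        spec = lf.ToySystemSpec(1, [lf.Well((0.0,), 1e-9, 10000.0)])
        fes = lf.reference_free_energy(spec, lf.RawTorsionCV(0),
                                       np.linspace(-np.pi, np.pi, 25),
                                       pts_per_dim=2400)
        assert np.nanmax(np.abs(fes.free_energy)) < 1e-6

    def test_symmetry(self, symmetric_double_well_1d):
        fes = lf.reference_free_energy(symmetric_double_well_1d,
                                       lf.RawTorsionCV(0),
                                       np.linspace(-np.pi, np.pi, 41),
                                       pts_per_dim=2000)
        assert np.allclose(fes.free_energy, fes.free_energy[::-1],
                           atol=1e-9)

    def test_basin_free_energy_difference(self, double_well_1d):
        """Basin probability ratio vs doubled-resolution quadrature."""
        edges = np.linspace(-np.pi, np.pi, 3)  # two basins split at 0
        fes = lf.reference_free_energy(double_well_1d, lf.RawTorsionCV(0),
                                       edges, pts_per_dim=2000)
        dF = fes.free_energy[0] - fes.free_energy[1]
        p = boltzmann_probabilities(double_well_1d, edges, pts=4000)
        dF_ref = -np.log(p[0] / p[1])
        assert dF == pytest.approx(dF_ref, abs=1e-3)

    def test_too_many_torsions(self):
        spec = lf.ToySystemSpec(4, [lf.Well((0.0,) * 4, 2.0, 0.5)])
        with pytest.raises(CapabilityError):
            lf.reference_free_energy(spec, lf.RawTorsionCV(0),
                                     np.linspace(-np.pi, np.pi, 11))


class TestTrajectoryIO:
    def test_round_trip_exact(self, tmp_path, double_well_1d):
        traj = lf.langevin_trajectory(double_well_1d, [0.1], 500, 5, seed=1)
        path = tmp_path / "traj.txt"
        lf.write_trajectory(traj, path)
        back = lf.read_trajectory(path)
        assert np.array_equal(back.angles, traj.angles)
        assert back.frame_interval == traj.frame_interval
        assert back.origin_label == traj.origin_label

    def test_wrap_convention(self):
        assert wrap_angle(np.pi) == np.pi
        assert wrap_angle(-np.pi) == np.pi
        assert wrap_angle(3 * np.pi) == pytest.approx(np.pi)
        t = lf.TorsionTrajectory(np.array([[4.0, -4.0]]), 1.0)
        assert np.all(t.angles > -np.pi) and np.all(t.angles <= np.pi)
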