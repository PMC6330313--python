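"""Well-tempered metadynamics: bias algebra, height schedule, FES, I/O."""

import numpy as np
import pytest

import loopflex as lf
from loopflex.errors import DimensionError, ValidationError
from loopflex.metadynamics import bias_gradient


def one_hill(height=2.0, sigma=0.5, center=0.0, periodic=False):
    return lf.HillsLog(times=[500], centers=[[center]], widths=[[sigma]],
                       heights=[height], biasfactor=10.0,
                       periodic=(periodic,))


class TestBiasValue:
    def test_empty_log_is_zero(self):
        hills = lf.HillsLog(times=np.empty(0), centers=np.empty((0, 1)),
                            widths=np.empty((0, 1)), heights=np.empty(0),
                            biasfactor=10.0, periodic=(False,))
        assert lf.bias_value(hills, [0.3]) == 0.0

    def test_peak_equals_height(self):
        assert lf.bias_value(one_hill(), [0.0]) == pytest.approx(2.0)

    def test_closed_form_off_center(self):
        v = lf.bias_value(one_hill(height=2.0, sigma=0.5), [0.5])
        assert v == pytest.approx(2.0 * np.exp(-0.5), abs=1e-12)
        assert v == pytest.approx(1.2131, abs=1e-4)

    def test_periodic_distance(self):
        hills = one_hill(center=np.pi - 0.1, periodic=True)
        # just across the branch cut: wrapped distance 0.2
        near = lf.bias_value(hills, [-np.pi + 0.1])
        assert near == pytest.approx(2.0 * np.exp(-0.2 ** 2 / 0.5), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            lf.bias_value(one_hill(), [0.0, 0.0])

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(17)
        hills = lf.HillsLog(times=[1, 2, 3],
                            centers=rng.normal(size=(3, 2)),
                            widths=np.full((3, 2), 0.4),
                            heights=[1.0, 0.8, 0.6], biasfactor=10.0,
                            periodic=(False, True))
        h = 1e-6
        for _ in range(10):
            s = rng.normal(size=2)
            g = bias_gradient(hills, s)
            for d in range(2):
                e = np.zeros(2)
                e[d] = h
                fd = (lf.bias_value(hills, s + e)
                      - lf.bias_value(hills, s - e)) / (2 * h)
                assert g[d] == pytest.approx(fd, abs=1e-6)


class TestWellTemperedRun:
    @pytest.fixture(autouse=True)
    def _system(self, double_well_1d):
        self.spec = double_well_1d
        self.cv = lf.RawTorsionCV(0)

    def test_first_hill_height_is_w0(self):
        params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=200)
        _, hills = lf.run_wt_metad(self.spec, self.cv, params, [np.pi / 2],
                                   2000, 10, seed=1)
        assert hills.heights[0] == 1.2

    def test_heights_bounded_and_tempered(self):
        params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=500)
        _, hills = lf.run_wt_metad(self.spec, self.cv, params, [np.pi / 2],
                                   100_000, 50, seed=2)
        assert np.all(hills.heights <= 1.2 + 1e-12)
        # heights near the dominant basin decay monotonically on revisits
        from loopflex.angles import angular_difference
        near = np.abs(angular_difference(hills.centers[:, 0],
                                         np.pi / 2)) < 0.15
        h_near = hills.heights[near]
        assert h_near.size >= 5
        assert np.all(np.diff(h_near) <= 1e-12)

    def test_large_biasfactor_recovers_constant_heights(self):
        params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=500,
                                biasfactor=1e9)
        _, hills = lf.run_wt_metad(self.spec, self.cv, params, [np.pi / 2],
                                   20_000, 50, seed=3)
        assert np.max(np.abs(hills.heights - 1.2)) / 1.2 < 1e-6

    def test_bias_enables_barrier_crossing(self):
        """Biased run visits both basins; equal-length unbiased run does
        not escape a deep (10 kT) starting well."""
        # narrow wells so the saddle is barrier-height-controlled (~10 kT)
        deep = lf.ToySystemSpec(1, [lf.Well((-np.pi / 2,), 4.0, 0.35),
                                    lf.Well((np.pi / 2,), 10.0, 0.35)],
                                seed=4)
        params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=500,
                                biasfactor=10.0)
        biased, _ = lf.run_wt_metad(deep, self.cv, params, [np.pi / 2],
                                    200_000, 20, seed=4)
        unbiased = lf.langevin_trajectory(deep, [np.pi / 2], 200_000,
                                          20, seed=4)

        def visits(traj):
            a = traj.angles[:, 0]
            return (np.any(np.abs(a - np.pi / 2) < 0.4),
                    np.any(np.abs(a + np.pi / 2) < 0.4))

        assert visits(biased) == (True, True)
        assert visits(unbiased) == (True, False)

    def test_determinism(self):
        params = lf.MetadParams(height=1.0, sigmas=(0.3,), stride=100)
        t1, h1 = lf.run_wt_metad(self.spec, self.cv, params, [0.0], 2000,
                                 10, seed=5)
        t2, h2 = lf.run_wt_metad(self.spec, self.cv, params, [0.0], 2000,
                                 10, seed=5)
        assert np.array_equal(t1.angles, t2.angles)
        assert np.array_equal(h1.heights, h2.heights)


class TestFESFromHills:
    def test_single_hill_inverted_gaussian(self):
        grid = np.linspace(-2, 2, 41)
        fes = lf.fes_from_hills(one_hill(), grid)
        centers = fes.bin_centers[0]
        assert centers[np.argmin(fes.free_energy)] == pytest.approx(
            0.0, abs=0.1)
        expected = (10 / 9) * (2.0 - 2.0 * np.exp(-centers ** 2 / 0.5))
        expected -= expected.min()  # same min-shift gauge
        assert np.allclose(fes.free_energy, expected, atol=1e-10)

    def test_biasfactor_scaling_exact(self):
        grid = np.linspace(-2, 2, 21)
        hills = one_hill()
        fes = lf.fes_from_hills(hills, grid)
        centers = fes.bin_centers[0]
        V = np.array([lf.bias_value(hills, [c]) for c in centers])
        direct = -(10.0 / 9.0) * V
        direct -= direct.min()
        assert np.allclose(fes.free_energy, direct, atol=1e-12)

    def test_empty_log_rejected(self):
        hills = lf.HillsLog(times=np.empty(0), centers=np.empty((0, 1)),
                            widths=np.empty((0, 1)), heights=np.empty(0),
                            biasfactor=10.0, periodic=(False,))
        with pytest.raises(ValidationError):
            lf.fes_from_hills(hills, np.linspace(-1, 1, 5))

    def test_gauge_invariance_under_constant_shift(self, double_well_1d):
        """Min-shifted FES is unchanged if the landscape gains a constant."""
        import dataclasses
        params = lf.MetadParams(height=1.2, sigmas=(0.3,), stride=500)
        shifted = dataclasses.replace(
            double_well_1d,
            wells=[lf.Well(w.center, w.depth + 2.0, w.width)
                   for w in double_well_1d.wells])
        grid = np.linspace(-np.pi, np.pi, 33)
        cv = lf.RawTorsionCV(0)
        _, h1 = lf.run_wt_metad(double_well_1d, cv, params, [np.pi / 2],
                                50_000, 50, seed=6)
        _, h2 = lf.run_wt_metad(shifted, cv, params, [np.pi / 2],
                                50_000, 50, seed=6)
        f1 = lf.fes_from_hills(h1, grid).free_energy
        f2 = lf.fes_from_hills(h2, grid).free_energy
        assert np.allclose(f1, f2, atol=1e-8)


class TestHillsIO:
    def test_round_trip_exact(self, tmp_path, double_well_1d):
        params = lf.MetadParams(height=1.1, sigmas=(0.25,), stride=200)
        _, hills = lf.run_wt_metad(double_well_1d, lf.RawTorsionCV(0),
                                   params, [0.0], 4000, 20, seed=8)
        path = tmp_path / "HILLS"
        lf.write_hills(hills, path)
        back = lf.read_hills(path)
        assert np.array_equal(back.times, hills.times)
        assert np.array_equal(back.centers, hills.centers)
        assert np.array_equal(back.widths, hills.widths)
        assert np.array_equal(back.heights, hills.heights)
        assert back.biasfactor == hills.biasfactor
        assert back.periodic == hills.periodic
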