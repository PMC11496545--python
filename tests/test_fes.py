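"""Umbrella sampling, WHAM and MBAR against analytic oracles."""

import numpy as np
import pytest

from protoflux import fes
from protoflux.constants import rt

KT = rt(310.15)


class TestModelPotential:
    def test_double_well_shape(self):
        pot = fes.ModelPotential("double_well", barrier_height=5.0, well_separation=2.0)
        assert pot.energy(0.0) == pytest.approx(5.0)
        assert pot.energy(1.0) == pytest.approx(0.0)
        assert pot.energy(-1.0) == pytest.approx(0.0)
        assert pot.analytic_forward_barrier() == pytest.approx(5.0, abs=1e-3)

    def test_tilt_lowers_forward_barrier(self):
        base = fes.ModelPotential("double_well", barrier_height=5.0)
        tilted = fes.ModelPotential("double_well", barrier_height=5.0, field_tilt=1.0)
        assert tilted.analytic_forward_barrier() < base.analytic_forward_barrier()

    def test_derivative_consistent(self):
        for kind in ("double_well", "harmonic", "flat"):
            pot = fes.ModelPotential(kind, barrier_height=4.0, field_tilt=0.3)
            x = np.linspace(-1.8, 1.8, 21)
            h = 1e-6
            num = (pot.energy(x + h) - pot.energy(x - h)) / (2 * h)
            assert np.allclose(pot.derivative(x), num, atol=1e-6)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            fes.ModelPotential("quartic_mess")


class TestSampler:
    def test_flat_potential_gives_bias_statistics(self):
        """Under a flat landscape samples follow the harmonic bias: Gaussian
        with variance RT/k, centred on the window."""
        w = fes.UmbrellaWindow(0.3, force_constant=100.0, n_samples=4000, seed=3)
        s = fes.sample_window(fes.ModelPotential("flat"), w)
        assert s.mean() == pytest.approx(0.3, abs=0.01)
        assert s.var() == pytest.approx(KT / 100.0, rel=0.1)

    def test_seeded_reproducibility(self):
        pot = fes.ModelPotential("double_well")
        w = fes.UmbrellaWindow(0.0, 100.0, 200, seed=9)
        assert np.array_equal(fes.sample_window(pot, w), fes.sample_window(pot, w))

    def test_stiff_bias_localises(self):
        pot = fes.ModelPotential("double_well")
        s = fes.sample_window(pot, fes.UmbrellaWindow(0.5, 5000.0, 500, seed=1))
        assert np.std(s) < 0.05
        assert abs(s.mean() - 0.5) < 0.05


class TestWham:
    def test_flat_potential_flat_pmf(self):
        windows = fes.default_windows(-1.6, 1.6, 24, n_samples=1500, seed=5)
        samples = [fes.sample_window(fes.ModelPotential("flat"), w) for w in windows]
        est = fes.WHAMEstimator(windows, samples).fit()
        inner = (est.grid > -1.6) & (est.grid < 1.6)
        v = est.values[inner]
        assert np.nanmax(v) - np.nanmin(v) < 0.4  # << any real barrier

    def test_double_well_barrier_recovery(self, double_well, wham_estimate):
        assert wham_estimate.barrier() == pytest.approx(
            double_well.analytic_forward_barrier(), abs=0.3
        )

    def test_field_tilt_shifts_barrier_by_expected_amount(self, double_well):
        tilted = fes.ModelPotential("double_well", barrier_height=5.0, field_tilt=1.0)
        windows = fes.default_windows(-1.6, 1.6, 24, n_samples=1500, seed=11)
        samples = [fes.sample_window(tilted, w) for w in windows]
        est = fes.WHAMEstimator(windows, samples).fit()
        assert est.barrier() == pytest.approx(tilted.analytic_forward_barrier(), abs=0.3)
        assert est.barrier() < 5.0 - 0.3  # tilt visibly lowers the barrier

    def test_bin_count_insensitivity(self, double_well_samples):
        windows, samples = double_well_samples
        b1 = fes.WHAMEstimator(windows, samples, n_bins=60).fit().barrier()
        b2 = fes.WHAMEstimator(windows, samples, n_bins=100).fit().barrier()
        assert b1 == pytest.approx(b2, abs=0.15)

    def test_convergence_with_sample_size(self, double_well):
        errs, uncs = [], []
        for n in (400, 1500, 5000):
            windows = fes.default_windows(-1.6, 1.6, 24, n_samples=n, seed=11)
            samples = [fes.sample_window(double_well, w) for w in windows]
            est = fes.WHAMEstimator(windows, samples).fit()
            errs.append(abs(est.barrier() - 5.0))
            uncs.append(float(np.nanmean(est.stat_uncertainty)))
        assert all(e < 0.3 for e in errs)
        assert uncs[0] > uncs[1] > uncs[2]

    def test_uncertainty_scales_as_sqrt_n(self, double_well):
        w1 = fes.default_windows(-1.6, 1.6, 24, n_samples=1000, seed=5)
        w2 = fes.default_windows(-1.6, 1.6, 24, n_samples=2000, seed=5)
        u1 = fes.WHAMEstimator(w1, [fes.sample_window(double_well, w) for w in w1]).fit()
        u2 = fes.WHAMEstimator(w2, [fes.sample_window(double_well, w) for w in w2]).fit()
        ratio = np.nanmean(u1.stat_uncertainty) / np.nanmean(u2.stat_uncertainty)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.15)

    def test_constant_shift_invariance(self, double_well, wham_estimate):
        """Adding a constant to the potential leaves the PMF untouched; the
        Metropolis chain sees identical energy differences, so the estimate
        is bitwise identical."""
        class Shifted(fes.ModelPotential):
            def energy(self, x):
                return super().energy(x) + 37.0

        shifted = Shifted("double_well", barrier_height=5.0, well_separation=2.0)
        windows = fes.default_windows(-1.6, 1.6, 24, n_samples=1500, seed=11)
        samples = [fes.sample_window(shifted, w) for w in windows]
        est = fes.WHAMEstimator(windows, samples).fit()
        assert np.allclose(est.values, wham_estimate.values, equal_nan=True)

    def test_nonoverlapping_windows_diagnosed(self):
        pot = fes.ModelPotential("double_well")
        windows = [fes.UmbrellaWindow(-1.5, 2000.0, 200, seed=0),
                   fes.UmbrellaWindow(1.5, 2000.0, 200, seed=1)]
        samples = [fes.sample_window(pot, w) for w in windows]
        with pytest.raises(ValueError, match="overlap"):
            fes.WHAMEstimator(windows, samples)


class TestMbar:
    def test_two_identical_states(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, 6000)
        u = np.array([0.5 * 100 * x**2 / KT] * 2)
        f = fes.solve_mbar(u, np.array([3000.0, 3000.0]))
        assert f[1] == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_free_energy_closed_form(self):
        """dF between two harmonic states is (RT/2) ln(k2/k1)."""
        rng = np.random.default_rng(0)
        k1, k2 = 50.0, 200.0
        x = np.concatenate([
            rng.normal(0, np.sqrt(KT / k1), 4000),
            rng.normal(0, np.sqrt(KT / k2), 4000),
        ])
        u = np.array([0.5 * k1 * x**2 / KT, 0.5 * k2 * x**2 / KT])
        f = fes.solve_mbar(u, np.array([4000.0, 4000.0]))
        assert f[1] * KT == pytest.approx(0.5 * KT * np.log(k2 / k1), abs=0.02)

    def test_double_well_barrier(self, double_well, mbar_estimate):
        assert mbar_estimate.barrier() == pytest.approx(
            double_well.analytic_forward_barrier(), abs=0.3
        )

    def test_agrees_with_wham_within_uncertainty(self, wham_estimate, mbar_estimate):
        mfin = np.isfinite(mbar_estimate.values)
        v_mbar = np.interp(wham_estimate.grid, mbar_estimate.grid[mfin],
                           mbar_estimate.values[mfin])
        dev = np.abs(wham_estimate.values - v_mbar)
        comb = np.sqrt(wham_estimate.stat_uncertainty**2
                       + np.interp(wham_estimate.grid, mbar_estimate.grid[mfin],
                                   mbar_estimate.stat_uncertainty[mfin])**2)
        ok = np.isfinite(dev) & np.isfinite(comb)
        assert np.all(dev[ok] <= 3 * comb[ok])

    def test_window_offsets_match_wham(self, wham_estimate, mbar_estimate):
        dw = wham_estimate.window_offsets - wham_estimate.window_offsets[0]
        dm = mbar_estimate.window_offsets - mbar_estimate.window_offsets[0]
        assert np.max(np.abs(dw - dm)) < 0.15

    def test_pairwise_differences_antisymmetric(self, double_well_samples):
        windows, samples = double_well_samples
        est = fes.MBAREstimator(windows, samples)
        est.fit()
        D = est.free_energy_differences()
        assert np.allclose(D, -D.T, atol=1e-12)


class TestPMFEstimate:
    def test_min_shifted_and_csv(self, wham_estimate, tmp_path):
        assert np.nanmin(wham_estimate.values) == 0.0
        p = tmp_path / "pmf.csv"
        wham_estimate.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["position_A", "pmf_kcal_mol", "uncertainty_kcal_mol"]
        assert len(df) == len(wham_estimate.grid)
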