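"""Diffuse optical spectroscopy: forward-model closed-form properties,
extinction-table invariants, and both inversion routes."""

import numpy as np
import pytest

from tumorvasc import dosrecon as d
from tumorvasc import synthkit


class TestExtinctionTable:
    def test_isosbestic_crossing_exists_in_band(self, extinction_table):
        crossings = extinction_table.isosbestic_wavelengths(520.0, 590.0)
        assert crossings.size >= 1

    def test_near_isosbestic_at_532(self, extinction_table):
        e1, e2 = extinction_table.interp(np.array([532.0]))
        scale = max(extinction_table.eps_hbo2.max(), extinction_table.eps_hhb.max())
        assert abs(e1[0] - e2[0]) / scale <= 0.10

    def test_no_extrapolation(self, extinction_table):
        with pytest.raises(ValueError):
            extinction_table.interp(np.array([450.0]))


class TestAbsorptionSpectrum:
    def test_pure_deoxy_proportional_to_hhb_extinction(self, extinction_table):
        p = d.TissueParams(sto2=0.0, thb=50.0, scatter_amp=1.0, scatter_power=1.0)
        wl = d.DEFAULT_WAVELENGTHS_NM
        mua = d.absorption_spectrum(p, extinction_table, wl)
        _, e_hhb = extinction_table.interp(wl)
        ratio = mua / e_hhb
        assert np.allclose(ratio, ratio[0])

    def test_linearity_in_concentration(self, extinction_table):
        wl = d.DEFAULT_WAVELENGTHS_NM
        p1 = d.TissueParams(sto2=0.6, thb=40.0, scatter_amp=1.0, scatter_power=1.0)
        p2 = d.TissueParams(sto2=0.6, thb=80.0, scatter_amp=1.0, scatter_power=1.0)
        assert np.allclose(
            2.0 * d.absorption_spectrum(p1, extinction_table, wl),
            d.absorption_spectrum(p2, extinction_table, wl),
        )

    def test_isosbestic_point_saturation_independent(self, extinction_table):
        """At the crossing wavelength mu_a depends on tHb only."""
        lam_iso = extinction_table.isosbestic_wavelengths(520.0, 590.0)[0]
        wl = np.array([lam_iso])
        muas = [
            d.absorption_spectrum(
                d.TissueParams(sto2=s, thb=60.0, scatter_amp=1.0, scatter_power=1.0),
                extinction_table,
                wl,
            )[0]
            for s in (0.0, 0.5, 1.0)
        ]
        assert max(muas) - min(muas) <= 0.005 * max(muas)


class TestScatteringAndReflectance:
    def test_power_law_values(self):
        wl = np.array([520.0, 560.0])
        musp = d.scattering_spectrum(1.0, 1.2, wl)
        assert musp[1] == pytest.approx(1.0)
        assert musp[0] == pytest.approx((520.0 / 560.0) ** -1.2, rel=1e-10)
        flat = d.scattering_spectrum(1.5, 0.0, wl)
        assert np.allclose(flat, 1.5)

    def test_reflectance_decreasing_in_distance(self):
        rhos = np.linspace(0.5, 5.0, 20)
        r = [d.diffuse_reflectance(0.05, 1.0, rho) for rho in rhos]
        assert np.all(np.diff(r) < 0)

    def test_log_slope_approaches_minus_mueff(self):
        """ln(rho^2 R) slope tends to -mueff at large rho (within 2% by 25 mm)."""
        mua, musp = 0.05, 1.0
        mueff = np.sqrt(3.0 * mua * (mua + musp))
        errs = []
        for rho in (20.0, 25.0, 40.0):
            r = np.array([rho - 0.1, rho + 0.1])
            vals = np.array([d.diffuse_reflectance(mua, musp, x) for x in r])
            slope = np.diff(np.log(r**2 * vals))[0] / 0.2
            errs.append(abs(slope + mueff) / mueff)
        assert errs[1] <= 0.02
        assert errs[2] < errs[1] < errs[0]

    def test_similarity_scaling(self):
        """R(rho/k; k mua, k musp) = k^2 R(rho; mua, musp)."""
        k = 2.0
        lhs = d.diffuse_reflectance(k * 0.05, k * 1.0, 1.75 / k)
        rhs = k**2 * d.diffuse_reflectance(0.05, 1.0, 1.75)
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestForwardSpectra:
    def test_gain_scales_all_entries(self, extinction_table):
        p1 = d.TissueParams(sto2=0.5, thb=60.0, scatter_amp=1.2, scatter_power=1.0)
        p2 = d.TissueParams(
            sto2=0.5, thb=60.0, scatter_amp=1.2, scatter_power=1.0, gain=2.0
        )
        s1 = d.forward_spectra(p1, extinction_table)
        s2 = d.forward_spectra(p2, extinction_table)
        assert np.allclose(s2.r, 2.0 * s1.r)

    def test_saturation_contrast_largest_away_from_isosbestic(self, extinction_table):
        wl = d.DEFAULT_WAVELENGTHS_NM
        p_oxy = d.TissueParams(sto2=1.0, thb=60.0, scatter_amp=1.2, scatter_power=1.0)
        p_deoxy = d.TissueParams(sto2=0.0, thb=60.0, scatter_amp=1.2, scatter_power=1.0)
        r_oxy = d.forward_spectra(p_oxy, extinction_table).r[0]
        r_deoxy = d.forward_spectra(p_deoxy, extinction_table).r[0]
        diff = np.abs(np.log(r_oxy) - np.log(r_deoxy))
        e1, e2 = extinction_table.interp(wl)
        eps_gap = np.abs(e1 - e2)
        assert abs(int(np.argmax(diff)) - int(np.argmax(eps_gap))) <= 2
        assert diff[np.argmin(eps_gap)] <= 0.25 * diff.max()

    def test_invariants_on_random_sweep(self, extinction_table):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = d.TissueParams(
                sto2=rng.uniform(0, 1),
                thb=rng.uniform(10, 120),
                scatter_amp=rng.uniform(0.5, 2.5),
                scatter_power=rng.uniform(0.5, 2.0),
                gain=rng.uniform(0.5, 2.0),
            )
            sp = d.forward_spectra(p, extinction_table)  # validates invariants
            assert np.all(sp.r > 0)


class TestTrainingSet:
    def test_labels_within_ranges_and_deterministic(self):
        X1, y1 = d.make_training_set(n=300, seed=4)
        X2, y2 = d.make_training_set(n=300, seed=4)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)
        for j, key in enumerate(("sto2", "thb", "a", "b")):
            lo, hi = d.DEFAULT_RANGES[key]
            assert y1[:, j].min() >= lo and y1[:, j].max() <= hi

    def test_features_invariant_to_gain(self, extinction_table):
        p = d.TissueParams(sto2=0.4, thb=70.0, scatter_amp=1.5, scatter_power=1.3)
        p2 = d.TissueParams(
            sto2=0.4, thb=70.0, scatter_amp=1.5, scatter_power=1.3, gain=1.7
        )
        f1 = d.spectra_features(d.forward_spectra(p, extinction_table).r)
        f2 = d.spectra_features(d.forward_spectra(p2, extinction_table).r)
        assert np.allclose(f1, f2)


class TestLsqOracle:
    def test_noiseless_round_trip(self, extinction_table):
        p = d.TissueParams(
            sto2=0.63, thb=55.0, scatter_amp=1.4, scatter_power=1.1, gain=1.3
        )
        sp = d.forward_spectra(p, extinction_table)
        rec = d.lsq_invert(sp, extinction_table, seed=1)
        assert rec.sto2 == pytest.approx(p.sto2, abs=1e-3)
        assert rec.thb == pytest.approx(p.thb, rel=1e-3)
        assert rec.gain == pytest.approx(p.gain, rel=1e-3)

    def test_noisy_median_error(self, extinction_table):
        """1% multiplicative noise: median |StO2 error| stays within 0.03."""
        rng = np.random.default_rng(8)
        errs = []
        p = d.TissueParams(sto2=0.55, thb=65.0, scatter_amp=1.3, scatter_power=1.2)
        for k in range(50):
            sp = synthkit.simulate_dos_spectrum(p, noise_sd=0.01, seed=1000 + k)
            rec = d.lsq_invert(sp, extinction_table, seed=k, n_starts=3)
            errs.append(abs(rec.sto2 - p.sto2))
        assert np.median(errs) <= 0.03

    def test_distance_monotonicity_enforced(self):
        wl = d.DEFAULT_WAVELENGTHS_NM
        bad = np.ones((2, wl.size))
        bad[1] *= 2.0  # increases with distance
        with pytest.raises(ValueError):
            d.ReflectanceSpectra(wl, d.DEFAULT_DISTANCES_MM, bad)


class TestNeuralInverse:
    def test_heldout_accuracy(self, trained_dos_model):
        Xt, yt = d.make_training_set(n=1500, noise_sd=0.0, seed=77)
        pred = trained_dos_model.predict_features(Xt)
        rmse_sto2 = np.sqrt(np.mean((pred[:, 0] - yt[:, 0]) ** 2))
        rel_thb = np.sqrt(np.mean(((pred[:, 1] - yt[:, 1]) / yt[:, 1]) ** 2))
        assert rmse_sto2 <= 0.03
        assert rel_thb <= 0.10

    def test_predictions_respect_bounds(self, trained_dos_model):
        Xt, _ = d.make_training_set(n=500, noise_sd=0.05, seed=21)
        pred = trained_dos_model.predict_features(Xt)
        assert pred[:, 0].min() >= 0.0 and pred[:, 0].max() <= 1.0

    def test_grid_mismatch_rejected(self, trained_dos_model, extinction_table):
        p = d.TissueParams(sto2=0.5, thb=60.0, scatter_amp=1.2, scatter_power=1.0)
        sp = d.forward_spectra(
            p, extinction_table, wavelengths=np.arange(530.0, 581.0, 2.0)
        )
        with pytest.raises(ValueError):
            d.invert_spectra(sp, trained_dos_model)

    def test_thb_identity(self, trained_dos_model, extinction_table):
        p = d.TissueParams(sto2=0.5, thb=60.0, scatter_amp=1.2, scatter_power=1.2)
        rec = d.invert_spectra(d.forward_spectra(p, extinction_table),
                               trained_dos_model)
        assert rec.c_hbo2 + rec.c_hhb == pytest.approx(rec.thb, rel=1e-12)

    def test_replicate_averaging_reduces_error(self, trained_dos_model):
        """Averaging 5 replicate probe placements beats a single spectrum."""
        p = d.TissueParams(sto2=0.6, thb=70.0, scatter_amp=1.4, scatter_power=1.1)
        single, averaged = [], []
        for trial in range(50):
            reps = [
                synthkit.simulate_dos_spectrum(p, noise_sd=0.05, seed=trial * 10 + k)
                for k in range(5)
            ]
            single.append(
                abs(d.invert_spectra(reps[0], trained_dos_model).sto2 - p.sto2)
            )
            averaged.append(
                abs(d.invert_spectra(reps, trained_dos_model).sto2 - p.sto2)
            )
        assert np.median(averaged) < np.median(single)

    def test_save_load_round_trip(self, trained_dos_model, tmp_path, extinction_table):
        path = tmp_path / "model.pkl"
        trained_dos_model.save(path)
        loaded = d.InverseModel.load(path)
        p = d.TissueParams(sto2=0.5, thb=60.0, scatter_amp=1.2, scatter_power=1.2)
        sp = d.forward_spectra(p, extinction_table)
        a = d.invert_spectra(sp, trained_dos_model)
        b = d.invert_spectra(sp, loaded)
        assert a.sto2 == b.sto2 and a.thb == b.thb
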