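"""Reconstruction chain: filters, f-k migration, motion correction,
autofocus, and the fluence safety arithmetic."""

import numpy as np
import pytest

from tumorvasc import oarecon, synthkit


class TestBandpass:
    def _tone_gain(self, f_hz, fs=2.0e8, n=4096):
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f_hz * t)
        y = oarecon.bandpass_filter(x, fs=fs)
        core = slice(n // 4, 3 * n // 4)
        return np.max(np.abs(y[core]))

    def test_dc_removed(self):
        with pytest.warns(UserWarning):
            y = oarecon.bandpass_filter(np.ones(2048))
        assert np.max(np.abs(y)) <= 1e-3

    def test_passband_tone_preserved_stopband_attenuated(self):
        with pytest.warns(UserWarning):
            g20 = self._tone_gain(20e6)
        with pytest.warns(UserWarning):
            g3 = self._tone_gain(3e6)
        assert g20 == pytest.approx(1.0, abs=0.12)  # within ~1 dB
        assert 20 * np.log10(g3 / g20) <= -20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            oarecon.bandpass_filter(np.zeros(64), f_lo=5e7, f_hi=1e7)


class TestFkMigration:
    def test_zero_in_zero_out(self):
        img = oarecon.reconstruct_plane_fk(np.zeros((32, 256)), 1500.0, 20.0, 2e8)
        assert np.allclose(img, 0.0)

    def test_nan_rejected(self):
        b = np.zeros((8, 64))
        b[0, 0] = np.nan
        with pytest.raises(ValueError):
            oarecon.reconstruct_plane_fk(b, 1500.0, 20.0, 2e8)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((16, 128))
        b = rng.standard_normal((16, 128))
        fa = oarecon.reconstruct_plane_fk(a, 1500.0, 20.0, 2e8)
        fb = oarecon.reconstruct_plane_fk(b, 1500.0, 20.0, 2e8)
        fab = oarecon.reconstruct_plane_fk(a + b, 1500.0, 20.0, 2e8)
        assert np.allclose(fab, fa + fb, atol=1e-6 * np.abs(fa).max())

    def test_point_source_focuses_at_true_position(self, point_scan):
        raw, (ix, iy, iz) = point_scan
        img = oarecon.reconstruct_plane_fk(
            raw.ascans[iy], raw.config.sound_speed_true, 20.0, 2e8
        )
        env = oarecon.hilbert_envelope(img, axis=-1)
        px, pz = np.unravel_index(np.argmax(env), env.shape)
        dz = raw.config.sound_speed_true / 2e8 * 1e6
        x_err = abs((px + 0.5) * 20.0 - (ix + 0.5) * 20.0)
        z_err = abs((pz + 0.5) * dz - (iz + 0.5) * 20.0)
        assert x_err <= 20.0 and z_err <= 20.0

    def test_random_positions_localize_within_one_voxel(self):
        """Twenty random in-plane sources each refocus within one voxel."""
        rng = np.random.default_rng(42)
        cfg = synthkit.ScanConfig(
            sound_speed_true=1505.0, field_of_view=(1.28, 0.12, 1.9)
        )
        dz = cfg.sound_speed_true / cfg.sampling_rate * 1e6
        for _ in range(20):
            ix = int(rng.integers(10, 54))
            iz = int(rng.integers(20, 80))
            amap = np.zeros((64, 6, 95))
            amap[ix, 3, iz] = 1.0
            ph = synthkit.VesselPhantom(
                amap, 20.0, [], 100.0 / amap.size, (1.28, 0.12, 1.9)
            )
            raw = synthkit.simulate_oa_scan(ph, cfg)
            img = oarecon.reconstruct_plane_fk(raw.ascans[3], 1505.0, 20.0, 2e8)
            env = oarecon.hilbert_envelope(img, axis=-1)
            px, pz = np.unravel_index(np.argmax(env), env.shape)
            assert abs((px + 0.5) * 20.0 - (ix + 0.5) * 20.0) <= 20.0
            assert abs((pz + 0.5) * dz - (iz + 0.5) * 20.0) <= 20.0

    def test_two_sources_resolved(self):
        """Two point sources 200 um apart laterally give two local maxima."""
        cfg = synthkit.ScanConfig(
            sound_speed_true=1500.0, field_of_view=(1.28, 0.12, 1.9)
        )
        amap = np.zeros((64, 6, 95))
        amap[27, 3, 50] = 1.0
        amap[37, 3, 50] = 1.0  # 10 voxels = 200 um apart
        ph = synthkit.VesselPhantom(amap, 20.0, [], 0.0, (1.28, 0.12, 1.9))
        raw = synthkit.simulate_oa_scan(ph, cfg)
        img = oarecon.reconstruct_plane_fk(raw.ascans[3], 1500.0, 20.0, 2e8)
        env = oarecon.hilbert_envelope(img, axis=-1)
        lateral = env.max(axis=1)
        peaks = [
            i
            for i in range(1, 63)
            if lateral[i] > lateral[i - 1]
            and lateral[i] >= lateral[i + 1]
            and lateral[i] > 0.3 * lateral.max()
        ]
        assert len(peaks) >= 2


class TestHilbertEnvelope:
    def test_pure_tone_envelope_is_unity(self):
        t = np.arange(2048) / 2e8
        x = np.cos(2 * np.pi * 10e6 * t)
        env = oarecon.hilbert_envelope(x)
        core = slice(200, -200)
        assert np.allclose(env[core], 1.0, atol=0.01)

    def test_gaussian_windowed_tone_recovers_window(self):
        t = np.arange(4096) / 2e8
        t0, sigma = t[2048], 2e-7
        window = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        x = window * np.cos(2 * np.pi * 20e6 * (t - t0))
        env = oarecon.hilbert_envelope(x)
        sel = window > 0.05
        assert np.max(np.abs(env[sel] - window[sel])) <= 0.02

    def test_envelope_dominates_signal(self):
        rng = np.random.default_rng(0)
        x = oarecon.bandpass_filter(rng.standard_normal(4096), 7e6, 9e7, 2e8)
        env = oarecon.hilbert_envelope(x)
        assert np.all(env >= np.abs(x) - 1e-9 * np.abs(x).max())


class TestMotionCorrection:
    def test_identical_planes_give_zero_shifts(self):
        rng = np.random.default_rng(3)
        plane = rng.standard_normal((32, 256))
        planes = np.stack([plane] * 10)
        _, shifts = oarecon.correct_motion(planes, dz_um=7.5)
        assert np.allclose(shifts, 0.0)

    def test_constant_offset_unidentifiable(self):
        """A shift common to all planes leaves relative shifts at zero."""
        rng = np.random.default_rng(4)
        plane = rng.standard_normal((16, 256))
        shifted = np.roll(plane, 5, axis=1)
        planes = np.stack([shifted] * 6)
        _, shifts = oarecon.correct_motion(planes, dz_um=7.5)
        assert np.allclose(shifts, 0.0)

    def test_featureless_plane_carries_previous_shift(self):
        rng = np.random.default_rng(5)
        plane = rng.standard_normal((16, 128))
        planes = np.stack([plane, np.zeros((16, 128)), plane])
        _, shifts = oarecon.correct_motion(planes, dz_um=7.5)
        assert shifts[1] == shifts[0]

    def test_injected_profile_recovered(self):
        """Synthetic smooth motion (<= 5 voxels) leaves <= 1 voxel RMS residual."""
        ph = synthkit.parallel_tube_phantom(
            3, seed=11, domain_size_mm=(1.28, 1.28, 1.28),
            depth_range_mm=(0.45, 1.1),
        )
        cfg = synthkit.ScanConfig(
            sound_speed_true=1505.0, field_of_view=(1.28, 1.28, 1.28),
            n_time_samples=384,
        )
        ny = ph.absorption_map.shape[1]
        motion = synthkit.simulate_motion_profile(ny, max_shift=100.0, seed=3)
        raw = synthkit.simulate_oa_scan(ph, cfg, motion)
        band = oarecon.bandpass_filter(raw.ascans, fs=cfg.sampling_rate)
        planes = np.stack(
            [oarecon.reconstruct_plane_fk(b, 1505.0, 20.0, 2e8) for b in band]
        )
        dz = 1505.0 / 2e8 * 1e6
        _, est = oarecon.correct_motion(planes, dz)
        true = motion.shifts - motion.shifts[0]
        resid = (est - true) - np.mean(est - true)
        assert np.sqrt(np.mean(resid**2)) <= 20.0


class TestAutofocus:
    def test_empty_scan_rejected(self):
        cfg = synthkit.ScanConfig(field_of_view=(0.64, 0.32, 1.9))
        raw = synthkit.RawScan(np.zeros((16, 32, 512)), cfg)
        with pytest.raises(ValueError):
            oarecon.autofocus_sound_speed(raw)

    def test_recovers_true_sound_speed(self):
        """Sharpness argmax lands within 3 m/s of the simulation speed."""
        ph = synthkit.parallel_tube_phantom(
            2, seed=21, domain_size_mm=(1.28, 0.32, 1.5),
            depth_range_mm=(0.45, 1.0), diameter_um=40.0,
        )
        for c_true in (1495.0, 1510.0):
            cfg = synthkit.ScanConfig(
                sound_speed_true=c_true, field_of_view=(1.28, 0.32, 1.5),
                n_time_samples=384,
            )
            raw = synthkit.simulate_oa_scan(ph, cfg)
            c_best, curve = oarecon.autofocus_sound_speed(raw)
            assert abs(c_best - c_true) <= 3.0
            assert curve.size == oarecon.SoundSpeedSearch().grid.size


class TestFullReconstruction:
    def test_zero_raw_gives_zero_volume(self):
        cfg = synthkit.ScanConfig(field_of_view=(0.64, 0.32, 1.9))
        raw = synthkit.RawScan(np.zeros((16, 32, 512)), cfg)
        vol = oarecon.reconstruct_volume(raw, c_fixed=1500.0, motion_correct=False)
        assert np.allclose(vol.envelope, 0.0)
        assert vol.sound_speed_used == 1500.0

    def test_tube_centerline_recovered(self):
        """Envelope maxima track the true centerline within one voxel."""
        ph = synthkit.parallel_tube_phantom(
            1, seed=31, domain_size_mm=(1.28, 0.64, 1.28), diameter_um=80.0,
            depth_range_mm=(0.55, 0.65),
        )
        cfg = synthkit.ScanConfig(
            sound_speed_true=1505.0, field_of_view=(1.28, 0.64, 1.28),
            n_time_samples=384,
        )
        raw = synthkit.simulate_oa_scan(ph, cfg)
        vol = oarecon.reconstruct_volume(raw, c_fixed=1505.0)
        (pts, _radius) = ph.centerlines[0]
        x_true, z_true = pts[0][0] * 1000, pts[0][2] * 1000
        dz = vol.voxel_size[2]
        hits = 0
        ny = vol.envelope.shape[1]
        for iy in range(4, ny - 4):
            plane = vol.envelope[:, iy, :]
            px, pz = np.unravel_index(np.argmax(plane), plane.shape)
            dxv = abs((px + 0.5) * 20.0 - x_true) / 20.0
            dzv = abs((pz + 0.5) * dz - z_true) / 20.0
            hits += (dxv <= 1.0) and (dzv <= 1.0)
        assert hits / (ny - 8) >= 0.95

    def test_motion_correction_restores_volume(self):
        """Corrected motion-corrupted scan correlates >= 0.9 with still scan."""
        ph = synthkit.parallel_tube_phantom(
            3, seed=41, domain_size_mm=(1.28, 1.28, 1.28),
            depth_range_mm=(0.45, 1.0),
        )
        cfg = synthkit.ScanConfig(
            sound_speed_true=1505.0, field_of_view=(1.28, 1.28, 1.28),
            n_time_samples=384,
        )
        ny = ph.absorption_map.shape[1]
        motion = synthkit.simulate_motion_profile(ny, max_shift=80.0, seed=13)
        still = oarecon.reconstruct_volume(
            synthkit.simulate_oa_scan(ph, cfg), c_fixed=1505.0,
            motion_correct=False,
        )
        moved = oarecon.reconstruct_volume(
            synthkit.simulate_oa_scan(ph, cfg, motion), c_fixed=1505.0,
            motion_correct=True,
        )
        a = still.envelope.ravel()
        b = moved.envelope.ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r >= 0.9


class TestFluenceSafety:
    def test_printed_system_parameters(self):
        """0.3 mJ over a 5.5 mm beam: ~1.26 mJ/cm^2, under the 20 mJ/cm^2 limit."""
        f = oarecon.compute_fluence(0.3, 5.5)
        assert f == pytest.approx(1.26, abs=0.01)
        assert f == pytest.approx(1.2, rel=0.06)
        assert oarecon.check_laser_safety(f)

    def test_hand_evaluated_case(self):
        assert oarecon.compute_fluence(0.2, 5.0) == pytest.approx(1.019, abs=0.002)

    def test_boundary_inclusive_and_exceedance(self):
        assert oarecon.check_laser_safety(20.0)
        assert not oarecon.check_laser_safety(25.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            oarecon.compute_fluence(0.0, 5.5)
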