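"""Band splitting, delay-and-sum beamforming, compositing, MIPs, unmixing."""

import numpy as np
import pytest

from rsompy.datatypes import ChromophoreSpectra, RawScan, ReconVolume, ScanConfig
from rsompy.reconstruction import (
    bandpass_split,
    beamform,
    composite_dual_band,
    project_mip,
    unmix_spectra,
)
from rsompy.simulate import simulate_scan

from conftest import make_point_phantom


def _tone_scan(freq_hz: float, cfg: ScanConfig) -> RawScan:
    t = np.arange(cfg.n_samples) / cfg.sample_rate_hz
    burst = np.sin(2 * np.pi * freq_hz * t) * np.hanning(cfg.n_samples)
    signals = np.broadcast_to(
        burst, (cfg.n_fast, cfg.n_slow, cfg.n_samples)
    ).astype(np.float32)
    return RawScan(config=cfg, signals=signals.copy())


def _band_energy(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    sel = (f >= band[0]) & (f < band[1])
    return float(spec[sel].sum())


class TestBandSplit:
    @pytest.mark.parametrize(
        "tone_mhz,main_band", [(30.0, 0), (80.0, 1)]
    )
    def test_tone_energy_lands_in_its_band(self, tone_mhz, main_band):
        cfg = ScanConfig(n_fast=2, n_slow=1, n_samples=1024)
        scan = _tone_scan(tone_mhz * 1e6, cfg)
        low, high = bandpass_split(scan)
        outs = [low, high]
        line_main = outs[main_band].signals[0, 0]
        line_other = outs[1 - main_band].signals[0, 0]
        e_main = float((line_main**2).sum())
        e_other = float((line_other**2).sum())
        assert e_main / (e_main + e_other) >= 0.95

    def test_dc_signal_suppressed(self):
        cfg = ScanConfig(n_fast=2, n_slow=1, n_samples=512)
        signals = np.ones((2, 1, 512), dtype=np.float32)
        scan = RawScan(config=cfg, signals=signals)
        low, high = bandpass_split(scan)
        assert np.abs(low.signals).max() < 1e-3
        assert np.abs(high.signals).max() < 1e-3

    def test_band_above_nyquist_rejected(self):
        cfg = ScanConfig(n_fast=2, n_slow=1, n_samples=512, sample_rate_hz=2e8)
        scan = _tone_scan(3e7, cfg)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_split(scan, bands=((10.0, 150.0),))

    def test_split_energy_preserved_within_rolloff(self):
        # broadband noise confined to 10-120 MHz
        cfg = ScanConfig(n_fast=1, n_slow=1, n_samples=4096)
        rng = np.random.default_rng(0)
        x = rng.normal(size=cfg.n_samples)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(cfg.n_samples, 1 / cfg.sample_rate_hz)
        spec[(f < 15e6) | (f > 110e6)] = 0  # comfortably inside the band
        x = np.fft.irfft(spec, n=cfg.n_samples)
        scan = RawScan(config=cfg,
                       signals=x[None, None, :].astype(np.float32))
        low, high = bandpass_split(scan)
        e_in = float((scan.signals[0, 0].astype(float) ** 2).sum())
        e_out = float((low.signals[0, 0].astype(float) ** 2).sum()
                      + (high.signals[0, 0].astype(float) ** 2).sum())
        assert e_out >= 0.9 * e_in


class TestBeamform:
    def test_all_zero_signals_give_zero_volume(self, small_config):
        scan = RawScan(
            config=small_config,
            signals=np.zeros(
                (small_config.n_fast, small_config.n_slow,
                 small_config.n_samples), dtype=np.float32),
        )
        vol = beamform(scan, voxel_size_um=(12, 12, 6), z_range_um=(0, 300))
        assert not vol.intensity.any()

    def test_point_source_localized_within_one_voxel(self, small_config):
        phantom = make_point_phantom((24, 24, 36))
        scan = simulate_scan(phantom, small_config, seed=0)
        vol = beamform(scan, voxel_size_um=(12, 12, 6), z_range_um=(0, 384))
        peak = np.unravel_index(np.argmax(vol.intensity), vol.shape)
        true_um = (np.array([24, 24, 36]) + 0.5) * np.array([12, 12, 6])
        peak_um = np.array(peak) * np.array([12, 12, 6])
        assert np.all(np.abs(peak_um - true_um) <= np.array([12, 12, 6]) + 1e-9)

    def test_two_absorbers_resolved_in_high_band(self, small_config):
        phantom = make_point_phantom((20, 24, 36))
        phantom.absorption[29, 24, 36] = 1.0  # 108 um apart laterally
        scan = simulate_scan(phantom, small_config, seed=0)
        _, high = bandpass_split(scan)
        vol = beamform(high, voxel_size_um=(12, 12, 6), z_range_um=(150, 300),
                       band_mhz=(40, 120))
        profile = vol.intensity[:, 24, :].max(axis=1)
        peaks = [i for i in range(1, len(profile) - 1)
                 if profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
                 and profile[i] > 0.3 * profile.max()]
        assert len(peaks) >= 2

    def test_linearity_before_envelope(self, small_config):
        ph1 = make_point_phantom((20, 24, 30))
        ph2 = make_point_phantom((28, 24, 40))
        s1 = simulate_scan(ph1, small_config, seed=0)
        s2 = simulate_scan(ph2, small_config, seed=0)
        combo = RawScan(
            config=small_config,
            signals=2.0 * s1.signals + 3.0 * s2.signals,
        )
        kw = dict(voxel_size_um=(24, 24, 12), z_range_um=(100, 320),
                  envelope=False)
        v1 = beamform(s1, **kw)
        v2 = beamform(s2, **kw)
        vc = beamform(combo, **kw)
        np.testing.assert_allclose(
            vc.intensity, 2.0 * v1.intensity + 3.0 * v2.intensity,
            rtol=1e-4, atol=1e-6 * np.abs(vc.intensity).max(),
        )


class TestCompositeAndMip:
    def _vol(self, arr):
        return ReconVolume(intensity=np.asarray(arr, dtype=np.float32),
                           voxel_size_um=(12, 12, 3))

    def test_empty_high_band_gives_empty_green(self):
        low = self._vol(np.random.default_rng(0).random((4, 4, 4)))
        high = self._vol(np.zeros((4, 4, 4)))
        comp = composite_dual_band(low, high)
        assert not comp.green.any()

    def test_equal_bands_give_equal_channels(self):
        v = np.random.default_rng(1).random((4, 4, 4))
        comp = composite_dual_band(self._vol(v), self._vol(v))
        np.testing.assert_allclose(comp.red, comp.green)

    def test_percentile_normalization_caps_at_one(self):
        v = np.random.default_rng(2).random((8, 8, 8))
        comp = composite_dual_band(self._vol(v), self._vol(2 * v))
        assert comp.red.max() == pytest.approx(1.0)
        assert comp.green.max() == pytest.approx(1.0)

    def test_mip_single_voxel(self):
        arr = np.zeros((5, 6, 7))
        arr[2, 3, 4] = 7.0
        mip = project_mip(self._vol(arr), axis="depth")
        assert mip[2, 3] == 7.0
        assert (mip > 0).sum() == 1

    def test_mip_slab_decomposition(self):
        rng = np.random.default_rng(3)
        arr = rng.random((5, 5, 10))
        vol = self._vol(arr)
        z_mid = vol.z_coords_um()[5]
        full = project_mip(vol, axis="depth")
        a = project_mip(vol, axis="depth", depth_range_um=(0, z_mid))
        b = project_mip(vol, axis="depth", depth_range_um=(z_mid, 1e9))
        np.testing.assert_allclose(np.maximum(a, b), full)

    def test_empty_depth_range_rejected(self):
        with pytest.raises(ValueError, match="depth range"):
            project_mip(self._vol(np.zeros((3, 3, 3))), depth_range_um=(500, 600))


class TestUnmix:
    def _spectra(self):
        # schematic absorption weights at 532/555/579/606 nm
        return ChromophoreSpectra(
            wavelengths_nm=np.array([532.0, 555.0, 579.0, 606.0]),
            matrix=np.array([
                [1.00, 0.55, 0.45],
                [0.85, 0.60, 0.55],
                [0.72, 0.65, 0.40],
                [0.60, 0.20, 0.45],
            ]),
        )

    def test_exact_mixture_recovered(self):
        spectra = self._spectra()
        rng = np.random.default_rng(0)
        fracs = rng.random((3, 50))
        measured = spectra.matrix @ fracs
        volumes = [m.reshape(5, 10, 1) for m in measured]
        comps, resid = unmix_spectra(volumes, spectra)
        out = np.stack([comps[c].ravel() for c in spectra.components])
        np.testing.assert_allclose(out, fracs, atol=1e-6)
        assert resid == pytest.approx(0.0, abs=1e-8)

    def test_pure_melanin_voxel(self):
        spectra = self._spectra()
        measured = spectra.matrix @ np.array([2.0, 0.0, 0.0])
        volumes = [np.full((1, 1, 1), m) for m in measured]
        comps, _ = unmix_spectra(volumes, spectra)
        assert comps["melanin"][0, 0, 0] == pytest.approx(2.0, abs=1e-8)
        assert comps["hbo2"][0, 0, 0] == pytest.approx(0.0, abs=1e-8)
        assert comps["hb"][0, 0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_noisy_mixture_small_error(self):
        spectra = self._spectra()
        rng = np.random.default_rng(42)
        fracs = rng.random((3, 400))
        measured = spectra.matrix @ fracs
        measured = measured + rng.normal(0, 0.01 * measured.mean(),
                                         size=measured.shape)
        volumes = [m.reshape(20, 20, 1) for m in measured]
        comps, _ = unmix_spectra(volumes, spectra)
        out = np.stack([comps[c].ravel() for c in spectra.components])
        assert np.abs(out - fracs).mean() < 0.05

    def test_rank_deficient_spectra_rejected(self):
        spectra = ChromophoreSpectra(
            wavelengths_nm=np.array([532.0, 555.0, 579.0]),
            matrix=np.array([[1.0, 1.0, 0.5], [2.0, 2.0, 1.0], [3.0, 3.0, 1.5]]),
        )
        with pytest.raises(ValueError, match="rank"):
            unmix_spectra([np.ones((2, 2, 1))] * 3, spectra)
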