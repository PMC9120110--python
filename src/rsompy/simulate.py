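"""Forward raster-scan optoacoustic acquisition model.

Single-scattering, fluence-flat model: every absorbing voxel emits an
N-shaped (derivative-of-Gaussian) bipolar pulse whose spectrum fills the
10-120 MHz detection band.  The pulse arrives at the detector after the
one-way acoustic travel time, weighted by the depth-dependent lateral
sensitivity of the focused transducer and attenuated as 1/distance.
Breathing is modeled as a rigid vertical translation of the whole object,
evaluated at each A-line's acquisition time.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .datatypes import MotionParams, PhantomTruth, RawScan, ScanConfig
from .reconstruction import SensitivityField

__all__ = ["simulate_scan", "bipolar_pulse"]


def bipolar_pulse(
    sample_rate_hz: float,
    peak_frequency_hz: float = 60.0e6,
    n_sigmas: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Band-limited N-shaped pulse: derivative of a Gaussian.

    Returns (kernel, center_index).  The spectral magnitude is
    ``|f| exp(-(f/f0)^2 ...)`` which peaks at ``peak_frequency_hz`` and spans
    roughly 10-120 MHz for the default 60 MHz peak.
    """
    tau = 1.0 / (2.0 * np.pi * peak_frequency_hz)
    dt = 1.0 / sample_rate_hz
    half = max(int(np.ceil(n_sigmas * tau / dt)), 2)
    t = (np.arange(-half, half + 1)) * dt
    pulse = -(t / tau) * np.exp(-(t**2) / (2 * tau**2))
    return pulse, half


def simulate_scan(
    phantom: PhantomTruth,
    config: ScanConfig,
    motion: MotionParams | None = None,
    noise_sd: float = 0.0,
    sensitivity: SensitivityField | None = None,
    peak_frequency_hz: float = 60.0e6,
    seed: int | None = 0,
) -> RawScan:
    """Simulate one raster scan of a phantom.

    For every scan position, each absorbing voxel inside the lateral
    sensitivity support contributes a delayed, weighted copy of the bipolar
    pulse; delays use the one-way distance from the (vertically displaced)
    voxel to the scan position divided by the speed of sound.  White
    Gaussian noise of standard deviation ``noise_sd`` is added last.
    """
    if motion is None:
        motion = MotionParams()
    if sensitivity is None:
        sensitivity = SensitivityField()
    rng = np.random.default_rng(seed)

    vox = np.asarray(phantom.voxel_size_um, dtype=float)
    extent = phantom.extent_um
    fov_x = (config.n_fast - 1) * config.step_fast_um
    fov_y = (config.n_slow - 1) * config.step_slow_um
    if fov_x > extent[0] + vox[0] or fov_y > extent[1] + vox[1]:
        raise ValueError(
            f"scan field of view ({fov_x} x {fov_y} um) exceeds phantom extent "
            f"({extent[0]} x {extent[1]} um)"
        )

    idx = np.nonzero(phantom.absorption)
    values = phantom.absorption[idx].astype(np.float64)
    coords = (np.stack(idx, axis=1) + 0.5) * vox  # (n_abs, 3) um

    signals = np.zeros((config.n_fast, config.n_slow, config.n_samples), dtype=np.float64)
    if values.size:
        order = RawScan(
            config=config,
            signals=np.zeros((config.n_fast, config.n_slow, config.n_samples), dtype=np.float32),
        ).acquisition_order
        times = np.arange(config.n_positions) / config.rep_rate_hz
        dz = np.asarray(motion.displacement_um(times), dtype=float)

        c_um_s = config.speed_of_sound_m_s * 1e6
        samples_per_um = config.sample_rate_hz / c_um_s
        z_max = float(coords[:, 2].max())
        r_max = sensitivity.max_radius_um(z_max)
        xy = coords[:, :2]
        z_abs = coords[:, 2]
        sigma2 = 2.0 * np.asarray(sensitivity.sigma_um(z_abs)) ** 2

        for k in range(config.n_positions):
            i_f, i_s = order[k]
            px = i_f * config.step_fast_um
            py = i_s * config.step_slow_um
            d2 = (xy[:, 0] - px) ** 2 + (xy[:, 1] - py) ** 2
            sel = d2 <= r_max**2
            if not sel.any():
                continue
            z_k = z_abs[sel] + dz[k]
            dist = np.sqrt(d2[sel] + z_k**2)
            amp = (
                values[sel]
                * np.exp(-d2[sel] / sigma2[sel])
                * (1000.0 / np.maximum(dist, vox.min()))
            )
            s = dist * samples_per_um
            s0 = np.floor(s).astype(np.int64)
            frac = s - s0
            ok = (s0 >= 0) & (s0 < config.n_samples - 1)
            np.add.at(signals[i_f, i_s], s0[ok], amp[ok] * (1 - frac[ok]))
            np.add.at(signals[i_f, i_s], s0[ok] + 1, amp[ok] * frac[ok])

        pulse, center = bipolar_pulse(config.sample_rate_hz, peak_frequency_hz)
        full = fftconvolve(signals, pulse[None, None, :], mode="full", axes=2)
        signals = full[:, :, center : center + config.n_samples]

    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return RawScan(config=config, signals=signals.astype(np.float32))
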