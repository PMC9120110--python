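"""Dual-band volumetric reconstruction of raster-scan optoacoustic data.

The corrected A-lines are split into a low (10-40 MHz) and a high
(40-120 MHz) frequency band, each band is beamformed onto a fixed voxel
grid by sensitivity-weighted delay-and-sum, and the two bands are composited
as red (large structures) and green (small structures) channels.  Linear
spectral unmixing of multiwavelength volumes separates melanin from oxy-
and deoxyhemoglobin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import nnls

from .datatypes import (
    ChromophoreSpectra,
    DualBandComposite,
    RawScan,
    ReconVolume,
)

__all__ = [
    "SensitivityField",
    "bandpass_split",
    "beamform",
    "composite_dual_band",
    "project_mip",
    "unmix_spectra",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((10.0, 40.0), (40.0, 120.0))


@dataclass(frozen=True)
class SensitivityField:
    """Depth-dependent lateral sensitivity of the focused detector.

    Modeled as a Gaussian aperture cone: the lateral 1/e half-width grows
    linearly away from the focal depth,

        sigma(z) = waist_um + spread * |z - focal_depth_um|.

    A voxel/scan-position pair contributes only within ``cutoff_sigmas``
    standard deviations; outside, the weight is treated as zero.
    """

    focal_depth_um: float = 0.0
    waist_um: float = 10.0
    spread: float = 0.5
    cutoff_sigmas: float = 2.5

    def sigma_um(self, z_um: np.ndarray | float) -> np.ndarray | float:
        return self.waist_um + self.spread * np.abs(
            np.asarray(z_um, dtype=float) - self.focal_depth_um
        )

    def weight(self, r2_um2: np.ndarray, z_um: np.ndarray) -> np.ndarray:
        sigma = self.sigma_um(z_um)
        return np.exp(-r2_um2 / (2.0 * sigma**2))

    def max_radius_um(self, z_max_um: float) -> float:
        return float(self.cutoff_sigmas * np.max(self.sigma_um([0.0, z_max_um])))


def bandpass_split(
    scan: RawScan,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    order: int = 4,
) -> list[RawScan]:
    """Zero-phase Butterworth band-pass of every A-line, one scan per band."""
    nyquist = scan.config.sample_rate_hz / 2.0
    out = []
    for f_lo, f_hi in bands:
        if f_hi * 1e6 >= nyquist:
            raise ValueError(
                f"band {f_lo}-{f_hi} MHz exceeds Nyquist {nyquist / 1e6:.0f} MHz"
            )
        sos = signal.butter(
            order,
            [f_lo * 1e6, f_hi * 1e6],
            btype="bandpass",
            fs=scan.config.sample_rate_hz,
            output="sos",
        )
        filtered = signal.sosfiltfilt(sos, scan.signals, axis=2).astype(np.float32)
        out.append(
            RawScan(
                config=scan.config,
                signals=filtered,
                acquisition_order=scan.acquisition_order.copy(),
                wavelength_index=scan.wavelength_index,
            )
        )
    return out


def beamform(
    scan: RawScan,
    voxel_size_um: tuple[float, float, float] = (12.0, 12.0, 3.0),
    z_range_um: tuple[float, float] = (0.0, 1500.0),
    sensitivity: SensitivityField | None = None,
    band_mhz: tuple[float, float] = (10.0, 120.0),
    envelope: bool = True,
    weight_compensation: bool = False,
) -> ReconVolume:
    """Sensitivity-weighted delay-and-sum reconstruction.

    Every voxel accumulates, over all scan positions inside the sensitivity
    support, the A-line sample at the one-way delay ``dist / c`` (the optical
    excitation is effectively instantaneous, so only the acoustic return
    travels).  Samples are read with linear sub-sample interpolation.  With
    ``envelope=True`` (default) the output is the magnitude of the analytic
    signal of the summed image along depth; ``envelope=False`` returns the
    signed sum, which is linear in the input signals.
    """
    if sensitivity is None:
        sensitivity = SensitivityField()
    cfg = scan.config
    vx, vy, vz = voxel_size_um
    x = np.arange(0.0, (cfg.n_fast - 1) * cfg.step_fast_um + vx / 2, vx)
    y = np.arange(0.0, (cfg.n_slow - 1) * cfg.step_slow_um + vy / 2, vy)
    z = np.arange(z_range_um[0], z_range_um[1], vz)
    if z.size == 0:
        raise ValueError("empty depth range")

    acc = np.zeros((x.size, y.size, z.size), dtype=np.float64)
    wsum = np.zeros_like(acc)
    c_um_s = cfg.speed_of_sound_m_s * 1e6
    samples_per_um = cfg.sample_rate_hz / c_um_s
    r_max = sensitivity.max_radius_um(float(z.max()))
    sigma2 = 2.0 * np.asarray(sensitivity.sigma_um(z)) ** 2  # (nz,)

    pos_x = np.arange(cfg.n_fast) * cfg.step_fast_um
    pos_y = np.arange(cfg.n_slow) * cfg.step_slow_um
    z2 = z**2
    for i_f in range(cfg.n_fast):
        dx2 = (x - pos_x[i_f]) ** 2
        for i_s in range(cfg.n_slow):
            dy2 = (y - pos_y[i_s]) ** 2
            r2 = dx2[:, None] + dy2[None, :]
            cols = np.nonzero(r2 <= r_max**2)
            if cols[0].size == 0:
                continue
            r2c = r2[cols]  # (m,)
            dist = np.sqrt(r2c[:, None] + z2[None, :])  # (m, nz)
            w = np.exp(-r2c[:, None] / sigma2[None, :])
            s = dist * samples_per_um
            s0 = np.floor(s).astype(np.int64)
            frac = s - s0
            valid = s0 < cfg.n_samples - 1
            s0 = np.clip(s0, 0, cfg.n_samples - 2)
            line = scan.signals[i_f, i_s].astype(np.float64)
            vals = line[s0] * (1.0 - frac) + line[s0 + 1] * frac
            vals[~valid] = 0.0
            w = np.where(valid, w, 0.0)
            acc[cols[0], cols[1], :] += w * vals
            wsum[cols[0], cols[1], :] += w

    uncovered = int(np.count_nonzero(wsum == 0))
    if weight_compensation:
        # equalize the depth-dependent aperture: voxels seen by fewer /
        # more weakly weighted positions are scaled up
        acc = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)
    if envelope:
        img = np.abs(signal.hilbert(acc, axis=2))
    else:
        img = acc
    return ReconVolume(
        intensity=img.astype(np.float32),
        voxel_size_um=voxel_size_um,
        band_mhz=band_mhz,
        origin_um=(0.0, 0.0, float(z_range_um[0])),
        meta={"uncovered_voxels": uncovered, "envelope": envelope},
    )


def composite_dual_band(
    low: ReconVolume,
    high: ReconVolume,
    percentile: float = 99.9,
) -> DualBandComposite:
    """Percentile-normalize each band to [0, 1]; low -> red, high -> green."""
    if low.shape != high.shape:
        raise ValueError("band volumes must share a grid")

    def _norm(v: np.ndarray) -> tuple[np.ndarray, float]:
        scale = float(np.percentile(v, percentile))
        if scale <= 0:
            return np.zeros_like(v, dtype=np.float32), 0.0
        return np.clip(v / scale, 0.0, 1.0).astype(np.float32), scale

    red, s_lo = _norm(low.intensity)
    green, s_hi = _norm(high.intensity)
    return DualBandComposite(
        red=red,
        green=green,
        normalization={"percentile": percentile, "scale_low": s_lo, "scale_high": s_hi},
    )


def project_mip(
    volume: ReconVolume,
    axis: str = "depth",
    depth_range_um: tuple[float, float] | None = None,
) -> np.ndarray:
    """Maximum intensity projection.

    ``axis="depth"`` gives the coronal view (projection along z, restricted
    to ``depth_range_um``, half-open); ``axis="slow"`` gives the
    cross-sectional view (projection along the slow scan axis).
    """
    z = volume.z_coords_um()
    if depth_range_um is None:
        sel = np.ones(z.size, dtype=bool)
    else:
        sel = (z >= depth_range_um[0]) & (z < depth_range_um[1])
    if not sel.any():
        raise ValueError(f"empty depth range {depth_range_um}")
    sub = volume.intensity[:, :, sel]
    if axis == "depth":
        return sub.max(axis=2)
    if axis == "slow":
        return sub.max(axis=1)
    raise ValueError(f"unknown MIP axis {axis!r}; use 'depth' or 'slow'")


def unmix_spectra(
    volumes: list[np.ndarray] | list[ReconVolume],
    spectra: ChromophoreSpectra,
) -> tuple[dict[str, np.ndarray], float]:
    """Per-voxel non-negative least-squares spectral unmixing.

    Solves ``spectra.matrix @ fractions = measured`` for each voxel with
    fractions >= 0; returns one component volume per chromophore and the
    total residual 2-norm.
    """
    arrays = [v.intensity if isinstance(v, ReconVolume) else np.asarray(v) for v in volumes]
    if len(arrays) != len(spectra.wavelengths_nm):
        raise ValueError("one volume per wavelength required")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("volumes must be co-registered on one grid")
    A = spectra.matrix
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient chromophore spectra")
    stacked = np.stack([a.ravel() for a in arrays], axis=0)  # (n_wl, n_vox)
    out = np.zeros((A.shape[1], stacked.shape[1]))
    resid_sq = 0.0
    # NNLS has no batched form; solve voxels with any signal only
    nonzero = np.nonzero(np.abs(stacked).sum(axis=0) > 0)[0]
    for j in nonzero:
        sol, res = nnls(A, stacked[:, j])
        out[:, j] = sol
        resid_sq += res**2
    components = {
        name: out[k].reshape(shape) for k, name in enumerate(spectra.components)
    }
    return components, float(np.sqrt(resid_sq))
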