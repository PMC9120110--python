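"""Breathing-motion estimation, correction and quality grading.

The skin surface produces the strongest echo in each A-line; vertical
breathing motion therefore shows up as a time shift of the whole A-line.
Displacement is estimated per scan position as the lag of the
cross-correlation maximum between the first A-line in acquisition order
(the reference) and every other A-line, refined to sub-sample precision by
a 3-point parabolic fit, and converted to micrometres through the one-way
relation ``dz = c * dt * lag``.  Correction shifts each A-line back by its
estimated displacement.  Scans are graded by the maximum absolute
displacement: Q1 (usable as-is), Q2 (correctable), Q3 (rejected).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sig

from .datatypes import MotionTrace, QCGrade, RawScan

__all__ = [
    "detect_surface",
    "estimate_displacement",
    "correct_motion",
    "classify_quality",
    "MISSING",
]

MISSING = -1  # sentinel for A-lines with no detectable surface


def _envelope(lines: np.ndarray) -> np.ndarray:
    return np.abs(sig.hilbert(lines, axis=-1))


def detect_surface(scan: RawScan, threshold_frac: float = 0.5) -> np.ndarray:
    """First sample whose envelope exceeds ``threshold_frac`` x line maximum.

    Returns an int array of shape (n_fast, n_slow); positions whose envelope
    is identically zero (or whose maximum does not rise above numerical
    noise) get the ``MISSING`` sentinel instead of raising.
    """
    env = _envelope(scan.signals)
    peak = env.max(axis=-1)
    out = np.full((scan.config.n_fast, scan.config.n_slow), MISSING, dtype=np.int64)
    ok = peak > 0
    thresh = threshold_frac * peak
    above = env >= thresh[..., None]
    first = np.argmax(above, axis=-1)
    out[ok] = first[ok]
    return out


def _parabolic_refine(corr: np.ndarray, peak: int) -> float:
    """Sub-sample peak position by a 3-point parabola around ``peak``."""
    if peak <= 0 or peak >= corr.size - 1:
        return float(peak)
    y0, y1, y2 = corr[peak - 1], corr[peak], corr[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(peak)
    return peak + 0.5 * (y0 - y2) / denom


def estimate_displacement(
    scan: RawScan,
    window_samples: int = 100,
    max_lag: int | None = None,
    use_envelope: bool = True,
    threshold_frac: float = 0.5,
) -> MotionTrace:
    """Cross-correlation displacement of every A-line against the reference.

    The reference is the first A-line in acquisition order.  Correlation is
    restricted to a window of ``+-window_samples`` around the reference's
    detected surface (deeper structure decorrelates between positions).
    Positive displacement means the surface moved toward the detector
    (echo arrives earlier).  Lines flagged missing by surface detection get
    a displacement interpolated from their acquisition-time neighbors and
    are marked in ``trace.missing``.
    """
    cfg = scan.config
    if cfg.n_positions < 2:
        raise ValueError("need at least two A-lines")
    if max_lag is None:
        max_lag = cfg.n_samples // 4
    order = scan.acquisition_order
    lines = scan.lines_in_order().astype(np.float64)
    if use_envelope:
        lines = _envelope(lines)

    surface = detect_surface(scan, threshold_frac)
    ref_fast, ref_slow = order[0]
    ref_surf = surface[ref_fast, ref_slow]
    if ref_surf == MISSING:
        raise ValueError("reference A-line has no detectable surface echo")

    lo = max(ref_surf - window_samples, 0)
    hi = min(ref_surf + window_samples + 1, cfg.n_samples)
    ref = lines[0, lo:hi]
    ref = ref - ref.mean()

    n_pos = cfg.n_positions
    lags = np.zeros(n_pos)
    missing = np.zeros(n_pos, dtype=bool)
    surf_ordered = surface[order[:, 0], order[:, 1]]
    for k in range(n_pos):
        if surf_ordered[k] == MISSING:
            missing[k] = True
            lags[k] = np.nan
            continue
        # search window in line k wide enough to see lags up to max_lag
        wlo = max(lo - max_lag, 0)
        whi = min(hi + max_lag, cfg.n_samples)
        seg = lines[k, wlo:whi] - lines[k, wlo:whi].mean()
        corr = sig.correlate(seg, ref, mode="full")
        # full-mode index i aligns ref start with seg index i - (len(ref)-1);
        # convert to an A-line time lag and restrict to +-max_lag
        lag_axis = np.arange(corr.size) - (ref.size - 1) + (wlo - lo)
        inside = np.abs(lag_axis) <= max_lag
        corr_in = np.where(inside, corr, -np.inf)
        peak = int(np.argmax(corr_in))
        # tie between equal maxima: smallest |lag|
        ties = np.nonzero(corr_in == corr_in[peak])[0]
        if ties.size > 1:
            peak = int(ties[np.argmin(np.abs(lag_axis[ties]))])
        refined = _parabolic_refine(corr, peak)
        lags[k] = refined - (ref.size - 1) + (wlo - lo)

    if missing.any():
        valid = ~missing
        lags[missing] = np.interp(
            np.nonzero(missing)[0], np.nonzero(valid)[0], lags[valid]
        )
    # lag > 0 means the echo in line k arrives LATER -> surface moved away;
    # report displacement toward the detector as positive
    disp_um = -lags * cfg.um_per_sample
    matrix = np.zeros((cfg.n_fast, cfg.n_slow))
    matrix[order[:, 0], order[:, 1]] = disp_um
    return MotionTrace(
        displacement_um=disp_um,
        displacement_matrix_um=matrix,
        reference_index=0,
        missing=missing,
    )


def correct_motion(scan: RawScan, trace: MotionTrace) -> RawScan:
    """Shift every A-line in time to undo the estimated displacement.

    Sub-sample shifts use linear interpolation.  Samples shifted in from
    outside the recording are zero.
    """
    cfg = scan.config
    if trace.displacement_matrix_um.shape != (cfg.n_fast, cfg.n_slow):
        raise ValueError("motion trace grid does not match scan grid")
    t = np.arange(cfg.n_samples, dtype=float)
    out = np.empty_like(scan.signals, dtype=np.float64)
    shift_samples = trace.displacement_matrix_um / cfg.um_per_sample
    for i in range(cfg.n_fast):
        for j in range(cfg.n_slow):
            # displacement > 0: echo arrived early; move it back (later)
            out[i, j] = np.interp(
                t - shift_samples[i, j], t, scan.signals[i, j], left=0.0, right=0.0
            )
    return RawScan(
        config=cfg,
        signals=out.astype(np.float32),
        acquisition_order=scan.acquisition_order.copy(),
        wavelength_index=scan.wavelength_index,
    )


def classify_quality(
    trace: MotionTrace,
    thresholds_um: tuple[float, float] = (70.0, 300.0),
) -> QCGrade:
    """Grade a scan by maximum absolute displacement.

    Q1: max |d| <= 70 um (usable without correction; breath-hold scans sit
    here).  Q2: <= 300 um (motion correctable).  Q3: beyond (rejected; free
    breathing on the torso reaches ~350 um, past what correction can fix).
    Boundaries are inclusive.
    """
    q1, q2 = thresholds_um
    m = trace.max_abs_um
    grade = "Q1" if m <= q1 else ("Q2" if m <= q2 else "Q3")
    return QCGrade(grade=grade, max_abs_um=m, thresholds_um=(q1, q2))
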