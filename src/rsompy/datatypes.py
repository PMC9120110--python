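"""Core containers for the RSOM analysis chain.

Conventions used throughout the package:

* all coordinates are 0-based; the depth axis ``z`` increases into the skin;
* regions of interest are half-open ``[start, stop)``;
* physical distances are micrometres unless a name says otherwise;
* A-line signal arrays are indexed ``[fast, slow, sample]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanConfig",
    "RawScan",
    "MotionParams",
    "MotionTrace",
    "QCGrade",
    "ReconVolume",
    "DualBandComposite",
    "ChromophoreSpectra",
    "PhantomTruth",
    "LayerBoundaries",
    "LesionRegions",
    "VesselSegment",
    "VesselNetwork",
    "BiomarkerSet",
]


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and timing of a raster scan.

    The default grid is 201 x 101 points covering 4 x 2 mm (20 um step) with
    A-lines digitized at 1 GS/s, matching a fast RSOM acquisition completed
    within a single 15 s breath-hold.
    """

    n_fast: int = 201
    n_slow: int = 101
    step_fast_um: float = 20.0
    step_slow_um: float = 20.0
    n_samples: int = 1024
    sample_rate_hz: float = 1.0e9
    speed_of_sound_m_s: float = 1500.0
    wavelengths_nm: tuple[float, ...] = (532.0,)
    rep_rate_hz: float = 1400.0

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1 or self.n_samples < 1:
            raise ValueError("grid and sample counts must be >= 1")
        if self.step_fast_um <= 0 or self.step_slow_um <= 0:
            raise ValueError("step sizes must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.speed_of_sound_m_s <= 0:
            raise ValueError("speed_of_sound_m_s must be positive")

    @property
    def n_positions(self) -> int:
        return self.n_fast * self.n_slow

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def um_per_sample(self) -> float:
        """One-way depth increment per time sample (c * dt)."""
        return self.speed_of_sound_m_s * 1e6 * self.dt_s

    def positions_um(self) -> np.ndarray:
        """(n_fast, n_slow, 2) array of lateral scan coordinates in um."""
        x = np.arange(self.n_fast) * self.step_fast_um
        y = np.arange(self.n_slow) * self.step_slow_um
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return np.stack([xx, yy], axis=-1)


def default_acquisition_order(n_fast: int, n_slow: int) -> np.ndarray:
    """Serpentine-free raster order: fast axis sweeps inside each slow step."""
    fast, slow = np.meshgrid(np.arange(n_fast), np.arange(n_slow), indexing="ij")
    order = np.stack([fast.T.ravel(), slow.T.ravel()], axis=1)
    return order.astype(np.int64)


@dataclass
class RawScan:
    """Time-resolved A-line pressure signals on a raster grid."""

    config: ScanConfig
    signals: np.ndarray  # float, [fast, slow, sample]
    acquisition_order: np.ndarray | None = None  # (n_positions, 2) int
    wavelength_index: int = 0

    def __post_init__(self) -> None:
        expected = (self.config.n_fast, self.config.n_slow, self.config.n_samples)
        self.signals = np.asarray(self.signals, dtype=np.float32)
        if self.signals.shape != expected:
            raise ValueError(
                f"signals shape {self.signals.shape} does not match config {expected}"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")
        if self.acquisition_order is None:
            self.acquisition_order = default_acquisition_order(
                self.config.n_fast, self.config.n_slow
            )
        self.acquisition_order = np.asarray(self.acquisition_order, dtype=np.int64)
        if self.acquisition_order.shape != (self.config.n_positions, 2):
            raise ValueError("acquisition_order must list every grid position once")
        flat = self.acquisition_order[:, 0] * self.config.n_slow + self.acquisition_order[:, 1]
        if len(np.unique(flat)) != self.config.n_positions:
            raise ValueError("acquisition_order is not a permutation of the grid")

    def acquisition_times_s(self) -> np.ndarray:
        """Time of each A-line in acquisition order (one laser shot per line)."""
        return np.arange(self.config.n_positions) / self.config.rep_rate_hz

    def lines_in_order(self) -> np.ndarray:
        """(n_positions, n_samples) view of A-lines sorted by acquisition time."""
        return self.signals[self.acquisition_order[:, 0], self.acquisition_order[:, 1]]


@dataclass(frozen=True)
class MotionParams:
    """Breathing motion model: vertical sinusoid plus linear drift.

    displacement(t) = amplitude * sin(2 pi t / period + phase) + drift * t
    """

    amplitude_um: float = 0.0
    period_s: float = 4.0
    drift_um_s: float = 0.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be >= 0")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")

    def displacement_um(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        d = self.amplitude_um * np.sin(2 * np.pi * t / self.period_s + self.phase_rad)
        return d + self.drift_um_s * t


@dataclass
class MotionTrace:
    """Per-position vertical displacement estimated from a raw scan."""

    displacement_um: np.ndarray  # 1D, ordered by acquisition time
    displacement_matrix_um: np.ndarray  # (n_fast, n_slow)
    reference_index: int = 0
    missing: np.ndarray | None = None  # bool per position (time order)

    @property
    def max_abs_um(self) -> float:
        return float(np.max(np.abs(self.displacement_um)))


@dataclass(frozen=True)
class QCGrade:
    """Motion-based quality grade: Q1 usable, Q2 correctable, Q3 reject."""

    grade: str
    max_abs_um: float
    thresholds_um: tuple[float, float]


@dataclass
class ReconVolume:
    """Reconstructed 3D intensity grid for one frequency band.

    ``intensity`` is indexed [x, y, z] with z increasing into the skin.
    """

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float] = (12.0, 12.0, 3.0)
    band_mhz: tuple[float, float] = (10.0, 120.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def z_coords_um(self) -> np.ndarray:
        return self.origin_um[2] + np.arange(self.shape[2]) * self.voxel_size_um[2]


@dataclass
class DualBandComposite:
    """Low band (red channel) and high band (green channel) on one grid."""

    red: np.ndarray
    green: np.ndarray
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green channels must share a grid")


@dataclass
class ChromophoreSpectra:
    """Absorption weights, rows = wavelengths (nm), cols = components."""

    wavelengths_nm: np.ndarray
    matrix: np.ndarray
    components: tuple[str, ...] = ("melanin", "hbo2", "hb")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.matrix.shape != (len(self.wavelengths_nm), len(self.components)):
            raise ValueError("spectra matrix shape mismatch")
        if np.any(self.matrix < 0):
            raise ValueError("absorption weights must be non-negative")
        if self.matrix.shape[0] < self.matrix.shape[1]:
            raise ValueError("need at least as many wavelengths as components")


@dataclass
class VesselSegment:
    """One skeleton path between branch points and/or endpoints."""

    path: np.ndarray  # (n, ndim) voxel coordinates along the path
    arc_length_um: float
    chord_length_um: float

    @property
    def distance_metric(self) -> float:
        return self.arc_length_um / self.chord_length_um


@dataclass
class VesselNetwork:
    """Binary vessel mask with skeleton, branch points and segments."""

    mask: np.ndarray
    skeleton: np.ndarray
    branch_points: np.ndarray  # (k, ndim)
    segments: list[VesselSegment]
    pixel_size_um: float | tuple[float, ...] = 12.0

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points)

    @property
    def total_skeleton_length_um(self) -> float:
        return float(sum(s.arc_length_um for s in self.segments))


@dataclass
class LayerBoundaries:
    """Epidermis top/bottom depth per (x, y), after surface flattening."""

    ep_top_um: np.ndarray
    ep_bottom_um: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ep_top_um > self.ep_bottom_um):
            raise ValueError("ep_top must not exceed ep_bottom")


@dataclass
class LesionRegions:
    """Pigmented-lesion mask, its boundary, and the surrounding-tissue band."""

    lesion_mask: np.ndarray
    boundary_path: np.ndarray  # (n, 2) pixel coordinates
    stv_mask: np.ndarray | None = None
    band_width_um: float = 500.0


@dataclass
class BiomarkerSet:
    """The six scalar vascular biomarkers for one lesion region.

    ``tortuosity`` is the tortuosity index mean(DM - 1); the raw mean distance
    metric is kept in ``mean_dm``.
    """

    tbv: float
    vessel_density: float
    avg_vessel_length_um: float
    tortuosity: float
    fractal_number: float
    lacunarity: float
    mean_dm: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "tbv": self.tbv,
            "vessel_density": self.vessel_density,
            "avg_vessel_length_um": self.avg_vessel_length_um,
            "tortuosity": self.tortuosity,
            "fractal_number": self.fractal_number,
            "lacunarity": self.lacunarity,
        }


BIOMARKER_COLUMNS = [
    "tbv",
    "vessel_density",
    "avg_vessel_length_um",
    "tortuosity",
    "fractal_number",
    "lacunarity",
]

GROUP_LABELS = ("nevus", "melanoma")
REGION_LABELS = ("edge", "center")


@dataclass
class PhantomTruth:
    """Ground-truth skin phantom: absorption grid plus vessel geometry."""

    absorption: np.ndarray  # [x, y, z], non-negative a.u.
    voxel_size_um: tuple[float, float, float]
    vessel_mask: np.ndarray
    melanin_mask: np.ndarray
    vessel_segments: list[dict]  # {"points": (n,3) um, "radius_um": float, ...}
    lesion_center_um: tuple[float, float] | None = None
    lesion_radius_um: float = 0.0
    seed: int | None = None
    true_biomarkers: BiomarkerSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be non-negative")
        if self.vessel_mask.shape != self.absorption.shape:
            raise ValueError("vessel_mask shape mismatch")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            s * v for s, v in zip(self.absorption.shape, self.voxel_size_um)
        )
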