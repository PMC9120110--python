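"""Readers and writers for raw scans, volumes, masks and cohort tables.

Raw scans live in HDF5 (one float32 dataset ``/signals`` indexed
[fast, slow, sample] plus scalar/array attributes for the acquisition
geometry).  Reconstructed volumes are multi-page float32 TIFF stacks with a
JSON sidecar holding voxel size, frequency band and origin.  Cohort tables
are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    BIOMARKER_COLUMNS,
    GROUP_LABELS,
    RawScan,
    ReconVolume,
    ScanConfig,
)

__all__ = [
    "read_raw_scan",
    "write_raw_scan",
    "read_volume",
    "write_volume",
    "read_cohort_table",
    "write_cohort_table",
    "FormatError",
]

_SCAN_ATTRS = [
    "sample_rate_hz",
    "step_fast_um",
    "step_slow_um",
    "speed_of_sound_m_s",
    "wavelengths_nm",
    "acquisition_order",
    "rep_rate_hz",
]

COHORT_COLUMNS = ["lesion_id", "group", "region"] + BIOMARKER_COLUMNS


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


def write_raw_scan(scan: RawScan, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=scan.signals.astype(np.float32))
        f.attrs["sample_rate_hz"] = scan.config.sample_rate_hz
        f.attrs["step_fast_um"] = scan.config.step_fast_um
        f.attrs["step_slow_um"] = scan.config.step_slow_um
        f.attrs["speed_of_sound_m_s"] = scan.config.speed_of_sound_m_s
        f.attrs["wavelengths_nm"] = np.asarray(scan.config.wavelengths_nm, dtype=float)
        f.attrs["acquisition_order"] = scan.acquisition_order
        f.attrs["rep_rate_hz"] = scan.config.rep_rate_hz
        f.attrs["wavelength_index"] = scan.wavelength_index
    return path


def read_raw_scan(path: str | Path) -> RawScan:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"{path}: missing dataset 'signals'")
        missing = [a for a in _SCAN_ATTRS if a not in f.attrs]
        if missing:
            raise FormatError(f"{path}: missing attributes {missing}")
        signals = np.asarray(f["signals"], dtype=np.float32)
        if signals.ndim != 3:
            raise FormatError(f"{path}: signals must be 3D [fast, slow, sample]")
        config = ScanConfig(
            n_fast=signals.shape[0],
            n_slow=signals.shape[1],
            n_samples=signals.shape[2],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            step_fast_um=float(f.attrs["step_fast_um"]),
            step_slow_um=float(f.attrs["step_slow_um"]),
            speed_of_sound_m_s=float(f.attrs["speed_of_sound_m_s"]),
            wavelengths_nm=tuple(np.atleast_1d(f.attrs["wavelengths_nm"]).tolist()),
            rep_rate_hz=float(f.attrs["rep_rate_hz"]),
        )
        order = np.asarray(f.attrs["acquisition_order"], dtype=np.int64)
        wl_index = int(f.attrs.get("wavelength_index", 0))
    return RawScan(config=config, signals=signals, acquisition_order=order,
                   wavelength_index=wl_index)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: ReconVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF (pages = z slices) + JSON sidecar."""
    path = Path(path)
    # pages along z so a stack viewer walks into the skin
    pages = np.moveaxis(volume.intensity.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "voxel_size_um": list(volume.voxel_size_um),
        "band_mhz": list(volume.band_mhz),
        "origin_um": list(volume.origin_um),
        "axes": "xyz, pages along z",
        "writer": "rsompy",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("voxel_size_um", "band_mhz", "origin_um"):
        if key not in sidecar:
            raise FormatError(f"{sidecar_path}: missing key '{key}'")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    intensity = np.moveaxis(pages, 0, 2)
    return ReconVolume(
        intensity=intensity,
        voxel_size_um=tuple(sidecar["voxel_size_um"]),
        band_mhz=tuple(sidecar["band_mhz"]),
        origin_um=tuple(sidecar["origin_um"]),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary 2D/3D mask as uint8 TIFF."""
    path = Path(path)
    arr = np.asarray(mask).astype(np.uint8)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, 2, 0)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    _validate_cohort(table)
    table.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    _validate_cohort(table)
    return table[COHORT_COLUMNS]


def _validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    bad = ~table["group"].isin(GROUP_LABELS)
    if bad.any():
        rows = table.index[bad].tolist()
        labels = table.loc[bad, "group"].unique().tolist()
        raise ValueError(
            f"unknown group labels {labels} in rows {rows}; "
            f"expected one of {list(GROUP_LABELS)}"
        )
    values = table[BIOMARKER_COLUMNS].to_numpy(dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("biomarker values must be finite")
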