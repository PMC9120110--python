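"""The six vascular biomarkers computed from segmented vessel data.

* total blood volume (TBV): nonzero-voxel fraction of the segmented volume;
* vessel density: skeleton (or mask) pixel fraction of the 2D analysis area;
* average vessel length: total skeleton arc length / number of branch points;
* tortuosity: distance metric DM = arc length / chord length per segment;
  reported primarily as the tortuosity index mean(DM - 1), with the raw
  mean DM kept alongside;
* fractal number (FN): box-counting dimension of the binary vessel pattern;
* lacunarity (L): mean of squares over squared mean, minus one, of the same
  image used for box counting.
"""

from __future__ import annotations

import numpy as np

from .datatypes import BiomarkerSet, VesselNetwork

__all__ = [
    "total_blood_volume",
    "vessel_density",
    "average_vessel_length",
    "tortuosity",
    "fractal_number",
    "lacunarity",
    "lacunarity_gliding",
    "compute_biomarkers",
]


def total_blood_volume(binary: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Nonzero-voxel count within the ROI divided by the ROI voxel count."""
    binary = np.asarray(binary)
    if roi is None:
        roi = np.ones(binary.shape, dtype=bool)
    if roi.shape != binary.shape:
        raise ValueError("roi shape mismatch")
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError("empty ROI")
    return float(np.count_nonzero(binary[roi.astype(bool)]) / n_roi)


def vessel_density(
    network: VesselNetwork,
    roi_2d: np.ndarray | None = None,
    representation: str = "skeleton",
) -> float:
    """Nonzero pixels of the chosen representation over the ROI pixel count.

    ``representation="skeleton"`` (default) counts skeleton pixels;
    ``"mask"`` counts full vessel-mask pixels.
    """
    img = network.skeleton if representation == "skeleton" else network.mask
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("vessel density is defined on the 2D analysis image")
    if roi_2d is None:
        roi_2d = np.ones(img.shape, dtype=bool)
    n_roi = int(np.count_nonzero(roi_2d))
    if n_roi == 0:
        raise ValueError("empty ROI")
    return float(np.count_nonzero(img & roi_2d.astype(bool)) / n_roi)


def average_vessel_length(network: VesselNetwork) -> float:
    """Total skeleton arc length divided by the branch-point count.

    A network with no branch points (a single unbranched vessel) uses a
    divisor of 1, so the value degrades gracefully to the total length.
    """
    if not network.segments:
        raise ValueError("empty vessel network")
    total = network.total_skeleton_length_um
    return total / max(network.n_branch_points, 1)


def tortuosity(
    network: VesselNetwork,
    weighted: bool = False,
    min_chord_um: float = 0.0,
) -> dict[str, float]:
    """Distance-metric tortuosity of the vessel segments.

    DM = AL / SL per segment.  Returns the tortuosity index mean(DM - 1)
    (the primary cohort output), the raw mean DM, and the count of segments
    skipped for zero chord length.  ``weighted=True`` weights the mean by
    arc length.  Segments with chord shorter than ``min_chord_um`` are
    excluded: at a few pixels the arc/chord ratio measures grid
    quantization around junctions, not vessel geometry.
    """
    dms, weights = [], []
    skipped = 0
    for seg in network.segments:
        if seg.chord_length_um <= 0:
            skipped += 1
            continue
        if seg.chord_length_um < min_chord_um:
            skipped += 1
            continue
        dms.append(seg.arc_length_um / seg.chord_length_um)
        weights.append(seg.arc_length_um)
    if not dms:
        raise ValueError("no segments with positive chord length")
    dms_a = np.asarray(dms)
    w = np.asarray(weights) if weighted else np.ones(len(dms))
    mean_dm = float(np.average(dms_a, weights=w))
    return {
        "tortuosity_index": float(np.average(dms_a - 1.0, weights=w)),
        "mean_dm": mean_dm,
        "n_segments": len(dms),
        "n_skipped": skipped,
    }


def _box_counts(img: np.ndarray, r: int) -> int:
    """Number of r x r boxes (grid anchored at the origin) containing any
    nonzero pixel."""
    h, w = img.shape
    ph = (-h) % r
    pw = (-w) % r
    padded = np.pad(img, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // r, r, padded.shape[1] // r, r)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_number(binary_2d: np.ndarray, min_scales: int = 4) -> float:
    """Box-counting fractal dimension of a binary 2D image.

    Counts occupied boxes at dyadic sizes r = 2, 4, 8, ... (grid anchored at
    the image origin) and returns the least-squares slope of log N(r)
    against log(1/r).  Box sizes stop at a quarter of the short image side:
    r = 1 saturates at the pixel count and very coarse boxes saturate at
    O(1) counts, and both bias the slope.  At least ``min_scales`` dyadic
    scales must fit.
    """
    img = np.asarray(binary_2d).astype(bool)
    if img.ndim != 2:
        raise ValueError("fractal number is defined on a 2D image")
    if not img.any():
        raise ValueError("empty image")
    max_r = min(img.shape) // 4
    sizes = []
    r = 2
    while r <= max_r:
        sizes.append(r)
        r *= 2
    if len(sizes) < min_scales:
        raise ValueError(
            f"image too small for {min_scales} dyadic box scales "
            f"(got {len(sizes)})"
        )
    counts = np.array([_box_counts(img, r) for r in sizes], dtype=float)
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(counts), 1)[0]
    return float(slope)


def lacunarity(image: np.ndarray) -> float:
    """Normalized second moment minus one: mean(I^2) / mean(I)^2 - 1.

    Measures the "lumpiness" of the pattern supplied to box counting.  A
    binary image with fill fraction p gives exactly 1/p - 1.
    """
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean == 0:
        raise ValueError("lacunarity undefined for a zero-mean image")
    return float((img**2).mean() / mean**2 - 1.0)


def lacunarity_gliding(image: np.ndarray, box_size: int) -> float:
    """Gliding-box lacunarity: second moment of box masses over all
    positions of a ``box_size`` window, normalized by the squared mean."""
    from scipy.ndimage import uniform_filter

    img = np.asarray(image, dtype=float)
    if box_size < 1 or box_size > min(img.shape):
        raise ValueError("box_size out of range")
    half = box_size // 2
    masses = uniform_filter(img, box_size, mode="constant")
    core = masses[half : img.shape[0] - half, half : img.shape[1] - half]
    m = core.mean()
    if m == 0:
        raise ValueError("lacunarity undefined for a zero-mean image")
    return float((core**2).mean() / m**2 - 1.0)


def compute_biomarkers(
    vessel_volume_mask: np.ndarray | None,
    network: VesselNetwork,
    roi_2d: np.ndarray,
    roi_3d: np.ndarray | None = None,
    density_representation: str = "skeleton",
    weighted_tortuosity: bool = False,
    min_chord_um: float = 0.0,
) -> BiomarkerSet:
    """All six biomarkers for one lesion region.

    ``vessel_volume_mask`` (3D, e.g. the segmented STV volume) feeds TBV;
    when None, TBV is computed from the 2D vessel mask instead.  The
    skeleton image restricted to the ROI feeds the fractal number and
    lacunarity.
    """
    if vessel_volume_mask is not None:
        tbv = total_blood_volume(vessel_volume_mask, roi_3d)
    else:
        tbv = total_blood_volume(network.mask, roi_2d)
    density = vessel_density(network, roi_2d, representation=density_representation)
    avg_len = average_vessel_length(network)
    tort = tortuosity(network, weighted=weighted_tortuosity,
                      min_chord_um=min_chord_um)
    texture = (network.skeleton & roi_2d.astype(bool)).astype(float)
    fn = fractal_number(texture > 0)
    lac = lacunarity(texture)
    return BiomarkerSet(
        tbv=tbv,
        vessel_density=density,
        avg_vessel_length_um=avg_len,
        tortuosity=tort["tortuosity_index"],
        mean_dm=tort["mean_dm"],
        fractal_number=fn,
        lacunarity=lac,
        provenance={
            "density_representation": density_representation,
            "weighted_tortuosity": weighted_tortuosity,
            "n_segments": tort["n_segments"],
            "n_branch_points": network.n_branch_points,
        },
    )
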