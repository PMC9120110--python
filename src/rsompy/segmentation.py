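"""Skin-layer, lesion-boundary and vessel segmentation.

The reconstructed volume is first flattened so the skin surface sits at
depth 0.  The epidermis (EP) / dermis (DR) interface is traced per B-scan
by a dynamic-programming shortest path on a depth-gradient cost image —
the melanin-rich EP band ends where intensity drops most steeply.  The
pigmented-lesion boundary is traced with the same DP machinery in polar
coordinates on the EP coronal projection, and the surrounding-tissue
band (STV) is the 500 um Euclidean-distance extension of the lesion
outward into healthy skin.  Vessels are segmented by background
subtraction, hysteresis thresholding, cleanup and topology-preserving
thinning, yielding a skeleton with branch points and per-segment
arc/chord lengths.
"""

from __future__ import annotations

import warnings
from math import ceil

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .datatypes import (
    LayerBoundaries,
    LesionRegions,
    ReconVolume,
    VesselNetwork,
    VesselSegment,
)

__all__ = [
    "find_surface",
    "flatten_surface",
    "unflatten_surface",
    "trace_boundary_dp",
    "segment_layers",
    "segment_lesion_boundary",
    "extract_stv_band",
    "segment_vessels",
    "skeleton_network",
    "vessel_mask",
]


# ---------------------------------------------------------------------------
# surface flattening


def find_surface(volume: ReconVolume, threshold_frac: float = 0.5) -> np.ndarray:
    """Per-(x, y) surface depth (um): first voxel above a fraction of the
    column maximum.  Columns with no signal get the median surface depth."""
    inten = volume.intensity
    peak = inten.max(axis=2)
    above = inten >= (threshold_frac * peak)[..., None]
    first = np.argmax(above, axis=2).astype(float)
    ok = peak > 0
    if not ok.any():
        raise ValueError("volume has no signal; cannot locate a surface")
    first[~ok] = np.median(first[ok])
    return volume.origin_um[2] + first * volume.voxel_size_um[2]


def flatten_surface(volume: ReconVolume, surface_um: np.ndarray) -> ReconVolume:
    """Shift each (x, y) column up so the detected surface sits at depth 0.

    Shifts are stored in ``meta['flatten_shift_um']`` for inversion.
    Sub-voxel shifts use linear interpolation.
    """
    if surface_um.shape != volume.shape[:2]:
        raise ValueError("surface map does not match the volume grid")
    z = volume.z_coords_um()
    if np.any(surface_um < z[0] - 1e-9) or np.any(surface_um > z[-1] + 1e-9):
        raise ValueError("surface lies outside the volume depth range")
    out = np.empty_like(volume.intensity, dtype=np.float32)
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            out[i, j] = np.interp(
                z + (surface_um[i, j] - z[0]), z, volume.intensity[i, j],
                left=0.0, right=0.0,
            )
    return ReconVolume(
        intensity=out,
        voxel_size_um=volume.voxel_size_um,
        band_mhz=volume.band_mhz,
        origin_um=(volume.origin_um[0], volume.origin_um[1], 0.0),
        meta={**volume.meta, "flatten_shift_um": surface_um - z[0]},
    )


def unflatten_surface(volume: ReconVolume) -> ReconVolume:
    """Invert :func:`flatten_surface` using the recorded shifts."""
    shift = volume.meta.get("flatten_shift_um")
    if shift is None:
        raise ValueError("volume carries no flattening shifts")
    z = volume.z_coords_um()
    out = np.empty_like(volume.intensity, dtype=np.float32)
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            out[i, j] = np.interp(
                z - shift[i, j], z, volume.intensity[i, j], left=0.0, right=0.0
            )
    meta = {k: v for k, v in volume.meta.items() if k != "flatten_shift_um"}
    return ReconVolume(
        intensity=out,
        voxel_size_um=volume.voxel_size_um,
        band_mhz=volume.band_mhz,
        origin_um=volume.origin_um,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# dynamic-programming boundary tracing


def trace_boundary_dp(cost: np.ndarray, max_jump: int = 2) -> np.ndarray:
    """Globally optimal column-monotone path through a cost image.

    Finds the path selecting one row per column, with vertical jumps of at
    most ``max_jump`` rows between adjacent columns, minimizing the sum of
    node costs.  Ties resolve to the topmost (smallest row index) path.
    Returns the row index per column.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[1] < 2:
        raise ValueError("cost image must be 2D with at least two columns")
    if np.isnan(cost).any():
        raise ValueError("cost image must be finite or +inf")
    n_rows, n_cols = cost.shape
    if np.isinf(cost).all(axis=0).any():
        raise ValueError("a column has no finite cost; no path exists")

    J = int(max_jump)
    dp = cost[:, 0].copy()
    back = np.zeros((n_rows, n_cols), dtype=np.int64)
    rows = np.arange(n_rows)
    for j in range(1, n_cols):
        # candidate predecessor rows r-J .. r+J, in that order so that the
        # first minimum is the smallest predecessor row
        cand = np.full((2 * J + 1, n_rows), np.inf)
        for o, d in enumerate(range(-J, J + 1)):
            lo = max(0, -d)
            hi = min(n_rows, n_rows - d)
            cand[o, lo:hi] = dp[lo + d : hi + d]
        best = np.argmin(cand, axis=0)
        back[:, j] = rows + (best - J)
        dp = cand[best, rows] + cost[:, j]
    end = int(np.argmin(dp))
    if np.isinf(dp[end]):
        raise ValueError("no feasible path through the cost image")
    path = np.empty(n_cols, dtype=np.int64)
    path[-1] = end
    for j in range(n_cols - 1, 0, -1):
        path[j - 1] = back[path[j], j]
    return path


# ---------------------------------------------------------------------------
# EP / DR layer segmentation


def segment_layers(
    volume: ReconVolume,
    exclusion_margin_um: float = 30.0,
    max_jump: int = 2,
    median_size: int = 3,
    contrast_ratio: float = 1.2,
    fixed_ep_thickness_um: float | None = None,
) -> LayerBoundaries:
    """Locate the epidermis bottom in a flattened volume.

    Per B-scan, the EP/DR interface is traced by :func:`trace_boundary_dp`
    on the depth gradient of intensity (cost low where intensity drops
    steeply with depth), excluding depths above ``exclusion_margin_um``.
    The traced depths are median-filtered across the coronal grid.

    If the superficial band does not stand out (mean intensity above the
    traced boundary below ``contrast_ratio`` x mean below), a ValueError is
    raised suggesting ``fixed_ep_thickness_um``; passing that value skips
    tracing and places the boundary at a constant depth.
    """
    nx, ny, nz = volume.shape
    vz = volume.voxel_size_um[2]
    z = volume.z_coords_um()
    ep_top = np.zeros((nx, ny))

    if fixed_ep_thickness_um is not None:
        ep_bottom = np.full((nx, ny), float(fixed_ep_thickness_um))
        return LayerBoundaries(ep_top_um=ep_top, ep_bottom_um=ep_bottom)

    margin = int(ceil(exclusion_margin_um / vz))
    grad = np.gradient(volume.intensity.astype(float), axis=2)
    bottom_idx = np.empty((nx, ny), dtype=float)
    for j in range(ny):
        # rows = depth, columns = fast axis
        cost = grad[:, j, :].T.copy()
        cost[: margin + 1, :] = np.inf
        bottom_idx[:, j] = trace_boundary_dp(cost, max_jump=max_jump)
    bottom_idx = ndimage.median_filter(bottom_idx, size=median_size, mode="nearest")
    ep_bottom = z[0] + bottom_idx * vz

    zz = z[None, None, :]
    above = volume.intensity * (zz < ep_bottom[..., None])
    below = volume.intensity * (zz >= ep_bottom[..., None])
    n_above = np.maximum((zz < ep_bottom[..., None]).sum(), 1)
    n_below = np.maximum((zz >= ep_bottom[..., None]).sum(), 1)
    mean_above = above.sum() / n_above
    mean_below = below.sum() / n_below
    if mean_below <= 0 or mean_above < contrast_ratio * mean_below:
        raise ValueError(
            "no epidermal gradient contrast; pass fixed_ep_thickness_um to "
            "override with a constant layer thickness"
        )
    return LayerBoundaries(ep_top_um=ep_top, ep_bottom_um=ep_bottom)


# ---------------------------------------------------------------------------
# lesion boundary and STV band


def segment_lesion_boundary(
    ep_mip: np.ndarray,
    min_variance_ratio: float = 0.2,
    n_angles: int = 360,
    max_jump: int = 2,
) -> LesionRegions:
    """Segment the pigmented lesion in an EP coronal projection.

    The high-intensity region is found by Otsu thresholding (rejected as
    "no lesion contrast" when the between-class variance explains less than
    ``min_variance_ratio`` of the total), the largest connected component is
    kept and hole-filled, and the boundary is refined as the DP-optimal
    radial-gradient contour in polar coordinates around the component
    centroid.
    """
    img = np.asarray(ep_mip, dtype=float)
    total_var = img.var()
    if total_var == 0:
        raise ValueError("no lesion contrast: uniform image")
    t = filters.threshold_otsu(img)
    fg = img > t
    if not fg.any() or fg.all():
        raise ValueError("no lesion contrast: threshold separates nothing")
    w1, w0 = fg.mean(), 1 - fg.mean()
    between_var = w0 * w1 * (img[fg].mean() - img[~fg].mean()) ** 2
    if between_var / total_var < min_variance_ratio:
        raise ValueError(
            f"no lesion contrast: inter-class variance ratio "
            f"{between_var / total_var:.3f} < {min_variance_ratio}"
        )

    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no lesion contrast: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == keep)

    cy, cx = ndimage.center_of_mass(mask)
    r_max = int(np.ceil(np.hypot(*mask.shape)))
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.arange(r_max)
    rr = radii[:, None]
    sample_y = cy + rr * np.sin(angles)[None, :]
    sample_x = cx + rr * np.cos(angles)[None, :]
    polar = ndimage.map_coordinates(
        img, [sample_y, sample_x], order=1, mode="constant", cval=img.min()
    )
    radial_grad = np.abs(np.gradient(polar, axis=0))
    cost = -radial_grad  # rows = radius, columns = angle
    path = trace_boundary_dp(cost, max_jump=max_jump)
    boundary = np.stack(
        [cy + path * np.sin(angles), cx + path * np.cos(angles)], axis=1
    )
    return LesionRegions(lesion_mask=mask, boundary_path=boundary)


def extract_stv_band(
    regions: LesionRegions,
    band_width_um: float = 500.0,
    pixel_size_um: float = 12.0,
) -> LesionRegions:
    """Surrounding-tissue band: lesion dilation by ``band_width_um`` minus
    the lesion, computed with a Euclidean distance transform.

    The band width converts to pixels by ``ceil(band / pixel)``.  If the
    band reaches the image border it is clipped and a warning recorded.
    """
    mask = regions.lesion_mask
    if not mask.any():
        raise ValueError("empty lesion mask; no boundary to extend")
    band_px = ceil(band_width_um / pixel_size_um)
    dist = ndimage.distance_transform_edt(~mask)
    stv = (dist > 0) & (dist <= band_px)
    border = np.zeros_like(stv)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (stv & border).any() or (mask & border).any():
        warnings.warn(
            "STV band clipped at the image border; quoted band area is partial",
            stacklevel=2,
        )
    regions.stv_mask = stv
    regions.band_width_um = band_width_um
    return regions


# ---------------------------------------------------------------------------
# vessel segmentation


def vessel_mask(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    background_sigma_px: float = 8.0,
    hysteresis_percentiles: tuple[float, float] = (97.0, 90.0),
    min_object_px: int = 5,
    closing_radius_px: int = 1,
    threshold: str = "percentile",
) -> np.ndarray:
    """Binary vessel mask: background subtraction, hysteresis threshold,
    small-object removal and morphological closing.  Works in 2D or 3D.

    ``threshold="percentile"`` seeds the hysteresis at intensity percentiles
    within the ROI (robust on clinical data with unknown dynamic range);
    ``"otsu"`` seeds it at the Otsu threshold with the low level at half of
    it, preserving the true foreground fraction on clean reconstructions.
    ``background_sigma_px <= 0`` skips background subtraction.
    """
    img = np.asarray(image, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(img.shape, dtype=bool)
    if roi_mask.shape != img.shape:
        raise ValueError("roi_mask shape does not match image")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    work = np.where(roi_mask, img, 0.0)
    if background_sigma_px > 0:
        bg = ndimage.gaussian_filter(work, background_sigma_px)
        enh = np.clip(work - bg, 0.0, None)
    else:
        enh = np.clip(work, 0.0, None)
    vals = enh[roi_mask]
    if not np.any(vals > 0):
        return np.zeros_like(roi_mask)
    if threshold == "otsu":
        hi = filters.threshold_otsu(vals)
        lo = 0.5 * hi
    elif threshold == "otsu-global":
        # plain global Otsu cut, no hysteresis growth: preserves the
        # foreground fraction, preferred for volumetric quantification
        hi = filters.threshold_otsu(vals)
        lo = hi
    elif threshold == "percentile":
        hi_p, lo_p = hysteresis_percentiles
        hi = np.percentile(vals, hi_p)
        lo = np.percentile(vals, lo_p)
    else:
        raise ValueError(f"unknown threshold mode {threshold!r}")
    if hi <= 0:
        return np.zeros_like(roi_mask)
    if lo > hi:
        lo = hi * 0.5
    mask = filters.apply_hysteresis_threshold(enh, lo, hi) & roi_mask
    labels, n = ndimage.label(mask, structure=np.ones((3,) * img.ndim, dtype=int))
    if n:
        sizes = ndimage.sum_labels(mask, labels, np.arange(1, n + 1))
        small = np.nonzero(sizes < min_object_px)[0] + 1
        mask[np.isin(labels, small)] = False
    if closing_radius_px > 0:
        footprint = (
            morphology.disk(closing_radius_px)
            if img.ndim == 2
            else morphology.ball(closing_radius_px)
        )
        mask = morphology.closing(mask, footprint) & roi_mask
    return mask


def _neighbor_offsets(ndim: int) -> np.ndarray:
    grids = np.meshgrid(*([[-1, 0, 1]] * ndim), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    return offs[np.any(offs != 0, axis=1)]


def _skeleton_graph(skeleton: np.ndarray) -> tuple[np.ndarray, dict, list]:
    """Coordinates, coordinate->index map, and adjacency lists of a skeleton."""
    coords = np.argwhere(skeleton)
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _neighbor_offsets(skeleton.ndim)
    adjacency: list[list[int]] = [[] for _ in coords]
    for i, c in enumerate(coords):
        for off in offsets:
            nb = tuple(c + off)
            j = index.get(nb)
            if j is not None:
                adjacency[i].append(j)
    return coords, index, adjacency


def _prune_spurs(skeleton: np.ndarray, min_length_px: int) -> np.ndarray:
    """Remove terminal branches shorter than ``min_length_px`` pixels."""
    skel = skeleton.copy()
    changed = True
    while changed:
        changed = False
        coords, _, adj = _skeleton_graph(skel)
        degree = np.array([len(a) for a in adj])
        for i in np.nonzero(degree == 1)[0]:
            # walk from the endpoint toward the first junction
            path = [i]
            prev, cur = -1, i
            while True:
                nxt = [j for j in adj[cur] if j != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                if degree[cur] >= 3:
                    break
                path.append(cur)
            if degree[cur] >= 3 and len(path) < min_length_px:
                for j in path:
                    skel[tuple(coords[j])] = False
                changed = True
                break
    return skel


def _smooth_path(pts: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing of a polyline, endpoints pinned.

    Skeleton pixels lie on the integer grid, so the raw path zig-zags and
    its cumulative length overestimates the true arc; a short moving
    average removes the quantization jitter without flattening real bends.
    """
    if window <= 1 or len(pts) <= window:
        return pts
    kernel = np.ones(window) / window
    inner = np.stack(
        [np.convolve(pts[:, ax], kernel, mode="valid") for ax in range(pts.shape[1])],
        axis=1,
    )
    return np.vstack([pts[:1], inner, pts[-1:]])


def _extract_segments(
    skeleton: np.ndarray,
    pixel_size_um: float | tuple[float, ...],
    smooth_window: int = 5,
) -> tuple[list[VesselSegment], np.ndarray]:
    """Split a skeleton into paths between junctions/endpoints.

    ``pixel_size_um`` may be a scalar (isotropic pixels) or one value per
    axis (anisotropic voxel grids).  Arc lengths are computed on a
    moving-average-smoothed copy of each path (see :func:`_smooth_path`).
    Returns the segment list and the merged branch-point coordinates
    (adjacent junction pixels collapse to their rounded centroid).
    """
    scale = np.broadcast_to(
        np.atleast_1d(np.asarray(pixel_size_um, dtype=float)), (skeleton.ndim,)
    )
    coords, _, adj = _skeleton_graph(skeleton)
    if len(coords) == 0:
        return [], np.empty((0, skeleton.ndim), dtype=np.int64)
    degree = np.array([len(a) for a in adj])
    is_node = degree != 2

    junction = np.zeros(skeleton.shape, dtype=bool)
    jc = coords[degree >= 3]
    junction[tuple(jc.T)] = True
    labels, n_j = ndimage.label(
        junction, structure=np.ones((3,) * skeleton.ndim, dtype=int)
    )
    branch_points = np.array(
        [
            np.round(np.mean(np.argwhere(labels == k), axis=0)).astype(np.int64)
            for k in range(1, n_j + 1)
        ]
    )
    if branch_points.size == 0:
        branch_points = np.empty((0, skeleton.ndim), dtype=np.int64)

    def _path_to_segment(path_idx: list[int]) -> list[VesselSegment]:
        pts = coords[path_idx].astype(float) * scale
        if len(pts) < 2:
            return []
        pts_s = _smooth_path(pts, smooth_window)
        steps = np.linalg.norm(np.diff(pts_s, axis=0), axis=1)
        arc = float(steps.sum())
        chord = float(np.linalg.norm(pts_s[-1] - pts_s[0]))
        if chord == 0 and len(pts) > 2:
            # closed loop: split at the point farthest from the start
            d = np.linalg.norm(pts - pts[0], axis=1)
            k = int(np.argmax(d))
            return _path_to_segment(path_idx[: k + 1]) + _path_to_segment(
                path_idx[k:]
            )
        return [
            VesselSegment(
                path=coords[path_idx], arc_length_um=arc, chord_length_um=chord
            )
        ]

    segments: list[VesselSegment] = []
    visited_edges: set[tuple[int, int]] = set()
    for start in np.nonzero(is_node)[0]:
        for first in adj[start]:
            if (start, first) in visited_edges:
                continue
            path = [start, first]
            visited_edges.add((start, first))
            visited_edges.add((first, start))
            prev, cur = start, first
            while not is_node[cur]:
                nxt = [j for j in adj[cur] if j != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                visited_edges.add((prev, cur))
                visited_edges.add((cur, prev))
                path.append(cur)
            segments.extend(_path_to_segment(path))
    if not segments and len(coords) >= 2 and not is_node.any():
        # pure cycle with no endpoints: walk it from an arbitrary pixel
        start = 0
        path = [start]
        prev, cur = -1, start
        while True:
            nxt = [j for j in adj[cur] if j != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                path.append(cur)
                break
            path.append(cur)
        segments.extend(_path_to_segment(path))
    return segments, branch_points


def skeleton_network(
    mask: np.ndarray,
    pixel_size_um: float | tuple[float, ...] = 12.0,
    min_spur_px: int = 3,
) -> VesselNetwork:
    """Skeletonize an existing binary vessel mask (2D or 3D) and extract
    branch points and segments.  ``pixel_size_um`` may be per-axis for
    anisotropic voxel grids."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return VesselNetwork(
            mask=mask,
            skeleton=np.zeros_like(mask),
            branch_points=np.empty((0, mask.ndim), dtype=np.int64),
            segments=[],
            pixel_size_um=pixel_size_um,
        )
    skel = morphology.skeletonize(mask)
    if min_spur_px > 0:
        skel = _prune_spurs(skel, min_spur_px)
    segments, branch_points = _extract_segments(skel, pixel_size_um)
    return VesselNetwork(
        mask=mask,
        skeleton=skel,
        branch_points=branch_points,
        segments=segments,
        pixel_size_um=pixel_size_um,
    )


def segment_vessels(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    pixel_size_um: float = 12.0,
    background_sigma_px: float = 8.0,
    hysteresis_percentiles: tuple[float, float] = (97.0, 90.0),
    min_object_px: int = 5,
    min_spur_px: int = 3,
    closing_radius_px: int = 1,
    threshold: str = "percentile",
) -> VesselNetwork:
    """Full vessel segmentation: mask, skeleton, branch points, segments.

    Accepts a 2D coronal projection (the default quantification input) or a
    3D volume.  Arc length is the cumulative voxel-to-voxel Euclidean path
    length times ``pixel_size_um``; chord length is the endpoint distance.
    An image with no vessels yields an empty network (with a warning), not
    an error.
    """
    mask = vessel_mask(
        image,
        roi_mask,
        background_sigma_px=background_sigma_px,
        hysteresis_percentiles=hysteresis_percentiles,
        min_object_px=min_object_px,
        closing_radius_px=closing_radius_px,
        threshold=threshold,
    )
    if not mask.any():
        warnings.warn("no vessels found in ROI; returning empty network",
                      stacklevel=2)
        empty = np.zeros_like(mask)
        return VesselNetwork(
            mask=mask,
            skeleton=empty,
            branch_points=np.empty((0, mask.ndim), dtype=np.int64),
            segments=[],
            pixel_size_um=pixel_size_um,
        )
    skel = morphology.skeletonize(mask)
    if min_spur_px > 0:
        skel = _prune_spurs(skel, min_spur_px)
    segments, branch_points = _extract_segments(skel, pixel_size_um)
    return VesselNetwork(
        mask=mask,
        skeleton=skel,
        branch_points=branch_points,
        segments=segments,
        pixel_size_um=pixel_size_um,
    )
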