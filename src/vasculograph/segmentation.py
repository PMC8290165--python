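"""Vessel segmentation: ROI extraction, gray-map transform, vesselness
enhancement, thresholding and seeded region growing.

The stages mirror a standard contrast-cast micro-CT workflow: restrict to
the organ region, rescale intensities robustly, enhance bright tubular
structures with a multiscale Hessian-eigenvalue (Frangi-type) filter, take
an initial threshold segmentation, and optionally repair it by homogeneity-
driven region growing. Connectivity is 26-neighbor throughout, matching the
graph-construction stage.
"""

from __future__ import annotations

import collections

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.filters import frangi, threshold_otsu

from .volume import BinaryMask, VolumeImage, warn

__all__ = [
    "extract_region",
    "transform_gray",
    "enhance_vessels",
    "threshold_segment",
    "region_grow",
    "DegenerateHistogramError",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on a (near-)constant volume is undefined."""


def extract_region(volume: VolumeImage, roi: BinaryMask) -> VolumeImage:
    """Zero every voxel outside the region of interest; keep the rest."""
    if volume.shape != roi.shape:
        raise ValueError(f"volume shape {volume.shape} != roi shape {roi.shape}")
    out = np.where(roi.values, volume.values, np.float32(0.0))
    return VolumeImage(out, volume.voxel_size)


def transform_gray(
    volume: VolumeImage, low_pct: float = 1.0, high_pct: float = 99.9
) -> VolumeImage:
    """Percentile-clipped linear rescale to [0, 1].

    The ``low_pct``/``high_pct`` intensity percentiles map to 0/1 and values
    beyond them are clipped — a robust, parameter-light gray-map transform.
    A constant volume has no usable window and maps to all zeros (warned).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("require 0 ≤ low_pct < high_pct ≤ 100")
    lo, hi = np.percentile(volume.values, [low_pct, high_pct])
    if hi - lo < 1e-12:
        vmin, vmax = float(volume.values.min()), float(volume.values.max())
        if vmax - vmin < 1e-12:
            warn("degenerate (constant) volume: gray transform returns all zeros")
            return VolumeImage(np.zeros_like(volume.values), volume.voxel_size)
        # sparse bright structures can collapse the percentile window; fall
        # back to the full range so they survive the transform
        warn("percentile window is degenerate; falling back to min/max rescale")
        lo, hi = vmin, vmax
    out = np.clip((volume.values - lo) / (hi - lo), 0.0, 1.0)
    return VolumeImage(out.astype(np.float32), volume.voxel_size)


def enhance_vessels(
    volume: VolumeImage,
    scales_um: list[float] | tuple[float, ...] = (4.5, 9.0, 13.5),
    alpha: float = 0.5,
    beta: float = 0.5,
    gamma: float | None = None,
    presmooth_um: float = 4.5,
) -> VolumeImage:
    """Multiscale Hessian-eigenvalue tubularity (bright tubes on dark).

    After a light Gaussian pre-smoothing (``presmooth_um``, suppressing
    voxel-scale noise), the Frangi vesselness is computed at each scale
    (Gaussian σ = scale in μm, converted to voxels) and the per-voxel
    maximum over scales is taken. The response is normalized to [0, 1] with
    a square-root stretch: raw vesselness is extremely right-skewed (most
    voxels near 0, centerlines near 1), and the stretch restores a bimodal
    histogram that a global threshold such as Otsu's can split at the
    vessel/background boundary. Scales should bracket the vessel radii of
    interest.
    """
    scales = [float(s) for s in scales_um]
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be a nonempty list of positive lengths (μm)")
    if max(scales) / volume.voxel_size > min(volume.shape) / 4:
        warn("largest scale exceeds ¼ of the smallest grid dimension")
    data = volume.values.astype(np.float64)
    if presmooth_um > 0:
        data = gaussian_filter(data, presmooth_um / volume.voxel_size)
    sigmas = [s / volume.voxel_size for s in scales]
    resp = frangi(
        data, sigmas=sigmas, alpha=alpha, beta=beta, gamma=gamma, black_ridges=False
    )
    peak = resp.max()
    if peak > 0:
        resp = np.sqrt(resp / peak)
    return VolumeImage(resp.astype(np.float32), volume.voxel_size)


def threshold_segment(
    volume: VolumeImage, method: str = "otsu", value: float | None = None
) -> BinaryMask:
    """Initial vessel segmentation by global thresholding.

    Voxels strictly above the threshold are foreground (ties → background).
    The chosen threshold is recorded in the mask's ``provenance``.
    """
    if method == "otsu":
        vmin, vmax = float(volume.values.min()), float(volume.values.max())
        if vmax - vmin < 1e-12:
            raise DegenerateHistogramError(
                "otsu thresholding undefined on a constant volume"
            )
        thr = float(threshold_otsu(volume.values))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = BinaryMask(volume.values > thr, volume.voxel_size)
    mask.provenance.update({"method": method, "threshold": thr, "comparison": "strictly_greater"})
    return mask


def region_grow(
    mask: BinaryMask,
    volume: VolumeImage,
    seeds: list[tuple[int, int, int]],
    tol: float,
    max_dilation: int = 2,
) -> BinaryMask:
    """Seeded region growing with a running-mean homogeneity criterion.

    Starting from the mask components containing the seeds, 26-connected
    voxels are absorbed while their intensity stays within ``tol`` of the
    running mean of the grown region. Growth is confined to a
    ``max_dilation``-step dilation of the input mask, so the algorithm
    bridges small gaps without flooding the background. The result always
    contains the seed components of the input mask.
    """
    if volume.shape != mask.shape:
        raise ValueError("mask and volume shapes differ")
    if not seeds:
        warn("region_grow called without seeds; returning mask unchanged")
        return BinaryMask(mask.values.copy(), mask.voxel_size)
    shape = mask.shape
    for s in seeds:
        if any(not 0 <= c < n for c, n in zip(s, shape)):
            raise ValueError(f"seed {s} outside grid {shape}")

    bound = ndimage.binary_dilation(mask.values, _STRUCT26, iterations=max_dilation)
    labels, _ = ndimage.label(mask.values, structure=_STRUCT26)
    seed_labels = {labels[tuple(s)] for s in seeds} - {0}
    grown = np.isin(labels, sorted(seed_labels)) if seed_labels else np.zeros(shape, bool)
    vals = volume.values
    total = float(vals[grown].sum())
    count = int(grown.sum())
    if count == 0:  # seeds off the mask: start from the seed voxels themselves
        for s in seeds:
            if not grown[tuple(s)]:
                grown[tuple(s)] = True
                total += float(vals[tuple(s)])
                count += 1

    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    queue = collections.deque(zip(*np.nonzero(grown)))
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx_ = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx_ < shape[2]):
                continue
            if grown[nz, ny, nx_] or not bound[nz, ny, nx_]:
                continue
            if abs(float(vals[nz, ny, nx_]) - total / count) <= tol:
                grown[nz, ny, nx_] = True
                total += float(vals[nz, ny, nx_])
                count += 1
                queue.append((nz, ny, nx_))
    out = BinaryMask(grown, mask.voxel_size)
    out.provenance.update({"tol": float(tol), "seeds": [tuple(map(int, s)) for s in seeds]})
    return out
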