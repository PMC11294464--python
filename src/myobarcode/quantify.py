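"""Image quantification operators.

Implements the measurement chain applied to myotome cross-sections:
Gaussian-blur preprocessing, oblique cross-sectioning of volumes, watershed
fiber segmentation on the membrane channel (with external label-mask
passthrough), scale-normalized Laplacian-of-Gaussian nucleus detection with a
MAD-normalized quality gate, centroid-based nucleus-to-fiber assignment,
voxel-count volume measurement, Otsu labeled-area fractions, and fiber
counting.

Coordinates are 0-based voxel indices in (z, y, x) (or (y, x) in 2-D) with
half-open extents; physical position in µm is index × voxel size
(voxel-center convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from skimage.feature import peak_local_max

__all__ = [
    "QuantConfig",
    "NucleusDetection",
    "preprocess",
    "cross_section",
    "segment_fibers",
    "detect_nuclei",
    "assign_nuclei_to_fibers",
    "measure_volume",
    "labeled_area_fraction",
    "count_fibers",
]


@dataclass
class QuantConfig:
    """Measurement parameters.

    ``blur_sigma`` is the preprocessing Gaussian sigma in pixels. Nucleus
    spot counting uses a physical blob ``nucleus_diameter`` (µm) and a
    signal-to-noise ``nucleus_quality_min`` gate. The 8-bit surface
    thresholds (myotome 50, fiber 240) are applied after linear rescale of
    each channel to [0, 255]. Surface thicknesses (0.9 / 0.2 µm) are carried
    for provenance; volumes are voxel-count based.
    """

    blur_sigma: float = 2.0
    nucleus_diameter: float = 7.0       # µm
    nucleus_quality_min: float = 3.0
    myotome_surface_threshold: float = 50.0
    fiber_surface_threshold: float = 240.0
    myotome_surface_thickness: float = 0.9   # µm, provenance only
    fiber_surface_thickness: float = 0.2     # µm, provenance only
    area_threshold_method: str = "otsu"      # 'otsu' | 'fixed'

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.nucleus_diameter <= 0:
            raise ValueError("nucleus_diameter must be > 0")
        for name in ("myotome_surface_threshold", "fiber_surface_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be in [0, 255]")
        if self.area_threshold_method not in ("otsu", "fixed"):
            raise ValueError("area_threshold_method must be 'otsu' or 'fixed'")


@dataclass
class NucleusDetection:
    """One detected nucleus: centroid in µm and SNR-style quality score."""

    centroid: tuple[float, ...]   # µm, same axis order as the input grid
    quality: float

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError("quality must be >= 0")


def rescale_8bit(img: np.ndarray) -> np.ndarray:
    """Linear rescale of one channel to [0, 255] (constant images -> 0)."""
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def preprocess(img: np.ndarray, config: QuantConfig | None = None) -> np.ndarray:
    """Gaussian-blur a copy of the image; sigma 0 returns an exact copy."""
    config = config or QuantConfig()
    img = np.asarray(img, dtype=float)
    if any(s < 2 for s in img.shape):
        raise ValueError("image must have at least 2 pixels per axis")
    if config.blur_sigma == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma=config.blur_sigma)


def cross_section(volume: np.ndarray, point: np.ndarray, normal: np.ndarray,
                  voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                  shape: tuple[int, int] | None = None) -> np.ndarray:
    """Bilinear resample of a 3-D grid along an arbitrary plane.

    The plane passes through ``point`` (voxel coordinates, (z, y, x)) with
    unit ``normal``. Output pixel size equals the in-plane voxel size.
    Axis-aligned planes reproduce the corresponding slice exactly.
    """
    volume = np.asarray(volume, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("degenerate plane normal")
    normal = normal / nn
    point = np.asarray(point, dtype=float)
    if ((point < 0) | (point > np.array(volume.shape) - 1)).any():
        raise ValueError("plane point lies outside the volume")

    # in-plane orthonormal basis (deterministic choice)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    if shape is None:
        side = int(math.ceil(np.linalg.norm(volume.shape)))
        shape = (side, side)
    h, w = shape
    a = np.arange(h) - (h - 1) / 2.0
    b = np.arange(w) - (w - 1) / 2.0
    A, B = np.meshgrid(a, b, indexing="ij")
    coords = (point[:, None, None]
              + u[:, None, None] * A[None] + v[:, None, None] * B[None])
    return ndi.map_coordinates(volume, coords, order=1, mode="constant",
                               cval=0.0)


def axis_slice(volume: np.ndarray, axis: int, index: int) -> np.ndarray:
    """Exact axis-aligned slice, the degenerate fast path of cross_section."""
    if not (0 <= index < volume.shape[axis]):
        raise ValueError("plane outside volume")
    return np.take(volume, index, axis=axis).astype(float)


def segment_fibers(membrane: np.ndarray,
                   seeds: np.ndarray | None = None,
                   external_mask: np.ndarray | None = None,
                   config: QuantConfig | None = None) -> np.ndarray:
    """Segment fibers by watershed on the membrane channel.

    Membrane signal is assumed brighter than fiber interiors; the watershed
    floods from interior minima (or from provided ``seeds``, an (n, 2) array
    of (y, x) marker positions). An ``external_mask`` (e.g. a Cellpose label
    map) is passed through unchanged. Labels are 1..K, background 0; ties are
    resolved deterministically by raster order of the markers.
    """
    if external_mask is not None:
        return np.asarray(external_mask).copy()
    config = config or QuantConfig()
    membrane = np.asarray(membrane, dtype=float)
    if membrane.max() <= membrane.min():
        warnings.warn("blank membrane image: no fibers segmented")
        return np.zeros(membrane.shape, dtype=np.int32)
    smoothed = preprocess(membrane, config)
    if seeds is None:
        # markers = connected interiors below the membrane ridge level
        thr = threshold_otsu(smoothed)
        interior = smoothed < thr
        markers, _ = ndi.label(interior)  # raster-order labeling
    else:
        markers = np.zeros(membrane.shape, dtype=np.int32)
        for k, (y, x) in enumerate(np.asarray(seeds, dtype=int), start=1):
            markers[y, x] = k
    return watershed(smoothed, markers).astype(np.int32)


def detect_nuclei(channel: np.ndarray, config: QuantConfig | None = None,
                  voxel_size: float | tuple[float, ...] = 1.0
                  ) -> list[NucleusDetection]:
    """Detect nuclei as scale-normalized Laplacian-of-Gaussian blobs.

    The LoG scale is sigma = diameter / (2*sqrt(2)). The per-detection quality
    score is the peak response divided by the robust noise of the response
    map (1.4826 × median absolute deviation); detections below
    ``nucleus_quality_min`` are discarded, and non-maximum suppression keeps
    one detection per blob within one diameter.
    """
    config = config or QuantConfig()
    channel = np.asarray(channel, dtype=float)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * channel.ndim
    voxel_size = tuple(float(v) for v in voxel_size)
    sigma_um = config.nucleus_diameter / (2.0 * math.sqrt(2.0))
    sigma_px = tuple(sigma_um / v for v in voxel_size)
    if config.nucleus_diameter < 2 * max(voxel_size):
        raise ValueError("nucleus_diameter smaller than 2 voxels")

    # scale-normalized LoG: bright blobs give positive peaks
    response = -np.mean(np.array(sigma_px) ** 2) \
        * ndi.gaussian_laplace(channel, sigma=sigma_px)
    mad = np.median(np.abs(response - np.median(response)))
    noise = 1.4826 * mad
    if noise == 0:
        return []

    min_dist = max(int(round(config.nucleus_diameter / max(voxel_size))), 1)
    peaks = peak_local_max(response, min_distance=min_dist,
                           threshold_abs=noise * config.nucleus_quality_min,
                           exclude_border=False)
    out = []
    for p in peaks:
        q = float(response[tuple(p)] / noise)
        if q >= config.nucleus_quality_min:
            centroid = tuple(float(c) * v for c, v in zip(p, voxel_size))
            out.append(NucleusDetection(centroid=centroid, quality=q))
    out.sort(key=lambda d: d.centroid)
    return out


def assign_nuclei_to_fibers(detections: list[NucleusDetection],
                            labels: np.ndarray,
                            voxel_size: float | tuple[float, ...] = 1.0
                            ) -> dict[int, int]:
    """Count detections per fiber by the label containing each centroid.

    Centroids on background (label 0) are tallied under key 0; counts are
    conserved: sum of all values equals the number of detections.
    """
    labels = np.asarray(labels)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * labels.ndim
    counts: dict[int, int] = {int(k): 0 for k in np.unique(labels)}
    for d in detections:
        if len(d.centroid) != labels.ndim:
            raise ValueError("detection and label-map dimensionality differ")
        idx = tuple(min(max(int(math.floor(c / v + 0.5)), 0), s - 1)
                    for c, v, s in zip(d.centroid, voxel_size, labels.shape))
        lab = int(labels[idx])
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def measure_volume(mask: np.ndarray,
                   voxel_size: tuple[float, ...],
                   config: QuantConfig | None = None,
                   prerescaled: bool = False) -> float:
    """Fiber volume in µm³: voxels above the fiber surface threshold × voxel volume.

    Boolean masks are counted directly. Intensity inputs are linearly
    rescaled to 8-bit range first (unless ``prerescaled``) and thresholded at
    ``fiber_surface_threshold``.
    """
    config = config or QuantConfig()
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel sizes must be > 0")
    mask = np.asarray(mask)
    if mask.dtype == bool:
        above = mask
    else:
        img = mask.astype(float) if prerescaled else rescale_8bit(mask)
        above = img >= config.fiber_surface_threshold
    return float(above.sum()) * float(np.prod(voxel_size))


def labeled_area_fraction(color_channels: np.ndarray,
                          compartment_mask: np.ndarray,
                          config: QuantConfig | None = None) -> float:
    """Percent of the compartment area occupied by tagged (colored) fibers.

    The color channels are max-projected, Otsu-thresholded within the mask
    (or thresholded at the fixed myotome level when configured), and the
    above-threshold fraction of mask pixels is returned ×100. A constant
    image has no Otsu threshold and returns 0 with a warning.
    """
    config = config or QuantConfig()
    compartment_mask = np.asarray(compartment_mask, dtype=bool)
    if not compartment_mask.any():
        raise ValueError("compartment mask is empty")
    proj = np.max(np.asarray(color_channels, dtype=float), axis=0) \
        if np.asarray(color_channels).ndim == 3 else \
        np.asarray(color_channels, dtype=float)
    vals = rescale_8bit(proj)[compartment_mask]
    if np.ptp(vals) == 0:
        warnings.warn("constant image within mask: threshold undefined, "
                      "returning 0")
        return 0.0
    if config.area_threshold_method == "otsu":
        thr = threshold_otsu(vals)
    else:
        thr = config.myotome_surface_threshold
    return float((vals > thr).mean() * 100.0)


def count_fibers(labels: np.ndarray,
                 myotome_of_label: dict[int, int] | None = None
                 ) -> tuple[int, pd.Series | None]:
    """Number of distinct nonzero labels, optionally aggregated per myotome."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids != 0]
    total = int(len(ids))
    if myotome_of_label is None:
        return total, None
    per = pd.Series({int(i): myotome_of_label.get(int(i), -1) for i in ids})
    return total, per.groupby(per).size().rename("n_fibers")
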