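"""Color-barcode analysis: CIELAB conversion, delta-E, and hue clustering.

A fiber's barcode is its triple of fluorophore channel proportions (after
background subtraction and normalization), interpreted as linear-RGB
primaries — confocal intensities are linear, so no gamma is applied — and
converted through the standard sRGB primary matrix to XYZ and on to CIELAB
under the D65 white point. Color differences use CIE76 (Euclidean distance
in Lab) by default, with CIEDE2000 available for sensitivity analysis.
Distinct hues are defined by agglomerative clustering of the pairwise
delta-E matrix cut at the threshold 37.4; under complete linkage every
intra-cluster pair then differs by at most the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "BarcodeConfig",
    "ColorBarcode",
    "fiber_mean_color",
    "rgb_to_lab",
    "delta_e",
    "cluster_hues",
    "barcode_distance",
]


@dataclass
class BarcodeConfig:
    """Delta-E metric, clustering threshold and linkage, background handling."""

    de_metric: str = "CIE76"        # 'CIE76' | 'CIEDE2000'
    de_threshold: float = 37.4
    linkage: str = "complete"       # 'complete' | 'single'
    background_percentile: float = 5.0
    de_saturation: float = 100.0    # normalization for tracking costs

    def __post_init__(self) -> None:
        if self.de_threshold <= 0:
            raise ValueError("de_threshold must be > 0")
        if self.de_metric not in ("CIE76", "CIEDE2000"):
            raise ValueError("de_metric must be 'CIE76' or 'CIEDE2000'")
        if self.linkage not in ("complete", "single"):
            raise ValueError("linkage must be 'complete' or 'single'")


@dataclass
class ColorBarcode:
    """One fiber's color: raw channel proportions, Lab coordinates, cluster."""

    fiber_id: int
    raw_rgb: tuple[float, float, float]
    lab: tuple[float, float, float] | None = None
    hue_cluster: int | None = None

    def __post_init__(self) -> None:
        if any(c < 0 or c > 1 for c in self.raw_rgb):
            raise ValueError("raw_rgb components must be in [0, 1]")
        if self.lab is None:
            self.lab = rgb_to_lab(self.raw_rgb)


def fiber_mean_color(channels: np.ndarray, labels: np.ndarray, fiber_id: int,
                     config: BarcodeConfig | None = None,
                     _norm: float | None = None) -> tuple[float, float, float]:
    """Background-corrected, normalized channel proportions of one fiber.

    Per channel: median over the fiber's pixels, minus the
    ``background_percentile`` value of the background (label 0) region,
    clipped at 0, then divided by the maximum corrected channel median found
    anywhere in the image (precomputable via ``_norm`` for batch use).
    """
    config = config or BarcodeConfig()
    channels = np.asarray(channels, dtype=float)
    labels = np.asarray(labels)
    mask = labels == fiber_id
    if not mask.any():
        raise ValueError(f"label {fiber_id} not present in label map")
    bg = labels == 0
    med = np.array([np.median(ch[mask]) for ch in channels])
    if bg.any():
        floor = np.array([np.percentile(ch[bg], config.background_percentile)
                          for ch in channels])
    else:
        floor = np.zeros(len(channels))
    corrected = np.clip(med - floor, 0.0, None)
    if _norm is None:
        _norm = _image_norm(channels, labels, config)
    if _norm <= 0:
        return (0.0, 0.0, 0.0)
    return tuple(np.clip(corrected / _norm, 0.0, 1.0))


def _image_norm(channels: np.ndarray, labels: np.ndarray,
                config: BarcodeConfig) -> float:
    """Max background-corrected channel median over all fibers in the image."""
    bg = labels == 0
    floor = np.array([np.percentile(ch[bg], config.background_percentile)
                      if bg.any() else 0.0 for ch in channels])
    best = 0.0
    for fid in np.unique(labels):
        if fid == 0:
            continue
        m = labels == fid
        med = np.array([np.median(ch[m]) for ch in channels]) - floor
        best = max(best, float(med.max()))
    return best


# sRGB primaries -> XYZ (D65), linear domain
_RGB2XYZ = np.array([[0.4124564, 0.3575761, 0.1804375],
                     [0.2126729, 0.7151522, 0.0721750],
                     [0.0193339, 0.1191920, 0.9503041]])
# D65 white point taken as the image of (1,1,1), so the neutral axis maps
# exactly onto a = b = 0 despite the matrix's printed-precision rounding
_D65 = _RGB2XYZ @ np.ones(3)


def _lab_f(t: np.ndarray) -> np.ndarray:
    d = 6.0 / 29.0
    return np.where(t > d ** 3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)


def rgb_to_lab(rgb) -> tuple[float, float, float]:
    """Linear-RGB triple in [0,1] -> CIELAB (L, a, b) under D65.

    Inputs are linear intensities (no sRGB gamma decoding), mapped through
    the sRGB primary matrix to XYZ and then the standard CIELAB transform.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,) or (rgb < 0).any() or (rgb > 1).any():
        raise ValueError("rgb must be a 3-vector in [0, 1]")
    xyz = _RGB2XYZ @ rgb
    fx, fy, fz = _lab_f(xyz / _D65)
    L = 116.0 * fy - 16.0
    return (float(L), float(500.0 * (fx - fy)), float(200.0 * (fy - fz)))


def delta_e(lab1, lab2, metric: str = "CIE76") -> float:
    """Color difference between two Lab triples (CIE76 or CIEDE2000)."""
    l1 = np.asarray(lab1, dtype=float)
    l2 = np.asarray(lab2, dtype=float)
    if metric == "CIE76":
        return float(np.linalg.norm(l1 - l2))
    if metric == "CIEDE2000":
        return _ciede2000(l1, l2)
    raise ValueError(f"unknown delta-E metric {metric!r}")


def _ciede2000(lab1: np.ndarray, lab2: np.ndarray,
               kL: float = 1.0, kC: float = 1.0, kH: float = 1.0) -> float:
    """CIEDE2000 color difference (Sharma, Wu & Dalal formulation)."""
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = (C1 + C2) / 2.0
    G = 0.5 * (1 - math.sqrt(Cbar ** 7 / (Cbar ** 7 + 25.0 ** 7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)
    h1p = math.degrees(math.atan2(b1, a1p)) % 360 if C1p else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360 if C2p else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    else:
        dh = h2p - h1p
        if dh > 180:
            dh -= 360
        elif dh < -180:
            dh += 360
        dhp = dh
    dHp = 2 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2)

    Lbp = (L1 + L2) / 2
    Cbp = (C1p + C2p) / 2
    if C1p * C2p == 0:
        hbp = h1p + h2p
    else:
        s = h1p + h2p
        if abs(h1p - h2p) > 180:
            hbp = (s + 360) / 2 if s < 360 else (s - 360) / 2
        else:
            hbp = s / 2
    T = (1 - 0.17 * math.cos(math.radians(hbp - 30))
         + 0.24 * math.cos(math.radians(2 * hbp))
         + 0.32 * math.cos(math.radians(3 * hbp + 6))
         - 0.20 * math.cos(math.radians(4 * hbp - 63)))
    dtheta = 30 * math.exp(-(((hbp - 275) / 25) ** 2))
    RC = 2 * math.sqrt(Cbp ** 7 / (Cbp ** 7 + 25.0 ** 7))
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / math.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2 * dtheta)) * RC
    return math.sqrt((dLp / (kL * SL)) ** 2 + (dCp / (kC * SC)) ** 2
                     + (dHp / (kH * SH)) ** 2
                     + RT * (dCp / (kC * SC)) * (dHp / (kH * SH)))


def cluster_hues(barcodes: list[ColorBarcode],
                 config: BarcodeConfig | None = None) -> int:
    """Cluster barcodes into distinct hues at the delta-E threshold.

    Agglomerative clustering on the pairwise delta-E matrix with the
    configured linkage, cut at ``de_threshold``. The result is invariant to
    input order: barcodes are canonicalized by sorted Lab coordinates before
    linkage, and cluster ids are renumbered 1..K by each cluster's smallest
    canonical member. Assigns ``hue_cluster`` in place and returns the
    cluster count.
    """
    config = config or BarcodeConfig()
    if not barcodes:
        raise ValueError("at least one barcode is required")
    if len(barcodes) == 1:
        barcodes[0].hue_cluster = 1
        return 1
    labs = np.array([b.lab for b in barcodes], dtype=float)
    order = np.lexsort((labs[:, 2], labs[:, 1], labs[:, 0]))
    sorted_labs = labs[order]
    if config.de_metric == "CIE76":
        diff = sorted_labs[:, None, :] - sorted_labs[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(axis=2))
    else:
        n = len(sorted_labs)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = _ciede2000(sorted_labs[i],
                                                     sorted_labs[j])
    Z = _scipy_linkage(squareform(dmat, checks=False), method=config.linkage)
    raw = fcluster(Z, t=config.de_threshold, criterion="distance")
    # renumber clusters by smallest canonical member index
    first = {}
    for idx, c in enumerate(raw):
        first.setdefault(c, idx)
    remap = {c: k for k, c in enumerate(
        sorted(first, key=lambda c: first[c]), start=1)}
    assign_sorted = np.array([remap[c] for c in raw])
    for pos, orig_idx in enumerate(order):
        barcodes[orig_idx].hue_cluster = int(assign_sorted[pos])
    return int(assign_sorted.max())


def barcode_distance(a: ColorBarcode, b: ColorBarcode,
                     config: BarcodeConfig | None = None) -> float:
    """Normalized color cost in [0, 1]: delta-E / saturation, clipped."""
    config = config or BarcodeConfig()
    de = delta_e(a.lab, b.lab, config.de_metric)
    return min(de / config.de_saturation, 1.0)
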