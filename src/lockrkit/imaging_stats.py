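"""Co-localization coefficients and puncta quantification.

Implements the two standard pixel-overlap statistics (Pearson correlation
over a mask; Manders M1/M2 split coefficients against per-channel
thresholds) and ImageJ-style particle analysis: threshold, label connected
components (8-connectivity), and retain components passing circularity
(> 0.5) and area (> 1 um^2) cutoffs.  Circularity is 4*pi*A/P^2 with the
perimeter estimated by the Crofton formula; digitised perimeters bias this
statistic for small regions, so values are capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "Punctum",
    "PunctaSet",
    "ColocResult",
    "RegionRatioStats",
    "pearson_coloc",
    "manders_coloc",
    "detect_puncta",
    "region_ratio_stats",
]

CIRCULARITY_CUTOFF = 0.5
AREA_CUTOFF_UM2 = 1.0


@dataclass(frozen=True)
class Punctum:
    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]
    mean_intensity: float


@dataclass
class PunctaSet:
    """Connected components surviving the circularity and area filters."""

    components: list[Punctum]
    mask: np.ndarray  # boolean mask of retained puncta pixels
    threshold: float
    threshold_method: str
    n_rejected: int

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float | None
    manders_m1: float | None
    manders_m2: float | None
    threshold_a: float | None = None
    threshold_b: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegionRatioStats:
    mean_ratio_puncta: float
    mean_ratio_diffuse: float | None
    per_punctum_means: tuple[float, ...]
    flags: tuple[str, ...] = ()


def _masked(channel: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    if mask is None:
        return channel.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != channel.shape:
        raise ValueError("mask shape does not match channel")
    if not mask.any():
        raise ValueError("empty mask")
    return channel[mask]


def pearson_coloc(
    channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation of the two channels' intensities over the mask.

    Ranges -1 (inversely proportional) to 1 (identical up to affine gain).
    Zero variance in either channel makes the statistic undefined (NaN,
    with a warning).
    """
    a = _masked(channel_a, mask)
    b = _masked(channel_b, mask)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance; Pearson coefficient undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def manders_coloc(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Manders split coefficients (M1, M2) over the mask.

    M1 is the fraction of channel-a intensity in pixels where channel b is
    above its threshold; M2 is the symmetric quantity.  Thresholds default
    to Otsu per channel within the mask.  Both coefficients lie in [0, 1].
    """
    a = _masked(channel_a, mask)
    b = _masked(channel_b, mask)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if thresholds is None:
        thresholds = (float(threshold_otsu(a)), float(threshold_otsu(b)))
    t_a, t_b = thresholds
    if t_a < 0 or t_b < 0:
        raise ValueError("thresholds must be non-negative")
    tot_a, tot_b = a.sum(), b.sum()
    if tot_a <= 0 or tot_b <= 0:
        warnings.warn("zero total intensity; Manders undefined", stacklevel=2)
        return float("nan"), float("nan")
    m1 = float(a[b > t_b].sum() / tot_a)
    m2 = float(b[a > t_a].sum() / tot_b)
    return m1, m2


def detect_puncta(
    image: np.ndarray,
    pixel_size_um: float,
    threshold_method: str | float | Callable[[np.ndarray], float] = "otsu",
    *,
    mask: np.ndarray | None = None,
    circularity_cutoff: float = CIRCULARITY_CUTOFF,
    area_cutoff_um2: float = AREA_CUTOFF_UM2,
) -> PunctaSet:
    """Threshold, label and filter bright particles.

    The image (optionally restricted to ``mask``) is thresholded (Otsu by
    default, or a fixed value / callable), connected components are labelled
    with 8-connectivity, and components are retained when circularity
    4*pi*A/P^2 exceeds ``circularity_cutoff`` (strict) and area exceeds
    ``area_cutoff_um2`` (strict).  An image with nothing above threshold
    yields an empty set, not an error.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    image = np.asarray(image, dtype=float)
    pixels = image[mask] if mask is not None else image.ravel()
    if callable(threshold_method):
        thr, method_name = float(threshold_method(pixels)), "callable"
    elif threshold_method == "otsu":
        if np.ptp(pixels) == 0:
            return PunctaSet([], np.zeros_like(image, bool), float(pixels.flat[0]), "otsu", 0)
        thr, method_name = float(threshold_otsu(pixels)), "otsu"
    else:
        thr, method_name = float(threshold_method), "fixed"
    binary = image > thr
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    labels = cc_label(binary, connectivity=2)
    px_area = pixel_size_um**2
    kept: list[Punctum] = []
    keep_mask = np.zeros_like(binary)
    n_rejected = 0
    for rp in regionprops(labels, intensity_image=image):
        area = rp.area * px_area
        perim = rp.perimeter_crofton * pixel_size_um
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        circ = min(circ, 1.0)
        if circ > circularity_cutoff and area > area_cutoff_um2:
            kept.append(
                Punctum(
                    label=rp.label,
                    area_um2=float(area),
                    perimeter_um=float(perim),
                    circularity=float(circ),
                    centroid=tuple(map(float, rp.centroid)),
                    mean_intensity=float(rp.intensity_mean),
                )
            )
            keep_mask[labels == rp.label] = True
        else:
            n_rejected += 1
    return PunctaSet(kept, keep_mask, thr, method_name, n_rejected)


def region_ratio_stats(
    ratio_field: np.ndarray,
    puncta_mask: np.ndarray,
    cell_mask: np.ndarray,
    puncta_labels: np.ndarray | None = None,
) -> RegionRatioStats:
    """Mean ratio inside puncta versus the diffuse (cell minus puncta) region.

    ``puncta_mask`` must be contained in ``cell_mask``.  If the puncta fill
    the whole cell the diffuse mean is undefined and flagged.  Per-punctum
    means use ``puncta_labels`` when given, else connected components of the
    mask.
    """
    ratio_field = np.ma.asarray(ratio_field)
    puncta_mask = np.asarray(puncta_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if (puncta_mask & ~cell_mask).any():
        raise ValueError("puncta mask extends outside the cell mask")
    flags: list[str] = []
    mean_puncta = (
        float(ratio_field[puncta_mask].mean()) if puncta_mask.any() else float("nan")
    )
    if not puncta_mask.any():
        flags.append("no_puncta")
    diffuse = cell_mask & ~puncta_mask
    if diffuse.any():
        mean_diffuse = float(ratio_field[diffuse].mean())
    else:
        mean_diffuse = None
        flags.append("empty_diffuse_region")
    if puncta_labels is None:
        puncta_labels = cc_label(puncta_mask, connectivity=2)
    per = tuple(
        float(ratio_field[puncta_labels == lbl].mean())
        for lbl in np.unique(puncta_labels)
        if lbl != 0
    )
    return RegionRatioStats(mean_puncta, mean_diffuse, per, tuple(flags))
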