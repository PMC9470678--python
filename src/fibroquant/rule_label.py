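"""Rule-based five-class tissue labeling of a limb CT cross-section.

The pipeline mirrors the semiautomatic labeling workflow used to build
ground truth for fibrosis quantification:

1. binarize the slice into body vs air and fill interior holes;
2. erode the body; the removed band along the boundary is *skin*;
3. within the eroded interior, select *muscle/water* by an HU window
   (default −34..26 HU, inclusive);
4. the remaining "donut" (subcutaneous annulus) is split into *fat* and
   *fibrosis* by 1-D k-means (k=2) on HU values — the lower-mean cluster is
   fat, the higher-mean cluster is fibrosis;
5. everything outside the body is *air*.

Blood vessels inside the donut are deliberately labeled fibrosis: paired-limb
indices difference them out under the assumption that vessel area is nearly
equal in the affected and unaffected limb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import morphology

from fibroquant._constants import AIR, FAT, FIBROSIS, MUSCLE_WATER, SKIN
from fibroquant.ct_io import CTSlice, LabelMap

__all__ = [
    "RuleParams",
    "EmptyBodyError",
    "DegenerateBodyError",
    "binarize_body",
    "extract_skin",
    "extract_muscle_water",
    "donut_region",
    "split_fat_fibrosis",
    "label_slice",
]


class EmptyBodyError(ValueError):
    """No pixel exceeds the body threshold."""


class DegenerateBodyError(ValueError):
    """Erosion removes the body entirely (object thinner than 2×radius)."""


@dataclass
class RuleParams:
    """Parameters of the rule-based labeling pipeline.

    ``mw_low``/``mw_high`` bound the muscle/water HU window (closed interval,
    −34..26 HU).  ``body_threshold`` separates body from air; −200 HU sits
    robustly between fat (≈ −90) and air (−1000).  ``skin_erosion_radius``
    sets the skin band thickness in pixels (~1 mm at 0.5 mm spacing for the
    default of 2).  ``bone_threshold``, when set, reassigns HU ≥ threshold to
    muscle/water instead of letting dense tissue fall into the fibrosis
    cluster; it is off by default.  The k-means split is deterministic given
    ``kmeans_init``; ties break toward the lower-HU cluster.
    """

    body_threshold: float = -200.0
    skin_erosion_radius: int = 2
    mw_low: float = -34.0
    mw_high: float = 26.0
    bone_threshold: Optional[float] = None
    kmeans_seed: int = 0
    kmeans_init: tuple[float, float] = (-80.0, 40.0)

    def __post_init__(self) -> None:
        if not self.mw_low < self.mw_high:
            raise ValueError("mw_low must be below mw_high")
        if self.skin_erosion_radius < 1:
            raise ValueError("skin_erosion_radius must be >= 1")
        if self.kmeans_init[0] == self.kmeans_init[1]:
            raise ValueError("k-means init centroids must be distinct")


def _largest_components_per_limb(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component in each image half.

    A paired-limb slice shows one body region per half; keeping the largest
    component per half drops table edges, cables and noise specks while
    retaining both limbs.
    """
    out = np.zeros_like(mask)
    mid = mask.shape[1] // 2
    for sl in (np.s_[:, :mid], np.s_[:, mid:]):
        lbl, n = ndimage.label(mask[sl])
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        out[sl] = lbl == (1 + int(np.argmax(sizes)))
    if not out.any():
        # single-limb or degenerate framing: fall back to global largest
        lbl, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        out = lbl == (1 + int(np.argmax(sizes)))
    return out


def binarize_body(sl: CTSlice, params: RuleParams) -> np.ndarray:
    """Binary body mask: HU above threshold, largest component per limb
    half, interior holes filled."""
    raw = sl.pixels > params.body_threshold
    if not raw.any():
        raise EmptyBodyError("no pixel above the body threshold")
    body = _largest_components_per_limb(raw)
    return ndimage.binary_fill_holes(body)


def extract_skin(body: np.ndarray, params: RuleParams) -> np.ndarray:
    """Skin = body minus its erosion by a disk of the configured radius."""
    if not body.any():
        raise EmptyBodyError("empty body mask")
    interior = ndimage.binary_erosion(body, structure=morphology.disk(params.skin_erosion_radius))
    if not interior.any():
        raise DegenerateBodyError(
            f"erosion radius {params.skin_erosion_radius} removes the body entirely"
        )
    return body & ~interior


def body_interior(body: np.ndarray, params: RuleParams) -> np.ndarray:
    """The eroded body (body minus skin band)."""
    interior = ndimage.binary_erosion(body, structure=morphology.disk(params.skin_erosion_radius))
    if not interior.any():
        raise DegenerateBodyError(
            f"erosion radius {params.skin_erosion_radius} removes the body entirely"
        )
    return interior


def extract_muscle_water(sl: CTSlice, interior: np.ndarray, params: RuleParams) -> np.ndarray:
    """Muscle/water: interior pixels inside the closed HU window
    [mw_low, mw_high]; optionally also HU ≥ bone_threshold."""
    hu = sl.pixels
    mask = (hu >= params.mw_low) & (hu <= params.mw_high) & interior
    if params.bone_threshold is not None:
        mask |= (hu >= params.bone_threshold) & interior
    return mask


def donut_region(interior: np.ndarray, mw: np.ndarray) -> np.ndarray:
    """Subcutaneous annulus: interior minus muscle/water."""
    if (mw & ~interior).any():
        raise ValueError("muscle/water mask is not a subset of the interior")
    return interior & ~mw


def kmeans_1d_two(
    values: np.ndarray,
    init: tuple[float, float] = (-80.0, 40.0),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Deterministic 1-D k-means with k=2.

    For scalar data the two-cluster k-means objective is minimized by a
    single threshold between consecutive sorted values, so the global
    optimum is found directly by a prefix-sum scan over all splits — no
    iterative restarts, no initialization sensitivity.  The returned
    partition is a Lloyd fixed point: the decision boundary equals the
    midpoint of the two final centroids, with ties assigned to the lower
    cluster.  Among splits of equal cost the one with the larger low
    cluster wins.

    Returns a boolean array (True = higher-mean cluster) and the final
    (low, high) centroids.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 1:
        # degenerate: nearest-init-centroid assignment
        high = abs(v[0] - init[1]) < abs(v[0] - init[0])
        c = (init[0], v[0]) if high else (v[0], init[1])
        return np.array([high]), c
    s = np.sort(v)
    n = s.size
    csum = np.cumsum(s)
    k = np.arange(1, n)  # low-cluster sizes
    lo_mean = csum[:-1] / k
    hi_mean = (csum[-1] - csum[:-1]) / (n - k)
    # within-cluster SSE decomposes as total SS minus between-cluster term
    between = k * lo_mean**2 + (n - k) * hi_mean**2
    # equal adjacent values must not straddle the threshold
    valid = s[1:] > s[:-1]
    between = np.where(valid, between, -np.inf)
    best = int(len(between) - 1 - np.argmax(between[::-1]))  # ties -> larger low cluster
    lo, hi = lo_mean[best], hi_mean[best]
    thr = (s[best] + s[best + 1]) / 2.0  # any point in the gap separates them
    high = v > thr
    return high, (float(lo), float(hi))


def split_fat_fibrosis(
    sl: CTSlice, donut: np.ndarray, params: RuleParams
) -> tuple[np.ndarray, np.ndarray]:
    """Split the donut into fat (lower-HU cluster) and fibrosis (higher-HU).

    Empty donut returns two empty masks; a donut with one distinct HU value
    is assigned entirely to fat (with nothing to separate, the lower class
    wins) — callers may warn.
    """
    fat = np.zeros_like(donut)
    fib = np.zeros_like(donut)
    if not donut.any():
        return fat, fib
    vals = sl.pixels[donut]
    if np.all(vals == vals[0]):
        fat |= donut
        return fat, fib
    high, _ = kmeans_1d_two(vals, params.kmeans_init)
    idx = np.flatnonzero(donut.ravel())
    fat_flat = np.zeros(donut.size, dtype=bool)
    fib_flat = np.zeros(donut.size, dtype=bool)
    fat_flat[idx[~high]] = True
    fib_flat[idx[high]] = True
    return fat_flat.reshape(donut.shape), fib_flat.reshape(donut.shape)


def label_slice(sl: CTSlice, params: RuleParams | None = None) -> LabelMap:
    """Run the full pipeline: every pixel gets exactly one of the five codes."""
    params = params or RuleParams()
    body = binarize_body(sl, params)
    skin = extract_skin(body, params)
    interior = body & ~skin
    mw = extract_muscle_water(sl, interior, params)
    donut = donut_region(interior, mw)
    fat, fib = split_fat_fibrosis(sl, donut, params)

    labels = np.full(sl.shape, AIR, dtype=np.uint8)
    labels[skin] = SKIN
    labels[mw] = MUSCLE_WATER
    labels[fat] = FAT
    labels[fib] = FIBROSIS
    return LabelMap(
        labels,
        spacing=sl.spacing,
        slice_index=sl.slice_index,
        patient_id=sl.patient_id,
        affected_side=sl.affected_side,
    )
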