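"""Fibrosis indices comparing the affected and unaffected limb.

Four per-slice/per-patient quantities summarize the fibrosis burden from a
labeled paired-limb cross-section:

- **Index 1** — (fat + fibrosis pixels, affected) / (fat + fibrosis pixels,
  unaffected): relative size of the whole subcutaneous compartment.
- **Index 2** — (fibrosis affected − fibrosis unaffected) / (limb pixels
  unaffected): subtraction-type, normalized by the unaffected limb area
  (pixels labeled skin, muscle/water, fat or fibrosis); may be negative.
- **Index 3** — fibrosis affected / fibrosis unaffected.
- **Index 4** — total fibrosis pixels in the affected limb over all slices
  of one patient (absolute burden).

Indices 1–3 are evaluated per slice and aggregated per patient as the mean
and the sum over all slices, proximal slices only, and distal slices only;
with Index 4 this yields 19 named subindices.  "Fibrosis" pixels in the
unaffected limb (fat septa, superficial fascia, vessels) are kept as-is —
the subtraction in Index 2 is precisely what cancels them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from fibroquant._constants import AIR, FAT, FIBROSIS
from fibroquant.ct_io import LabelMap

__all__ = [
    "LimbPairCounts",
    "split_limbs",
    "count_limb_pair",
    "index1",
    "index2",
    "index3",
    "index4",
    "aggregate_subindices",
    "SUBINDEX_NAMES",
]

SUBINDEX_NAMES = tuple(
    f"Index {i} {agg}"
    for i in (1, 2, 3)
    for agg in ("Mean", "Sum", "Mean of Proximal", "Sum of Proximal", "Mean of Distal", "Sum of Distal")
) + ("Index 4",)


@dataclass
class LimbPairCounts:
    """Per-slice class pixel counts for the affected/unaffected limb halves.

    ``p_limb_*`` is the total of pixels labeled skin, muscle/water, fat or
    fibrosis (i.e. everything except air) in that limb.
    """

    p_fat_aff: int
    p_fib_aff: int
    p_fat_un: int
    p_fib_un: int
    p_limb_un: int
    p_limb_aff: int = 0
    region: str = "distal"  # "proximal" or "distal"

    def __post_init__(self) -> None:
        for name in ("p_fat_aff", "p_fib_aff", "p_fat_un", "p_fib_un", "p_limb_un", "p_limb_aff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p_limb_un < self.p_fat_un + self.p_fib_un:
            raise ValueError("unaffected limb total below its fat+fibrosis count")
        if self.region not in ("proximal", "distal"):
            raise ValueError("region must be 'proximal' or 'distal'")


def split_limbs(lm: LabelMap, affected_side: str | None = None) -> tuple[LabelMap, LabelMap]:
    """Split a paired-limb label map at the vertical midline.

    Image-left corresponds to the patient's right limb under the
    radiological convention, so ``affected_side="right"`` returns the left
    half as affected.  Raises if a non-air component straddles the midline.
    """
    side = affected_side or lm.affected_side
    mid = lm.shape[1] // 2
    body = lm.labels != AIR
    comp, n = ndimage.label(body)
    for i in range(1, n + 1):
        cols = np.flatnonzero((comp == i).any(axis=0))
        if cols.min() < mid <= cols.max():
            raise ValueError("a body component straddles the vertical midline")
    left = LabelMap(lm.labels[:, :mid].copy(), spacing=lm.spacing,
                    slice_index=lm.slice_index, patient_id=lm.patient_id,
                    affected_side=side)
    right = LabelMap(lm.labels[:, mid:].copy(), spacing=lm.spacing,
                     slice_index=lm.slice_index, patient_id=lm.patient_id,
                     affected_side=side)
    # radiological convention: image-left half is the patient's right limb
    if side == "right":
        return left, right
    return right, left


def count_limb_pair(lm: LabelMap, affected_side: str | None = None,
                    region: str = "distal") -> LimbPairCounts:
    """Class pixel counts for both limb halves of one labeled slice."""
    aff, un = split_limbs(lm, affected_side)
    return LimbPairCounts(
        p_fat_aff=int((aff.labels == FAT).sum()),
        p_fib_aff=int((aff.labels == FIBROSIS).sum()),
        p_fat_un=int((un.labels == FAT).sum()),
        p_fib_un=int((un.labels == FIBROSIS).sum()),
        p_limb_un=int((un.labels != AIR).sum()),
        p_limb_aff=int((aff.labels != AIR).sum()),
        region=region,
    )


def index1(c: LimbPairCounts) -> float:
    """(fat+fibrosis affected)/(fat+fibrosis unaffected); NaN if undefined."""
    denom = c.p_fat_un + c.p_fib_un
    if denom == 0:
        warnings.warn("Index 1 undefined: unaffected fat+fibrosis count is zero")
        return float("nan")
    return (c.p_fat_aff + c.p_fib_aff) / denom


def index2(c: LimbPairCounts) -> float:
    """(fibrosis affected − fibrosis unaffected)/(unaffected limb pixels);
    negative values are preserved."""
    if c.p_limb_un == 0:
        warnings.warn("Index 2 undefined: unaffected limb count is zero")
        return float("nan")
    return (c.p_fib_aff - c.p_fib_un) / c.p_limb_un


def index3(c: LimbPairCounts) -> float:
    """fibrosis affected / fibrosis unaffected; NaN if undefined."""
    if c.p_fib_un == 0:
        warnings.warn("Index 3 undefined: unaffected fibrosis count is zero")
        return float("nan")
    return c.p_fib_aff / c.p_fib_un


def index4(slices: list[LimbPairCounts]) -> int:
    """Total affected-limb fibrosis pixels over all slices of one patient."""
    if not slices:
        raise ValueError("index 4 requires at least one slice")
    return int(sum(c.p_fib_aff for c in slices))


def _aggregate(values: list[float], how: str) -> float:
    """Mean skips undefined (NaN) slices; Sum counts them as 0."""
    arr = np.asarray(values, dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    if how == "mean":
        return float(finite.mean()) if finite.size else float("nan")
    return float(finite.sum())


def aggregate_subindices(slices: list[LimbPairCounts]) -> dict[str, float]:
    """The 19 patient-level subindices of the four fibrosis indices.

    For Indices 1–3: Mean and Sum over all slices, proximal-only, and
    distal-only (18 values), plus Index 4.  A region with no valid slice
    yields NaN for its subindices.
    """
    if not slices:
        raise ValueError("at least one slice required")
    out: dict[str, float] = {}
    fns = {1: index1, 2: index2, 3: index3}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, fn in fns.items():
            per_slice = [(fn(c), c.region) for c in slices]
            groups = {
                "": [v for v, _ in per_slice],
                " of Proximal": [v for v, r in per_slice if r == "proximal"],
                " of Distal": [v for v, r in per_slice if r == "distal"],
            }
            for suffix, vals in groups.items():
                if not vals:
                    out[f"Index {i} Mean{suffix}"] = float("nan")
                    out[f"Index {i} Sum{suffix}"] = float("nan")
                    continue
                out[f"Index {i} Mean{suffix}"] = _aggregate(vals, "mean")
                out[f"Index {i} Sum{suffix}"] = _aggregate(vals, "sum")
    out["Index 4"] = float(index4(slices))
    assert set(out) == set(SUBINDEX_NAMES)
    return out
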