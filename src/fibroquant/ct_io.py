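"""Slice and label-map I/O in calibrated Hounsfield units.

A :class:`CTSlice` holds one axial cross-section of a paired-limb scan as a
float HU grid with its in-plane pixel spacing and position along the limb
axis.  Supported dialects:

``dicom``
    Single-frame CT via :mod:`pydicom`; raw values are calibrated with the
    stored rescale slope/intercept.
``nifti``
    NIfTI-1 via :mod:`nibabel`; ``scl_slope``/``scl_inter`` applied when set.
``png``
    16-bit grayscale PNG with a JSON sidecar ``<path>.json`` holding
    ``{"slope": ..., "intercept": ..., "spacing": [r, c], ...}``.  This keeps
    text-friendly fixtures lossless: stored = (HU − intercept) / slope.

Label maps travel as paletted/integer PNG or integer NIfTI; both round-trip
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from fibroquant._constants import AIR_HU

__all__ = [
    "CTSlice",
    "LabelMap",
    "CalibrationError",
    "crop_center",
    "read_slice",
    "write_slice",
    "read_labelmap",
    "write_labelmap",
]


class CalibrationError(ValueError):
    """Raised when HU calibration metadata is missing or unusable."""


@dataclass
class CTSlice:
    """One axial CT cross-section in Hounsfield units.

    Attributes
    ----------
    pixels : ndarray of float
        2-D HU grid, row-major.
    spacing : tuple of float
        (row, col) pixel size in mm; both > 0.
    slice_index : int
        Position along the limb axis.  By default indices increase from
        distal to proximal; the convention is declared per scan in config.
    patient_id : str
        Opaque patient identifier.
    affected_side : str
        ``"left"`` or ``"right"``.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (0.5, 0.5)
    slice_index: int = 0
    patient_id: str = ""
    affected_side: str = "left"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Per-pixel tissue class on the same grid as its slice.

    Codes: 0=air, 1=muscle/water, 2=fat, 3=skin, 4=fibrosis.  Every pixel
    carries exactly one code (exhaustive, exclusive partition).
    """

    labels: np.ndarray
    spacing: tuple[float, float] = (0.5, 0.5)
    slice_index: int = 0
    patient_id: str = ""
    affected_side: str = "left"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0 or self.labels.max() > 4:
            raise ValueError("labels must lie in {0..4}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.spacing == other.spacing
            and self.slice_index == other.slice_index
        )


def _read_png16(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a single-channel gray image")
    return arr


def read_slice(path: str | Path, dialect: Literal["dicom", "nifti", "png"]) -> CTSlice:
    """Read one axial slice and calibrate it to HU.

    Parameters
    ----------
    path : path-like
        Input file.  For ``png`` a JSON sidecar ``<path>.json`` must carry
        the affine calibration and pixel spacing.
    dialect : {"dicom", "nifti", "png"}
        File format.

    Returns
    -------
    CTSlice
        Pixels in HU (raw × slope + intercept), metadata populated.

    Raises
    ------
    IOError
        Unreadable or malformed file.
    CalibrationError
        Missing calibration (e.g. PNG without sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")

    if dialect == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (0.5, 0.5)))
        idx = int(getattr(ds, "InstanceNumber", 0))
        pid = str(getattr(ds, "PatientID", ""))
        return CTSlice(hu, spacing=spacing, slice_index=idx, patient_id=pid)

    if dialect == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        # get_fdata applies scl_slope/scl_inter when present
        data = np.asarray(img.get_fdata(dtype=np.float64))
        data = np.squeeze(data)
        if data.ndim != 2:
            raise IOError(f"{path}: expected a single 2-D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        return CTSlice(data, spacing=(float(zooms[0]), float(zooms[1])))

    if dialect == "png":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise CalibrationError(f"PNG slice {path} has no calibration sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        raw = _read_png16(path).astype(np.float64)
        hu = raw * float(meta["slope"]) + float(meta["intercept"])
        return CTSlice(
            hu,
            spacing=tuple(meta.get("spacing", (0.5, 0.5))),
            slice_index=int(meta.get("slice_index", 0)),
            patient_id=str(meta.get("patient_id", "")),
            affected_side=str(meta.get("affected_side", "left")),
        )

    raise ValueError(f"unknown dialect: {dialect!r}")


def write_slice(sl: CTSlice, path: str | Path) -> None:
    """Write a slice as 16-bit PNG + JSON calibration sidecar (lossless for
    integer-valued HU in [-1024, 3071])."""
    import imageio.v3 as iio

    path = Path(path)
    intercept = -1024.0
    raw = np.round(sl.pixels - intercept)
    if raw.min() < 0 or raw.max() > 65535:
        raise ValueError("HU range not representable in 16-bit storage")
    iio.imwrite(path, raw.astype(np.uint16))
    meta = {
        "slope": 1.0,
        "intercept": intercept,
        "spacing": list(sl.spacing),
        "slice_index": sl.slice_index,
        "patient_id": sl.patient_id,
        "affected_side": sl.affected_side,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def crop_center(sl: CTSlice, size: int, pad: bool = True) -> CTSlice:
    """Extract the centered ``size`` × ``size`` window of a slice.

    Pixel values are copied, never resampled.  If an axis is smaller than
    ``size`` and ``pad`` is true, the window is padded with air (−1000 HU);
    with ``pad`` false a dimension error is raised.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    rows, cols = sl.shape
    if (size > rows or size > cols) and not pad:
        raise ValueError(f"crop size {size} exceeds grid {sl.shape} and padding is disabled")

    out = np.full((size, size), AIR_HU, dtype=np.float64)
    # overlap of the centered window with the source grid
    r0 = (rows - size) // 2
    c0 = (cols - size) // 2
    src_r = slice(max(r0, 0), min(r0 + size, rows))
    src_c = slice(max(c0, 0), min(c0 + size, cols))
    dst_r = slice(src_r.start - r0, src_r.stop - r0)
    dst_c = slice(src_c.start - c0, src_c.stop - c0)
    out[dst_r, dst_c] = sl.pixels[src_r, src_c]
    return replace(sl, pixels=out)


def write_labelmap(lm: LabelMap, path: str | Path) -> None:
    """Write a label map losslessly (8-bit PNG or integer NIfTI by suffix)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.Nifti1Image(lm.labels[..., None].astype(np.uint8), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, lm.labels.astype(np.uint8))
    meta = {
        "spacing": list(lm.spacing),
        "slice_index": lm.slice_index,
        "patient_id": lm.patient_id,
        "affected_side": lm.affected_side,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_labelmap(path: str | Path) -> LabelMap:
    """Read a label map written by :func:`write_labelmap`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        labels = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj)).astype(np.uint8)
    else:
        import imageio.v3 as iio

        labels = iio.imread(path).astype(np.uint8)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LabelMap(
        labels,
        spacing=tuple(meta.get("spacing", (0.5, 0.5))),
        slice_index=int(meta.get("slice_index", 0)),
        patient_id=str(meta.get("patient_id", "")),
        affected_side=str(meta.get("affected_side", "left")),
    )
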