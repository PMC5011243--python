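"""Reading and writing CT slices and binary masks.

A CT slice enters the pipeline either as a single-frame DICOM file (Hounsfield
units recovered through the rescale slope/intercept tags) or as a 16-bit
grayscale raster image accompanied by an explicit ``(slope, intercept)``
mapping.  Raster images carry no HU semantics of their own, so the mapping is
mandatory rather than guessed: a silent unit error would corrupt the HU-based
seed selection downstream.

Coordinate convention used throughout the package: ``(row, col)``, 0-based,
row 0 at the top of the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Mean in-plane pixel size (mm) used when no spacing is available.
DEFAULT_SPACING_MM = 0.692

#: Admissible Hounsfield range for slice pixels.
HU_MIN = -2048
HU_MAX = 4096


@dataclass
class CTSlice:
    """A 2D signed-intensity raster in Hounsfield units.

    Attributes
    ----------
    pixels : ndarray of int
        HU values, shape (rows, cols), both dimensions >= 16.
    spacing_mm : tuple of float
        (row, col) pixel size in mm, strictly positive.
    origin_note : str
        Free-text provenance (file path, phantom scenario name, ...).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    origin_note: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("CTSlice pixels must be a non-empty 2D array")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValidationError(f"CTSlice dimensions must be >= 16, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(np.isfinite(px)):
                raise ValidationError("CTSlice pixels must be finite")
            px = np.rint(px).astype(np.int32)
        else:
            px = px.astype(np.int32)
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValidationError(
                f"HU values must lie in [{HU_MIN}, {HU_MAX}], "
                f"got [{px.min()}, {px.max()}]"
            )
        self.pixels = px
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 2 or any(not np.isfinite(s) or s <= 0 for s in sp):
            raise ValidationError(f"spacing_mm must be two positive finite values, got {self.spacing_mm}")
        self.spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A 2D boolean raster aligned to a :class:`CTSlice`."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("BinaryMask pixels must be a non-empty 2D array")
        if px.dtype != np.bool_:
            if not np.isin(px, (0, 1)).all():
                raise ValidationError("BinaryMask values must be strictly boolean")
            px = px.astype(bool)
        self.pixels = px
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 2 or any(not np.isfinite(s) or s <= 0 for s in sp):
            raise ValidationError(f"spacing_mm must be two positive finite values, got {self.spacing_mm}")
        self.spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())


def _read_dicom(path: Path, spacing_mm) -> CTSlice:
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # unreadable / truncated / not DICOM
        raise OSError(f"cannot read DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise ValidationError(f"{path}: multi-frame DICOM not supported; slices only")
    try:
        arr = ds.pixel_array
    except Exception as exc:
        raise OSError(f"cannot decode pixel data in {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a single-frame grayscale image, got shape {arr.shape}")
    slope = getattr(ds, "RescaleSlope", None)
    intercept = getattr(ds, "RescaleIntercept", None)
    if slope is None or intercept is None:
        raise ConfigurationError(
            f"{path}: RescaleSlope/RescaleIntercept missing; HU cannot be recovered"
        )
    hu = arr.astype(np.float64) * float(slope) + float(intercept)
    if spacing_mm is None:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing_mm = (float(ps[0]), float(ps[1]))
        else:
            spacing_mm = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    return CTSlice(hu, spacing_mm=spacing_mm, origin_note=f"dicom:{path}")


def _read_raster(path: Path, slope, intercept, spacing_mm) -> CTSlice:
    if slope is None or intercept is None:
        raise ConfigurationError(
            "raster CT input requires an intensity-to-HU mapping: "
            "supply input.slope and input.intercept"
        )
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read raster file {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: CT raster must be single-channel grayscale, got shape {arr.shape}")
    hu = arr.astype(np.float64) * float(slope) + float(intercept)
    if spacing_mm is None:
        spacing_mm = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    return CTSlice(hu, spacing_mm=spacing_mm, origin_note=f"raster:{path}")


def read_ct_slice(
    path,
    format_hint: str | None = None,
    *,
    slope: float | None = None,
    intercept: float | None = None,
    spacing_mm: tuple[float, float] | None = None,
) -> CTSlice:
    """Read a CT slice from DICOM or a 16-bit raster and normalize to HU.

    Parameters
    ----------
    path : path-like
        File to read.
    format_hint : {"dicom", "raster"}, optional
        Forced format; inferred from the file suffix when omitted
        (``.dcm``/``.dicom`` -> dicom, anything else -> raster).
    slope, intercept : float, optional
        Intensity-to-HU mapping, mandatory for raster inputs
        (``HU = stored * slope + intercept``).  Ignored for DICOM, which
        carries its own rescale tags.
    spacing_mm : (float, float), optional
        Pixel spacing override; for DICOM defaults to the PixelSpacing tag,
        otherwise to 0.692 mm isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        format_hint = "dicom" if path.suffix.lower() in (".dcm", ".dicom") else "raster"
    if format_hint == "dicom":
        return _read_dicom(path, spacing_mm)
    if format_hint == "raster":
        return _read_raster(path, slope, intercept, spacing_mm)
    raise ValidationError(f"unknown format hint {format_hint!r}; use 'dicom' or 'raster'")


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF (true -> 255, false -> 0)."""
    if not isinstance(mask, BinaryMask):
        raise ValidationError("write_mask expects a BinaryMask")
    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def read_mask(path, spacing_mm: tuple[float, float] | None = None) -> BinaryMask:
    """Read a binary mask written by :func:`write_mask`.

    Values > 0 map to true.  A grayscale (non-binary) image is accepted with a
    logged warning, using the same > 0 convention.  PNG stores no physical
    spacing, so ``spacing_mm`` must be supplied by the caller when it matters;
    it defaults to 0.692 mm isotropic.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    arr = np.squeeze(arr)
    if arr.ndim == 3:  # RGB(A) mask: collapse, any nonzero channel counts
        arr = arr.max(axis=-1)
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 1, 255, 65535}:
        logger.warning(
            "mask %s is not strictly binary (values %s); mapping values > 0 to true",
            path, values[:8],
        )
    if spacing_mm is None:
        spacing_mm = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)
    return BinaryMask(arr > 0, spacing_mm=spacing_mm)
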