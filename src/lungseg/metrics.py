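"""Segmentation evaluation measures.

Given an automatic mask V_auto and a reference mask V_manual:

- oversegmentation rate  OR = |V_auto \\ V_manual| / |V_manual|
- undersegmentation rate UR = |V_manual \\ V_auto| / |V_manual|
- average absolute border distance (ABD): mean over automatic-border pixels
  of the Euclidean distance (mm) to the nearest reference-border pixel;
  border pixels are mask pixels with at least one false 4-neighbor.
- overlap ratio = (N_TP + N_TN) / (N_TP + N_TN + N_FP + N_FN), i.e. pixel
  accuracy over the whole image (it counts true negatives, so it is neither
  Dice nor Jaccard; both are provided as extras).
- PSNR = 10 log10(peak^2 / MSE) in dB, for comparing denoising filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .guided_filter import GrayImage
from .image_io import BinaryMask


@dataclass
class MetricsReport:
    """Bundle of evaluation measures for one (auto, manual) mask pair.

    Rates and the overlap ratio are stored as fractions; the ``*_pct``
    properties report percentages.
    """

    over_rate: float
    under_rate: float
    abd_mm: float
    overlap_ratio: float
    n_auto_px: int
    n_manual_px: int

    @property
    def over_pct(self) -> float:
        return 100.0 * self.over_rate

    @property
    def under_pct(self) -> float:
        return 100.0 * self.under_rate

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.overlap_ratio


def _check_pair(auto: BinaryMask, manual: BinaryMask) -> None:
    if auto.shape != manual.shape:
        raise ValidationError(f"shape mismatch {auto.shape} vs {manual.shape}")


def over_under_rates(auto: BinaryMask, manual: BinaryMask) -> tuple[float, float]:
    """Over- and undersegmentation rates relative to the reference size."""
    _check_pair(auto, manual)
    a, m = auto.pixels, manual.pixels
    n_manual = int(m.sum())
    if n_manual == 0:
        raise ValidationError("reference mask is empty; rates are undefined")
    over = int((a & ~m).sum()) / n_manual
    under = int((m & ~a).sum()) / n_manual
    return over, under


def border_pixels(mask: BinaryMask) -> np.ndarray:
    """Mask pixels with >= 1 false 4-neighbor (image edge alone does not
    count as a border)."""
    cross = ndi.generate_binary_structure(2, 1)
    return mask.pixels & ~ndi.binary_erosion(mask.pixels, structure=cross, border_value=1)


def border_distance(auto: BinaryMask, manual: BinaryMask,
                    spacing_mm: tuple[float, float] | None = None,
                    symmetric: bool = False) -> float:
    """Mean distance (mm) from automatic-border pixels to the reference border.

    The measure follows the one-directional definition (auto -> manual); pass
    ``symmetric=True`` for the average of both directions.
    """
    _check_pair(auto, manual)
    if not auto.pixels.any() or not manual.pixels.any():
        raise ValidationError("border_distance requires two non-empty masks")
    if spacing_mm is None:
        spacing_mm = auto.spacing_mm
    b_auto = border_pixels(auto)
    b_manual = border_pixels(manual)

    def one_way(src, dst):
        dt = ndi.distance_transform_edt(~dst, sampling=spacing_mm)
        return float(dt[src].mean())

    d = one_way(b_auto, b_manual)
    if symmetric:
        d = 0.5 * (d + one_way(b_manual, b_auto))
    return d


def overlap_ratio(auto: BinaryMask, manual: BinaryMask) -> float:
    """Pixel accuracy over the whole image: (TP + TN) / all pixels."""
    _check_pair(auto, manual)
    a, m = auto.pixels, manual.pixels
    return float((a == m).sum()) / a.size


def dice(auto: BinaryMask, manual: BinaryMask) -> float:
    _check_pair(auto, manual)
    a, m = auto.pixels, manual.pixels
    denom = int(a.sum()) + int(m.sum())
    return 1.0 if denom == 0 else 2.0 * int((a & m).sum()) / denom


def jaccard(auto: BinaryMask, manual: BinaryMask) -> float:
    _check_pair(auto, manual)
    a, m = auto.pixels, manual.pixels
    union = int((a | m).sum())
    return 1.0 if union == 0 else int((a & m).sum()) / union


def psnr(reference: GrayImage, test: GrayImage, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    if reference.shape != test.shape:
        raise ValidationError(f"shape mismatch {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference.pixels - test.pixels) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def evaluate(auto: BinaryMask, manual: BinaryMask,
             spacing_mm: tuple[float, float] | None = None) -> MetricsReport:
    """Compute the full report for one mask pair.

    ABD is NaN when either mask is empty (border undefined).
    """
    over, under = over_under_rates(auto, manual)
    if auto.pixels.any() and manual.pixels.any():
        abd = border_distance(auto, manual, spacing_mm=spacing_mm)
    else:
        abd = math.nan
    return MetricsReport(
        over_rate=over,
        under_rate=under,
        abd_mm=abd,
        overlap_ratio=overlap_ratio(auto, manual),
        n_auto_px=auto.area_px(),
        n_manual_px=manual.area_px(),
    )
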