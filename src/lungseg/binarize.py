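"""Otsu adaptive thresholding of the denoised slice.

Pixels are histogrammed into L equal-width bins over [0, 1] (bins numbered
1..L).  For a candidate threshold k, class C0 holds bins < k and class C1
bins >= k; the intra-class variance

    sigma_intra^2(k) = w0(k) sigma0^2(k) + w1(k) sigma1^2(k)

is minimized over k in [1, L] (equivalently the between-class variance is
maximized; the two argmin/argmax sets coincide because their sum is the total
variance).  Ties are broken toward the smallest k for reproducibility.

Polarity convention: the thresholded mask is true for the LOW-density class
(air and lung), because the downstream stages grow the background air and
segment the low-density lungs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .guided_filter import GrayImage
from .image_io import BinaryMask

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 256


@dataclass
class ThresholdResult:
    """Result of the intra-class variance scan.

    level : the selected threshold bin index T, in [1, n_bins]; class C0 is
        bins < T.
    criterion_curve : sigma_intra^2(k) for k = 1..n_bins (index k-1).
    n_bins : L, the number of histogram bins.
    """

    level: int
    criterion_curve: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.criterion_curve = np.asarray(self.criterion_curve, dtype=np.float64)
        if not 1 <= self.level <= self.n_bins:
            raise ValidationError(f"level {self.level} outside [1, {self.n_bins}]")
        if self.criterion_curve.shape != (self.n_bins,):
            raise ValidationError("criterion_curve must have one value per bin")
        if (self.criterion_curve < -1e-12).any():
            raise ValidationError("criterion_curve values must be >= 0")


def _bin_indices(pixels: np.ndarray, n_bins: int) -> np.ndarray:
    """1-based equal-width bin index over [0, 1]; 1.0 falls in the last bin."""
    idx = np.floor(pixels * n_bins).astype(np.int64)
    return 1 + np.clip(idx, 0, n_bins - 1)


def otsu_threshold(image: GrayImage, n_bins: int = DEFAULT_N_BINS) -> ThresholdResult:
    """Select the threshold minimizing the intra-class variance.

    A constant image is degenerate (every split is equivalent); it returns
    level 1 with a warning.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    px = image.pixels
    if np.ptp(px) == 0.0:
        logger.warning("otsu_threshold: constant image, returning degenerate level 1")
        return ThresholdResult(level=1, criterion_curve=np.zeros(n_bins), n_bins=n_bins)

    bins = _bin_indices(px, n_bins)
    hist = np.bincount(bins.ravel(), minlength=n_bins + 1)[1:].astype(np.float64)
    p = hist / hist.sum()
    v = (np.arange(1, n_bins + 1) - 0.5) / n_bins  # bin-center intensities

    # cumulative stats of C0 = bins < k; index k-1 holds sums over bins 1..k-1
    cw = np.concatenate(([0.0], np.cumsum(p)))[:-1]
    cs = np.concatenate(([0.0], np.cumsum(p * v)))[:-1]
    cs2 = np.concatenate(([0.0], np.cumsum(p * v * v)))[:-1]

    w0, s0, q0 = cw, cs, cs2
    w1 = 1.0 - w0
    s1 = np.sum(p * v) - s0
    q1 = np.sum(p * v * v) - q0

    def class_term(w, s, q):
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(w > 0, s / np.where(w > 0, w, 1.0), 0.0)
            var = np.where(w > 0, q / np.where(w > 0, w, 1.0) - m * m, 0.0)
        return w * np.maximum(var, 0.0)  # empty class contributes zero

    curve = class_term(w0, s0, q0) + class_term(w1, s1, q1)
    level = int(np.argmin(curve)) + 1  # first occurrence = smallest k
    return ThresholdResult(level=level, criterion_curve=curve, n_bins=n_bins)


def apply_threshold(image: GrayImage, level: int, n_bins: int = DEFAULT_N_BINS) -> BinaryMask:
    """Binarize: true where the pixel's bin index is < level (low density)."""
    if not 1 <= level <= n_bins:
        raise ValidationError(f"level {level} outside [1, {n_bins}]")
    bins = _bin_indices(image.pixels, n_bins)
    return BinaryMask(bins < level, spacing_mm=image.spacing_mm)
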