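"""Edge-preserving denoising with the guided image filter.

The guided filter expresses the output q as a local linear transform of a
guidance image I: within each square window w_k,

    q_i = a_k * I_i + b_k,

with (a_k, b_k) chosen to minimize sum_i (a_k I_i + b_k - p_i)^2 + eps a_k^2
over the window, giving

    a_k = (mean(I p) - mean(I) mean(p)) / (var(I) + eps),
    b_k = mean(p) - a_k mean(I).

Since every pixel is covered by many windows, the established formulation
averages the coefficients of all covering windows:

    q_i = mean_k(a) * I_i + mean_k(b).

Smoothing strength is set by the window side length and the regularizer eps,
interpreted on the normalized [0, 1] intensity scale.  For CT denoising the
filter is self-guided (guide = input), which smooths homogeneous parenchyma
while keeping the lung wall sharp; image borders use reflective padding so
edges are not darkened.

Box means are computed with an integral image (summed-area table), which is
O(N) per image independent of window size, and makes the eps = 0 self-guided
case an exact identity (window sums of ones/zeros are exact integers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import CTSlice, DEFAULT_SPACING_MM

#: Default display/normalization window for thoracic CT, in HU.
DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class GuidedFilterParams:
    """Guided-filter tuning knobs.

    window : odd side length of the averaging window in pixels (default 15).
    eps : regularization keeping a_k bounded; units of squared normalized
        intensity (default 0.008).
    """

    window: int = 15
    eps: float = 0.008

    def __post_init__(self) -> None:
        if int(self.window) != self.window or self.window < 3 or self.window % 2 == 0:
            raise ValidationError(f"window must be an odd integer >= 3, got {self.window}")
        self.window = int(self.window)
        if not np.isfinite(self.eps) or self.eps < 0:
            raise ValidationError(f"eps must be >= 0, got {self.eps}")
        self.eps = float(self.eps)


@dataclass
class GrayImage:
    """A 2D real image with normalized intensities in [0, 1]."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("GrayImage pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("GrayImage pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError(
                f"GrayImage values must lie in [0, 1], got [{px.min()}, {px.max()}]"
            )
        self.pixels = px
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_hu(ct: CTSlice, hu_min: float = DEFAULT_HU_WINDOW[0],
                 hu_max: float = DEFAULT_HU_WINDOW[1]) -> GrayImage:
    """Map HU linearly onto [0, 1], clipping outside [hu_min, hu_max]."""
    if not hu_min < hu_max:
        raise ValidationError(f"degenerate HU window [{hu_min}, {hu_max}]")
    hu = np.clip(ct.pixels.astype(np.float64), hu_min, hu_max)
    return GrayImage((hu - hu_min) / (hu_max - hu_min), spacing_mm=ct.spacing_mm)


def denormalize_hu(img: GrayImage, hu_min: float = DEFAULT_HU_WINDOW[0],
                   hu_max: float = DEFAULT_HU_WINDOW[1]) -> CTSlice:
    """Inverse of :func:`normalize_hu` (up to the clipping, which is lossy)."""
    hu = img.pixels * (hu_max - hu_min) + hu_min
    return CTSlice(np.rint(hu).astype(np.int32), spacing_mm=img.spacing_mm,
                   origin_note="denormalized")


def _box_mean(a: np.ndarray, window: int) -> np.ndarray:
    """Mean over a window x window neighborhood with reflective padding."""
    r = window // 2
    p = np.pad(a, r, mode="symmetric")
    ii = np.zeros((p.shape[0] + 1, p.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = p.cumsum(axis=0).cumsum(axis=1)
    s = (ii[window:, window:] - ii[:-window, window:]
         - ii[window:, :-window] + ii[:-window, :-window])
    return s / float(window * window)


def guided_filter(inp: GrayImage, guide: GrayImage | None = None,
                  params: GuidedFilterParams | None = None) -> GrayImage:
    """Filter ``inp`` using ``guide`` (defaults to self-guided).

    Returns the window-averaged local linear transform described in the module
    docstring, clipped back to [0, 1].
    """
    if params is None:
        params = GuidedFilterParams()
    if guide is None:
        guide = inp
    if inp.shape != guide.shape:
        raise ValidationError(f"input shape {inp.shape} != guide shape {guide.shape}")

    p = inp.pixels
    I = guide.pixels
    # A globally constant image is a fixed point of the filter (var = 0 in
    # every window forces a_k = 0, b_k = the constant); return it unchanged
    # so repeated filtering is exactly idempotent.
    if np.ptp(p) == 0.0 and np.ptp(I) == 0.0:
        return GrayImage(p.copy(), spacing_mm=inp.spacing_mm)

    w = params.window
    mean_I = _box_mean(I, w)
    mean_p = mean_I if p is I else _box_mean(p, w)
    corr_II = _box_mean(I * I, w)
    corr_Ip = corr_II if p is I else _box_mean(I * p, w)
    var_I = np.maximum(corr_II - mean_I * mean_I, 0.0)
    cov_Ip = var_I if p is I else corr_Ip - mean_I * mean_p

    denom = var_I + params.eps
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0.0, cov_Ip / np.where(denom > 0.0, denom, 1.0), 0.0)
    b = mean_p - a * mean_I

    q = _box_mean(a, w) * I + _box_mean(b, w)
    return GrayImage(np.clip(q, 0.0, 1.0), spacing_mm=inp.spacing_mm)


def filter_multichannel(channels: list[GrayImage],
                        params: GuidedFilterParams | None = None) -> list[GrayImage]:
    """Filter up to three channels, each self-guided.

    Retained as an API generalization for RGB-coded inputs; CT slices are
    processed single-channel.
    """
    if not channels:
        raise ValidationError("filter_multichannel needs at least one channel")
    if len(channels) > 3:
        raise ValidationError(f"at most 3 channels supported, got {len(channels)}")
    shape = channels[0].shape
    for ch in channels:
        if ch.shape != shape:
            raise ValidationError("all channels must share one shape")
    return [guided_filter(ch, ch, params) for ch in channels]
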