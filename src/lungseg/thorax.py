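"""Thorax extraction: remove background air and external artifacts.

The binarized slice marks low-density pixels (air, lungs, airway) true.  The
external air touches the image corners, so flood-filling ("region growing")
from the four corners over true pixels recovers exactly the background air
component(s).  Removing the background leaves the patient's body together
with any detached artifacts such as the scanner bed; components that do not
overlap the central region of the image are discarded as artifacts, and the
surviving body outline is hole-filled so the returned thorax mask is the
solid body cross-section containing the lungs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError
from .image_io import BinaryMask

logger = logging.getLogger(__name__)


@dataclass
class RegionGrowingParams:
    """connectivity: 4 or 8 neighborhood; corner_margin: side length in px of
    the corner patches used as flood-fill seeds; central_fraction: fraction of
    each image dimension defining the central box a body component must touch."""

    connectivity: int = 4
    corner_margin: int = 1
    central_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValidationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.corner_margin < 1:
            raise ValidationError("corner_margin must be >= 1")
        if not 0.0 < self.central_fraction <= 1.0:
            raise ValidationError("central_fraction must be in (0, 1]")


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def grow_background(binary: BinaryMask, params: RegionGrowingParams | None = None) -> BinaryMask:
    """Flood-fill the low-density mask from the four image corners.

    Returns the union of connected components reachable from any corner
    patch; pixels false in the input are never included.
    """
    if params is None:
        params = RegionGrowingParams()
    px = binary.pixels
    labels, _ = ndi.label(px, structure=_structure(params.connectivity))
    m = params.corner_margin
    corner_labels = np.unique(np.concatenate([
        labels[:m, :m].ravel(), labels[:m, -m:].ravel(),
        labels[-m:, :m].ravel(), labels[-m:, -m:].ravel(),
    ]))
    corner_labels = corner_labels[corner_labels > 0]
    bg = np.isin(labels, corner_labels)
    return BinaryMask(bg, spacing_mm=binary.spacing_mm)


def extract_thorax(binary: BinaryMask, background: BinaryMask,
                   params: RegionGrowingParams | None = None) -> BinaryMask:
    """Subtract the background and keep the solid central body region.

    Everything that is not background (chest wall, lungs, enclosed air, bed)
    is labeled; components overlapping the central box survive, the rest are
    discarded as external artifacts; enclosed holes are filled so the thorax
    is solid.
    """
    if params is None:
        params = RegionGrowingParams()
    if binary.shape != background.shape:
        raise ValidationError(f"shape mismatch {binary.shape} vs {background.shape}")
    candidates = ~background.pixels
    if not candidates.any():
        logger.warning("extract_thorax: background covers the whole image; empty thorax")
        return BinaryMask(np.zeros(binary.shape, bool), spacing_mm=binary.spacing_mm)

    labels, n = ndi.label(candidates, structure=_structure(params.connectivity))
    rows, cols = binary.shape
    f = params.central_fraction
    r0, r1 = int(rows * (1 - f) / 2), int(np.ceil(rows * (1 + f) / 2))
    c0, c1 = int(cols * (1 - f) / 2), int(np.ceil(cols * (1 + f) / 2))
    central = np.unique(labels[r0:r1, c0:c1])
    central = central[central > 0]
    body = np.isin(labels, central)
    if not body.any():
        logger.warning("extract_thorax: no component overlaps the central region; empty thorax")
    thorax = ndi.binary_fill_holes(body)
    # Enclosed holes cannot belong to the corner-connected background, so the
    # fill never reintroduces background pixels.
    return BinaryMask(thorax, spacing_mm=binary.spacing_mm)
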