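"""Deterministic synthetic thorax phantom.

The phantom emulates a supine axial chest CT slice on a 512x512 grid with
0.692 mm pixels: background air (-1000 HU), an elliptical soft-tissue body
(+40 HU), two elliptical low-density lung fields (-500 HU), a circular
mediastinal airway (-1000 HU, excluded from the lung ground truth), a
vertebral body (+400 HU), a thin scanner-bed bar (+100 HU) separated from
the body by air, optional nodules (dense disks, counted as lung in the
ground truth so that refinement can be scored on recovering them), and
additive Gaussian noise in HU.

What it does NOT emulate: vascular/bronchial texture, partial-volume blur at
tissue interfaces, beam hardening, patient asymmetry.  Its intensity
histogram is cleanly bimodal (air/lung cluster vs soft-tissue cluster),
which is exactly the precondition the Otsu stage relies on; results on the
phantom therefore demonstrate pipeline mechanics, not clinical performance.

Structure codes in the labeled map: 0 air, 1 soft tissue, 2 lung, 3 airway,
4 bone, 5 bed, 6 nodule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .image_io import BinaryMask, CTSlice, HU_MAX, HU_MIN

STRUCT_AIR = 0
STRUCT_SOFT = 1
STRUCT_LUNG = 2
STRUCT_AIRWAY = 3
STRUCT_BONE = 4
STRUCT_BED = 5
STRUCT_NODULE = 6


@dataclass
class Nodule:
    """A circular nodule: center (row, col), radius in px, HU, and whether it
    abuts the pleural border (juxtapleural) or is fully internal."""

    center: tuple[float, float]
    radius: float
    hu: float = 20.0
    juxtapleural: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("nodule radius must be > 0")


@dataclass
class PhantomSpec:
    """Geometry (in px, defaults for a 512x512 slice) and tissue HU levels."""

    size: tuple[int, int] = (512, 512)
    spacing_mm: tuple[float, float] = (0.692, 0.692)
    body_center: tuple[float, float] = (266.0, 256.0)
    body_axes: tuple[float, float] = (175.0, 215.0)
    lung_centers: tuple[tuple[float, float], ...] = ((266.0, 150.0), (266.0, 362.0))
    lung_axes: tuple[float, float] = (115.0, 72.0)
    airway_center: tuple[float, float] = (186.0, 256.0)
    airway_radius: float = 8.0
    bone_center: tuple[float, float] = (380.0, 256.0)
    bone_axes: tuple[float, float] = (28.0, 22.0)
    include_lungs: bool = True
    include_bed: bool = True
    bed_rows: tuple[int, int] = (470, 479)
    bed_cols: tuple[int, int] = (56, 456)
    hu_air: float = -1000.0
    hu_lung: float = -500.0
    hu_soft: float = 40.0
    hu_bone: float = 400.0
    hu_bed: float = 100.0
    nodules: tuple[Nodule, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if min(self.size) < 16:
            raise ValidationError("phantom must be at least 16x16")

    @classmethod
    def scaled(cls, size: int | tuple[int, int], **overrides) -> "PhantomSpec":
        """A spec with all default 512-px geometry scaled to ``size``."""
        if isinstance(size, int):
            size = (size, size)
        sr, sc = size[0] / 512.0, size[1] / 512.0
        s = (sr + sc) / 2.0
        spec = cls(
            size=size,
            body_center=(266.0 * sr, 256.0 * sc),
            body_axes=(175.0 * sr, 215.0 * sc),
            lung_centers=((266.0 * sr, 150.0 * sc), (266.0 * sr, 362.0 * sc)),
            lung_axes=(115.0 * sr, 72.0 * sc),
            airway_center=(186.0 * sr, 256.0 * sc),
            airway_radius=max(3.0, 8.0 * s),
            bone_center=(380.0 * sr, 256.0 * sc),
            bone_axes=(28.0 * sr, 22.0 * sc),
            bed_rows=(int(470 * sr), int(479 * sr)),
            bed_cols=(int(56 * sc), int(456 * sc)),
        )
        return replace(spec, **overrides) if overrides else spec


def _ellipse(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def _disk(shape, center, radius) -> np.ndarray:
    return _ellipse(shape, center, (radius, radius))


def generate(spec: PhantomSpec) -> tuple[CTSlice, BinaryMask, np.ndarray]:
    """Rasterize the phantom.

    Returns (slice, lung ground truth, structure-code map).  Deterministic
    for a given spec (including its RNG seed); noise is added last.
    """
    shape = spec.size
    hu = np.full(shape, spec.hu_air, dtype=np.float64)
    struct = np.full(shape, STRUCT_AIR, dtype=np.int8)

    body = _ellipse(shape, spec.body_center, spec.body_axes)
    hu[body] = spec.hu_soft
    struct[body] = STRUCT_SOFT

    truth = np.zeros(shape, bool)
    if spec.include_lungs:
        for center in spec.lung_centers:
            lung = _ellipse(shape, center, spec.lung_axes)
            if (lung & ~body).any():
                raise ValidationError("lungs must lie strictly inside the body")
            hu[lung] = spec.hu_lung
            struct[lung] = STRUCT_LUNG
            truth |= lung
        airway = _disk(shape, spec.airway_center, spec.airway_radius)
        if (airway & ~body).any():
            raise ValidationError("airway must lie inside the body")
        hu[airway] = spec.hu_air
        struct[airway] = STRUCT_AIRWAY
        truth &= ~airway

    bone = _ellipse(shape, spec.bone_center, spec.bone_axes)
    hu[bone & body] = spec.hu_bone
    struct[bone & body] = STRUCT_BONE

    if spec.include_bed:
        r0, r1 = spec.bed_rows
        c0, c1 = spec.bed_cols
        bed = np.zeros(shape, bool)
        bed[r0:r1 + 1, c0:c1 + 1] = True
        bed &= ~body
        hu[bed] = spec.hu_bed
        struct[bed] = STRUCT_BED

    for nod in spec.nodules:
        dsk = _disk(shape, nod.center, nod.radius)
        hu[dsk] = nod.hu
        struct[dsk] = STRUCT_NODULE
        truth |= dsk  # nodules count as lung in the reference standard

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape)
    hu = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int32)

    ct = CTSlice(hu, spacing_mm=spec.spacing_mm, origin_note=f"phantom(seed={spec.seed})")
    return ct, BinaryMask(truth, spacing_mm=spec.spacing_mm), struct


def _nodule_on_medial_border(spec: PhantomSpec, radius: float, hu: float,
                             inset: float) -> Nodule:
    """A nodule centered ``inset`` px inside the right lung's medial border,
    at the lung's vertical center."""
    (row, col) = spec.lung_centers[1]
    medial_col = col - spec.lung_axes[1] + inset
    return Nodule(center=(row, medial_col), radius=radius, hu=hu, juxtapleural=True)


def generate_suite(seed: int = 0, size: int | tuple[int, int] = (512, 512)
                   ) -> list[tuple[str, CTSlice, BinaryMask]]:
    """The fixed scenario battery every pipeline stage is exercised on.

    Scenarios: clean, noisy (sd 20 HU), juxtapleural_nodule,
    mediastinal_indentation, bed_artifact, lungless.
    """
    base = PhantomSpec.scaled(size, seed=seed)
    s = (base.size[0] / 512.0 + base.size[1] / 512.0) / 2.0

    scenarios: list[tuple[str, PhantomSpec]] = []
    scenarios.append(("clean", base))
    scenarios.append(("noisy", replace(base, noise_sd=20.0)))
    scenarios.append((
        "juxtapleural_nodule",
        replace(base, nodules=(
            _nodule_on_medial_border(base, radius=max(4.0, 8.0 * s), hu=20.0,
                                     inset=max(3.5, 7.0 * s)),
        )),
    ))
    # soft-tissue bump indenting the left lung's medial (mediastinal) border
    lrow, lcol = base.lung_centers[0]
    bump = Nodule(center=(lrow, lcol + base.lung_axes[1] - max(5.0, 10.0 * s)),
                  radius=max(6.0, 12.0 * s), hu=base.hu_soft, juxtapleural=True)
    scenarios.append(("mediastinal_indentation", replace(base, nodules=(bump,))))
    scenarios.append((
        "bed_artifact",
        replace(base, hu_bed=300.0,
                bed_rows=(int(base.bed_rows[0] - 12 * s), base.bed_rows[1])),
    ))
    scenarios.append(("lungless", replace(base, include_lungs=False)))

    out = []
    for name, spec in scenarios:
        ct, truth, _ = generate(spec)
        ct.origin_note = f"phantom:{name}(seed={seed})"
        out.append((name, ct, truth))
    return out
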