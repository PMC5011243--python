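"""End-to-end lung segmentation: six strategies in three operation steps.

Stage order (CT image processing -> initial segmentation -> refinement):

1. normalize HU to [0, 1] and denoise with the guided filter;
2. Otsu-binarize into the low-density class;
3. grow the background from the image corners and extract the solid thorax;
4. select lung/background seeds, build the pixel graph on the denoised
   intensities, solve the Dirichlet problem, threshold the lung probability;
5. rolling-ball hole filling;
6. scan-line curvature correction of the lung contour.

Inference is fully deterministic: identical input and configuration produce
bit-identical masks.  A lungless slice is a result ("no-lung" status, empty
mask), not a crash.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import image_io
from .binarize import DEFAULT_N_BINS, apply_threshold, otsu_threshold
from .errors import LungSegError, SeedSelectionError, ValidationError
from .guided_filter import (DEFAULT_HU_WINDOW, GuidedFilterParams, denormalize_hu,
                            guided_filter, normalize_hu)
from .image_io import BinaryMask, CTSlice
from .metrics import evaluate
from .random_walk import (RandomWalkParams, build_graph, field_to_mask,
                          select_seeds, solve_dirichlet)
from .refine import RefineParams, correct_contour, fill_holes, scan_mask
from .thorax import RegionGrowingParams, extract_thorax, grow_background

logger = logging.getLogger(__name__)


@dataclass
class InputConfig:
    """Intensity-to-HU mapping for raster inputs; ignored for DICOM."""

    slope: float | None = None
    intercept: float | None = None
    spacing_mm: tuple[float, float] | None = None


@dataclass
class OutputConfig:
    dump_stages: bool = False
    log_level: str = "INFO"


@dataclass
class PipelineConfig:
    """All stage parameters in one place; see each stage's dataclass."""

    input: InputConfig = field(default_factory=InputConfig)
    filter: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    n_bins: int = DEFAULT_N_BINS
    thorax: RegionGrowingParams = field(default_factory=RegionGrowingParams)
    rw: RandomWalkParams = field(default_factory=RandomWalkParams)
    refine: RefineParams = field(default_factory=RefineParams)
    output: OutputConfig = field(default_factory=OutputConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from nested config keys (input.slope, filter.window, ...)."""
        d = dict(d or {})
        inp = dict(d.get("input", {}))
        filt = dict(d.get("filter", {}))
        hu_window = tuple(filt.pop("hu_window", DEFAULT_HU_WINDOW))
        binz = dict(d.get("binarize", {}))
        tho = dict(d.get("thorax", {}))
        rw = dict(d.get("rw", {}))
        ref = dict(d.get("refine", {}))
        out = dict(d.get("output", {}))
        if inp.get("spacing_mm") is not None:
            inp["spacing_mm"] = tuple(inp["spacing_mm"])
        return cls(
            input=InputConfig(**inp),
            filter=GuidedFilterParams(**filt),
            hu_window=hu_window,
            n_bins=int(binz.get("n_bins", DEFAULT_N_BINS)),
            thorax=RegionGrowingParams(**tho),
            rw=RandomWalkParams(**rw),
            refine=RefineParams(**ref),
            output=OutputConfig(**out),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "input": asdict(self.input),
            "filter": {**asdict(self.filter), "hu_window": list(self.hu_window)},
            "binarize": {"n_bins": self.n_bins},
            "thorax": asdict(self.thorax),
            "rw": asdict(self.rw),
            "refine": asdict(self.refine),
            "output": asdict(self.output),
        }


@dataclass
class SegmentationResult:
    """mask: final lung mask; status: "ok" or "no-lung"; artifacts: per-stage
    intermediates when dump_stages is enabled (always includes "thorax")."""

    mask: BinaryMask
    status: str
    artifacts: dict


def segment_lung(ct: CTSlice, config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full pipeline on one slice."""
    if config is None:
        config = PipelineConfig()
    t0 = time.perf_counter()
    artifacts: dict = {}
    dump = config.output.dump_stages

    def stage(name, value):
        if dump:
            artifacts[name] = value
        logger.info("stage %-14s %6.2f s", name, time.perf_counter() - t0)
        return value

    gray = stage("normalize", normalize_hu(ct, *config.hu_window))
    filtered = stage("guided_filter", guided_filter(gray, None, config.filter))
    thr = otsu_threshold(filtered, config.n_bins)
    low = stage("binarize", apply_threshold(filtered, thr.level, config.n_bins))
    background = stage("grow_background", grow_background(low, config.thorax))
    thorax = stage("thorax", extract_thorax(low, background, config.thorax))
    artifacts["thorax"] = thorax

    empty = BinaryMask(np.zeros(ct.shape, bool), spacing_mm=ct.spacing_mm)
    if not thorax.pixels.any():
        logger.warning("empty thorax: reporting no-lung result")
        return SegmentationResult(empty, "no-lung", artifacts)

    # Seeds are selected on the denoised slice: the whole flow operates on
    # the smoothed image, and window averaging shrinks HU noise accordingly.
    denoised_ct = denormalize_hu(filtered, *config.hu_window)
    denoised_ct.origin_note = ct.origin_note
    try:
        seeds = select_seeds(denoised_ct, thorax, config.rw)
    except SeedSelectionError as exc:
        logger.warning("seed selection failed (%s): reporting no-lung result", exc)
        return SegmentationResult(empty, "no-lung", artifacts)
    if dump:
        artifacts["seeds"] = seeds

    graph = build_graph(filtered, thorax, beta=config.rw.beta,
                        connectivity=config.rw.connectivity)
    fieldp = stage("random_walk", solve_dirichlet(graph, seeds))
    rw_mask = field_to_mask(fieldp)
    if dump:
        artifacts["rw_mask"] = rw_mask

    filled = stage("fill_holes", fill_holes(rw_mask, config.refine.ball_radius))
    points = scan_mask(filled, config.refine.scan_interval)
    final = stage("correct_contour", correct_contour(filled, points, config.refine))
    final = BinaryMask(final.pixels & thorax.pixels, spacing_mm=ct.spacing_mm)
    return SegmentationResult(final, "ok", artifacts)


CSV_HEADER = ["slice", "over_pct", "under_pct", "abd_mm", "overlap_pct", "status"]


def run_batch(paths, config: PipelineConfig | None = None, out_dir=None,
              truth_paths=None) -> tuple[list[dict], bool]:
    """Segment a batch of slice files; write masks and (given references) a
    per-slice metrics CSV.

    Returns (rows, ok); ``ok`` is False when any slice failed, and failures
    appear as rows with an error status.
    """
    if config is None:
        config = PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    truth_paths = list(truth_paths) if truth_paths is not None else [None] * len(paths)
    if len(truth_paths) != len(paths):
        raise ValidationError("truth_paths must match paths in length")

    rows: list[dict] = []
    ok = True
    for path, tpath in zip(paths, truth_paths):
        name = Path(path).stem
        row = {k: "" for k in CSV_HEADER}
        row["slice"] = name
        try:
            ct = image_io.read_ct_slice(
                path,
                slope=config.input.slope,
                intercept=config.input.intercept,
                spacing_mm=config.input.spacing_mm,
            )
            result = segment_lung(ct, config)
            row["status"] = result.status
            if out_dir is not None:
                image_io.write_mask(result.mask, out_dir / f"{name}_mask.png")
            if tpath is not None:
                truth = image_io.read_mask(tpath, spacing_mm=ct.spacing_mm)
                rep = evaluate(result.mask, truth)
                row.update(
                    over_pct=f"{rep.over_pct:.4f}",
                    under_pct=f"{rep.under_pct:.4f}",
                    abd_mm="" if np.isnan(rep.abd_mm) else f"{rep.abd_mm:.4f}",
                    overlap_pct=f"{rep.overlap_pct:.4f}",
                )
        except (OSError, LungSegError) as exc:
            logger.error("slice %s failed: %s", name, exc)
            row["status"] = f"error: {exc}"
            ok = False
        rows.append(row)

    if out_dir is not None:
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_HEADER)
            writer.writeheader()
            writer.writerows(rows)
    return rows, ok
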