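"""Curvature-based contour correction recovering a juxtapleural nodule.

A dense (+20 HU) nodule abutting the pleural border is excluded by every
density-driven stage, carving a notch into the lung mask.  Scan-line
curvature screening detects the notch as a curvature anomaly on the border
chain and bridges it, restoring the nodule to the mask.
"""

from lungseg import PhantomSpec, evaluate, segment_lung
from lungseg.phantom import _disk, _nodule_on_medial_border, generate
from lungseg.pipeline import PipelineConfig

base = PhantomSpec(seed=2)
nodule = _nodule_on_medial_border(base, radius=8.0, hu=20.0, inset=7.0)
spec = PhantomSpec(seed=2, nodules=(nodule,))
ct, truth, _ = generate(spec)

cfg = PipelineConfig()
cfg.output.dump_stages = True
res = segment_lung(ct, cfg)

npx = _disk(ct.shape, nodule.center, nodule.radius)
rw_cov = 100 * (res.artifacts["rw_mask"].pixels & npx).sum() / npx.sum()
final_cov = 100 * (res.mask.pixels & npx).sum() / npx.sum()
rep = evaluate(res.mask, truth)
print(f"nodule pixels          : {npx.sum()}")
print(f"random-walk coverage   : {rw_cov:.1f}%   (dense nodule excluded)")
print(f"after refinement       : {final_cov:.1f}%  (notch bridged)")
print(f"whole-slice overlap    : {rep.overlap_pct:.3f}%")
# Refinement lifts nodule coverage from 0% to >95% while the rest of the
# border moves by at most a pixel.
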