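"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written the slow, direct way (explicit
per-window loops, dense linear algebra, Monte-Carlo simulation, all-pairs
distances) and shares no code with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def guided_filter_bruteforce(p: np.ndarray, I: np.ndarray, window: int,
                             eps: float) -> np.ndarray:
    """Per-window guided filter: explicit loops, reflective padding."""
    r = window // 2
    P = np.pad(p, r, mode="symmetric")
    G = np.pad(I, r, mode="symmetric")
    H, W = p.shape
    a = np.zeros((H, W))
    b = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            gw = G[i:i + window, j:j + window]
            pw = P[i:i + window, j:j + window]
            mI, mp = gw.mean(), pw.mean()
            var = (gw * gw).mean() - mI * mI
            cov = (gw * pw).mean() - mI * mp
            denom = var + eps
            ak = cov / denom if denom > 0 else 0.0
            a[i, j] = ak
            b[i, j] = mp - ak * mI
    A = np.pad(a, r, mode="symmetric")
    B = np.pad(b, r, mode="symmetric")
    q = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            q[i, j] = (A[i:i + window, j:j + window].mean() * I[i, j]
                       + B[i:i + window, j:j + window].mean())
    return np.clip(q, 0.0, 1.0)


def otsu_exhaustive(pixels: np.ndarray, n_bins: int) -> tuple[int, np.ndarray]:
    """Direct scan over every candidate threshold k in [1, L].

    Bins are 1-based equal-width over [0, 1]; class C0 = bins < k.
    Returns (argmin level, criterion curve).
    """
    bins = 1 + np.clip(np.floor(pixels.ravel() * n_bins).astype(int), 0, n_bins - 1)
    curve = np.zeros(n_bins)
    v = (bins - 0.5) / n_bins  # bin-center intensity per pixel
    for k in range(1, n_bins + 1):
        c0 = v[bins < k]
        c1 = v[bins >= k]
        term = 0.0
        for cls in (c0, c1):
            if len(cls):
                w = len(cls) / len(v)
                term += w * cls.var()
        curve[k - 1] = term
    return int(np.argmin(curve)) + 1, curve


def grid_graph_dense(g: np.ndarray, beta: float) -> np.ndarray:
    """Dense Laplacian of the full-grid 4-connected pixel graph."""
    H, W = g.shape
    n = H * W
    L = np.zeros((n, n))
    for r in range(H):
        for c in range(W):
            i = r * W + c
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < H and cc < W:
                    j = rr * W + cc
                    w = np.exp(-beta * (g[r, c] - g[rr, cc]) ** 2)
                    L[i, j] -= w
                    L[j, i] -= w
                    L[i, i] += w
                    L[j, j] += w
    return L


def dirichlet_dense(g: np.ndarray, beta: float,
                    seeds: list[tuple[int, int, str]], label: str) -> np.ndarray:
    """Dense direct solve for the probability of reaching ``label`` seeds
    first, on the full grid of image g.  Returns an (H, W) array."""
    H, W = g.shape
    L = grid_graph_dense(g, beta)
    seed_nodes = {r * W + c: lab for r, c, lab in seeds}
    m = sorted(seed_nodes)
    u = [i for i in range(H * W) if i not in seed_nodes]
    xm = np.array([1.0 if seed_nodes[i] == label else 0.0 for i in m])
    Luu = L[np.ix_(u, u)]
    Lum = L[np.ix_(u, m)]
    xu = np.linalg.solve(Luu, -Lum @ xm)
    x = np.zeros(H * W)
    x[u] = xu
    for i in m:
        x[i] = xm[m.index(i)]
    return x.reshape(H, W)


def mc_absorption(g: np.ndarray, beta: float, seeds: list[tuple[int, int, str]],
                  start: tuple[int, int], label: str, n_walks: int,
                  rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of the absorbing-walk probability.

    Walkers step from pixel i to neighbor j with probability w_ij / deg_i
    and are absorbed at seed pixels; returns the fraction absorbed at seeds
    of ``label``.
    """
    H, W = g.shape
    n = H * W

    nb = np.full((n, 4), -1, dtype=np.int64)
    wt = np.zeros((n, 4))
    for r in range(H):
        for c in range(W):
            i = r * W + c
            for s, (dr, dc) in enumerate(((0, 1), (0, -1), (1, 0), (-1, 0))):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    nb[i, s] = rr * W + cc
                    wt[i, s] = np.exp(-beta * (g[r, c] - g[rr, cc]) ** 2)
    cum = np.cumsum(wt, axis=1)
    cum /= cum[:, -1:]

    seed_label = np.full(n, -1, dtype=np.int64)
    for r, c, lab in seeds:
        seed_label[r * W + c] = 1 if lab == label else 0

    pos = np.full(n_walks, start[0] * W + start[1], dtype=np.int64)
    hits = 0
    done = 0
    for _ in range(1_000_000):
        absorbed = seed_label[pos] >= 0
        if absorbed.any():
            hits += int(seed_label[pos[absorbed]].sum())
            done += int(absorbed.sum())
            pos = pos[~absorbed]
        if len(pos) == 0:
            break
        u = rng.random(len(pos))
        step = (u[:, None] > cum[pos]).sum(axis=1)
        pos = nb[pos, step]
    if len(pos):
        raise RuntimeError("walkers failed to absorb")
    return hits / done


def abd_bruteforce(auto_border: np.ndarray, manual_border: np.ndarray,
                   spacing: tuple[float, float]) -> float:
    """All-pairs mean nearest-border distance in mm (O(n^2))."""
    pa = np.argwhere(auto_border).astype(float) * np.asarray(spacing)
    pm = np.argwhere(manual_border).astype(float) * np.asarray(spacing)
    dmin = np.empty(len(pa))
    for i, p in enumerate(pa):
        dmin[i] = np.sqrt(((pm - p) ** 2).sum(axis=1)).min()
    return float(dmin.mean())


def border_4n(px: np.ndarray) -> np.ndarray:
    """Border pixels: true with >= 1 false 4-neighbor inside the image."""
    out = np.zeros_like(px)
    H, W = px.shape
    for r in range(H):
        for c in range(W):
            if not px[r, c]:
                continue
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and not px[rr, cc]:
                    out[r, c] = True
                    break
    return out


def random_blob(shape: tuple[int, int], rng: np.random.Generator,
                threshold_q: float = 0.7) -> np.ndarray:
    """A random smooth blob mask (largest component of thresholded noise)."""
    from scipy import ndimage as ndi

    noise = ndi.gaussian_filter(rng.random(shape), sigma=4)
    mask = noise > np.quantile(noise, threshold_q)
    labels, n = ndi.label(mask)
    if n == 0:
        mask[shape[0] // 2, shape[1] // 2] = True
        return mask
    sizes = ndi.sum(mask, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
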