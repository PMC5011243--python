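"""Seeded random-walk lung segmentation inside the thorax.

The thorax pixels form the nodes of a weighted grid graph; an edge between
neighboring pixels i, j carries the Gaussian affinity

    w_ij = exp(-beta (g_i - g_j)^2)

on normalized intensities g, so a random walker crosses homogeneous tissue
freely but almost never steps across a density edge.  For each label, the
probability that a walker started at a pixel reaches that label's seeds
first is the harmonic function solving the combinatorial Dirichlet problem

    L_u x_u = -B x_m,

where L is the graph Laplacian (degree on the diagonal, -w_ij off-diagonal)
partitioned into unseeded (u) and seeded (m) blocks and x_m is the seed
indicator.  The system is sparse and symmetric positive definite and is
solved with a sparse LU factorization; probabilities over labels sum to 1.

Seeds are placed automatically from tissue-density priors: lung parenchyma
sits near -500 HU, so the thorax pixels closest to that target (mutually
separated, each expanded by its lowest-HU neighbors) become lung seeds,
while the thorax boundary ring and the highest-HU interior pixels (chest
wall / bone) become background seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .errors import NumericalError, SeedSelectionError, ValidationError
from .guided_filter import GrayImage
from .image_io import BinaryMask, CTSlice, DEFAULT_SPACING_MM

logger = logging.getLogger(__name__)

LABEL_LUNG = "lung"
LABEL_BACKGROUND = "background"


@dataclass
class RandomWalkParams:
    """Random-walk stage parameters.

    beta : edge-weight sharpness on normalized [0, 1] intensities (> 0).
    target_hu : HU value lung seeds are matched against (lung parenchyma).
    hu_tolerance : maximum |HU - target| for any usable lung seed; if no
        thorax pixel is that close the slice is declared lungless.
    n_initial : number of initial lung seeds.
    seed_min_sep : minimum Euclidean separation (px) between initial seeds.
    seed_expand_radius / seed_expand_k : each initial seed is expanded by its
        k lowest-HU thorax neighbors within this radius.
    n_background : number of highest-HU interior pixels added as background
        seeds (the thorax boundary ring is always background-seeded).
    connectivity : 4 or 8 pixel graph.
    """

    beta: float = 90.0
    target_hu: float = -500.0
    hu_tolerance: float = 300.0
    n_initial: int = 3
    seed_min_sep: float = 20.0
    seed_expand_radius: float = 5.0
    seed_expand_k: int = 8
    n_background: int = 3
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        if self.connectivity not in (4, 8):
            raise ValidationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.n_initial < 1 or self.seed_expand_k < 0 or self.n_background < 0:
            raise ValidationError("seed counts must be positive")


@dataclass
class SeedSet:
    """Labeled pixel coordinates driving the random walk.

    seeds : list of (row, col, label) with label in {lung, background}.
    provenance : "auto" (from select_seeds) or "user".
    """

    seeds: list[tuple[int, int, str]]
    provenance: str = "auto"

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for r, c, lab in self.seeds:
            if (r, c) in seen and seen[(r, c)] != lab:
                raise ValidationError(f"pixel ({r}, {c}) carries two labels")
            seen[(r, c)] = lab
        if not self.seeds:
            raise ValidationError("SeedSet must contain at least one seed")

    @property
    def labels(self) -> list[str]:
        out: list[str] = []
        for _, _, lab in self.seeds:
            if lab not in out:
                out.append(lab)
        return out

    def coords(self, label: str) -> np.ndarray:
        return np.array([(r, c) for r, c, lab in self.seeds if lab == label], dtype=int)


@dataclass
class PixelGraph:
    """Weighted grid graph over the true pixels of a mask.

    nodes : (N, 2) array of (row, col) node coordinates.
    index : (rows, cols) int array mapping pixel -> node id (-1 outside).
    edges : (E, 2) array of node-id pairs; weights : (E,) positive weights.
    """

    shape: tuple[int, int]
    connectivity: int
    beta: float
    nodes: np.ndarray
    index: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights <= 0).any():
            raise ValidationError("edge weights must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ProbabilityField:
    """Per-pixel, per-label membership probabilities.

    probs : (rows, cols, n_labels); each pixel's vector sums to 1.
    labels : ordered label names matching the last axis.
    """

    probs: np.ndarray
    labels: tuple[str, ...]
    spacing_mm: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(self.labels):
            raise ValidationError("probs must be (rows, cols, n_labels)")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValidationError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError("per-pixel probabilities must sum to 1")


def select_seeds(ct: CTSlice, thorax: BinaryMask,
                 params: RandomWalkParams | None = None) -> SeedSet:
    """Automatic HU-prior seed selection within the thorax.

    Raises :class:`SeedSelectionError` when no thorax pixel lies within
    ``hu_tolerance`` of the lung target HU (lungless slice).
    """
    if params is None:
        params = RandomWalkParams()
    if ct.shape != thorax.shape:
        raise ValidationError("slice and thorax shapes differ")
    tpx = thorax.pixels
    if not tpx.any():
        raise ValidationError("thorax mask is empty")

    hu = ct.pixels.astype(np.float64)
    rows, cols = np.nonzero(tpx)
    dist = np.abs(hu[rows, cols] - params.target_hu)
    if dist.min() > params.hu_tolerance:
        raise SeedSelectionError(
            f"no thorax pixel within {params.hu_tolerance} HU of target "
            f"{params.target_hu} HU; slice appears lungless"
        )

    # Greedy pick of n_initial pixels closest to the target HU, ties broken
    # toward the smaller (row, col), enforcing a minimum mutual separation.
    order = np.lexsort((cols, rows, dist))
    picked: list[tuple[int, int]] = []
    for k in order:
        if dist[k] > params.hu_tolerance:
            break
        r, c = int(rows[k]), int(cols[k])
        if all((r - pr) ** 2 + (c - pc) ** 2 >= params.seed_min_sep ** 2
               for pr, pc in picked):
            picked.append((r, c))
            if len(picked) == params.n_initial:
                break

    lung: list[tuple[int, int]] = list(picked)
    used = set(picked)
    rad = int(np.ceil(params.seed_expand_radius))
    dr, dc = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    disk = (dr ** 2 + dc ** 2 <= params.seed_expand_radius ** 2) & ~((dr == 0) & (dc == 0))
    offs = np.stack([dr[disk], dc[disk]], axis=1)
    H, W = ct.shape
    for r, c in picked:
        nb = offs + (r, c)
        ok = (nb[:, 0] >= 0) & (nb[:, 0] < H) & (nb[:, 1] >= 0) & (nb[:, 1] < W)
        nb = nb[ok]
        nb = nb[tpx[nb[:, 0], nb[:, 1]]]
        nb = np.array([p for p in nb if (int(p[0]), int(p[1])) not in used], dtype=int).reshape(-1, 2)
        if len(nb) == 0:
            continue
        nhu = hu[nb[:, 0], nb[:, 1]]
        sel = np.lexsort((nb[:, 1], nb[:, 0], nhu))[:params.seed_expand_k]
        for i in sel:
            p = (int(nb[i, 0]), int(nb[i, 1]))
            lung.append(p)
            used.add(p)

    # Background: thorax boundary ring plus the highest-HU interior pixels.
    ring = tpx & ~ndi.binary_erosion(tpx, structure=ndi.generate_binary_structure(2, 1),
                                     border_value=0)
    bg: list[tuple[int, int]] = [
        (int(r), int(c)) for r, c in np.argwhere(ring) if (int(r), int(c)) not in used
    ]
    interior = tpx & ~ring
    ir, ic = np.nonzero(interior)
    if len(ir) and params.n_background > 0:
        order_hi = np.lexsort((ic, ir, -hu[ir, ic]))
        n_added = 0
        for k in order_hi:
            p = (int(ir[k]), int(ic[k]))
            if p in used:
                continue
            bg.append(p)
            n_added += 1
            if n_added == params.n_background:
                break

    seeds = [(r, c, LABEL_LUNG) for r, c in lung] + [(r, c, LABEL_BACKGROUND) for r, c in bg]
    return SeedSet(seeds, provenance="auto")


def build_graph(image: GrayImage, mask: BinaryMask, beta: float = 90.0,
                connectivity: int = 4) -> PixelGraph:
    """Build the weighted pixel graph over the true pixels of ``mask``."""
    if beta <= 0:
        raise ValidationError(f"beta must be > 0, got {beta}")
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    mpx = mask.pixels
    if not mpx.any():
        raise ValidationError("empty mask: the graph has no nodes")

    index = np.full(mpx.shape, -1, dtype=np.int64)
    nodes = np.argwhere(mpx)
    index[mpx] = np.arange(len(nodes))
    g = image.pixels

    shifts = [(0, 1), (1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1)]
    e_a, e_b, wts = [], [], []
    for dr, dc in shifts:
        a = index[max(0, -dr):index.shape[0] - max(0, dr),
                  max(0, -dc):index.shape[1] - max(0, dc)]
        b = index[max(0, dr):index.shape[0] + min(0, dr) or None,
                  max(0, dc):index.shape[1] + min(0, dc) or None]
        ok = (a >= 0) & (b >= 0)
        ia, ib = a[ok], b[ok]
        ga = g[nodes[ia, 0], nodes[ia, 1]]
        gb = g[nodes[ib, 0], nodes[ib, 1]]
        e_a.append(ia)
        e_b.append(ib)
        wts.append(np.exp(-beta * (ga - gb) ** 2))
    edges = np.stack([np.concatenate(e_a), np.concatenate(e_b)], axis=1)
    weights = np.concatenate(wts)
    return PixelGraph(shape=mpx.shape, connectivity=connectivity, beta=float(beta),
                      nodes=nodes, index=index, edges=edges, weights=weights,
                      spacing_mm=mask.spacing_mm)


def _laplacian(graph: PixelGraph) -> sparse.csr_matrix:
    n = graph.n_nodes
    i, j, w = graph.edges[:, 0], graph.edges[:, 1], graph.weights
    W = sparse.coo_matrix((np.concatenate([w, w]),
                           (np.concatenate([i, j]), np.concatenate([j, i]))),
                          shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    return sparse.diags(deg) - W


def solve_dirichlet(graph: PixelGraph, seeds: SeedSet) -> ProbabilityField:
    """Solve the seeded Dirichlet problem on the pixel graph.

    Connected components without any seed are assigned to the background
    label with a warning.
    """
    labels = sorted(set(seeds.labels))
    if len(labels) < 2:
        raise ValidationError("solve_dirichlet needs seeds for >= 2 labels")
    if LABEL_BACKGROUND in labels:  # keep background last so it absorbs 1-sum
        labels.remove(LABEL_BACKGROUND)
        labels.append(LABEL_BACKGROUND)

    n = graph.n_nodes
    seed_idx, seed_lab = [], []
    for r, c, lab in seeds.seeds:
        node = graph.index[r, c] if (0 <= r < graph.shape[0] and 0 <= c < graph.shape[1]) else -1
        if node < 0:
            raise ValidationError(f"seed ({r}, {c}) lies outside the graph mask")
        seed_idx.append(int(node))
        seed_lab.append(lab)
    seed_idx = np.array(seed_idx)
    is_seed = np.zeros(n, bool)
    is_seed[seed_idx] = True

    i, j, w = graph.edges[:, 0], graph.edges[:, 1], graph.weights
    adj = sparse.coo_matrix((np.concatenate([w, w]),
                             (np.concatenate([i, j]), np.concatenate([j, i]))),
                            shape=(n, n)).tocsr()
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    seeded_comps = np.zeros(n_comp, bool)
    seeded_comps[comp[seed_idx]] = True
    orphan = ~seeded_comps[comp]
    if orphan.any():
        logger.warning("solve_dirichlet: %d nodes in seedless components assigned background",
                       int(orphan.sum()))

    L = _laplacian(graph)
    u_mask = ~is_seed & ~orphan
    u = np.nonzero(u_mask)[0]
    m = seed_idx

    probs = np.zeros((n, len(labels)))
    bg_col = labels.index(LABEL_BACKGROUND) if LABEL_BACKGROUND in labels else len(labels) - 1
    probs[orphan, bg_col] = 1.0
    for node, lab in zip(seed_idx, seed_lab):
        probs[node, labels.index(lab)] = 1.0

    if len(u):
        Luu = L[np.ix_(u, u)].tocsc()
        Lum = L[np.ix_(u, m)].tocsr()
        try:
            lu = splu(Luu)
        except RuntimeError as exc:
            raise NumericalError(f"Dirichlet system is singular: {exc}") from exc
        x_parts = []
        for col in range(len(labels) - 1):
            xm = np.array([1.0 if lab == labels[col] else 0.0 for lab in seed_lab])
            rhs = -Lum @ xm
            x = lu.solve(rhs)
            if not np.all(np.isfinite(x)):
                raise NumericalError("Dirichlet solve produced non-finite values")
            x_parts.append(np.clip(x, 0.0, 1.0))
        rest = np.clip(1.0 - np.sum(x_parts, axis=0), 0.0, 1.0)
        for col in range(len(labels) - 1):
            probs[u, col] = x_parts[col]
        probs[u, len(labels) - 1] = rest
        # renormalize against accumulated clipping error
        probs[u] /= probs[u].sum(axis=1, keepdims=True)

    field = np.zeros((*graph.shape, len(labels)))
    field[..., bg_col] = 1.0  # pixels outside the graph mask are background
    field[graph.nodes[:, 0], graph.nodes[:, 1], :] = probs
    return ProbabilityField(field, labels=tuple(labels), spacing_mm=graph.spacing_mm)


def field_to_mask(field: ProbabilityField) -> BinaryMask:
    """Assign lung where the lung probability strictly exceeds every other
    label's probability; ties go to background (conservative)."""
    if LABEL_LUNG not in field.labels:
        raise ValidationError("field carries no 'lung' label")
    li = field.labels.index(LABEL_LUNG)
    lung = field.probs[..., li]
    others = np.delete(field.probs, li, axis=2).max(axis=2)
    return BinaryMask(lung > others, spacing_mm=field.spacing_mm)
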