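import numpy as np
import pytest

from lungseg import (BinaryMask, CTSlice, GrayImage, SeedSelectionError,
                     ValidationError, build_graph, field_to_mask, select_seeds,
                     solve_dirichlet)
from lungseg.random_walk import (LABEL_BACKGROUND, LABEL_LUNG, PixelGraph,
                                 RandomWalkParams, SeedSet)
from oracles import dirichlet_dense, mc_absorption


def gray(arr):
    return GrayImage(np.asarray(arr, dtype=float))


def full_mask(shape):
    return BinaryMask(np.ones(shape, bool))


def chain_graph(weights):
    """A 1 x n pixel chain with explicitly chosen edge weights."""
    n = len(weights) + 1
    nodes = np.array([[0, i] for i in range(n)])
    index = np.arange(n).reshape(1, n)
    edges = np.array([[i, i + 1] for i in range(n - 1)])
    return PixelGraph(shape=(1, n), connectivity=4, beta=1.0, nodes=nodes,
                      index=index, edges=edges, weights=np.asarray(weights, float))


class TestSelectSeeds:
    def test_initial_seeds_fall_inside_lungs(self, phantom_small):
        spec, ct, truth, _ = phantom_small
        from lungseg import apply_threshold, normalize_hu, otsu_threshold
        from lungseg import extract_thorax, grow_background

        g = normalize_hu(ct)
        low = apply_threshold(g, otsu_threshold(g).level)
        thorax = extract_thorax(low, grow_background(low))
        params = RandomWalkParams()
        seeds = select_seeds(ct, thorax, params)
        initial = seeds.coords(LABEL_LUNG)[:params.n_initial]
        for r, c in initial:
            assert truth.pixels[r, c], f"initial lung seed ({r},{c}) outside lungs"
        assert len(seeds.coords(LABEL_BACKGROUND)) >= 1

    def test_lungless_thorax_raises(self):
        hu = np.full((32, 32), 40, dtype=np.int32)
        ct = CTSlice(hu, spacing_mm=(1, 1))
        thorax = full_mask((32, 32))
        with pytest.raises(SeedSelectionError):
            select_seeds(ct, thorax)

    def test_tie_break_prefers_smaller_row_col(self):
        """Two pixels equally far from the target HU: the lexicographically
        smaller coordinate is seeded first."""
        hu = np.full((32, 32), 40, dtype=np.int32)
        hu[10, 10] = -400   # |HU + 500| = 100
        hu[5, 20] = -600    # |HU + 500| = 100, smaller row wins
        ct = CTSlice(hu, spacing_mm=(1, 1))
        seeds = select_seeds(ct, full_mask((32, 32)),
                             RandomWalkParams(n_initial=1, seed_expand_k=0))
        assert seeds.seeds[0][:2] == (5, 20)

    def test_no_pixel_carries_two_labels(self, phantom_small):
        spec, ct, truth, _ = phantom_small
        thorax = BinaryMask(np.ones(ct.shape, bool))
        seeds = select_seeds(ct, thorax)
        coords = [(r, c) for r, c, _ in seeds.seeds]
        assert len(coords) == len(set(coords))


class TestBuildGraph:
    def test_equal_intensity_weight_is_one(self):
        g = gray(np.full((2, 2), 0.4))
        graph = build_graph(g, full_mask((2, 2)), beta=90.0)
        np.testing.assert_allclose(graph.weights, 1.0)

    def test_extreme_contrast_weight(self):
        px = np.zeros((1, 2))
        px[0, 1] = 1.0
        graph = build_graph(gray(px), full_mask((1, 2)), beta=90.0)
        assert graph.weights[0] == pytest.approx(np.exp(-90.0))

    def test_3x3_uniform_grid_edge_count(self):
        graph = build_graph(gray(np.full((3, 3), 0.5)), full_mask((3, 3)),
                            connectivity=4)
        assert len(graph.edges) == 12  # 2 * 3 * (3 - 1) grid edges
        np.testing.assert_allclose(graph.weights, 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            build_graph(gray(np.zeros((4, 4))), BinaryMask(np.zeros((4, 4), bool)))


class TestSolveDirichlet:
    def test_symmetric_chain_midpoint(self):
        graph = chain_graph([1.0, 1.0])
        seeds = SeedSet([(0, 0, LABEL_LUNG), (0, 2, LABEL_BACKGROUND)])
        field = solve_dirichlet(graph, seeds)
        li = field.labels.index(LABEL_LUNG)
        assert field.probs[0, 1, li] == pytest.approx(0.5)

    def test_weighted_chain_exact_value(self):
        """Single unknown: x1 = (w01 * 1 + w12 * 0) / (w01 + w12) = 0.25."""
        graph = chain_graph([1.0, 3.0])
        seeds = SeedSet([(0, 0, LABEL_LUNG), (0, 2, LABEL_BACKGROUND)])
        field = solve_dirichlet(graph, seeds)
        li = field.labels.index(LABEL_LUNG)
        assert field.probs[0, 1, li] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("size", [4, 9, 14, 20])
    def test_sparse_matches_dense_direct_solve(self, size):
        rng = np.random.default_rng(size)
        g = rng.random((size, size))
        seeds_list = [(0, 0, LABEL_LUNG),
                      (size - 1, size - 1, LABEL_BACKGROUND),
                      (size // 2, size // 2, LABEL_LUNG)]
        graph = build_graph(gray(g), full_mask((size, size)), beta=50.0)
        field = solve_dirichlet(graph, SeedSet(seeds_list))
        li = field.labels.index(LABEL_LUNG)
        ref = dirichlet_dense(g, 50.0, seeds_list, LABEL_LUNG)
        assert np.abs(field.probs[:, :, li] - ref).max() < 1e-6

    def test_probability_field_invariants(self):
        rng = np.random.default_rng(0)
        g = rng.random((16, 16))
        seeds_list = [(0, 0, LABEL_LUNG), (15, 15, LABEL_BACKGROUND)]
        graph = build_graph(gray(g), full_mask((16, 16)), beta=30.0)
        field = solve_dirichlet(graph, SeedSet(seeds_list))
        assert field.probs.min() >= 0.0 and field.probs.max() <= 1.0
        np.testing.assert_allclose(field.probs.sum(axis=2), 1.0, atol=1e-6)
        li = field.labels.index(LABEL_LUNG)
        assert field.probs[0, 0, li] == 1.0       # seed pixels are exact
        assert field.probs[15, 15, li] == 0.0

    def test_matches_monte_carlo_absorbing_walks(self):
        """The Dirichlet solution equals the probability that an absorbing
        random walker reaches a lung seed first (10^5 walks, +-0.02)."""
        rng = np.random.default_rng(123)
        g = rng.random((16, 16))
        seeds_list = [(0, 0, LABEL_LUNG), (15, 15, LABEL_BACKGROUND)]
        graph = build_graph(gray(g), full_mask((16, 16)), beta=10.0)
        field = solve_dirichlet(graph, SeedSet(seeds_list))
        li = field.labels.index(LABEL_LUNG)
        for start in [(8, 8), (2, 12), (13, 3)]:
            est = mc_absorption(g, 10.0, seeds_list, start, LABEL_LUNG,
                                n_walks=100_000, rng=np.random.default_rng(7))
            assert abs(field.probs[start[0], start[1], li] - est) < 0.02

    def test_seedless_component_assigned_background(self, caplog):
        px = np.zeros((4, 9), bool)
        px[:, :4] = True
        px[:, 5:] = True  # two islands separated by a false column
        g = gray(np.full((4, 9), 0.5))
        graph = build_graph(g, BinaryMask(px))
        seeds = SeedSet([(0, 0, LABEL_LUNG), (3, 3, LABEL_BACKGROUND)])
        with caplog.at_level("WARNING"):
            field = solve_dirichlet(graph, seeds)
        assert "seedless components" in caplog.text
        bi = field.labels.index(LABEL_BACKGROUND)
        assert (field.probs[:, 5:, bi] == 1.0).all()

    def test_single_label_rejected(self):
        graph = chain_graph([1.0, 1.0])
        with pytest.raises(ValidationError):
            solve_dirichlet(graph, SeedSet([(0, 0, LABEL_LUNG)]))


class TestFieldToMask:
    def test_tie_goes_to_background(self):
        graph = chain_graph([1.0, 1.0])
        seeds = SeedSet([(0, 0, LABEL_LUNG), (0, 2, LABEL_BACKGROUND)])
        mask = field_to_mask(solve_dirichlet(graph, seeds))
        assert mask.pixels[0, 0]          # lung seed
        assert not mask.pixels[0, 1]      # exact 0.5/0.5 tie -> background
        assert not mask.pixels[0, 2]

    def test_mask_is_argmax_of_dense_solution(self):
        rng = np.random.default_rng(1)
        g = rng.random((16, 16))
        seeds_list = [(0, 0, LABEL_LUNG), (15, 15, LABEL_BACKGROUND)]
        graph = build_graph(gray(g), full_mask((16, 16)), beta=50.0)
        mask = field_to_mask(solve_dirichlet(graph, SeedSet(seeds_list)))
        ref = dirichlet_dense(g, 50.0, seeds_list, LABEL_LUNG)
        np.testing.assert_array_equal(mask.pixels, ref > 0.5)


class TestBetaMonotonicity:
    def test_dice_non_decreasing_in_beta(self, phantom_noisy_small):
        """Sharper edge weights align the lung boundary with the intensity
        edge: Dice against the intensity-defined lungs does not decrease
        over beta in {1, 10, 100}."""
        from lungseg import (apply_threshold, dice, extract_thorax,
                             grow_background, normalize_hu, otsu_threshold)

        spec, ct, truth, _ = phantom_noisy_small
        g = normalize_hu(ct)
        low = apply_threshold(g, otsu_threshold(g).level)
        thorax = extract_thorax(low, grow_background(low))
        seeds = select_seeds(ct, thorax)
        scores = []
        for beta in (1.0, 10.0, 100.0):
            graph = build_graph(g, thorax, beta=beta)
            mask = field_to_mask(solve_dirichlet(graph, seeds))
            scores.append(dice(mask, truth))
        assert scores[0] <= scores[1] + 1e-9
        assert scores[1] <= scores[2] + 1e-9
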