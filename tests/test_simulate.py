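"""Forward simulation: trees, histories, and ambiguity treatments."""

import numpy as np
import pytest

import biomeshift as bs
from biomeshift.anagenesis import transition_probs
from biomeshift.simulate import (
    SimulationDesign,
    mask_tips,
    recode_dec,
    recode_dec_masks,
    simulate_history,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_tips_unit_cherry(self, rng):
        tree = simulate_tree(2, rng)
        assert tree.n_tips == 2
        assert tree.branch_lengths[0] == pytest.approx(1.0)
        assert tree.branch_lengths[1] == pytest.approx(1.0)

    def test_yule_shape_and_height(self, rng):
        tree = simulate_tree(50, rng)
        assert tree.n_tips == 50
        assert len(tree.left) == 49
        assert tree.height == pytest.approx(1.0)
        # ultrametric: all tips at depth == height
        depth = np.zeros(tree.n_nodes)
        for k in range(len(tree.left) - 1, -1, -1):
            v = tree.n_tips + k
            for c in (tree.left[k], tree.right[k]):
                depth[c] = depth[v] + tree.branch_lengths[c]
        assert np.allclose(depth[:50], 1.0)

    def test_seed_determinism(self):
        a = simulate_tree(10, np.random.default_rng(77))
        b = simulate_tree(10, np.random.default_rng(77))
        assert a.newick() == b.newick()
        c = simulate_tree(10, np.random.default_rng(78))
        assert a.newick() != c.newick()


class TestSimulateHistory:
    def test_static_process_copies_root(self, space2, rng):
        q = bs.build_q(bs.AnageneticRates(0, 0, 0, 0, 0), space2)
        tensor = bs.build_clado_tensor(space2, bs.CladoParams(1, 0, 0))
        tree = simulate_tree(20, rng)
        h = simulate_history(tree, q, tensor, rng)
        assert np.all(h.node_states == h.root_state)
        assert np.all(h.corner_states[:-1] == h.root_state)

    def test_single_branch_marginal_matches_expm(self, space2, rng):
        """Empirical tip-state distribution after Gillespie simulation on
        one branch matches the matrix-exponential transition row."""
        rates = bs.AnageneticRates(0.6, 0.9, 0.4, 0.7, 1.2)
        q = bs.build_q(rates, space2)
        tensor = bs.build_clado_tensor(space2, bs.CladoParams(1, 0, 0))
        tree = bs.parse_newick("(A:1.0,B:1.0);")
        start = space2.index("22")
        pi = np.zeros(5)
        pi[start] = 1.0
        n = 40_000
        counts = np.zeros(5)
        for _ in range(n):
            h = simulate_history(tree, q, tensor, rng, root_distribution=pi)
            counts[h.node_states[0]] += 1
        expected = transition_probs(q, 1.0)[start]
        tv = 0.5 * np.abs(counts / n - expected).sum()
        assert tv < 0.015

    def test_node_event_frequencies_match_tensor(self, space2, rng):
        """Cladogenetic daughter-pair frequencies at a fixed parent state
        match the tensor slice probabilities."""
        q = bs.build_q(bs.AnageneticRates(0, 0, 0, 0, 0), space2)
        params = bs.CladoParams(0.5, 0.3, 0.2)
        tensor = bs.build_clado_tensor(space2, params)
        tree = bs.parse_newick("(A:0.1,B:0.1);")
        hc = space2.index("22")
        pi = np.zeros(5)
        pi[hc] = 1.0
        n = 30_000
        pair_counts: dict[tuple[int, int], int] = {}
        for _ in range(n):
            h = simulate_history(tree, q, tensor, rng, root_distribution=pi)
            key = (int(h.corner_states[0]), int(h.corner_states[1]))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        lj, rk, pp = tensor.slice(hc)
        for j, k, p in zip(lj, rk, pp):
            freq = pair_counts.get((int(j), int(k)), 0) / n
            assert freq == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / n) + 1e-3)

    def test_segments_tile_branches(self, space2, rng):
        rates = bs.AnageneticRates(1, 1, 1, 1, 1)
        q = bs.build_q(rates, space2)
        tensor = bs.build_clado_tensor(space2, bs.CladoParams.from_free(0.3, 0.2))
        tree = simulate_tree(10, rng)
        h = simulate_history(tree, q, tensor, rng)
        for node, path in h.segments.items():
            assert sum(d for _, d in path) == pytest.approx(
                tree.branch_lengths[node]
            )
            assert path[-1][0] == h.node_states[node]


class TestMaskTips:
    def _truth(self, space3):
        return [(2, 1, 1), (2, 1, 0), (2, 2, 0), (2, 0, 0)]

    def test_worst_case_masks(self, space3, rng):
        truth = self._truth(space3)
        design = SimulationDesign(n_tips=4, n_biomes=3, resolve_fraction=0.0)
        masks = mask_tips(truth, list("abcd"), space3, design, rng)
        assert masks[0].n_compatible == 4  # 2 unestablished biomes
        assert masks[2].n_compatible == 2
        admitted = {s.digits() for s in masks[0].admitted(space3)}
        assert admitted == {"211", "210", "201", "200"}

    @pytest.mark.parametrize(
        "fraction,expected_left", [(1 / 3, 3), (2 / 3, 2), (1.0, 1)]
    )
    def test_resolution_removes_ceil_fraction(self, space3, rng, fraction,
                                              expected_left):
        """From the 4-state worst case, 33% removes 1 of 3 non-true states,
        66% removes 2, and full confirmation leaves a singleton."""
        truth = [(2, 1, 1)]
        design = SimulationDesign(
            n_tips=2, n_biomes=3, resolve_fraction=fraction,
            treated_tip_fraction=1.0,
        )
        masks = mask_tips(truth, ["a"], space3, design, rng)
        assert masks[0].n_compatible == expected_left

    def test_truth_never_removed(self, space3, rng):
        truth = self._truth(space3)
        for frac in (0.0, 1 / 3, 2 / 3, 1.0):
            design = SimulationDesign(
                n_tips=4, n_biomes=3, resolve_fraction=frac
            )
            masks = mask_tips(truth, list("abcd"), space3, design, rng)
            for codes, m in zip(truth, masks):
                assert m.state_mask[space3.index(codes)] == 1.0

    def test_untreated_fraction_left_ambiguous(self, space3, rng):
        truth = [(2, 1, 1)] * 100
        labels = [f"t{i}" for i in range(100)]
        design = SimulationDesign(
            n_tips=100, n_biomes=3, resolve_fraction=1.0,
            treated_tip_fraction=0.25,
        )
        masks = mask_tips(truth, labels, space3, design, rng)
        sizes = np.array([m.n_compatible for m in masks])
        assert (sizes == 1).sum() == 25
        assert (sizes == 4).sum() == 75


class TestRecodeDec:
    def test_examples(self):
        assert recode_dec((2, 1, 1)) == (1, 0, 0)
        assert recode_dec((2, 2, 2)) == (1, 1, 1)
        assert recode_dec((0, 1, 2)) == (0, 0, 1)

    def test_masks_are_singletons(self, space3):
        from biomeshift.dec import build_dec_space

        dspace = build_dec_space(3)
        masks = recode_dec_masks([(2, 1, 1), (2, 2, 0)], ["a", "b"], dspace)
        for m in masks:
            assert m.n_compatible == 1
        assert masks[0].state_mask[dspace.index((1, 0, 0))] == 1
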