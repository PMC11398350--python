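"""Joint ancestral-state sampling and affinity-type summaries."""

import numpy as np
import pytest

import biomeshift as bs
from biomeshift.ancestral import (
    AncestralSummary,
    HistorySample,
    affinity_accuracy,
    null_baseline,
    sample_history,
    summarize_histories,
)
from biomeshift.likelihood import PruningWorkspace

from conftest import brute_force_loglik, random_masks


def _setup(space, rng, newick="((A:0.3,B:0.4):0.5,C:0.8);"):
    tree = bs.parse_newick(newick)
    rates = bs.AnageneticRates(*rng.exponential(1.0, 5))
    clado = bs.CladoParams.from_free(0.3, 0.2)
    q = bs.build_q(rates, space)
    tensor = bs.build_clado_tensor(space, clado)
    masks = random_masks(tree, space.n_states, rng)
    ws = PruningWorkspace(tree, masks, space)
    trans = ws.transition_stack(q)
    pi = np.full(space.n_states, 1.0 / space.n_states)
    return tree, q, tensor, masks, ws, trans, pi


def test_no_change_limit_recovers_tip_state(space2):
    """Zero rates and pure equal inheritance pin every node and corner to
    the shared tip state."""
    tree = bs.parse_newick("(A:0.5,B:0.5);")
    q = bs.build_q(bs.AnageneticRates(0, 0, 0, 0, 0), space2)
    tensor = bs.build_clado_tensor(space2, bs.CladoParams(1, 0, 0))
    h_idx = space2.index("20")
    mask = np.zeros(5)
    mask[h_idx] = 1
    masks = [bs.TipAmbiguity(s, mask.copy()) for s in "AB"]
    ws = PruningWorkspace(tree, masks, space2)
    trans = ws.transition_stack(q)
    pi = np.full(5, 0.2)
    rng = np.random.default_rng(0)
    for _ in range(20):
        h = sample_history(ws, trans, tensor, pi, rng)
        assert h.node_states[tree.root_id] == h_idx
        assert np.all(h.corner_states[:2] == h_idx)


def test_node_marginals_match_enumeration_oracle(space2, rng):
    """Empirical root-state frequencies over joint draws agree with the
    brute-force conditional marginal at fixed parameters (chi-square not
    rejected at alpha = 0.01)."""
    from scipy.stats import chisquare

    tree, q, tensor, masks, ws, trans, pi = _setup(space2, rng)
    root = tree.root_id

    # oracle: condition the exhaustive joint on each root state
    lls = []
    for i in range(5):
        pi_i = np.zeros(5)
        pi_i[i] = pi[i]
        with np.errstate(divide="ignore"):
            lls.append(brute_force_loglik(tree, masks, q, tensor, pi_i))
    w = np.exp(np.array(lls) - max(lls))
    expected = w / w.sum()

    n = 20_000
    counts = np.zeros(5)
    for _ in range(n):
        h = sample_history(ws, trans, tensor, pi, rng)
        counts[h.node_states[root]] += 1
    keep = expected > 1e-6
    _, pval = chisquare(counts[keep], expected[keep] / expected[keep].sum() * counts[keep].sum())
    assert pval > 0.01


def test_corner_draws_respect_tensor_support(space2, rng):
    tree, q, tensor, masks, ws, trans, pi = _setup(space2, rng)
    for _ in range(200):
        h = sample_history(ws, trans, tensor, pi, rng)
        for k in range(len(tree.left)):
            v = tree.n_tips + k
            a, b = tree.left[k], tree.right[k]
            p = tensor.prob(
                int(h.node_states[v]),
                int(h.corner_states[a]),
                int(h.corner_states[b]),
            )
            assert p > 0


class TestSummaries:
    def test_single_sample_is_one_hot(self, space2):
        h = HistorySample(
            node_states=np.array([2, 0, 4]),  # cherry: 2 tips + root
            corner_states=np.array([3, 0, -1]),
        )
        s = summarize_histories([h], space2)
        assert s.node_probs.shape == (1, 2, 3)
        # root state index 4 = codes (2, 2)
        assert np.allclose(s.node_probs[0, 0], [0, 0, 1])
        assert np.allclose(s.node_probs[0, 1], [0, 0, 1])
        # corner of tip 0 is state 3 = (2, 1)
        assert np.allclose(s.corner_probs[0, 1], [0, 1, 0])
        assert np.isnan(s.corner_probs[2]).all()

    def test_uniform_state_frequencies_marginalize(self, space2):
        """Uniform frequency over {02,12,20,21,22} gives biome-1 (hot)
        affinity-type probabilities (0.2, 0.2, 0.6)."""
        samples = [
            HistorySample(
                node_states=np.array([0, 0, i]),
                corner_states=np.array([i, i, -1]),
            )
            for i in range(5)
        ]
        s = summarize_histories(samples, space2)
        assert np.allclose(s.node_probs[0, 0], [0.2, 0.2, 0.6])

    def test_probabilities_sum_to_one(self, space2, rng):
        samples = [
            HistorySample(
                node_states=rng.integers(0, 5, size=5),
                corner_states=np.append(rng.integers(0, 5, size=4), -1),
            )
            for _ in range(7)
        ]
        s = summarize_histories(samples, space2)
        assert np.allclose(s.node_probs.sum(axis=2), 1.0)
        defined = ~np.isnan(s.corner_probs).all(axis=(1, 2))
        assert np.allclose(s.corner_probs[defined].sum(axis=2), 1.0)


class TestAccuracy:
    def _summary(self, node_probs, corner_probs, n_tips=2):
        return AncestralSummary(
            node_probs=node_probs,
            corner_probs=corner_probs,
            n_tips=n_tips,
            n_levels=3,
        )

    def test_perfect_one_hot_accuracy(self, space2):
        truth_nodes = np.array([0, 0, 4])
        truth_corners = np.array([2, 0, -1])
        codes = space2.codes_array()
        node_probs = np.eye(3)[codes[truth_nodes[2:]]]
        corner_probs = np.full((3, 2, 3), np.nan)
        corner_probs[0] = np.eye(3)[codes[2]]
        corner_probs[1] = np.eye(3)[codes[0]]
        s = self._summary(node_probs, corner_probs)
        acc = affinity_accuracy(truth_nodes, truth_corners, s, space2)
        assert all(v == pytest.approx(1.0) for v in acc.values())

    def test_uniform_summary_gives_one_third(self, space2):
        truth_nodes = np.array([0, 0, 4])
        truth_corners = np.array([2, 0, -1])
        node_probs = np.full((1, 2, 3), 1 / 3)
        corner_probs = np.full((3, 2, 3), 1 / 3)
        corner_probs[2] = np.nan
        s = self._summary(node_probs, corner_probs)
        acc = affinity_accuracy(truth_nodes, truth_corners, s, space2)
        assert all(v == pytest.approx(1 / 3) for v in acc.values())

    def test_two_location_mean(self, space2):
        """Supports 0.7 and 0.9 on the same true type average to 0.8."""
        truth_nodes = np.array([0, 0, 4])  # root = HC, codes (2, 2)
        truth_corners = np.full(3, -1)
        node_probs = np.zeros((1, 2, 3))
        node_probs[0, 0] = [0.2, 0.1, 0.7]
        node_probs[0, 1] = [0.05, 0.05, 0.9]
        s = self._summary(node_probs, np.full((3, 2, 3), np.nan))
        acc = affinity_accuracy(truth_nodes, truth_corners, s, space2)
        assert acc[2] == pytest.approx(0.8)
        assert 0 not in acc and 1 not in acc  # absent types not reported


def test_annotated_newick_embeds_node_probabilities(space2):
    from biomeshift.ancestral import annotated_newick

    tree = bs.parse_newick("((A:1,B:1):1,C:2);")
    node_probs = np.zeros((2, 2, 3))
    node_probs[:, :, 2] = 0.75
    node_probs[:, :, 1] = 0.25
    s = AncestralSummary(
        node_probs=node_probs,
        corner_probs=np.full((5, 2, 3), np.nan),
        n_tips=3,
        n_levels=3,
    )
    out = annotated_newick(tree, s, space2)
    assert out.endswith(";")
    assert "Hot_p2=0.7500" in out and "Cold_p1=0.2500" in out
    # stripping comments yields the original topology and lengths
    import re

    stripped = re.sub(r"\[&[^\]]*\]", "", out)
    back = bs.parse_newick(stripped)
    assert set(back.tip_labels) == {"A", "B", "C"}


class TestNullBaseline:
    def test_uniform_replicates(self, space2):
        s = AncestralSummary(
            node_probs=np.full((2, 2, 3), 1 / 3),
            corner_probs=np.full((5, 2, 3), 1 / 3),
            n_tips=3,
            n_levels=3,
        )
        base = null_baseline([s, s])
        assert all(v == pytest.approx(1 / 3) for v in base.values())

    def test_pooled_mean_recomputed(self, rng):
        summaries = []
        for _ in range(3):
            p = rng.dirichlet(np.ones(3), size=(4, 2))
            summaries.append(
                AncestralSummary(
                    node_probs=p,
                    corner_probs=np.full((9, 2, 3), np.nan),
                    n_tips=5,
                    n_levels=3,
                )
            )
        base = null_baseline(summaries)
        pooled = np.concatenate([s.node_probs.reshape(-1, 3) for s in summaries])
        for a in range(3):
            assert base[a] == pytest.approx(pooled[:, a].mean())

    def test_single_replicate_rejected(self, space2):
        s = AncestralSummary(
            node_probs=np.full((1, 2, 3), 1 / 3),
            corner_probs=np.full((3, 2, 3), np.nan),
            n_tips=2,
            n_levels=3,
        )
        with pytest.raises(ValueError):
            null_baseline([s])
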