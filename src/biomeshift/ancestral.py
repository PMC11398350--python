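"""Joint ancestral-state sampling and per-biome affinity summaries.

A history draw assigns a state to every internal node (immediately before
cladogenesis) and to the start of every branch (the "corner", immediately
after cladogenesis), jointly and conditionally on the full tip data and the
current parameters.  Sampling runs backward-filtering / forward-sampling:
the root state is drawn proportional to ``pi_i * D(root)_i``, each node's
daughter corner pair proportional to ``P(i; j, k) F_left(j) F_right(k)``,
and each child node state proportional to ``expm(Q t)[j, j'] D(child)_j'``.

Summaries marginalize sampled states per biome into affinity-type
probabilities (non-affinity / enabled / established), the scale on which
reconstruction accuracy and the chance-level null baseline are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cladogenesis import CladoTensor
from .likelihood import PruningWorkspace

__all__ = [
    "HistorySample",
    "AncestralSummary",
    "sample_history",
    "summarize_histories",
    "affinity_accuracy",
    "null_baseline",
    "annotated_newick",
]


@dataclass(frozen=True)
class HistorySample:
    """One joint draw: per-node pre-cladogenesis states (tips hold their
    sampled realized state) and per-branch corner states (-1 at the root,
    which has no branch above it)."""

    node_states: np.ndarray
    corner_states: np.ndarray


def _draw(rng: np.random.Generator, weights: np.ndarray) -> int:
    tot = weights.sum()
    if tot <= 0:
        raise RuntimeError("zero normalizer while sampling ancestral states")
    return int(rng.choice(len(weights), p=weights / tot))


def sample_history(
    ws: PruningWorkspace,
    trans: np.ndarray,
    tensor: CladoTensor,
    root_pi: np.ndarray,
    rng: np.random.Generator,
) -> HistorySample:
    tree = ws.tree
    partials, tops = ws.branch_tops(trans, tensor)
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    corner_states = np.full(tree.n_nodes, -1, dtype=np.int64)

    root = tree.root_id
    node_states[root] = _draw(rng, root_pi * partials[root])
    # preorder = reverse postorder over internal nodes
    for k in range(len(tree.left) - 1, -1, -1):
        v = tree.n_tips + k
        i = node_states[v]
        a, b = tree.left[k], tree.right[k]
        lj, rk, pp = tensor.slice(i)
        e = _draw(rng, pp * tops[a][lj] * tops[b][rk])
        corner_states[a], corner_states[b] = lj[e], rk[e]
        for c in (a, b):
            node_states[c] = _draw(
                rng, trans[c][corner_states[c]] * partials[c]
            )
    return HistorySample(node_states=node_states, corner_states=corner_states)


@dataclass
class AncestralSummary:
    """Per-location, per-biome affinity-type probabilities.

    ``node_probs`` covers internal nodes (pre-cladogenesis) in tree node-id
    order; ``corner_probs`` covers branch starts keyed by the child node id
    (the root row is all-nan).  The trailing axis indexes affinity types
    (0, 1, 2 for the full model; 0, 1 presence coding for the baseline) and
    sums to one wherever defined.
    """

    node_probs: np.ndarray  # (n_internal, n_biomes, n_levels)
    corner_probs: np.ndarray  # (n_nodes, n_biomes, n_levels)
    n_tips: int
    n_levels: int

    def stacked(self, include_corners: bool = True) -> np.ndarray:
        """All defined (location, biome) rows as one (m, n_levels) array."""
        rows = [self.node_probs.reshape(-1, self.n_levels)]
        if include_corners:
            corners = self.corner_probs[
                ~np.isnan(self.corner_probs).all(axis=(1, 2))
            ]
            rows.append(corners.reshape(-1, self.n_levels))
        return np.concatenate(rows, axis=0)


def summarize_histories(
    samples: Sequence[HistorySample],
    space,
    n_levels: int = 3,
) -> AncestralSummary:
    """Turn joint history draws into per-biome affinity-type frequencies."""
    if not samples:
        raise ValueError("need at least one history sample")
    codes = space.codes_array()  # (n_states, n_biomes)
    n_biomes = codes.shape[1]
    n_nodes = samples[0].node_states.size
    n_tips = (n_nodes + 1) // 2
    n_internal = n_nodes - n_tips
    onehot = np.eye(n_levels)[codes]  # (n_states, n_biomes, n_levels)

    node_acc = np.zeros((n_internal, n_biomes, n_levels))
    corner_acc = np.zeros((n_nodes, n_biomes, n_levels))
    for h in samples:
        node_acc += onehot[h.node_states[n_tips:]]
        has_corner = h.corner_states >= 0
        corner_acc[has_corner] += onehot[h.corner_states[has_corner]]
    node_probs = node_acc / len(samples)
    corner_probs = corner_acc / len(samples)
    corner_probs[samples[0].corner_states < 0] = np.nan
    return AncestralSummary(
        node_probs=node_probs,
        corner_probs=corner_probs,
        n_tips=n_tips,
        n_levels=n_levels,
    )


def _truth_onehot_rows(
    truth_nodes: np.ndarray,
    truth_corners: np.ndarray,
    codes: np.ndarray,
    n_tips: int,
) -> np.ndarray:
    """True affinity codes per (location, biome), matching ``stacked``."""
    rows = [codes[truth_nodes[n_tips:]].reshape(-1)]
    has = truth_corners >= 0
    rows.append(codes[truth_corners[has]].reshape(-1))
    return np.concatenate(rows)


def affinity_accuracy(
    truth_nodes: np.ndarray,
    truth_corners: np.ndarray,
    summary: AncestralSummary,
    space,
) -> dict[int, float]:
    """Mean posterior probability on the true affinity, per affinity type.

    For each type ``a`` the accuracy is the average, over every (location,
    biome) whose true code is ``a``, of the posterior probability the
    summary assigns to ``a``.  Types with no occurrences are absent from
    the result rather than reported as zero.
    """
    codes = space.codes_array()
    truth = _truth_onehot_rows(truth_nodes, truth_corners, codes, summary.n_tips)
    probs = summary.stacked()
    flat = probs.reshape(-1, summary.n_levels)
    if truth.size != flat.shape[0]:
        raise ValueError(
            f"truth has {truth.size} (location, biome) cells, summary has "
            f"{flat.shape[0]}"
        )
    support = flat[np.arange(truth.size), truth]
    out: dict[int, float] = {}
    for a in range(summary.n_levels):
        sel = truth == a
        if sel.any():
            out[a] = float(support[sel].mean())
    return out


def null_baseline(
    summaries: Sequence[AncestralSummary],
) -> dict[int, float]:
    """Chance level: mean posterior probability assigned to each affinity
    type, pooled over every (location, biome) of every replicate posterior.

    Reconstruction accuracy for a type is judged against this pooled mean
    rather than against a uniform 1/levels, because a model can inflate
    apparent accuracy simply by saying the common type everywhere.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicate summaries for a baseline")
    pooled = np.concatenate([s.stacked() for s in summaries], axis=0)
    means = pooled.mean(axis=0)
    return {a: float(means[a]) for a in range(summaries[0].n_levels)}


def annotated_newick(tree, summary: AncestralSummary, space) -> str:
    """Newick string with per-biome affinity probabilities as comments.

    Internal nodes carry an extended-newick comment
    ``[&<biome>_p0=..,<biome>_p1=..,<biome>_p2=..]`` (two probability
    levels for the presence/absence baseline) built from the node's
    marginal summary; tips are left unannotated.
    """
    labels = space.biome_labels

    def comment(k: int) -> str:
        parts = []
        for b, biome in enumerate(labels):
            p = summary.node_probs[k, b]
            parts.append(
                ",".join(
                    f"{biome}_p{a}={p[a]:.4f}" for a in range(summary.n_levels)
                )
            )
        return "[&" + ",".join(parts) + "]"

    def fmt(node: int) -> str:
        if tree.is_tip(node):
            base = tree.tip_labels[node]
        else:
            k = int(np.flatnonzero(tree.internal_ids == node)[0])
            base = f"({fmt(tree.left[k])},{fmt(tree.right[k])}){comment(k)}"
        if node == tree.root_id:
            return base
        return f"{base}:{tree.branch_lengths[node]:.12g}"

    return fmt(tree.root_id) + ";"
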