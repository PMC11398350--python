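"""Forward simulation: trees, character histories, and tip-data treatments.

Trees come from a pure-birth (Yule) process rescaled to unit root height,
matching the convention that rates are expressed per unit tree height.
Character histories evolve by the Gillespie algorithm along branches
(competing exponentials over the allowed anagenetic events of the current
state) with cladogenetic daughter states drawn from the tensor at every
node.  Tip observations are derived from the true tip states under the
ambiguity treatments used in the validation experiments: worst-case coding
of unestablished biomes, partial resolution (a fraction of non-true states
removed for a fraction of tips), or entire confirmation, plus binary
recoding for the presence/absence baseline.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .cladogenesis import CladoTensor
from .states import (
    ESTABLISHED,
    StateSpace,
    TipAmbiguity,
    TipObservation,
    compatible_states,
)
from .trees import Phylogeny

__all__ = [
    "SimulationDesign",
    "TrueHistory",
    "simulate_tree",
    "simulate_history",
    "mask_tips",
    "recode_dec",
    "recode_dec_masks",
]


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the validation experiment grid.

    ``resolve_fraction`` is the fraction of non-true ambiguous states
    removed from a treated tip's compatible set (0 = worst case, 1 =
    entirely confirmed); ``treated_tip_fraction`` is the fraction of tips
    the treatment touches.
    """

    n_tips: int = 150
    n_biomes: int = 3
    prior_beta: float = 1.0
    resolve_fraction: float = 0.0
    treated_tip_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if not (0 <= self.resolve_fraction <= 1):
            raise ValueError("resolve_fraction must be in [0, 1]")
        if not (0 <= self.treated_tip_fraction <= 1):
            raise ValueError("treated_tip_fraction must be in [0, 1]")


@dataclass
class TrueHistory:
    """A realization of the process on a tree.

    ``node_states`` holds the pre-cladogenesis state of every node (tips:
    their true state); ``corner_states`` the branch-start state below every
    non-root node (-1 at the root); ``segments[node]`` the piecewise-
    constant path along the branch above ``node`` as (state, duration)
    pairs.
    """

    root_state: int
    node_states: np.ndarray
    corner_states: np.ndarray
    segments: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def tip_states(self, n_tips: int) -> np.ndarray:
        return self.node_states[:n_tips]


def simulate_tree(
    n_tips: int, rng: np.random.Generator, unit_height: bool = True
) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` extant tips, rescaled to height 1.

    Tips are labeled ``t1 .. tN``.  All randomness flows through ``rng``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if n_tips == 2:  # a cherry: the Yule shape is fixed, height sets lengths
        from .trees import parse_newick

        return parse_newick("(t1:1.0,t2:1.0);")
    seed = int(rng.integers(0, 2**31 - 1))
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=_pyrandom.Random(seed),
    )
    phylo = Phylogeny.from_dendropy(tree)
    return phylo.rescaled(1.0) if unit_height else phylo


def simulate_history(
    tree: Phylogeny,
    q: np.ndarray,
    tensor: CladoTensor,
    rng: np.random.Generator,
    root_distribution: Optional[np.ndarray] = None,
) -> TrueHistory:
    """Gillespie simulation of a character history down the tree."""
    n_states = q.shape[0]
    if root_distribution is None:
        root_distribution = np.full(n_states, 1.0 / n_states)
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    corner_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    segments: dict[int, list[tuple[int, float]]] = {}

    root = tree.root_id
    node_states[root] = rng.choice(n_states, p=root_distribution)

    def evolve(node: int, start_state: int) -> int:
        """Run anagenesis along the branch above ``node``."""
        t_total = tree.branch_lengths[node]
        s = start_state
        t = 0.0
        path: list[tuple[int, float]] = []
        while True:
            out_rate = -q[s, s]
            if out_rate <= 0:
                break
            dt = rng.exponential(1.0 / out_rate)
            if t + dt >= t_total:
                break
            path.append((s, dt))
            t += dt
            probs = np.clip(q[s], 0, None)
            probs[s] = 0.0
            s = int(rng.choice(n_states, p=probs / probs.sum()))
        path.append((s, t_total - t))
        segments[node] = path
        return s

    for k in range(len(tree.left) - 1, -1, -1):  # preorder
        v = tree.n_tips + k
        i = node_states[v]
        lj, rk, pp = tensor.slice(i)
        e = int(rng.choice(len(pp), p=pp / pp.sum()))
        for child, corner in ((tree.left[k], lj[e]), (tree.right[k], rk[e])):
            corner_states[child] = corner
            node_states[child] = evolve(child, int(corner))
    return TrueHistory(
        root_state=int(node_states[root]),
        node_states=node_states,
        corner_states=corner_states,
        segments=segments,
    )


def mask_tips(
    true_tip_codes: Sequence[Sequence[int]],
    tip_labels: Sequence[str],
    space: StateSpace,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> list[TipAmbiguity]:
    """Apply an ambiguity-resolution treatment to true tip states.

    Baseline (worst-case) coding admits every state sharing the tip's
    established pattern.  For a treated fraction of tips (drawn without
    replacement), ``ceil(resolve_fraction * n_non_true)`` of the non-true
    compatible states are removed uniformly at random; the true state is
    never removed, so a fraction of 1 leaves a singleton.
    """
    n = len(true_tip_codes)
    masks: list[TipAmbiguity] = []
    n_treated = int(round(design.treated_tip_fraction * n))
    treated = set(rng.choice(n, size=n_treated, replace=False).tolist())
    for i, codes in enumerate(true_tip_codes):
        obs = TipObservation.worst_case(tip_labels[i], codes)
        amb = compatible_states(obs, None, space)
        mask = amb.state_mask.copy()
        if i in treated and design.resolve_fraction > 0:
            true_idx = space.index(tuple(int(c) for c in codes))
            non_true = np.flatnonzero(mask)
            non_true = non_true[non_true != true_idx]
            n_remove = min(
                ceil(design.resolve_fraction * len(non_true)), len(non_true)
            )
            if n_remove > 0:
                drop = rng.choice(non_true, size=n_remove, replace=False)
                mask[drop] = 0.0
        masks.append(TipAmbiguity(species=tip_labels[i], state_mask=mask))
    return masks


def recode_dec(codes: Sequence[int]) -> tuple[int, ...]:
    """Binary presence recoding: established (2) -> 1, else -> 0."""
    return tuple(1 if c == ESTABLISHED else 0 for c in codes)


def recode_dec_masks(
    true_tip_codes: Sequence[Sequence[int]],
    tip_labels: Sequence[str],
    dec_space,
) -> list[TipAmbiguity]:
    """Recode tips for the baseline model.

    The recoding collapses enabled/non-affinity ambiguity entirely: every
    state in a worst-case ambiguity set shares the established pattern, so
    the baseline tip is a singleton presence set.
    """
    masks = []
    for label, codes in zip(tip_labels, true_tip_codes):
        mask = np.zeros(dec_space.n_states)
        mask[dec_space.index(recode_dec(codes))] = 1.0
        masks.append(TipAmbiguity(species=label, state_mask=mask))
    return masks
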