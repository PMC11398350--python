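"""Pruning likelihood with cladogenetic node transitions.

The likelihood of tip ambiguity masks under an anagenetic generator ``Q``
and a cladogenetic tensor ``P`` is computed by postorder pruning.  Tip
partials are the 0/1 masks; a branch of length ``t`` maps a child's partial
through ``expm(Q t)``; at each internal node the daughters' branch-top
partials combine through the tensor,

    D(parent)_i = sum_{j,k} P(i; j, k) F_left(j) F_right(k),

and the root sums against the root state frequencies.  Partials are
rescaled at every internal node with log-scale accumulation so 500-tip
trees do not underflow.  The machinery is generic over any (state space,
generator, tensor) triple, so the binary presence/absence baseline model
reuses it unchanged.

A numba-compiled kernel carries the inner loop; MCMC evaluates this
function millions of times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .anagenesis import AnageneticRates, TransitionKernel
from .cladogenesis import CladoParams, CladoTensor
from .states import StateSpace, TipAmbiguity
from .trees import Phylogeny

__all__ = ["ModelParams", "prune_loglik", "PruningWorkspace"]

_log = logging.getLogger("biomeshift")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the full model plus the root-state convention.

    The root frequency vector defaults to uniform over the valid state
    space (least informative; the choice is recorded in all run headers)
    and may be replaced by any user-supplied probability vector.
    """

    rates: AnageneticRates
    clado: CladoParams
    root_option: str = "uniform"
    root_freqs: Optional[np.ndarray] = field(default=None)

    def root_vector(self, n_states: int) -> np.ndarray:
        if self.root_option == "uniform":
            return np.full(n_states, 1.0 / n_states)
        if self.root_option == "custom":
            f = np.asarray(self.root_freqs, dtype=float)
            if f.shape != (n_states,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("custom root frequencies must be a probability "
                                 f"vector of length {n_states}")
            return f
        raise ValueError(f"unknown root_option {self.root_option!r}")


@njit(cache=True)
def _prune_kernel(left, right, trans, tip_partials, parent_ptr,
                  p_left, p_right, p_prob, pi):  # pragma: no cover - jit
    n_internal = left.shape[0]
    n_tips = tip_partials.shape[0]
    s = pi.shape[0]
    partials = np.empty((n_tips + n_internal, s))
    partials[:n_tips] = tip_partials
    log_scale = np.zeros(n_tips + n_internal)
    for k in range(n_internal):
        v = n_tips + k
        a = left[k]
        b = right[k]
        fa = trans[a] @ partials[a]
        fb = trans[b] @ partials[b]
        d = np.zeros(s)
        for i in range(s):
            acc = 0.0
            for e in range(parent_ptr[i], parent_ptr[i + 1]):
                acc += p_prob[e] * fa[p_left[e]] * fb[p_right[e]]
            d[i] = acc
        m = d.max()
        if m <= 0.0:
            return -np.inf, v
        d /= m
        partials[v] = d
        log_scale[v] = np.log(m) + log_scale[a] + log_scale[b]
    root = n_tips + n_internal - 1
    tot = 0.0
    for i in range(s):
        tot += pi[i] * partials[root, i]
    if tot <= 0.0:
        return -np.inf, root
    return np.log(tot) + log_scale[root], -1


class PruningWorkspace:
    """Reusable pruning state for one (tree, tips, space) combination.

    Caches the tip-partial matrix and tree arrays; ``loglik`` accepts a
    fresh transition-matrix stack and tensor so MCMC can swap either one
    cheaply (rate moves rebuild the transition stack, cladogenetic moves
    reuse it).
    """

    def __init__(
        self,
        tree: Phylogeny,
        tips: Sequence[TipAmbiguity],
        space: StateSpace,
    ) -> None:
        self.tree = tree
        self.space = space
        by_species = {t.species: t for t in tips}
        missing = [l for l in tree.tip_labels if l not in by_species]
        extra = [t.species for t in tips if t.species not in set(tree.tip_labels)]
        if missing or extra:
            raise ValueError(
                f"tip data does not match tree: missing={missing[:5]}, "
                f"unmatched={extra[:5]}"
            )
        self.tip_partials = np.ascontiguousarray(
            np.stack([by_species[l].state_mask for l in tree.tip_labels])
        )
        if self.tip_partials.shape[1] != space.n_states:
            raise ValueError("tip masks do not match the state space size")

    def transition_stack(self, q: np.ndarray) -> np.ndarray:
        kernel = TransitionKernel(q)
        return kernel.matrices(self.tree.branch_lengths)

    def loglik(
        self,
        trans: np.ndarray,
        tensor: CladoTensor,
        root_pi: np.ndarray,
    ) -> float:
        ll, bad = _prune_kernel(
            self.tree.left,
            self.tree.right,
            trans,
            self.tip_partials,
            tensor.parent_ptr,
            tensor.left_idx,
            tensor.right_idx,
            tensor.probs,
            root_pi,
        )
        if bad >= 0:
            # impossible data under these parameters
            _log.debug("all-zero partial at node %d; returning -inf", bad)
            return -np.inf
        return float(ll)

    def branch_tops(
        self, trans: np.ndarray, tensor: CladoTensor
    ) -> tuple[np.ndarray, np.ndarray]:
        """Full pass returning per-node combined partials ``D`` and branch-top
        partials ``F`` (ancestral sampling needs both; scalers are folded in
        per node and cancel on normalization)."""
        tree, s = self.tree, self.space.n_states
        n = tree.n_nodes
        partials = np.zeros((n, s))
        partials[: tree.n_tips] = self.tip_partials
        tops = np.zeros((n, s))
        for k in range(len(tree.left)):
            v = tree.n_tips + k
            a, b = tree.left[k], tree.right[k]
            tops[a] = trans[a] @ partials[a]
            tops[b] = trans[b] @ partials[b]
            d = tensor.combine(tops[a], tops[b])
            m = d.max()
            if m <= 0:
                raise RuntimeError(f"all-zero partial at node {v}")
            partials[v] = d / m
        return partials, tops


def prune_loglik(
    tree: Phylogeny,
    tips: Sequence[TipAmbiguity],
    params: ModelParams,
    space: StateSpace,
    q: np.ndarray,
    p: CladoTensor,
) -> float:
    """Log-likelihood (natural log) of the tip data under (Q, P).

    Returns ``-inf`` when the data are impossible under the parameters.
    """
    ws = PruningWorkspace(tree, tips, space)
    trans = ws.transition_stack(q)
    return ws.loglik(trans, p, params.root_vector(space.n_states))


def prune_loglik_reference(
    tree: Phylogeny,
    tips: Sequence[TipAmbiguity],
    params: ModelParams,
    space: StateSpace,
    q: np.ndarray,
    p: CladoTensor,
    rescale: bool = True,
) -> float:
    """Plain-numpy pruning, optionally without per-node rescaling.

    Slow path kept for numerical cross-checks of the compiled kernel and of
    the rescaling scheme.
    """
    ws = PruningWorkspace(tree, tips, space)
    trans = ws.transition_stack(q)
    s = space.n_states
    n = tree.n_nodes
    partials = np.zeros((n, s))
    partials[: tree.n_tips] = ws.tip_partials
    log_scale = np.zeros(n)
    for k in range(len(tree.left)):
        v = tree.n_tips + k
        a, b = tree.left[k], tree.right[k]
        fa = trans[a] @ partials[a]
        fb = trans[b] @ partials[b]
        d = p.combine(fa, fb)
        if rescale:
            m = d.max()
            if m <= 0:
                return -np.inf
            partials[v] = d / m
            log_scale[v] = np.log(m) + log_scale[a] + log_scale[b]
        else:
            partials[v] = d
            log_scale[v] = log_scale[a] + log_scale[b]
    pi = params.root_vector(s)
    tot = float(pi @ partials[tree.root_id])
    if tot <= 0:
        return -np.inf
    return np.log(tot) + log_scale[tree.root_id]
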