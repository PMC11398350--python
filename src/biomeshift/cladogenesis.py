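"""Cladogenetic inheritance of affinity-set states.

At a speciation node the parental established affinities are passed to the
two daughters under one of three scenarios whose probabilities sum to one:

* equal inheritance (probability ``pe``): both daughters copy the parent;
* subset inheritance (``ps``): one daughter keeps the full established set,
  the other keeps a proper non-empty subset;
* between-biome split inheritance (``pb``): the established set is divided
  into two disjoint non-empty parts.

In subset and split events the established biomes a daughter does not
inherit all reduce together, either to enabled affinities (divergence
unrelated to biome suitability, e.g. geographic isolation) or to
non-affinities (ecological divergence); the reduction mode is a single
per-event choice.  Enabled-only parental biomes (code 1) pass unchanged to
both daughters.  With ``n`` established parental biomes and ``n >= 2`` the
outcome counts are ``n_e = 1``, ``n_s = 2**(n+2) - 8`` and
``n_b = 2**(n+1) - 4``; each outcome within a scenario is equally likely
(``pe / n_e``, ``ps / n_s``, ``pb / n_b``).  A parent with a single
established biome always transmits its state identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np

from .states import ESTABLISHED, ENABLED, NON_AFFINITY, AffinityState, StateSpace

__all__ = [
    "CladoParams",
    "OutcomeCounts",
    "CladoEvent",
    "CladoTensor",
    "count_outcomes",
    "enumerate_clado_events",
    "build_clado_tensor",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class CladoParams:
    """Scenario probabilities (pe, ps, pb) on the 2-simplex."""

    pe: float
    ps: float
    pb: float

    def __post_init__(self) -> None:
        for name in ("pe", "ps", "pb"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -1e-12:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if abs(self.pe + self.ps + self.pb - 1.0) > 1e-9:
            raise ValueError(
                f"pe + ps + pb must equal 1, got {self.pe + self.ps + self.pb}"
            )

    @classmethod
    def from_free(cls, ps: float, pb: float) -> "CladoParams":
        """Build from the two free parameters with ``pe = 1 - ps - pb``."""
        return cls(pe=1.0 - ps - pb, ps=ps, pb=pb)


@dataclass(frozen=True)
class OutcomeCounts:
    n_est: int
    n_e: int
    n_s: int
    n_b: int


def count_outcomes(n_est: int) -> OutcomeCounts:
    """Closed-form outcome counts per scenario for ``n_est`` established
    parental biomes; a single-biome parent has only the identical outcome."""
    if n_est < 1:
        raise ValueError(f"n_est must be >= 1, got {n_est}")
    if n_est == 1:
        return OutcomeCounts(n_est=1, n_e=1, n_s=0, n_b=0)
    return OutcomeCounts(
        n_est=n_est,
        n_e=1,
        n_s=2 ** (n_est + 2) - 8,
        n_b=2 ** (n_est + 1) - 4,
    )


@dataclass(frozen=True)
class CladoEvent:
    parent: AffinityState
    left: AffinityState
    right: AffinityState
    scenario: Literal["equal", "subset", "split"]
    reduction: Literal["to_enabled", "to_non_affinity", "not_applicable"]
    probability: float


def _daughter(
    parent: AffinityState, inherited: frozenset[int], reduce_to: int
) -> AffinityState:
    codes = []
    for b, c in enumerate(parent.codes):
        if c == ESTABLISHED:
            codes.append(ESTABLISHED if b in inherited else reduce_to)
        else:
            codes.append(c)  # enabled-only and non-affinity biomes unchanged
    return AffinityState(tuple(codes))


def _proper_subsets(est: Sequence[int]) -> Iterator[frozenset[int]]:
    for r in range(1, len(est)):
        for combo in combinations(est, r):
            yield frozenset(combo)


def enumerate_clado_events(
    parent: AffinityState, params: CladoParams
) -> list[CladoEvent]:
    """All cladogenetic outcomes for one parental state, with probabilities.

    Mirror-image outcomes (left/right swapped) are distinct events; the
    scenario counts already include both orders, so the event list is
    symmetric under daughter exchange.
    """
    est = parent.established
    counts = count_outcomes(len(est))
    if counts.n_est == 1:
        return [
            CladoEvent(parent, parent, parent, "equal", "not_applicable", 1.0)
        ]

    events: list[CladoEvent] = [
        CladoEvent(
            parent, parent, parent, "equal", "not_applicable",
            params.pe / counts.n_e,
        )
    ]
    w_s = params.ps / counts.n_s
    w_b = params.pb / counts.n_b
    full = frozenset(est)
    for sub in _proper_subsets(est):
        for reduce_to, mode in ((ENABLED, "to_enabled"),
                                (NON_AFFINITY, "to_non_affinity")):
            partial = _daughter(parent, sub, reduce_to)
            # subset: either daughter may be the one holding the full set
            events.append(CladoEvent(parent, parent, partial, "subset", mode, w_s))
            events.append(CladoEvent(parent, partial, parent, "subset", mode, w_s))
            # split: the complement goes to the other daughter; one global
            # reduction mode covers both daughters.  Each ordered partition
            # (sub, full - sub) arises exactly once per mode.
            other = _daughter(parent, full - sub, reduce_to)
            events.append(CladoEvent(parent, partial, other, "split", mode, w_b))
    return events


class CladoTensor:
    """Sparse parent -> (left, right) cladogenetic probability tensor.

    Stored as a COO triple list grouped by parent-state index (CSR-style
    ``parent_ptr``); probabilities for each parent sum to one and the
    tensor is symmetric under daughter exchange.
    """

    def __init__(
        self,
        space: StateSpace,
        parent_idx: np.ndarray,
        left_idx: np.ndarray,
        right_idx: np.ndarray,
        probs: np.ndarray,
    ) -> None:
        self.space = space
        order = np.lexsort((right_idx, left_idx, parent_idx))
        self.parent_idx = parent_idx[order]
        self.left_idx = left_idx[order]
        self.right_idx = right_idx[order]
        self.probs = probs[order]
        n = space.n_states
        counts = np.bincount(self.parent_idx, minlength=n)
        self.parent_ptr = np.concatenate(([0], np.cumsum(counts)))
        sums = np.bincount(self.parent_idx, weights=self.probs, minlength=n)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise RuntimeError(
                "cladogenetic tensor rows do not normalize: "
                f"max |sum - 1| = {np.max(np.abs(sums - 1.0)):.3e}"
            )

    @property
    def n_entries(self) -> int:
        return len(self.probs)

    def slice(self, parent: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo, hi = self.parent_ptr[parent], self.parent_ptr[parent + 1]
        return self.left_idx[lo:hi], self.right_idx[lo:hi], self.probs[lo:hi]

    def prob(self, parent: int, left: int, right: int) -> float:
        l, r, p = self.slice(parent)
        hit = (l == left) & (r == right)
        return float(p[hit].sum())

    def dense(self) -> np.ndarray:
        n = self.space.n_states
        out = np.zeros((n, n, n))
        np.add.at(out, (self.parent_idx, self.left_idx, self.right_idx), self.probs)
        return out

    def combine(self, f_left: np.ndarray, f_right: np.ndarray) -> np.ndarray:
        """Node merge: D_i = sum_{j,k} p(i; j, k) f_left[j] f_right[k]."""
        out = np.zeros(self.space.n_states)
        np.add.at(
            out,
            self.parent_idx,
            self.probs * f_left[self.left_idx] * f_right[self.right_idx],
        )
        return out


def build_clado_tensor(space: StateSpace, params: CladoParams) -> CladoTensor:
    """Assemble the full tensor by enumerating events for every parent."""
    pi, li, ri, pr = [], [], [], []
    for i, parent in enumerate(space.states):
        for ev in enumerate_clado_events(parent, params):
            pi.append(i)
            li.append(space.index(ev.left))
            ri.append(space.index(ev.right))
            pr.append(ev.probability)
    return CladoTensor(
        space,
        np.array(pi, dtype=np.int64),
        np.array(li, dtype=np.int64),
        np.array(ri, dtype=np.int64),
        np.array(pr, dtype=float),
    )
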