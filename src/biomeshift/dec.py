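"""Binary presence/absence baseline over non-empty biome subsets.

A DEC-style comparison model: each biome is either occupied (1) or not (0),
the state space is the ``2**B - 1`` non-empty subsets (the empty set is
excluded, matching the at-least-one-established convention of the full
model), anagenesis gains and loses single biomes at two rates, and
cladogenesis mirrors the three scenarios of the full model on presence
sets: equal inheritance, subset inheritance (one daughter keeps the full
set, the other a proper non-empty subset; ``2 * (2**n - 2)`` outcomes) and
split inheritance (ordered partition into non-empty parts; ``2**n - 2``
outcomes).  The generic pruning / MCMC / ancestral machinery is reused
unchanged, so the comparison isolates the enabled-affinity tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Optional, Sequence

import numpy as np

from .cladogenesis import CladoParams, CladoTensor, OutcomeCounts

__all__ = [
    "DecParams",
    "DecStateSpace",
    "build_dec_space",
    "build_dec_q",
    "build_dec_clado",
    "dec_count_outcomes",
]


@dataclass(frozen=True)
class DecParams:
    gain: float
    loss: float
    clado: CladoParams

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise ValueError("gain and loss rates must be >= 0")


@dataclass(frozen=True)
class DecStateSpace:
    """Non-empty presence subsets in lexicographic digit order."""

    biome_labels: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]
    index_of: Mapping[tuple[int, ...], int] = field(repr=False)

    @property
    def n_biomes(self) -> int:
        return len(self.biome_labels)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: Sequence[int] | str) -> int:
        if isinstance(state, str):
            state = tuple(int(c) for c in state)
        return self.index_of[tuple(state)]

    def label(self, state: Sequence[int] | int) -> str:
        if isinstance(state, (int, np.integer)):
            state = self.states[int(state)]
        return "".join(
            b[0].upper() for b, c in zip(self.biome_labels, state) if c == 1
        )

    def codes_array(self) -> np.ndarray:
        return np.array(self.states, dtype=np.int64)


def build_dec_space(
    n_biomes: int, labels: Optional[Sequence[str]] = None
) -> DecStateSpace:
    if n_biomes < 1:
        raise ValueError(f"n_biomes must be >= 1, got {n_biomes}")
    if labels is None:
        labels = tuple(f"B{i + 1}" for i in range(n_biomes))
    labels = tuple(str(b) for b in labels)
    states = tuple(
        codes for codes in product((0, 1), repeat=n_biomes) if any(codes)
    )
    return DecStateSpace(
        biome_labels=labels,
        states=states,
        index_of={s: i for i, s in enumerate(states)},
    )


def build_dec_q(params: DecParams, space: DecStateSpace) -> np.ndarray:
    """Single-biome presence gains/losses; losing the last presence has no
    destination and is absent, so rows still sum to zero."""
    n = space.n_states
    codes = space.codes_array()
    q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = np.flatnonzero(codes[i] != codes[j])
            if diff.size != 1:
                continue
            q[i, j] = params.gain if codes[j, diff[0]] == 1 else params.loss
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def dec_count_outcomes(n_present: int) -> OutcomeCounts:
    """Scenario outcome counts on presence sets of size ``n_present``."""
    if n_present < 1:
        raise ValueError(f"n_present must be >= 1, got {n_present}")
    if n_present == 1:
        return OutcomeCounts(n_est=1, n_e=1, n_s=0, n_b=0)
    k = 2**n_present - 2
    return OutcomeCounts(n_est=n_present, n_e=1, n_s=2 * k, n_b=k)


def _subset_state(full: tuple[int, ...], keep: frozenset[int]) -> tuple[int, ...]:
    return tuple(1 if (c == 1 and b in keep) else 0 for b, c in enumerate(full))


def build_dec_clado(space: DecStateSpace, clado: CladoParams) -> CladoTensor:
    pi_, li, ri, pr = [], [], [], []

    def add(parent_i: int, left: tuple[int, ...], right: tuple[int, ...], p: float):
        pi_.append(parent_i)
        li.append(space.index(left))
        ri.append(space.index(right))
        pr.append(p)

    for i, parent in enumerate(space.states):
        present = [b for b, c in enumerate(parent) if c == 1]
        counts = dec_count_outcomes(len(present))
        if counts.n_est == 1:
            add(i, parent, parent, 1.0)
            continue
        add(i, parent, parent, clado.pe / counts.n_e)
        w_s = clado.ps / counts.n_s
        w_b = clado.pb / counts.n_b
        full = frozenset(present)
        for r in range(1, len(present)):
            for combo in combinations(present, r):
                sub = frozenset(combo)
                part = _subset_state(parent, sub)
                add(i, parent, part, w_s)
                add(i, part, parent, w_s)
                add(i, part, _subset_state(parent, full - sub), w_b)
    return CladoTensor(
        space,
        np.array(pi_, dtype=np.int64),
        np.array(li, dtype=np.int64),
        np.array(ri, dtype=np.int64),
        np.array(pr, dtype=float),
    )
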