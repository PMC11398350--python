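"""Affinity-set state spaces and tip ambiguity coding.

A species' relationship to each of ``B`` biomes is coded on a three-level
scale: ``0`` (non-affinity: the biome offers too little suitable habitat),
``1`` (enabled affinity: the species could persist there but does not), and
``2`` (established affinity: the species occupies and persists there).  A
valid affinity-set state is a length-``B`` vector over ``{0, 1, 2}`` with at
least one established biome — an extant species must live somewhere — giving
``3**B - 2**B`` states in total (5 for two biomes, 19 for three).

Observed data rarely pin down the full state.  Established affinities are
observable; an unestablished biome is ambiguous between enabled and
non-affinity, so a tip observation is a per-biome *allowed set* of codes, and
the tip enters the likelihood as a 0/1 mask over the state space admitting
every state compatible with the observation and with any include / exclude /
climatic-adjacency constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AffinityState",
    "StateSpace",
    "TipObservation",
    "AdjacencyRule",
    "ConstraintSet",
    "TipAmbiguity",
    "ContradictoryConstraintsError",
    "enumerate_states",
    "state_label",
    "parse_state_label",
    "compatible_states",
]

NON_AFFINITY = 0
ENABLED = 1
ESTABLISHED = 2


class ContradictoryConstraintsError(ValueError):
    """Raised when constraints leave a species with no admissible state."""


@dataclass(frozen=True)
class AffinityState:
    """A full affinity-set state: one code in {0, 1, 2} per biome."""

    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("state must cover at least one biome")
        if any(c not in (0, 1, 2) for c in self.codes):
            raise ValueError(f"codes must be in {{0,1,2}}, got {self.codes}")
        if ESTABLISHED not in self.codes:
            raise ValueError(
                f"state {self.codes} has no established biome; "
                "every extant species needs at least one"
            )

    @property
    def n_biomes(self) -> int:
        return len(self.codes)

    @property
    def established(self) -> tuple[int, ...]:
        """Indices of established biomes."""
        return tuple(i for i, c in enumerate(self.codes) if c == ESTABLISHED)

    @property
    def n_established(self) -> int:
        return sum(1 for c in self.codes if c == ESTABLISHED)

    def digits(self) -> str:
        """Digit-string form, e.g. ``(2, 1, 0) -> '210'``."""
        return "".join(str(c) for c in self.codes)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.digits()


@dataclass(frozen=True)
class StateSpace:
    """Canonical enumeration of all valid affinity-set states.

    States are ordered lexicographically by their digit vectors; the order is
    internal and stable, and all public results are keyed by state, digit
    string, or label rather than raw index.
    """

    biome_labels: tuple[str, ...]
    states: tuple[AffinityState, ...]
    index_of: Mapping[AffinityState, int] = field(repr=False)

    @property
    def n_biomes(self) -> int:
        return len(self.biome_labels)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: AffinityState | Sequence[int] | str) -> int:
        if isinstance(state, str):
            state = AffinityState(tuple(int(c) for c in state))
        elif not isinstance(state, AffinityState):
            state = AffinityState(tuple(state))
        return self.index_of[state]

    def label(self, state: AffinityState | int) -> str:
        if isinstance(state, (int, np.integer)):
            state = self.states[int(state)]
        return state_label(state, self.biome_labels)

    def codes_array(self) -> np.ndarray:
        """(n_states, n_biomes) integer array of codes, row per state."""
        return np.array([s.codes for s in self.states], dtype=np.int64)

    def report(self) -> "pandas.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        return pd.DataFrame(
            {
                "index": range(self.n_states),
                "digits": [s.digits() for s in self.states],
                "label": [self.label(s) for s in self.states],
            }
        )


def enumerate_states(
    n_biomes: int, labels: Optional[Sequence[str]] = None
) -> StateSpace:
    """Enumerate the ``3**B - 2**B`` valid affinity-set states.

    Parameters
    ----------
    n_biomes:
        Number of biomes ``B`` (>= 1).
    labels:
        Optional biome names; their first letters must be distinct because
        compact state labels are built from initials.  Defaults to
        ``B1, B2, ...`` for B > 4 or ``H, C`` / ``T, W, C`` style initials
        are left to the caller.
    """
    if n_biomes < 1:
        raise ValueError(f"n_biomes must be >= 1, got {n_biomes}")
    if labels is None:
        import string

        if n_biomes > 26:
            raise ValueError("provide explicit labels for more than 26 biomes")
        labels = tuple(string.ascii_uppercase[:n_biomes])
    labels = tuple(str(b) for b in labels)
    if len(labels) != n_biomes:
        raise ValueError(
            f"expected {n_biomes} labels, got {len(labels)}"
        )
    initials = [b[0].upper() for b in labels]
    if len(set(initials)) != n_biomes:
        raise ValueError(f"biome label initials must be distinct: {labels}")

    states = tuple(
        AffinityState(codes)
        for codes in product((0, 1, 2), repeat=n_biomes)
        if ESTABLISHED in codes
    )
    index_of = {s: i for i, s in enumerate(states)}
    return StateSpace(biome_labels=labels, states=states, index_of=index_of)


def state_label(state: AffinityState, labels: Sequence[str]) -> str:
    """Compact label: uppercase initial for established, lowercase for
    enabled, nothing for non-affinity, in biome order (``(2,1) -> 'Hc'``)."""
    if len(labels) != state.n_biomes:
        raise ValueError("label count must match state length")
    out = []
    for code, biome in zip(state.codes, labels):
        initial = biome[0]
        if code == ESTABLISHED:
            out.append(initial.upper())
        elif code == ENABLED:
            out.append(initial.lower())
    return "".join(out)


def parse_state_label(label: str, labels: Sequence[str]) -> AffinityState:
    """Inverse of :func:`state_label` for a given biome ordering."""
    codes = []
    seen = set()
    for biome in labels:
        initial = biome[0]
        if initial.upper() in label:
            codes.append(ESTABLISHED)
            seen.add(initial.upper())
        elif initial.lower() in label:
            codes.append(ENABLED)
            seen.add(initial.lower())
        else:
            codes.append(NON_AFFINITY)
    if len(seen) != len(label):
        raise ValueError(f"label {label!r} does not parse over biomes {labels}")
    return AffinityState(tuple(codes))


@dataclass(frozen=True)
class TipObservation:
    """Per-biome allowed code sets for one species.

    An observed established biome is the singleton ``{2}``; a worst-case
    unestablished biome is ``{0, 1}`` (enabled vs non-affinity unresolved).
    """

    species: str
    per_biome_allowed: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        for i, allowed in enumerate(self.per_biome_allowed):
            if not allowed:
                raise ValueError(
                    f"{self.species}: empty allowed set at biome {i}"
                )
            if not allowed <= {0, 1, 2}:
                raise ValueError(
                    f"{self.species}: invalid codes {set(allowed)} at biome {i}"
                )

    @classmethod
    def worst_case(cls, species: str, true_codes: Sequence[int]) -> "TipObservation":
        """Observation recording only the established pattern: established
        biomes -> {2}, all unestablished biomes -> {0, 1}."""
        return cls(
            species,
            tuple(
                frozenset({2}) if c == ESTABLISHED else frozenset({0, 1})
                for c in true_codes
            ),
        )

    @classmethod
    def exact(cls, species: str, codes: Sequence[int]) -> "TipObservation":
        return cls(species, tuple(frozenset({int(c)}) for c in codes))


@dataclass(frozen=True)
class AdjacencyRule:
    """Climatic-adjacency constraint along an ordered biome gradient.

    Biomes arrayed along an environmental gradient (e.g. tropical - warm
    temperate - cold temperate) cannot plausibly bracket a gap: a candidate
    state is dropped when two gradient-flanking biomes carry established
    affinities while an intermediate biome has a non-affinity.  With
    ``established_only=False`` the trigger extends to enabled flanks too.
    """

    gradient: tuple[int, ...]
    established_only: bool = True

    def admits(self, codes: Sequence[int]) -> bool:
        thresh = ESTABLISHED if self.established_only else ENABLED
        g = self.gradient
        for a in range(len(g)):
            if codes[g[a]] < thresh:
                continue
            for b in range(a + 2, len(g)):
                if codes[g[b]] < thresh:
                    continue
                if any(codes[g[m]] == NON_AFFINITY for m in range(a + 1, b)):
                    return False
        return True


@dataclass
class ConstraintSet:
    """Include / exclude / adjacency constraints on tip ambiguity.

    ``includes`` force a biome to at-minimum enabled (code 1 at unestablished
    biomes: the evidence, e.g. garden survival, demonstrates suitability, not
    occupancy); ``excludes`` force non-affinity (code 0).  A biome observed
    as established can never be excluded.
    """

    includes: set[tuple[str, int]] = field(default_factory=set)
    excludes: set[tuple[str, int]] = field(default_factory=set)
    adjacency: Optional[AdjacencyRule] = None

    def __post_init__(self) -> None:
        clash = self.includes & self.excludes
        if clash:
            raise ValueError(f"include and exclude clash on {sorted(clash)}")


@dataclass(frozen=True)
class TipAmbiguity:
    """0/1 indicator over the state space of states compatible with a tip."""

    species: str
    state_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.state_mask, dtype=float)
        if mask.ndim != 1 or not mask.any():
            raise ValueError(f"{self.species}: mask must be 1-D and non-empty")
        object.__setattr__(self, "state_mask", mask)

    @property
    def n_compatible(self) -> int:
        return int(self.state_mask.sum())

    def admitted(self, space: StateSpace) -> list[AffinityState]:
        return [space.states[i] for i in np.flatnonzero(self.state_mask)]


def compatible_states(
    obs: TipObservation,
    constraints: Optional[ConstraintSet],
    space: StateSpace,
) -> TipAmbiguity:
    """Build the tip ambiguity mask for one species.

    Every admitted state reproduces the observed established pattern exactly
    and respects the per-biome allowed sets after applying constraints:

    * include (species, biome): allowed set restricted to ``{1}`` when the
      biome is not observed established (``{2}`` stays ``{2}``);
    * exclude (species, biome): allowed set restricted to ``{0}``; raises if
      the biome is observed established;
    * adjacency: states violating the gradient rule are dropped.

    Raises :class:`ContradictoryConstraintsError` if nothing survives.
    """
    if len(obs.per_biome_allowed) != space.n_biomes:
        raise ValueError(
            f"{obs.species}: observation covers {len(obs.per_biome_allowed)} "
            f"biomes, space has {space.n_biomes}"
        )
    allowed = [set(a) for a in obs.per_biome_allowed]
    constraints = constraints or ConstraintSet()
    for sp, biome in constraints.includes:
        if sp != obs.species:
            continue
        if allowed[biome] == {ESTABLISHED}:
            continue  # established already implies enabled
        if ENABLED not in allowed[biome]:
            raise ContradictoryConstraintsError(
                f"{obs.species}: biome {biome} cannot be included "
                f"(allowed codes {sorted(allowed[biome])})"
            )
        allowed[biome] = {ENABLED}
    for sp, biome in constraints.excludes:
        if sp != obs.species:
            continue
        if allowed[biome] == {ESTABLISHED}:
            raise ContradictoryConstraintsError(
                f"{obs.species}: biome {biome} observed established "
                "but excluded by constraint"
            )
        if NON_AFFINITY not in allowed[biome]:
            raise ContradictoryConstraintsError(
                f"{obs.species}: biome {biome} cannot be excluded "
                f"(allowed codes {sorted(allowed[biome])})"
            )
        allowed[biome] = {NON_AFFINITY}

    mask = np.zeros(space.n_states)
    for i, state in enumerate(space.states):
        ok = all(c in a for c, a in zip(state.codes, allowed))
        if ok and constraints.adjacency is not None:
            ok = constraints.adjacency.admits(state.codes)
        mask[i] = 1.0 if ok else 0.0
    if not mask.any():
        raise ContradictoryConstraintsError(
            f"{obs.species}: constraints admit no state"
        )
    return TipAmbiguity(species=obs.species, state_mask=mask)
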