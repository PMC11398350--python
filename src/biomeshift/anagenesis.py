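"""Anagenetic rate generator over affinity-set states.

Along a branch, a species changes its affinity with one biome at a time:
gain of an enabled affinity (0 -> 1, rate ``g01``), gain of an established
affinity from enabled (1 -> 2, rate ``g12``), "lock-step" double gain
(0 -> 2, rate ``g02``), loss of an established affinity (2 -> 1, rate
``l21``) and loss of an enabled affinity (1 -> 0, rate ``l10``).  Double
losses (2 -> 0) are forbidden, and so is any event that would leave a
species with no established biome, since such a species would be extinct.

Rates are interpreted per unit of tree height; branch lengths are taken in
the same units (rescale the tree to unit height to match the prior scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .states import StateSpace

__all__ = ["AnageneticRates", "build_q", "transition_probs", "TransitionKernel"]

ROW_SUM_RTOL = 1e-10


@dataclass(frozen=True)
class AnageneticRates:
    """The five anagenetic event rates (events per unit tree height)."""

    g01: float
    g12: float
    g02: float
    l10: float
    l21: float

    def __post_init__(self) -> None:
        for name in ("g01", "g12", "g02", "l10", "l21"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.g01, self.g12, self.g02, self.l10, self.l21])


# single-biome code changes and the rate field each one draws
_EVENTS = {
    (0, 1): "g01",
    (1, 2): "g12",
    (0, 2): "g02",
    (1, 0): "l10",
    (2, 1): "l21",
}


def build_q(rates: AnageneticRates, space: StateSpace) -> np.ndarray:
    """Dense generator matrix over ``space`` (rows sum to zero).

    An off-diagonal entry (s, s') is nonzero only when s' differs from s at
    exactly one biome by an allowed event and s' is itself a valid state;
    the transition that would drop the last established affinity simply has
    no destination and is absent.
    """
    n = space.n_states
    q = np.zeros((n, n))
    codes = space.codes_array()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = np.flatnonzero(codes[i] != codes[j])
            if diff.size != 1:
                continue
            b = diff[0]
            ev = (int(codes[i, b]), int(codes[j, b]))
            field = _EVENTS.get(ev)
            if field is not None:
                q[i, j] = getattr(rates, field)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """Finite-time transition matrix ``expm(q * t)``.

    Uses scaling-and-squaring on the dense generator; the state spaces here
    are tiny (19 states for three biomes) so robustness wins over speed.
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    if t == 0:
        return np.eye(q.shape[0])
    p = scipy.linalg.expm(q * t)
    np.clip(p, 0.0, 1.0, out=p)
    return p


class TransitionKernel:
    """Batch evaluator of ``expm(Q t)`` over many branch lengths.

    Diagonalizes Q once and reconstitutes each transition matrix with two
    small matrix products; falls back to scaling-and-squaring per branch
    when the eigenbasis is ill-conditioned.  Generators here are tiny, so
    the eigendecomposition dominates and reuse across the hundreds of
    branches of a tree is the main cost saver during MCMC.
    """

    def __init__(self, q: np.ndarray, resid_limit: float = 1e-9) -> None:
        self.q = q
        self._ok = False
        try:
            w, v = np.linalg.eig(q)
            vinv = np.linalg.inv(v)
            n = q.shape[0]
            resid = np.abs(v @ vinv - np.eye(n)).max()
            if np.isfinite(resid) and resid < resid_limit:
                self._w, self._v, self._vinv = w, v, vinv
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def matrices(self, ts: np.ndarray) -> np.ndarray:
        """(len(ts), n, n) stack of transition matrices."""
        ts = np.asarray(ts, dtype=float)
        if np.any(~np.isfinite(ts)) or np.any(ts < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        if self._ok:
            ew = np.exp(np.multiply.outer(ts, self._w))  # (m, n)
            out = np.matmul(self._v[None, :, :] * ew[:, None, :], self._vinv)
            out = np.ascontiguousarray(out.real)
        else:
            out = np.stack([scipy.linalg.expm(self.q * t) for t in ts])
        np.clip(out, 0.0, 1.0, out=out)
        return out
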