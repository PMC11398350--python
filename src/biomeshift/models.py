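"""Model adapters binding parameter vectors to (Q, P) for the sampler.

An adapter exposes a flat parameter vector (names, priors, initial values)
and rebuilds the anagenetic generator and cladogenetic tensor from it.  The
sampler only talks to this interface, so the full affinity model and the
binary presence/absence baseline share all inference code.

Tensor structure (which daughter pairs each parent can produce, and which
scenario each outcome belongs to) is fixed by the state space; only the
scenario weights depend on (ps, pb).  The adapters therefore enumerate the
structure once and rebuild probability vectors in O(entries) per proposal.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .anagenesis import AnageneticRates, build_q
from .cladogenesis import (
    CladoParams,
    CladoTensor,
    build_clado_tensor,
    count_outcomes,
)
from .dec import DecParams, DecStateSpace, build_dec_clado, build_dec_q, dec_count_outcomes
from .inference import PriorSpec
from .states import StateSpace

__all__ = ["AffinityModel", "DecModel"]

_SCEN_CODE = {"equal": 0, "subset": 1, "split": 2}


class _QTemplate:
    """Fixed generator sparsity pattern with fast refill from a rate vector.

    The set of allowed single-biome transitions never changes; only the
    rate attached to each entry does, so proposals refill a scatter of
    precomputed (row, col, rate-slot) triples instead of re-deriving the
    structure.
    """

    def __init__(self, n_states: int, i_idx, j_idx, rate_id) -> None:
        self.n_states = n_states
        self.i_idx = np.asarray(i_idx, dtype=np.int64)
        self.j_idx = np.asarray(j_idx, dtype=np.int64)
        self.rate_id = np.asarray(rate_id, dtype=np.int64)

    @classmethod
    def from_builder(cls, space, builder, rate_names: Sequence[str]):
        """Probe the builder once per rate to recover the pattern."""
        n = space.n_states
        i_all, j_all, r_all = [], [], []
        for rid, _ in enumerate(rate_names):
            probe = np.zeros(len(rate_names))
            probe[rid] = 1.0
            q = builder(probe)
            ii, jj = np.nonzero(q)
            off = ii != jj
            i_all.append(ii[off])
            j_all.append(jj[off])
            r_all.append(np.full(off.sum(), rid))
        return cls(
            n,
            np.concatenate(i_all),
            np.concatenate(j_all),
            np.concatenate(r_all),
        )

    def q(self, rates: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_states, self.n_states))
        out[self.i_idx, self.j_idx] = rates[self.rate_id]
        np.fill_diagonal(out, -out.sum(axis=1))
        return out


class _CladoTemplate:
    """Fixed tensor structure with fast reweighting by (pe, ps, pb)."""

    def __init__(self, space, parent_idx, left_idx, right_idx, scen, divisor):
        self.space = space
        self.parent_idx = parent_idx
        self.left_idx = left_idx
        self.right_idx = right_idx
        self.scen = scen  # -1 fixed prob 1, else _SCEN_CODE
        self.divisor = divisor

    def tensor(self, clado: CladoParams) -> CladoTensor:
        w = np.array([1.0, clado.pe, clado.ps, clado.pb])
        probs = w[self.scen + 1] / self.divisor
        return CladoTensor(
            self.space, self.parent_idx, self.left_idx, self.right_idx, probs
        )


def _template_from_tensor_builder(space, builder, counts_fn, n_est_fn):
    ref = CladoParams(pe=1 / 3, ps=1 / 3, pb=1 / 3)
    tensor = builder(space, ref)
    scen = np.empty(tensor.n_entries, dtype=np.int64)
    divisor = np.ones(tensor.n_entries)
    w_ref = {0: 1 / 3, 1: 1 / 3, 2: 1 / 3}
    for e in range(tensor.n_entries):
        i = tensor.parent_idx[e]
        counts = counts_fn(n_est_fn(i))
        if counts.n_s == 0:  # single-established parent: identical, prob 1
            scen[e] = -1
            divisor[e] = 1.0
            continue
        p = tensor.probs[e]
        # classify by matching the reference weight of each scenario
        options = [
            (0, w_ref[0] / counts.n_e, counts.n_e),
            (1, w_ref[1] / counts.n_s, counts.n_s),
            (2, w_ref[2] / counts.n_b, counts.n_b),
        ]
        code, _, div = min(options, key=lambda o: abs(o[1] - p))
        scen[e] = code
        divisor[e] = div
    return _CladoTemplate(
        space, tensor.parent_idx, tensor.left_idx, tensor.right_idx, scen, divisor
    )


class AffinityModel:
    """The established/enabled affinity model: five anagenetic rates with a
    shared Exponential(beta) prior and two free cladogenetic probabilities
    with a flat simplex prior."""

    rate_names = ("g01", "g12", "g02", "l10", "l21")
    param_names = rate_names + ("ps", "pb")
    name = "rfbs"

    def __init__(self, space: StateSpace, prior: PriorSpec) -> None:
        self.space = space
        self.prior = prior
        self._n_est = np.array([s.n_established for s in space.states])
        self._template = _template_from_tensor_builder(
            space, build_clado_tensor, count_outcomes, lambda i: self._n_est[i]
        )
        self._q_template = _QTemplate.from_builder(
            space,
            lambda r: build_q(AnageneticRates(*r), space),
            self.rate_names,
        )

    def is_clado_param(self, j: int) -> bool:
        return j >= 5

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        rates = rng.exponential(self.prior.beta, size=5)
        return np.concatenate([np.maximum(rates, 1e-8), [1 / 3, 1 / 3]])

    def logprior(self, theta: np.ndarray) -> float:
        rates, ps, pb = theta[:5], theta[5], theta[6]
        if (rates < 0).any() or ps + pb > 1 or ps > 1 or pb > 1:
            return -math.inf
        b = self.prior.beta
        return float(-rates.sum() / b - 5 * math.log(b))

    def build_q(self, theta: np.ndarray) -> np.ndarray:
        return self._q_template.q(theta[:5])

    def build_tensor(self, theta: np.ndarray) -> CladoTensor:
        return self._template.tensor(CladoParams.from_free(theta[5], theta[6]))

    def prior_mean(self, name: str) -> float:
        if name in self.rate_names:
            return self.prior.beta
        return 1 / 3  # marginal mean of ps (or pb) on the flat simplex

    def draw_from_prior(self, rng: np.random.Generator) -> np.ndarray:
        rates = rng.exponential(self.prior.beta, size=5)
        while True:
            ps, pb = rng.uniform(size=2)
            if ps + pb <= 1:
                break
        return np.concatenate([rates, [ps, pb]])


class DecModel:
    """Binary presence/absence baseline: gain/loss rates with the same
    exponential prior, and the same flat simplex cladogenetic prior."""

    rate_names = ("gain", "loss")
    param_names = rate_names + ("ps", "pb")
    name = "dec"

    def __init__(self, space: DecStateSpace, prior: PriorSpec) -> None:
        self.space = space
        self.prior = prior
        codes = space.codes_array()
        self._n_present = codes.sum(axis=1)
        self._template = _template_from_tensor_builder(
            space,
            build_dec_clado,
            dec_count_outcomes,
            lambda i: int(self._n_present[i]),
        )
        self._q_template = _QTemplate.from_builder(
            space,
            lambda r: build_dec_q(
                DecParams(r[0], r[1], CladoParams(1 / 3, 1 / 3, 1 / 3)), space
            ),
            self.rate_names,
        )

    def is_clado_param(self, j: int) -> bool:
        return j >= 2

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        rates = rng.exponential(self.prior.beta, size=2)
        return np.concatenate([np.maximum(rates, 1e-8), [1 / 3, 1 / 3]])

    def logprior(self, theta: np.ndarray) -> float:
        rates, ps, pb = theta[:2], theta[2], theta[3]
        if (rates < 0).any() or ps + pb > 1 or ps > 1 or pb > 1:
            return -math.inf
        b = self.prior.beta
        return float(-rates.sum() / b - 2 * math.log(b))

    def build_q(self, theta: np.ndarray) -> np.ndarray:
        return self._q_template.q(theta[:2])

    def build_tensor(self, theta: np.ndarray) -> CladoTensor:
        return self._template.tensor(CladoParams.from_free(theta[2], theta[3]))

    def prior_mean(self, name: str) -> float:
        if name in self.rate_names:
            return self.prior.beta
        return 1 / 3

    def draw_from_prior(self, rng: np.random.Generator) -> np.ndarray:
        rates = rng.exponential(self.prior.beta, size=2)
        while True:
            ps, pb = rng.uniform(size=2)
            if ps + pb <= 1:
                break
        return np.concatenate([rates, [ps, pb]])
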