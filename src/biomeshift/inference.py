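"""Bayesian MCMC over model parameters, with trace diagnostics.

Each free parameter gets an exponential prior (the five anagenetic rates,
scale ``beta`` in events per unit tree height) or a flat prior on the
cladogenetic simplex (``ps, pb ~ Uniform(0, 1)`` with ``pe = 1 - ps - pb``;
density zero outside the simplex).  Sampling is Metropolis-Hastings with a
univariate multiplier proposal per parameter, ``x' = x * exp(lambda * u)``
with ``u ~ Uniform(-0.5, 0.5)``, swept deterministically over the
parameters each iteration.  Default tunings are 1.5 for rate parameters
and 0.2 for cladogenetic probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import PruningWorkspace
from .states import TipAmbiguity
from .trees import Phylogeny

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorTrace",
    "multiplier_propose",
    "run_mcmc",
    "hpd_interval",
    "effective_sample_size",
]


@dataclass(frozen=True)
class PriorSpec:
    """Shared exponential scale for rates; flat simplex prior on (ps, pb)."""

    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"prior scale beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 10_000
    thin: int = 1
    burn_in_fraction: float = 0.1
    lambda_rates: float = 1.5
    lambda_clado: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < self.thin or self.thin < 1:
            raise ValueError("need iterations >= thin >= 1")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.lambda_rates <= 0 or self.lambda_clado <= 0:
            raise ValueError("proposal tunings must be > 0")


@dataclass
class PosteriorTrace:
    """Thinned MCMC samples plus run metadata.

    ``samples`` has one row per retained iteration with the free parameters,
    ``loglik`` and ``logprior``.  ``histories`` holds joint ancestral-state
    draws when history sampling was enabled.
    """

    samples: pd.DataFrame
    param_names: tuple[str, ...]
    config: McmcConfig
    prior: PriorSpec
    acceptance: dict[str, float]
    seed: int
    model: str
    histories: list = field(default_factory=list)

    def post_burn_in(self) -> pd.DataFrame:
        cut = int(math.floor(self.config.burn_in_fraction * len(self.samples)))
        return self.samples.iloc[cut:]

    def ess(self) -> dict[str, float]:
        post = self.post_burn_in()
        out = {}
        for name in self.param_names:
            x = post[name].to_numpy()
            out[name] = (
                effective_sample_size(x) if np.ptp(x) > 0 else float("nan")
            )
        return out

    def hpd(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.post_burn_in()[name].to_numpy(), mass)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model\t{self.model}\n")
            fh.write(f"# seed\t{self.seed}\n")
            fh.write(f"# prior_beta\t{self.prior.beta}\n")
            cfg = self.config
            fh.write(
                f"# mcmc\titerations={cfg.iterations} thin={cfg.thin} "
                f"burn_in={cfg.burn_in_fraction} lambda_rates={cfg.lambda_rates} "
                f"lambda_clado={cfg.lambda_clado}\n"
            )
            acc = " ".join(f"{k}={v:.3f}" for k, v in self.acceptance.items())
            fh.write(f"# acceptance\t{acc}\n")
            self.samples.to_csv(fh, sep="\t", index=False)


def multiplier_propose(
    x: float, lam: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Multiplier proposal ``x' = x e^{lambda u}``, ``u ~ U(-0.5, 0.5)``.

    Returns the proposal and the log Hastings correction ``log(x'/x)``.
    """
    if not x > 0:
        raise ValueError(f"multiplier proposal needs x > 0, got {x}")
    u = rng.uniform(-0.5, 0.5)
    x_new = x * math.exp(lam * u)
    return x_new, math.log(x_new / x)


def run_mcmc(
    tree: Phylogeny,
    tips: Sequence[TipAmbiguity],
    prior: PriorSpec,
    config: McmcConfig,
    space,
    model=None,
    root_pi: Optional[np.ndarray] = None,
    history_every: Optional[int] = None,
    history_callback: Optional[Callable] = None,
) -> PosteriorTrace:
    """Metropolis-Hastings sampler for the given model on one dataset.

    Parameters
    ----------
    model:
        A model adapter (see :mod:`biomeshift.models`); defaults to the
        full established/enabled affinity model on ``space``.
    root_pi:
        Root state frequencies; uniform over the state space by default.
    history_every:
        When set, a joint ancestral-state history is drawn every this many
        iterations after burn-in and appended to ``trace.histories`` (or
        passed to ``history_callback`` if given).
    """
    from .models import AffinityModel

    if model is None:
        model = AffinityModel(space, prior)
    rng = np.random.default_rng(config.seed)
    ws = PruningWorkspace(tree, tips, space)
    n_states = space.n_states
    pi = (
        np.full(n_states, 1.0 / n_states)
        if root_pi is None
        else np.asarray(root_pi, dtype=float)
    )

    theta = model.initial(rng)
    names = model.param_names
    q = model.build_q(theta)
    trans = ws.transition_stack(q)
    tensor = model.build_tensor(theta)
    lp = model.logprior(theta)
    ll = ws.loglik(trans, tensor, pi)
    if not np.isfinite(ll):
        raise RuntimeError(
            "initial likelihood is not finite; check that tip masks are "
            "consistent with the tree and state space"
        )

    n_params = len(names)
    lambdas = np.array(
        [
            config.lambda_clado if model.is_clado_param(j) else config.lambda_rates
            for j in range(n_params)
        ]
    )
    accept = np.zeros(n_params, dtype=np.int64)
    burn_end = int(math.floor(config.burn_in_fraction * config.iterations))

    rows = np.empty(
        (config.iterations // config.thin, n_params + 2), dtype=float
    )
    iters = np.empty(config.iterations // config.thin, dtype=np.int64)
    histories: list = []
    n_kept = 0

    for it in range(config.iterations):
        for j in range(n_params):
            x = theta[j]
            x_new, log_h = multiplier_propose(x, lambdas[j], rng)
            theta_new = theta.copy()
            theta_new[j] = x_new
            lp_new = model.logprior(theta_new)
            log_u = math.log(rng.uniform())
            if not np.isfinite(lp_new):
                continue  # outside the prior support (e.g. off the simplex)
            if model.is_clado_param(j):
                tensor_new = model.build_tensor(theta_new)
                ll_new = ws.loglik(trans, tensor_new, pi)
                if log_u < ll_new + lp_new - ll - lp + log_h:
                    theta, lp, ll, tensor = theta_new, lp_new, ll_new, tensor_new
                    accept[j] += 1
            else:
                q_new = model.build_q(theta_new)
                trans_new = ws.transition_stack(q_new)
                ll_new = ws.loglik(trans_new, tensor, pi)
                if log_u < ll_new + lp_new - ll - lp + log_h:
                    theta, lp, ll = theta_new, lp_new, ll_new
                    q, trans = q_new, trans_new
                    accept[j] += 1
        if (it + 1) % config.thin == 0:
            rows[n_kept, :n_params] = theta
            rows[n_kept, n_params] = ll
            rows[n_kept, n_params + 1] = lp
            iters[n_kept] = it + 1
            n_kept += 1
        if (
            history_every is not None
            and it >= burn_end
            and (it + 1) % history_every == 0
        ):
            from .ancestral import sample_history

            h = sample_history(ws, trans, tensor, pi, rng)
            if history_callback is not None:
                history_callback(h)
            else:
                histories.append(h)

    samples = pd.DataFrame(rows[:n_kept], columns=list(names) + ["loglik", "logprior"])
    samples.insert(0, "iteration", iters[:n_kept])
    if "ps" in samples.columns and "pb" in samples.columns:
        samples.insert(
            samples.columns.get_loc("pb") + 1,
            "pe",
            1.0 - samples["ps"] - samples["pb"],
        )
    acceptance = {
        name: accept[j] / config.iterations for j, name in enumerate(names)
    }
    return PosteriorTrace(
        samples=samples,
        param_names=tuple(names),
        config=config,
        prior=prior,
        acceptance=acceptance,
        seed=config.seed,
        model=model.name,
        histories=histories,
    )


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ``mass``.

    The interval covers ``ceil(mass * n)`` samples; among equally short
    windows the one with the lowest start wins.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not (0 < mass <= 1):
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + k - 1])


def effective_sample_size(samples: Sequence[float]) -> float:
    """ESS via the initial-positive-sequence truncation rule.

    ``n / (1 + 2 * sum(rho_k))`` with the autocorrelation sum truncated at
    the first lag pair ``(rho_{2m-1} + rho_{2m})`` that is not positive
    (Geyer's rule).  The estimate is capped at ``n``: antithetic chains
    report at most ``n`` rather than a super-efficient or negative value.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined ESS")
    x = x - x.mean()
    # autocovariance by FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    ess = n / tau
    return float(min(ess, n))
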