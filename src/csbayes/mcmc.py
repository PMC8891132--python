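"""Random-walk Metropolis sampling infrastructure.

All Bayesian models in this package share one sampler: a component-wise
random-walk Metropolis over a user-supplied log-posterior.  Per-parameter
proposal scales are tuned during burn-in by a Robbins-Monro recursion toward
a target acceptance rate and frozen afterwards, so the retained chain is a
time-homogeneous Markov chain with the correct stationary distribution.

The default schedule — three chains, 5 000 burn-in iterations, 150 000
retained iterations thinned by 3 — matches the study this package
reproduces, and every run is bit-reproducible given its integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "OrSummary",
    "InitializationError",
    "run_chains",
    "gelman_rubin",
    "effective_sample_size",
    "summarize",
]


class InitializationError(RuntimeError):
    """The log-posterior is not finite at a chain's initial point."""


class DiagnosticError(ValueError):
    """A convergence diagnostic was requested on an unsuitable run."""


@dataclass(frozen=True)
class McmcSettings:
    """Chain schedule and seeding.

    ``n_iterations`` counts post-burn-in iterations; ``n_iterations // thin``
    draws per chain are stored.
    """

    n_chains: int = 3
    burn_in: int = 5000
    n_iterations: int = 150_000
    thin: int = 3
    seed: int = 0
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.n_iterations, self.thin) < 1:
            raise ValueError("n_chains, burn_in, n_iterations, thin must be positive")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")

    @property
    def n_stored(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class PosteriorDraws:
    """Stored MCMC draws with chain structure and run provenance.

    Attributes
    ----------
    draws : ndarray, shape (n_chains, n_stored, n_params)
    param_names : list of unique parameter names
    settings : the `McmcSettings` that produced the run
    acceptance_rates : ndarray (n_chains, n_params), retained phase only
    scales_post_burnin, scales_final : proposal scales at burn-in end and at
        run end; equal by construction (adaptation is frozen after burn-in).
    """

    draws: np.ndarray
    param_names: list[str]
    settings: McmcSettings
    acceptance_rates: np.ndarray
    scales_post_burnin: np.ndarray
    scales_final: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("parameter names must be unique")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws/param_names mismatch")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index(self, parameter: str) -> int:
        try:
            return self.param_names.index(parameter)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {parameter!r}") from exc

    def stacked(self, parameter: str) -> np.ndarray:
        """All chains' draws of one parameter, concatenated."""
        return self.draws[:, :, self.index(parameter)].reshape(-1)

    def to_frame(self):
        """Flat (chain, iteration, parameters...) DataFrame."""
        import pandas as pd

        n_chains, n_stored, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(n_chains * n_stored, -1), columns=self.param_names
        )
        frame.insert(0, "iteration", np.tile(np.arange(n_stored), n_chains))
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_stored))
        return frame

    def to_arviz(self):
        import arviz as az

        return az.from_dict(
            {name: self.draws[:, :, i] for i, name in enumerate(self.param_names)}
        )


@dataclass(frozen=True)
class OrSummary:
    """Posterior summary of a scalar (odds-ratio-style) quantity.

    ``point`` is the posterior median, the interval is the equal-tailed 95%
    credible interval, and ``pr_gt_1`` the posterior probability of exceeding
    the decision threshold (1 on an odds-ratio scale, 0 on a log scale).
    """

    point: float
    ci_low: float
    ci_high: float
    pr_gt_1: float
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("summary must satisfy ci_low <= point <= ci_high")
        if not 0.0 <= self.pr_gt_1 <= 1.0:
            raise ValueError("pr_gt_1 must lie in [0, 1]")


_ADAPT_BATCH = 50


def _sample_one_chain(
    log_posterior: Callable[[np.ndarray], float],
    x0: np.ndarray,
    settings: McmcSettings,
    rng: np.random.Generator,
    initial_scales: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_params = x0.size
    x = x0.astype(float).copy()
    lp = float(log_posterior(x))
    if not math.isfinite(lp):
        raise InitializationError(
            f"log-posterior not finite at initial point {x0!r}"
        )

    log_scales = np.log(initial_scales).tolist()
    scales = [math.exp(s) for s in log_scales]
    target = settings.target_acceptance
    burn_in, n_iter, thin = settings.burn_in, settings.n_iterations, settings.thin
    total = burn_in + n_iter
    stored = np.empty((settings.n_stored, n_params))
    accepted_retained = np.zeros(n_params, dtype=np.int64)
    batch_accept = [0] * n_params
    scales_post_burnin = np.array(scales)

    chunk = 8192
    buf = chunk  # force refill on first use
    store_row = 0
    for it in range(total):
        if buf == chunk:
            normals = rng.standard_normal((chunk, n_params))
            logu = np.log(rng.random((chunk, n_params)))
            buf = 0
        zrow, urow = normals[buf], logu[buf]
        buf += 1
        adapting = it < burn_in
        for j in range(n_params):
            old = x[j]
            x[j] = old + scales[j] * zrow[j]
            lp_new = float(log_posterior(x))
            if lp_new - lp >= urow[j]:
                lp = lp_new
                if adapting:
                    batch_accept[j] += 1
                else:
                    accepted_retained[j] += 1
            else:
                x[j] = old
        if adapting and (it + 1) % _ADAPT_BATCH == 0:
            # Robbins-Monro step on the log proposal scale, vanishing gain
            batch_no = (it + 1) // _ADAPT_BATCH
            gain = min(1.0, 5.0 / math.sqrt(batch_no))
            for j in range(n_params):
                rate = batch_accept[j] / _ADAPT_BATCH
                log_scales[j] += gain * (rate - target)
                scales[j] = math.exp(log_scales[j])
                batch_accept[j] = 0
        if it == burn_in - 1:
            scales_post_burnin = np.array(scales)
        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            if store_row < stored.shape[0]:
                stored[store_row] = x
                store_row += 1

    return (
        stored,
        accepted_retained / float(n_iter),
        scales_post_burnin,
        np.array(scales),
    )


def run_chains(
    log_posterior: Callable[[np.ndarray], float],
    init: Sequence[float] | Callable[[int, np.random.Generator], Sequence[float]],
    settings: McmcSettings,
    param_names: Sequence[str] | None = None,
    initial_scales: Sequence[float] | None = None,
) -> PosteriorDraws:
    """Run multiple adaptive random-walk Metropolis chains.

    Parameters
    ----------
    log_posterior
        Callable returning the unnormalized log posterior density at a
        parameter vector (passed as a 1-d ndarray).  Must be finite at every
        chain's initial point.
    init
        Either a single starting vector (each chain receives an independent
        Gaussian jitter of scale 0.1 around it) or a callable
        ``init(chain_index, rng) -> vector``.
    settings
        Chain schedule; per-chain RNG streams are spawned deterministically
        from ``settings.seed``.
    initial_scales
        Optional per-parameter starting proposal scales (default 1).
    """
    seed_seq = np.random.SeedSequence(settings.seed)
    chain_seqs = seed_seq.spawn(settings.n_chains)

    chains, rates, post_scales, final_scales = [], [], [], []
    for c in range(settings.n_chains):
        rng = np.random.Generator(np.random.PCG64(chain_seqs[c]))
        if callable(init):
            x0 = np.asarray(init(c, rng), dtype=float)
        else:
            x0 = np.asarray(init, dtype=float)
            if c > 0:  # jitter all but the first chain for dispersion
                x0 = x0 + 0.1 * rng.standard_normal(x0.size)
        scales0 = (
            np.ones(x0.size)
            if initial_scales is None
            else np.asarray(initial_scales, dtype=float)
        )
        stored, rate, sc_post, sc_final = _sample_one_chain(
            log_posterior, x0, settings, rng, scales0
        )
        chains.append(stored)
        rates.append(rate)
        post_scales.append(sc_post)
        final_scales.append(sc_final)

    draws = PosteriorDraws(
        draws=np.stack(chains),
        param_names=list(param_names)
        if param_names is not None
        else [f"p{i}" for i in range(chains[0].shape[1])],
        settings=settings,
        acceptance_rates=np.stack(rates),
        scales_post_burnin=np.stack(post_scales),
        scales_final=np.stack(final_scales),
    )
    if (draws.acceptance_rates < 0.01).any():
        warnings.warn(
            "near-zero acceptance rate on at least one parameter; "
            "the run is likely pathological",
            RuntimeWarning,
            stacklevel=2,
        )
    return draws


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain potential scale reduction factor (R-hat) per parameter.

    Each chain is split in half, giving 2m sequences of length n/2; R-hat is
    sqrt of (pooled-variance estimate / mean within-sequence variance).
    Values near 1 indicate the chains have mixed.
    """
    if draws.n_chains < 2:
        raise DiagnosticError("R-hat needs at least two chains")
    if draws.draws.shape[1] < 10:
        raise DiagnosticError("R-hat needs at least 10 stored draws per chain")
    return {
        name: _split_rhat(draws.draws[:, :, i])
        for i, name in enumerate(draws.param_names)
    }


def _split_rhat(chains: np.ndarray) -> float:
    m, n = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n = half
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    if w == 0.0:
        return 1.0
    return float(math.sqrt(var_hat / w))


def effective_sample_size(draws: PosteriorDraws) -> dict[str, float]:
    """Bulk effective sample size per parameter (via arviz)."""
    import arviz as az

    ess = az.ess(draws.to_arviz())
    return {name: float(ess[name].values) for name in draws.param_names}


def summarize(
    draws: PosteriorDraws,
    parameter: str,
    transform: str | Callable[[np.ndarray], np.ndarray] = "identity",
    threshold: float | None = None,
) -> OrSummary:
    """Median, equal-tailed 95% CrI and exceedance probability of a parameter.

    ``transform="exp"`` summarizes on the anti-log scale — with the default
    threshold this turns a log-odds-ratio parameter into the posterior
    Pr(OR > 1).  Quantiles interpolate linearly between order statistics.
    """
    values = draws.stacked(parameter)
    if transform == "identity":
        thr = 0.0 if threshold is None else threshold
    elif transform == "exp":
        values = np.exp(values)
        thr = 1.0 if threshold is None else threshold
    elif callable(transform):
        values = transform(values)
        thr = 0.0 if threshold is None else threshold
    else:
        raise ValueError(f"unknown transform {transform!r}")
    lo, med, hi = np.quantile(values, [0.025, 0.5, 0.975])
    return OrSummary(
        point=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        pr_gt_1=float(np.mean(values > thr)),
        n_draws=values.size,
        seed=draws.settings.seed,
    )
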