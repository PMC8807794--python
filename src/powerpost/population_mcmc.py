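"""Tempered-ensemble (population) MCMC over power posteriors.

One Metropolis-Hastings chain is run per inverse temperature ``beta`` of a
:class:`TemperatureSchedule`; neighbouring chains exchange states through a
Metropolis "swap" accept-reject step.  The chain at ``beta = 0`` targets the
prior exactly and is sampled by independent prior draws; the chain at
``beta = 1`` targets the posterior.  The resulting :class:`PopulationTrace`
carries the cached per-draw log-likelihoods that thermodynamic integration
consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from powerpost.exceptions import InvalidConfigError
from powerpost.model_core import BayesianModel

__all__ = [
    "TemperatureSchedule",
    "PowerPosterior",
    "PopulationTrace",
    "SamplerConfig",
    "make_power_schedule",
    "mh_step",
    "swap_log_accept",
    "swap_step",
    "run_population_mcmc",
    "gelman_rubin",
    "split_rhat",
]


@dataclass(frozen=True)
class TemperatureSchedule:
    """Ordered grid of inverse temperatures from the prior to the posterior.

    ``betas[0] = 0`` and ``betas[-1] = 1``; strictly increasing.  For the
    power rule, ``betas[j] = (j / (N - 1)) ** order``.
    """

    betas: np.ndarray
    order: float | None = None

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", betas)
        if betas.ndim != 1 or betas.size < 2:
            raise InvalidConfigError("schedule needs at least two temperatures")
        if betas[0] != 0.0 or betas[-1] != 1.0:
            raise InvalidConfigError("schedule must start at beta=0 and end at beta=1")
        if np.any(np.diff(betas) <= 0):
            raise InvalidConfigError("schedule must be strictly increasing")

    @property
    def n_chains(self) -> int:
        return self.betas.size


def make_power_schedule(n_chains: int, order: float = 5.0) -> TemperatureSchedule:
    """Power-rule schedule ``beta_j = (j / (n_chains - 1)) ** order``.

    A fifth-order rule concentrates temperatures near the prior end of the
    path, where the expected log-likelihood changes fastest.
    """
    if n_chains < 2:
        raise InvalidConfigError("need at least 2 chains (beta endpoints 0 and 1)")
    if order <= 0:
        raise InvalidConfigError("power-rule order must be positive")
    j = np.arange(n_chains, dtype=float)
    return TemperatureSchedule(betas=(j / (n_chains - 1)) ** order, order=order)


@dataclass(frozen=True)
class PowerPosterior:
    """Unnormalized tempered target ``beta * log_likelihood + log_prior``."""

    model: BayesianModel
    beta: float

    def log_density(self, theta: np.ndarray) -> float:
        lp = self.model.log_prior(theta)
        if self.beta == 0.0:
            return lp
        return self.beta * self.model.log_likelihood(theta) + lp


def mh_step(
    state: np.ndarray,
    power_posterior: PowerPosterior,
    proposal_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One Gaussian random-walk Metropolis update of the tempered target.

    Accepts the proposal with probability
    ``min(1, exp(delta[beta * loglik + logprior]))``.  Proposals with
    ``-inf`` density are always rejected.
    """
    proposal = state + proposal_scale * rng.standard_normal(state.shape)
    cur = power_posterior.log_density(state)
    new = power_posterior.log_density(proposal)
    if new - cur >= 0 or rng.random() < np.exp(new - cur):
        return proposal, True
    return np.asarray(state), False


def swap_log_accept(beta_i: float, beta_j: float, loglik_i: float, loglik_j: float) -> float:
    """Log acceptance ratio of exchanging states between temperatures i and j.

    ``(beta_i - beta_j) * (loglik_j - loglik_i)``: the prior factors cancel,
    so only the cached log-likelihoods enter.
    """
    if loglik_i == loglik_j:  # covers the -inf/-inf pair without NaN
        return 0.0
    return (beta_i - beta_j) * (loglik_j - loglik_i)


def swap_step(
    beta_i: float,
    beta_j: float,
    state_i: np.ndarray,
    state_j: np.ndarray,
    loglik_i: float,
    loglik_j: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Propose exchanging the states of two neighbouring chains.

    Cached log-likelihoods travel with their states on acceptance.
    """
    log_alpha = swap_log_accept(beta_i, beta_j, loglik_i, loglik_j)
    if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
        return state_j, state_i, loglik_j, loglik_i, True
    return state_i, state_j, loglik_i, loglik_j, False


@dataclass
class SamplerConfig:
    """Tunables of the population sampler.

    ``proposal_scale`` seeds the per-chain random-walk scale, which is
    adapted during burn-in toward ``target_accept`` by a Robbins-Monro
    recursion on the log scale and frozen afterwards (so the post-burn-in
    kernel is a valid fixed MCMC kernel).  When ``adapt_covariance`` is on,
    each chain additionally learns the empirical covariance of its draws
    during burn-in (adaptive-Metropolis shaping, ``2.38^2 / d`` scaling)
    starting after ``covariance_start`` burn-in sweeps; correlated tempered
    posteriors mix far faster under shaped proposals than under isotropic
    ones.  ``swap_every`` controls how many sweeps separate swap passes
    (1 = every sweep).
    """

    proposal_scale: float = 0.5
    target_accept: float = 0.25
    adapt: bool = True
    adapt_covariance: bool = True
    covariance_start: int = 200
    diminishing_adaptation: bool = True
    scale_jitter: float = 0.3
    indep_prob: float = 0.1
    swap_every: int = 1
    swap_passes: int = 1


@dataclass
class PopulationTrace:
    """Post-burn-in draws and cached log-densities of every tempered chain.

    ``draws`` has shape ``(n_chains, K, dim)``; ``loglik`` and ``logprior``
    have shape ``(n_chains, K)`` and are coherent with ``draws`` (each entry
    is the model log-density evaluated at the matching draw).
    """

    schedule: TemperatureSchedule
    draws: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    acceptance: np.ndarray
    swap_acceptance: np.ndarray
    seed: int | None
    burn_in: int
    proposal_scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_kept(self) -> int:
        return self.loglik.shape[1]

    def summary(self) -> pd.DataFrame:
        """Per-temperature summary: mean log-likelihood, acceptance, split R-hat."""
        rows = []
        for j, beta in enumerate(self.schedule.betas):
            rhat = split_rhat(self.loglik[j]) if self.n_kept >= 8 else np.nan
            rows.append(
                {
                    "beta": beta,
                    "mean_loglik": float(np.mean(self.loglik[j])) if self.n_kept else np.nan,
                    "acceptance": float(self.acceptance[j]),
                    "split_rhat": rhat,
                }
            )
        return pd.DataFrame(rows)

    def max_split_rhat(self) -> float:
        """Maximum over temperatures of the split-half R-hat of the
        log-likelihood trace; the convergence figure reported by runs."""
        return float(np.max([split_rhat(self.loglik[j]) for j in range(self.schedule.n_chains)]))

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["burn_in"] = self.burn_in
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["order"] = np.nan if self.schedule.order is None else self.schedule.order
            f.create_dataset("betas", data=self.schedule.betas)
            f.create_dataset("draws", data=self.draws)
            f.create_dataset("loglik", data=self.loglik)
            f.create_dataset("logprior", data=self.logprior)
            f.create_dataset("acceptance", data=self.acceptance)
            f.create_dataset("swap_acceptance", data=self.swap_acceptance)
            if self.proposal_scales is not None:
                f.create_dataset("proposal_scales", data=self.proposal_scales)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "PopulationTrace":
        with h5py.File(path, "r") as f:
            order = float(f.attrs["order"])
            seed = int(f.attrs["seed"])
            return cls(
                schedule=TemperatureSchedule(
                    betas=f["betas"][...], order=None if np.isnan(order) else order
                ),
                draws=f["draws"][...],
                loglik=f["loglik"][...],
                logprior=f["logprior"][...],
                acceptance=f["acceptance"][...],
                swap_acceptance=f["swap_acceptance"][...],
                seed=None if seed < 0 else seed,
                burn_in=int(f.attrs["burn_in"]),
                proposal_scales=f["proposal_scales"][...] if "proposal_scales" in f else None,
            )


def run_population_mcmc(
    model: BayesianModel,
    schedule: TemperatureSchedule,
    n_samples: int,
    burn_in: int,
    seed: int | None = None,
    config: SamplerConfig | None = None,
) -> PopulationTrace:
    """Run the tempered ensemble and return the post-burn-in trace.

    Every chain is initialized from a prior draw.  Each sweep performs one
    Metropolis update per chain (the ``beta = 0`` chain instead redraws
    independently from the prior, which samples its target exactly) followed
    by a swap pass over alternating even/odd neighbour pairs, so every
    adjacency is visited every two sweeps.  Proposal scales adapt during
    burn-in only.  Fully reproducible given ``seed``.
    """
    if n_samples < 0 or burn_in < 0:
        raise InvalidConfigError("n_samples and burn_in must be nonnegative")
    config = config or SamplerConfig()
    betas = schedule.betas
    n_chains = betas.size

    # one independent substream per chain plus one for the swap pass, spawned
    # from the master seed so chain-count changes never alias streams
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_chains + 1)]
    chain_rngs, swap_rng = streams[:n_chains], streams[n_chains]

    states = np.empty((n_chains, model.dim))
    loglik = np.empty(n_chains)
    logprior = np.empty(n_chains)
    for j in range(n_chains):
        states[j] = model.prior_sampler(chain_rngs[j])
        loglik[j] = model.log_likelihood(states[j])
        logprior[j] = model.log_prior(states[j])

    # optional model-provided block update (Metropolis-within-Gibbs) for
    # coordinates whose conditional is cheap to evaluate
    gibbs = getattr(model, "gibbs_step", None)

    log_scales = np.full(n_chains, np.log(config.proposal_scale))
    # Welford accumulators and Cholesky shapes for adaptive-Metropolis proposals
    d = model.dim
    am_n = np.zeros(n_chains)
    am_mean = np.zeros((n_chains, d))
    am_m2 = np.zeros((n_chains, d, d))
    prop_chol: list[np.ndarray | None] = [None] * n_chains
    am_scale = 2.38 / np.sqrt(d)
    accept_count = np.zeros(n_chains)
    swap_attempts = np.zeros(max(n_chains - 1, 1))
    swap_accepts = np.zeros(max(n_chains - 1, 1))

    draws = np.empty((n_chains, n_samples, model.dim))
    kept_ll = np.empty((n_chains, n_samples))
    kept_lp = np.empty((n_chains, n_samples))

    total = burn_in + n_samples
    for sweep in range(total):
        # with diminishing_adaptation the (ergodic) Haario-style adaptation
        # continues through the sampling phase at a decaying rate; otherwise
        # proposals freeze at the end of burn-in
        adapting = config.adapt and (config.diminishing_adaptation or sweep < burn_in)
        in_keep = sweep >= burn_in
        for j in range(n_chains):
            rng = chain_rngs[j]
            if betas[j] == 0.0:
                # exact independent draw from the prior
                states[j] = model.prior_sampler(rng)
                loglik[j] = model.log_likelihood(states[j])
                logprior[j] = model.log_prior(states[j])
                if in_keep:
                    accept_count[j] += 1
                continue
            if config.indep_prob > 0 and rng.random() < config.indep_prob:
                # independence proposal from the prior: global regeneration
                # for weakly tempered chains; prior and proposal densities
                # cancel, leaving the tempered-likelihood ratio
                proposal = model.prior_sampler(rng)
                prop_lp = model.log_prior(proposal)
                prop_ll = model.log_likelihood(proposal)
                if np.isneginf(prop_ll):
                    accepted = False
                else:
                    delta = betas[j] * (prop_ll - loglik[j])
                    accepted = delta >= 0 or rng.random() < np.exp(delta)
                if accepted:
                    states[j] = proposal
                    loglik[j] = prop_ll
                    logprior[j] = prop_lp
                if in_keep:
                    accept_count[j] += accepted
                continue
            scale = np.exp(log_scales[j])
            if config.scale_jitter > 0:
                # lognormal step-size jitter: occasional long jumps, cheap wins
                scale *= np.exp(config.scale_jitter * rng.standard_normal())
            z = rng.standard_normal(model.dim)
            if prop_chol[j] is not None:
                proposal = states[j] + scale * am_scale * (prop_chol[j] @ z)
            else:
                proposal = states[j] + scale * z
            prop_lp = model.log_prior(proposal)
            prop_ll = model.log_likelihood(proposal) if np.isfinite(prop_lp) else -np.inf
            new = betas[j] * prop_ll + prop_lp
            if not np.isfinite(new):
                accepted = False  # -inf proposals are always rejected
            else:
                cur = betas[j] * loglik[j] + logprior[j]
                delta = new - cur  # cur may be -inf, making delta +inf: accept
                accepted = delta >= 0 or rng.random() < np.exp(delta)
            if accepted:
                states[j] = proposal
                loglik[j] = prop_ll
                logprior[j] = prop_lp
            if in_keep:
                accept_count[j] += accepted
            if adapting:
                gamma = (sweep + 1) ** -0.6
                log_scales[j] += gamma * ((1.0 if accepted else 0.0) - config.target_accept)
                if config.adapt_covariance:
                    am_n[j] += 1.0
                    delta = states[j] - am_mean[j]
                    am_mean[j] += delta / am_n[j]
                    am_m2[j] += np.outer(delta, states[j] - am_mean[j])
                    if (
                        sweep >= config.covariance_start
                        and am_n[j] > 2 * d
                        and sweep % 25 == 0
                    ):
                        cov = am_m2[j] / (am_n[j] - 1.0)
                        jitter = 1e-8 + 1e-6 * np.trace(cov) / d
                        try:
                            chol = np.linalg.cholesky(cov + jitter * np.eye(d))
                        except np.linalg.LinAlgError:
                            chol = None
                        if chol is not None:
                            if prop_chol[j] is None:
                                log_scales[j] = 0.0  # re-tune around the AM scale
                            prop_chol[j] = chol

        # block update of coordinates the model can refresh cheaply given the
        # rest (e.g. observation-noise precisions given cached residuals)
        if gibbs is not None:
            for j in range(n_chains):
                if betas[j] == 0.0:
                    continue
                states[j], loglik[j], logprior[j] = gibbs(
                    states[j], betas[j], chain_rngs[j]
                )

        if n_chains > 1 and config.swap_every > 0 and sweep % config.swap_every == 0:
            # alternating even/odd passes; swaps reuse the cached
            # log-likelihoods, so ladder transport is essentially free
            for p in range(max(config.swap_passes, 1)):
                start = (sweep // config.swap_every + p) % 2
                for i in range(start, n_chains - 1, 2):
                    swap_attempts[i] += 1
                    log_alpha = swap_log_accept(
                        betas[i], betas[i + 1], loglik[i], loglik[i + 1]
                    )
                    if log_alpha >= 0 or swap_rng.random() < np.exp(log_alpha):
                        states[[i, i + 1]] = states[[i + 1, i]]
                        loglik[[i, i + 1]] = loglik[[i + 1, i]]
                        logprior[[i, i + 1]] = logprior[[i + 1, i]]
                        swap_accepts[i] += 1

        if in_keep:
            k = sweep - burn_in
            draws[:, k, :] = states
            kept_ll[:, k] = loglik
            kept_lp[:, k] = logprior

    acceptance = accept_count / n_samples if n_samples else np.zeros(n_chains)
    if n_samples and np.any(acceptance[betas > 0] == 0.0):
        warnings.warn(
            "at least one tempered chain accepted no post-burn-in move; "
            "inspect proposal scales and adaptation window",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        swap_rates = np.where(swap_attempts > 0, swap_accepts / np.maximum(swap_attempts, 1), np.nan)
    return PopulationTrace(
        schedule=schedule,
        draws=draws,
        loglik=kept_ll,
        logprior=kept_lp,
        acceptance=acceptance,
        swap_acceptance=swap_rates,
        seed=seed,
        burn_in=burn_in,
        proposal_scales=np.exp(log_scales),
    )


def gelman_rubin(chain_segments: Sequence[np.ndarray] | np.ndarray) -> float:
    """Classical potential scale reduction factor R-hat of scalar segments.

    ``chain_segments`` is a sequence of m >= 2 equal-length scalar
    sequences.  Returns exactly 1.0 when all segments have zero within
    variance (degenerate convention).
    """
    seg = np.asarray(chain_segments, dtype=float)
    if seg.ndim != 2 or seg.shape[0] < 2:
        raise InvalidConfigError("need >= 2 equal-length segments")
    m, n = seg.shape
    if n < 4:
        raise InvalidConfigError("segments must have length >= 4")
    W = float(np.mean(np.var(seg, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(seg, axis=1), ddof=1))
    if W == 0.0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def split_rhat(values: np.ndarray) -> float:
    """Split-half R-hat of one scalar trace (first half vs second half)."""
    values = np.asarray(values, dtype=float).ravel()
    half = values.size // 2
    return gelman_rubin(np.stack([values[:half], values[half : 2 * half]]))
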