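"""Log-model-evidence estimators and path diagnostics.

Thermodynamic integration (TI) turns the identity

    ln p(y|m) = integral_0^1  E[ ln p(y|theta,m) ]_{p_beta(theta|y,m)}  d beta

into a trapezoid quadrature over the per-temperature Monte Carlo means
``E_MC(beta_j)`` cached in a :class:`~powerpost.population_mcmc.PopulationTrace`.
The prior arithmetic-mean (AME) and posterior harmonic-mean (HME) estimators
are included as reference implementations of known-biased estimators: AME
systematically underestimates and HME overestimates the evidence.

The expected log-likelihood along the path, ``A(beta)``, is the model's
*accuracy*; its running integral is the negative free energy, and
``beta * A(beta)`` minus that integral is the KL divergence of the power
posterior from the prior (the *complexity*).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from powerpost.exceptions import EstimationError, InvalidTraceError
from powerpost.model_core import BayesianModel
from powerpost.population_mcmc import PopulationTrace

__all__ = [
    "EvidenceEstimate",
    "FreeEnergyDecomposition",
    "ti_estimate",
    "ame_estimate",
    "hme_estimate",
    "accuracy_curve",
    "decompose_free_energy",
]


@dataclass
class EvidenceEstimate:
    """One LME value with its provenance.

    ``curve`` (TI only) holds one row per temperature with columns
    ``beta``, ``e_mc`` (the Monte Carlo mean log-likelihood) and ``mc_se``
    (its autocorrelation-corrected standard error).
    """

    method: str
    lme: float
    n_samples_used: int
    mc_se: float = np.nan
    curve: pd.DataFrame | None = None
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "lme": self.lme,
            "mc_se": None if np.isnan(self.mc_se) else self.mc_se,
            "n_samples_used": self.n_samples_used,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def curve_to_csv(self, path: str | Path) -> None:
        if self.curve is None:
            raise ValueError(f"{self.method} estimate carries no per-beta curve")
        self.curve.to_csv(path, index=False)


@dataclass(frozen=True)
class FreeEnergyDecomposition:
    """Accuracy/complexity split of the negative free energy at one beta.

    ``neg_free_energy = accuracy_term - kl_term`` by construction, with
    ``accuracy_term = beta * A(beta)`` and ``kl_term`` the KL divergence of
    the power posterior from the prior (nonnegative up to MC error).
    """

    beta: float
    neg_free_energy: float
    accuracy_term: float
    kl_term: float


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0.0:
        return float(n)
    xc = x - x.mean()
    # FFT autocovariance, biased normalization
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs while they stay positive
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(np.clip(n / tau, 1.0, n))


def _mc_se(x: np.ndarray) -> float:
    """Autocorrelation-aware standard error of a chain mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(_ess(x)))


def _e_mc_table(trace: PopulationTrace) -> pd.DataFrame:
    betas = trace.schedule.betas
    if trace.n_kept < 1:
        raise InvalidTraceError("trace holds no post-burn-in samples")
    e_mc = trace.loglik.mean(axis=1)
    if not np.all(np.isfinite(e_mc)):
        bad = betas[~np.isfinite(e_mc)]
        raise EstimationError(f"non-finite E_MC at beta = {bad.tolist()}")
    se = np.array([_mc_se(trace.loglik[j]) for j in range(betas.size)])
    return pd.DataFrame({"beta": betas, "e_mc": e_mc, "mc_se": se})


def _trapezoid_weights(betas: np.ndarray) -> np.ndarray:
    w = np.zeros_like(betas)
    d = np.diff(betas)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def ti_estimate(trace: PopulationTrace, rule: str = "trapezoid") -> EvidenceEstimate:
    """Thermodynamic-integration LME from a population trace.

    ``E_MC(beta_j)`` is the mean of the cached log-likelihoods at each
    temperature; the LME is the trapezoid quadrature
    ``0.5 * sum_j (beta_{j+1} - beta_j) (E_MC(beta_{j+1}) + E_MC(beta_j))``.
    ``rule="simpson"`` switches to composite Simpson on the same grid; the
    trapezoid rule stays the default.  The MC standard error is propagated
    from the per-temperature standard errors assuming independence across
    temperatures.
    """
    if rule not in ("trapezoid", "simpson"):
        raise InvalidTraceError(f"unknown quadrature rule {rule!r}")
    betas = trace.schedule.betas
    if betas.size < 2 or betas[0] != 0.0 or betas[-1] != 1.0:
        raise InvalidTraceError("TI requires a schedule spanning beta=0 to beta=1")
    curve = _e_mc_table(trace)
    w = _trapezoid_weights(betas)
    if rule == "simpson":
        from scipy.integrate import simpson

        lme = float(simpson(curve["e_mc"].to_numpy(), x=betas))
    else:
        lme = float(w @ curve["e_mc"].to_numpy())
    se = float(np.sqrt(np.sum((w * curve["mc_se"].to_numpy()) ** 2)))
    return EvidenceEstimate(
        method="TI",
        lme=lme,
        mc_se=se,
        curve=curve,
        n_samples_used=int(trace.n_kept * betas.size),
        seed=trace.seed,
    )


def ame_estimate(
    model: BayesianModel, n_samples: int, seed: int | None = None
) -> EvidenceEstimate:
    """Prior arithmetic-mean estimator: ``log mean exp(loglik)`` over prior draws.

    Known to underestimate the LME because prior draws rarely land in the
    high-likelihood region.  Max-shifted log-sum-exp keeps it stable.
    """
    if n_samples < 1:
        raise EstimationError("AME needs at least one prior draw")
    rng = np.random.default_rng(seed)
    lls = np.array(
        [model.log_likelihood(model.prior_sampler(rng)) for _ in range(n_samples)]
    )
    if np.all(np.isneginf(lls)):
        raise EstimationError("all prior draws had log-likelihood -inf")
    lme = float(logsumexp(lls) - np.log(n_samples))
    return EvidenceEstimate(method="AME", lme=lme, n_samples_used=n_samples, seed=seed)


def hme_estimate(posterior_loglik_samples: np.ndarray) -> EvidenceEstimate:
    """Posterior harmonic-mean estimator: ``-log mean exp(-loglik)``.

    Consumes cached log-likelihoods from the ``beta = 1`` chain of an
    existing trace.  Known to overestimate the LME (the reciprocal
    likelihood has heavy tails under the posterior).
    """
    lls = np.asarray(posterior_loglik_samples, dtype=float).ravel()
    finite = lls[np.isfinite(lls)]
    if finite.size < 1:
        raise EstimationError("HME needs at least one finite log-likelihood sample")
    lme = float(-(logsumexp(-finite) - np.log(finite.size)))
    return EvidenceEstimate(method="HME", lme=lme, n_samples_used=int(finite.size))


def hme_from_trace(trace: PopulationTrace) -> EvidenceEstimate:
    """HME on the posterior (beta = 1) chain of a population trace."""
    est = hme_estimate(trace.loglik[-1])
    est.seed = trace.seed
    return est


def accuracy_curve(trace: PopulationTrace) -> pd.DataFrame:
    """Per-temperature accuracy ``A(beta_j) = E_MC(beta_j)`` with MC errors.

    Because the variance of the log-likelihood under any power posterior is
    positive, A(beta) is monotonically nondecreasing in beta up to MC noise;
    ``df.attrs['monotone']`` flags whether every adjacent pair is
    nondecreasing within two pooled standard errors.
    """
    curve = _e_mc_table(trace).rename(columns={"e_mc": "accuracy"})
    a = curve["accuracy"].to_numpy()
    se = curve["mc_se"].to_numpy()
    tol = 2.0 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
    curve.attrs["monotone"] = bool(np.all(np.diff(a) >= -tol))
    return curve


def decompose_free_energy(trace: PopulationTrace, beta_index: int) -> FreeEnergyDecomposition:
    """Accuracy/complexity decomposition at ``betas[beta_index]``.

    The negative free energy at beta is the partial trapezoid integral of
    the accuracy from 0 to beta; the KL term is the remainder
    ``beta * A(beta) - (-F_H(beta))``.
    """
    curve = _e_mc_table(trace)
    betas = curve["beta"].to_numpy()
    if not 0 <= beta_index < betas.size:
        raise InvalidTraceError(f"beta_index {beta_index} out of range")
    e = curve["e_mc"].to_numpy()
    b, a = betas[: beta_index + 1], e[: beta_index + 1]
    neg_f = float(np.sum(np.diff(b) * (a[1:] + a[:-1]) / 2.0)) if beta_index > 0 else 0.0
    beta = float(betas[beta_index])
    acc_term = beta * float(e[beta_index])
    return FreeEnergyDecomposition(
        beta=beta,
        neg_free_energy=neg_f,
        accuracy_term=acc_term,
        kl_term=acc_term - neg_f,
    )
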