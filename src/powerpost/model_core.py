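"""Generic Bayesian-model contract and the conjugate linear-regression family.

Every evidence estimator in this package consumes the same minimal model
surface: a parameter dimension, a normalized log-prior, a log-likelihood and
a prior sampler.  :class:`BayesianModel` packages arbitrary callables into
that surface; :class:`LinRegModel` implements it for Bayesian linear
regression with Gaussian prior ``N(0, Pi_p^-1)`` and likelihood
``N(X theta, Pi_e^-1)``, whose log model evidence (LME) is available in
closed form and therefore serves as the analytic oracle for estimator
benchmarks.

All log densities are in nats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from powerpost.exceptions import InvalidConfigError, InvalidModelError, ShapeError

__all__ = [
    "BayesianModel",
    "LinRegModel",
    "LinRegPosterior",
    "linreg_log_evidence",
    "linreg_posterior",
    "generate_linreg_dataset",
    "save_linreg",
    "load_linreg",
]


@dataclass
class BayesianModel:
    """The pluggable triple every estimator consumes.

    Parameters
    ----------
    name : str
        Identifier for reports and manifests.
    dim : int
        Length of the parameter vector theta.
    log_prior : callable
        Maps a parameter vector to the log of a properly normalized prior
        density (nats).
    log_likelihood : callable
        Maps a parameter vector to the log-likelihood of the observed data
        (nats).  Must return a finite float or ``-inf``, never NaN.
    prior_sampler : callable
        Maps a :class:`numpy.random.Generator` to a draw from the prior.
    """

    name: str
    dim: int
    log_prior: Callable[[np.ndarray], float]
    log_likelihood: Callable[[np.ndarray], float]
    prior_sampler: Callable[[np.random.Generator], np.ndarray]

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InvalidModelError("parameter dimension must be >= 1")


def _check_spd(mat: np.ndarray, label: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ShapeError(f"{label} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, rtol=1e-10, atol=1e-12):
        raise InvalidModelError(f"{label} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as err:
        raise InvalidModelError(f"{label} must be positive definite") from err
    return mat


def _logdet_spd(mat: np.ndarray) -> float:
    # factorization-based log-determinant; inputs already verified SPD
    c = np.linalg.cholesky(mat)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


@dataclass
class LinRegModel:
    """Bayesian linear regression ``y = X theta + e`` with Gaussian conjugacy.

    Prior ``theta ~ N(0, prior_precision^-1)``; noise
    ``e ~ N(0, noise_precision^-1)``.  Exposes the :class:`BayesianModel`
    surface directly (``dim``, ``log_prior``, ``log_likelihood``,
    ``prior_sampler``).
    """

    design: np.ndarray
    data: np.ndarray
    prior_precision: np.ndarray
    noise_precision: np.ndarray
    name: str = "linreg"
    seed: int | None = None

    # cached factorizations, built once in __post_init__
    _chol_prior: np.ndarray = field(init=False, repr=False)
    _logdet_prior: float = field(init=False, repr=False)
    _logdet_noise: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.data = np.asarray(self.data, dtype=float).ravel()
        self.prior_precision = _check_spd(self.prior_precision, "prior_precision")
        self.noise_precision = _check_spd(self.noise_precision, "noise_precision")
        M, p = self.design.shape
        if self.data.shape[0] != M:
            raise ShapeError(f"data has length {self.data.shape[0]}, design has {M} rows")
        if self.prior_precision.shape[0] != p:
            raise ShapeError("prior_precision dimension does not match design columns")
        if self.noise_precision.shape[0] != M:
            raise ShapeError("noise_precision dimension does not match design rows")
        self._chol_prior = np.linalg.cholesky(self.prior_precision)
        self._logdet_prior = _logdet_spd(self.prior_precision)
        self._logdet_noise = _logdet_spd(self.noise_precision)

    @property
    def n_obs(self) -> int:
        return self.design.shape[0]

    @property
    def dim(self) -> int:
        return self.design.shape[1]

    def log_prior(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        quad = theta @ self.prior_precision @ theta
        return 0.5 * (self._logdet_prior - self.dim * np.log(2.0 * np.pi) - quad)

    def log_likelihood(self, theta: np.ndarray) -> float:
        r = self.data - self.design @ np.asarray(theta, dtype=float)
        quad = r @ self.noise_precision @ r
        return 0.5 * (self._logdet_noise - self.n_obs * np.log(2.0 * np.pi) - quad)

    def prior_sampler(self, rng: np.random.Generator) -> np.ndarray:
        # N(0, Pi_p^-1): solve L^T z = eps with L the Cholesky of the precision
        eps = rng.standard_normal(self.dim)
        return np.linalg.solve(self._chol_prior.T, eps)


@dataclass(frozen=True)
class LinRegPosterior:
    """Exact conjugate posterior ``N(mean, precision^-1)`` of a LinRegModel."""

    mean: np.ndarray
    precision: np.ndarray


def linreg_posterior(model: LinRegModel) -> LinRegPosterior:
    """Exact posterior moments: precision ``Pi_p + X' Pi_e X`` and mean
    ``Pi^-1 X' Pi_e y``.
    """
    X = model.design
    precision = model.prior_precision + X.T @ model.noise_precision @ X
    c = cho_factor(precision)
    mean = cho_solve(c, X.T @ (model.noise_precision @ model.data))
    return LinRegPosterior(mean=mean, precision=precision)


def linreg_log_evidence(model: LinRegModel) -> float:
    """Closed-form log model evidence of the conjugate Gaussian model.

    Returns ``0.5 * (-ln|Pi| - M ln 2pi + ln|Pi_e| + ln|Pi_p|
    - (y - X eta)' Pi_e (y - X eta) - eta' Pi_p eta)`` with the posterior
    moments of :func:`linreg_posterior`.  Deterministic; no sampling.
    """
    post = linreg_posterior(model)
    X, y = model.design, model.data
    r = y - X @ post.mean
    fit = r @ model.noise_precision @ r
    penalty = post.mean @ model.prior_precision @ post.mean
    return 0.5 * (
        -_logdet_spd(post.precision)
        - model.n_obs * np.log(2.0 * np.pi)
        + model._logdet_noise
        + model._logdet_prior
        - fit
        - penalty
    )


def anova_design(p: int, M: int) -> np.ndarray:
    """One-hot block design for a one-way ANOVA with ``p`` levels.

    Each level receives ``M // p`` rows; excess rows are assigned to the
    last cell.
    """
    if not 1 <= p <= M:
        raise InvalidConfigError(f"need 1 <= p <= M, got p={p}, M={M}")
    sizes = [M // p] * p
    sizes[-1] += M - sum(sizes)
    X = np.zeros((M, p))
    row = 0
    for level, size in enumerate(sizes):
        X[row : row + size, level] = 1.0
        row += size
    return X


def generate_linreg_dataset(
    p: int,
    M: int,
    prior_var: float = 16.0,
    noise_var: float = 10.0,
    seed: int | None = None,
) -> LinRegModel:
    """Draw a synthetic regression dataset from its own generative model.

    The design is the one-way-ANOVA block matrix of :func:`anova_design`;
    regression weights are drawn from the prior ``N(0, prior_var I)`` and
    the data from the likelihood ``N(X theta, noise_var I)``.  The theta
    draw consumes the RNG stream before the noise draw, so datasets are
    bit-reproducible given the seed.
    """
    X = anova_design(p, M)
    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, np.sqrt(prior_var), size=p)
    y = X @ theta + rng.normal(0.0, np.sqrt(noise_var), size=M)
    return LinRegModel(
        design=X,
        data=y,
        prior_precision=np.eye(p) / prior_var,
        noise_precision=np.eye(M) / noise_var,
        name=f"linreg_p{p}_M{M}",
        seed=seed,
    )


def save_linreg(model: LinRegModel, directory: str | Path, stem: str = "linreg") -> None:
    """Persist a LinRegModel as two CSV files plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{stem}_design.csv", model.design, delimiter=",")
    np.savetxt(directory / f"{stem}_data.csv", model.data, delimiter=",")
    sidecar = {
        "name": model.name,
        "seed": model.seed,
        "prior_precision": model.prior_precision.tolist(),
        "noise_precision": model.noise_precision.tolist(),
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(sidecar))


def load_linreg(directory: str | Path, stem: str = "linreg") -> LinRegModel:
    """Inverse of :func:`save_linreg`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return LinRegModel(
        design=np.loadtxt(directory / f"{stem}_design.csv", delimiter=",", ndmin=2),
        data=np.loadtxt(directory / f"{stem}_data.csv", delimiter=","),
        prior_precision=np.asarray(meta["prior_precision"]),
        noise_precision=np.asarray(meta["noise_precision"]),
        name=meta.get("name", "linreg"),
        seed=meta.get("seed"),
    )
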