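"""Deterministic DCM-for-fMRI forward model and its Gaussian likelihood.

A dynamic causal model (DCM) couples neuronal state equations

    dx/dt = (A + sum_j u_j B^(j) + sum_d x_d D^(d)) x + C u

with a per-region hemodynamic (balloon/windkessel) observation model that
maps neuronal activity x to the BOLD signal: vasodilatory signal s, blood
inflow f, venous volume v and deoxyhemoglobin content q evolve as

    ds/dt = x - kappa s - gamma (f - 1)
    df/dt = s
    dv/dt = (f - v^(1/alpha)) / tau
    dq/dt = (f E(f, rho)/rho - v^(1/alpha) q / v) / tau,
    E(f, rho) = 1 - (1 - rho)^(1/f)

and the BOLD output (% signal change) is

    y = 100 V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)).

``A`` is endogenous connectivity (Hz), ``B^(j)`` the bilinear modulation by
input j, ``C`` the driving-input weights and ``D^(d)`` the nonlinear gating
of connections by regional activity.  Integration is fixed-step Euler at the
input sampling resolution (RK4 available behind a flag); both run in a
compiled kernel because the likelihood is evaluated tens of thousands of
times per model inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from powerpost.exceptions import (
    DegenerateSignalError,
    DivergenceError,
    InvalidConfigError,
    ShapeError,
)

__all__ = [
    "HemoParams",
    "DCMSpec",
    "BoldDataset",
    "DCMModel",
    "integrate_dcm",
    "add_noise_at_snr",
    "dcm_log_likelihood",
    "make_fixture_models",
    "block_inputs",
]

_STATE_BOUND = 1.0e4


@dataclass(frozen=True)
class HemoParams:
    """Hemodynamic constants of the balloon/windkessel model (per region).

    Defaults are the standard prior means: signal decay kappa = 0.64 1/s,
    feedback gamma = 0.32 1/s, transit time tau = 2 s, stiffness
    alpha = 0.32, resting oxygen extraction rho = 0.32 and resting venous
    volume fraction V0 = 0.04.  The field-dependent output constants default
    to k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2 (1.5 T convention).
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    rho: float = 0.32
    V0: float = 0.04
    k1: float | None = None
    k2: float = 2.0
    k3: float | None = None

    def resolved(self) -> tuple[float, ...]:
        k1 = 7.0 * self.rho if self.k1 is None else self.k1
        k3 = 2.0 * self.rho - 0.2 if self.k3 is None else self.k3
        return (self.kappa, self.gamma, self.tau, self.alpha, self.rho, self.V0, k1, self.k2, k3)


@dataclass
class DCMSpec:
    """One DCM: connectivity, inputs and acquisition parameters.

    ``A`` is [R x R] (diagonal = self-connections, negative for stability),
    ``B`` one [R x R] matrix per input, ``C`` [R x n_inputs], ``D`` one
    [R x R] matrix per region.  ``inputs`` holds the stimulus time courses
    sampled every ``input_dt`` seconds and must cover the acquisition
    window ``n_scans * TR``.
    """

    name: str
    A: np.ndarray
    B: np.ndarray  # (n_inputs, R, R)
    C: np.ndarray  # (R, n_inputs)
    D: np.ndarray  # (R, R, R)
    inputs: np.ndarray  # (n_timesteps, n_inputs)
    TR: float = 2.0
    n_scans: int = 720
    input_dt: float = 0.5
    hemo: HemoParams = field(default_factory=HemoParams)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        R = self.A.shape[0]
        n_inputs = self.C.shape[1] if self.C.ndim == 2 else 0
        if self.A.shape != (R, R):
            raise ShapeError("A must be square")
        if self.B.shape != (n_inputs, R, R):
            raise ShapeError(f"B must have shape ({n_inputs}, {R}, {R}), got {self.B.shape}")
        if self.C.shape != (R, n_inputs):
            raise ShapeError("C must be [R x n_inputs]")
        if self.D.shape != (R, R, R):
            raise ShapeError(f"D must have shape ({R}, {R}, {R}), got {self.D.shape}")
        if self.inputs.shape[1] != n_inputs:
            raise ShapeError("inputs must have one column per driving input")
        if self.inputs.shape[0] * self.input_dt < self.n_scans * self.TR - self.TR:
            raise ShapeError("inputs do not cover the acquisition window")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "inputs": self.inputs.tolist(),
            "TR": self.TR,
            "n_scans": self.n_scans,
            "input_dt": self.input_dt,
            "hemo": {
                k: getattr(self.hemo, k)
                for k in ("kappa", "gamma", "tau", "alpha", "rho", "V0", "k1", "k2", "k3")
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMSpec":
        d = dict(d)
        hemo = HemoParams(**d.pop("hemo", {}))
        return cls(hemo=hemo, **{k: (np.asarray(v) if k in "ABCD" or k == "inputs" else v) for k, v in d.items()})

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "DCMSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class BoldDataset:
    """Noiseless and noise-corrupted BOLD time series (% signal change).

    ``snr`` is the per-region ratio of signal standard deviation to noise
    standard deviation used to scale the added Gaussian noise.
    """

    signal: np.ndarray
    observed: np.ndarray
    noise_sd: np.ndarray
    snr: float
    seed: int | None = None

    def to_csv(self, path: str | Path, region_names: list[str] | None = None) -> None:
        import pandas as pd

        R = self.observed.shape[1]
        names = region_names or [f"region_{r + 1}" for r in range(R)]
        pd.DataFrame(self.observed, columns=names).to_csv(path, index=False)


@njit(cache=True, fastmath=True)
def _deriv(x, s, f, v, q, A, B, C, D, ut, kappa, gamma, tau, alpha, rho,
           dx, ds, df, dv, dq):  # pragma: no cover - compiled
    R = A.shape[0]
    nI = C.shape[1]
    for r in range(R):
        acc = 0.0
        for c in range(R):
            a_rc = A[r, c]
            for j in range(nI):
                a_rc += ut[j] * B[j, r, c]
            for d in range(R):
                a_rc += x[d] * D[d, r, c]
            acc += a_rc * x[c]
        for j in range(nI):
            acc += C[r, j] * ut[j]
        dx[r] = acc
        ds[r] = x[r] - kappa * s[r] - gamma * (f[r] - 1.0)
        df[r] = s[r]
        fv = v[r] ** (1.0 / alpha)
        dv[r] = (f[r] - fv) / tau
        E = 1.0 - (1.0 - rho) ** (1.0 / f[r])
        dq[r] = (f[r] * E / rho - fv * q[r] / v[r]) / tau


@njit(cache=True, fastmath=True)
def _simulate(A, B, C, D, u, dt, input_ratio, scan_steps,
              kappa, gamma, tau, alpha, rho, V0, k1, k2, k3,
              bound, use_rk4):  # pragma: no cover - compiled
    R = A.shape[0]
    nI = C.shape[1]
    n_scans = scan_steps.shape[0]
    n_u = u.shape[0]
    bold = np.zeros((n_scans, R))

    x = np.zeros(R)
    s = np.zeros(R)
    f = np.ones(R)
    v = np.ones(R)
    q = np.ones(R)
    dx = np.zeros(R); ds = np.zeros(R); df = np.zeros(R)
    dv = np.zeros(R); dq = np.zeros(R)
    # RK4 workspace
    x2 = np.zeros(R); s2 = np.zeros(R); f2 = np.zeros(R)
    v2 = np.zeros(R); q2 = np.zeros(R)
    kx = np.zeros(R); ks = np.zeros(R); kf = np.zeros(R)
    kv = np.zeros(R); kq = np.zeros(R)

    inv_alpha = 1.0 / alpha
    ln1mrho = np.log(1.0 - rho)
    inv_tau = 1.0 / tau

    n_steps = scan_steps[n_scans - 1] + 1
    ptr = 0
    for t in range(n_steps):
        if ptr < n_scans and t == scan_steps[ptr]:
            for r in range(R):
                bold[ptr, r] = 100.0 * V0 * (
                    k1 * (1.0 - q[r]) + k2 * (1.0 - q[r] / v[r]) + k3 * (1.0 - v[r])
                )
            ptr += 1
        iu = int(t * input_ratio)
        if iu > n_u - 1:
            iu = n_u - 1
        ut = u[iu]
        if use_rk4:
            _deriv(x, s, f, v, q, A, B, C, D, ut, kappa, gamma, tau, alpha, rho,
                   dx, ds, df, dv, dq)
            for r in range(R):
                kx[r] = dx[r]; ks[r] = ds[r]; kf[r] = df[r]; kv[r] = dv[r]; kq[r] = dq[r]
                x2[r] = x[r] + 0.5 * dt * dx[r]; s2[r] = s[r] + 0.5 * dt * ds[r]
                f2[r] = f[r] + 0.5 * dt * df[r]; v2[r] = v[r] + 0.5 * dt * dv[r]
                q2[r] = q[r] + 0.5 * dt * dq[r]
            _deriv(x2, s2, f2, v2, q2, A, B, C, D, ut, kappa, gamma, tau, alpha, rho,
                   dx, ds, df, dv, dq)
            for r in range(R):
                kx[r] += 2.0 * dx[r]; ks[r] += 2.0 * ds[r]; kf[r] += 2.0 * df[r]
                kv[r] += 2.0 * dv[r]; kq[r] += 2.0 * dq[r]
                x2[r] = x[r] + 0.5 * dt * dx[r]; s2[r] = s[r] + 0.5 * dt * ds[r]
                f2[r] = f[r] + 0.5 * dt * df[r]; v2[r] = v[r] + 0.5 * dt * dv[r]
                q2[r] = q[r] + 0.5 * dt * dq[r]
            _deriv(x2, s2, f2, v2, q2, A, B, C, D, ut, kappa, gamma, tau, alpha, rho,
                   dx, ds, df, dv, dq)
            for r in range(R):
                kx[r] += 2.0 * dx[r]; ks[r] += 2.0 * ds[r]; kf[r] += 2.0 * df[r]
                kv[r] += 2.0 * dv[r]; kq[r] += 2.0 * dq[r]
                x2[r] = x[r] + dt * dx[r]; s2[r] = s[r] + dt * ds[r]
                f2[r] = f[r] + dt * df[r]; v2[r] = v[r] + dt * dv[r]
                q2[r] = q[r] + dt * dq[r]
            _deriv(x2, s2, f2, v2, q2, A, B, C, D, ut, kappa, gamma, tau, alpha, rho,
                   dx, ds, df, dv, dq)
            for r in range(R):
                x[r] += dt * (kx[r] + dx[r]) / 6.0
                s[r] += dt * (ks[r] + ds[r]) / 6.0
                f[r] += dt * (kf[r] + df[r]) / 6.0
                v[r] += dt * (kv[r] + dv[r]) / 6.0
                q[r] += dt * (kq[r] + dq[r]) / 6.0
        else:
            # fused Euler hot path: generic pow rewritten as exp/log
            for r in range(R):
                acc = 0.0
                for c in range(R):
                    a_rc = A[r, c]
                    for j in range(nI):
                        a_rc += ut[j] * B[j, r, c]
                    for d in range(R):
                        a_rc += x[d] * D[d, r, c]
                    acc += a_rc * x[c]
                for j in range(nI):
                    acc += C[r, j] * ut[j]
                dx[r] = acc
            for r in range(R):
                fr = f[r]; vr = v[r]; qr = q[r]
                fv = np.exp(inv_alpha * np.log(vr))
                E = 1.0 - np.exp(ln1mrho / fr)
                x_new = x[r] + dt * dx[r]
                s_new = s[r] + dt * (x[r] - kappa * s[r] - gamma * (fr - 1.0))
                f[r] = fr + dt * s[r]
                v[r] = vr + dt * inv_tau * (fr - fv)
                q[r] = qr + dt * inv_tau * (fr * E / rho - fv * qr / vr)
                x[r] = x_new
                s[r] = s_new
        for r in range(R):
            if not (np.isfinite(x[r]) and np.isfinite(q[r]) and np.isfinite(s[r])):
                return bold, 1
            if np.abs(x[r]) > bound:
                return bold, 1
            # hemodynamic states stay in a wide physiological band; extreme
            # neuronal drive saturates them instead of aborting the run
            if f[r] < 1e-2:
                f[r] = 1e-2
            elif f[r] > 1e3:
                f[r] = 1e3
            if v[r] < 1e-2:
                v[r] = 1e-2
            elif v[r] > 1e3:
                v[r] = 1e3
            if q[r] < 1e-4:
                q[r] = 1e-4
            elif q[r] > 1e4:
                q[r] = 1e4
            if s[r] > 1e3:
                s[r] = 1e3
            elif s[r] < -1e3:
                s[r] = -1e3
    return bold, 0


def integrate_dcm(
    spec: DCMSpec,
    A: np.ndarray | None = None,
    B: np.ndarray | None = None,
    C: np.ndarray | None = None,
    D: np.ndarray | None = None,
    dt: float | None = None,
    method: str = "euler",
    state_bound: float = _STATE_BOUND,
    hemo: HemoParams | None = None,
) -> np.ndarray:
    """Noiseless BOLD signal [n_scans x R] of a DCM.

    Connectivity defaults to the spec's own matrices; overrides allow the
    likelihood to evaluate candidate parameter values without mutating the
    spec.  Raises :class:`DivergenceError` when the neuronal state norm
    exceeds ``state_bound`` or a hemodynamic state degenerates (signals an
    unstable connectivity draw).
    """
    if method not in ("euler", "rk4"):
        raise InvalidConfigError(f"unknown integration method {method!r}")
    dt = spec.input_dt if dt is None else float(dt)
    A = spec.A if A is None else np.asarray(A, dtype=float)
    B = spec.B if B is None else np.asarray(B, dtype=float)
    C = spec.C if C is None else np.asarray(C, dtype=float)
    D = spec.D if D is None else np.asarray(D, dtype=float)
    scan_steps = np.round(np.arange(spec.n_scans) * spec.TR / dt).astype(np.int64)
    consts = (hemo or spec.hemo).resolved()
    bold, flag = _simulate(
        np.ascontiguousarray(A),
        np.ascontiguousarray(B),
        np.ascontiguousarray(C),
        np.ascontiguousarray(D),
        np.ascontiguousarray(spec.inputs),
        dt,
        dt / spec.input_dt,
        scan_steps,
        *consts,
        state_bound,
        method == "rk4",
    )
    if flag != 0:
        raise DivergenceError(f"DCM integration diverged for spec {spec.name!r}")
    return bold


def add_noise_at_snr(
    signal: np.ndarray, snr: float, seed: int | None = None
) -> BoldDataset:
    """Corrupt a noiseless BOLD signal with iid Gaussian noise at a given SNR.

    Per region, the noise standard deviation is ``SD(signal) / snr``.
    """
    if snr <= 0:
        raise InvalidConfigError("snr must be positive")
    signal = np.asarray(signal, dtype=float)
    sd = signal.std(axis=0, ddof=0)
    if np.any(sd == 0.0):
        raise DegenerateSignalError("a region has zero signal variance; SNR undefined")
    noise_sd = sd / snr
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.shape) * noise_sd
    return BoldDataset(
        signal=signal, observed=signal + noise, noise_sd=noise_sd, snr=snr, seed=seed
    )


def dcm_log_likelihood(
    spec: DCMSpec,
    params: np.ndarray,
    observed: np.ndarray,
    model: "DCMModel | None" = None,
) -> float:
    """Gaussian log-likelihood of observed BOLD under a parameter vector.

    ``params`` follows the layout of :class:`DCMModel` built on ``spec``
    (connectivity parameters followed by per-region noise log-precisions).
    Divergent integrations return ``-inf`` so tempered samplers simply
    reject, rather than raising inside a chain.
    """
    model = model or DCMModel(spec, observed)
    return model.log_likelihood(params)


class DCMModel:
    """A DCM plus observed data, exposing the generic Bayesian-model surface.

    Free parameters are, in order: the R self-connection parameters
    (``A_rr = -0.5 exp(a_r)``, always negative for stability), the free
    off-diagonal entries of A, the free entries of each B and of C and each
    D (free = nonzero in the spec's matrices), and finally R per-region
    noise log-precisions.  Priors are Gaussian: N(0, 1/16) on self,
    off-diagonal and modulatory parameters, N(0, 1) on driving-input
    weights and N(ln 10, 1) on the noise log-precisions.
    """

    #: prior variances by parameter block
    PRIOR_VAR = {"self": 1.0 / 16.0, "a": 1.0 / 16.0, "b": 1.0 / 16.0,
                 "c": 1.0, "d": 1.0 / 16.0, "log_lambda": 1.0}
    PRIOR_MEAN_LOG_LAMBDA = np.log(10.0)

    def __init__(
        self,
        spec: DCMSpec,
        observed: np.ndarray,
        name: str | None = None,
        method: str = "euler",
    ) -> None:
        observed = np.asarray(observed, dtype=float)
        if observed.shape != (spec.n_scans, spec.n_regions):
            raise ShapeError(
                f"observed must be [{spec.n_scans} x {spec.n_regions}], got {observed.shape}"
            )
        self.spec = spec
        self.observed = observed
        self.name = name or spec.name
        self.method = method
        R = spec.n_regions
        self._mask_a = (spec.A != 0) & ~np.eye(R, dtype=bool)
        self._mask_b = spec.B != 0
        self._mask_c = spec.C != 0
        self._mask_d = spec.D != 0
        self._n_blocks = [
            R,
            int(self._mask_a.sum()),
            int(self._mask_b.sum()),
            int(self._mask_c.sum()),
            int(self._mask_d.sum()),
            R,
        ]
        sd = []
        mean = []
        sd += [np.sqrt(self.PRIOR_VAR["self"])] * R
        sd += [np.sqrt(self.PRIOR_VAR["a"])] * self._n_blocks[1]
        sd += [np.sqrt(self.PRIOR_VAR["b"])] * self._n_blocks[2]
        sd += [np.sqrt(self.PRIOR_VAR["c"])] * self._n_blocks[3]
        sd += [np.sqrt(self.PRIOR_VAR["d"])] * self._n_blocks[4]
        sd += [np.sqrt(self.PRIOR_VAR["log_lambda"])] * R
        mean = [0.0] * (self.dim - R) + [self.PRIOR_MEAN_LOG_LAMBDA] * R
        self._prior_sd = np.array(sd)
        self._prior_mean = np.array(mean)
        self._log_prior_const = -0.5 * self.dim * np.log(2 * np.pi) - np.sum(
            np.log(self._prior_sd)
        )
        # per-region residual sums of squares keyed by the connectivity
        # sub-vector; lets noise-precision updates skip the ODE integration
        self._rss_cache: dict[bytes, np.ndarray | None] = {}
        self._rss_cache_max = 128

    @property
    def dim(self) -> int:
        return sum(self._n_blocks)

    def unpack(self, theta: np.ndarray):
        """Parameter vector -> (A, B, C, D, log_lambda)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            raise ShapeError(f"expected parameter vector of length {self.dim}")
        R = self.spec.n_regions
        i = 0
        a_self = theta[i : i + R]; i += R
        A = np.zeros_like(self.spec.A)
        np.fill_diagonal(A, -0.5 * np.exp(a_self))
        n = self._n_blocks[1]
        A[self._mask_a] = theta[i : i + n]; i += n
        B = np.zeros_like(self.spec.B)
        n = self._n_blocks[2]
        B[self._mask_b] = theta[i : i + n]; i += n
        C = np.zeros_like(self.spec.C)
        n = self._n_blocks[3]
        C[self._mask_c] = theta[i : i + n]; i += n
        D = np.zeros_like(self.spec.D)
        n = self._n_blocks[4]
        D[self._mask_d] = theta[i : i + n]; i += n
        log_lambda = theta[i : i + R]
        return A, B, C, D, log_lambda

    def true_params(self, noise_sd: np.ndarray) -> np.ndarray:
        """Generative parameter vector: spec matrices + given noise SDs."""
        R = self.spec.n_regions
        diag = np.diag(self.spec.A)
        if np.any(diag >= 0):
            raise InvalidConfigError("spec self-connections must be negative")
        parts = [
            np.log(-diag / 0.5),
            self.spec.A[self._mask_a],
            self.spec.B[self._mask_b],
            self.spec.C[self._mask_c],
            self.spec.D[self._mask_d],
            np.log(1.0 / np.asarray(noise_sd, dtype=float) ** 2),
        ]
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def log_prior(self, theta: np.ndarray) -> float:
        z = (np.asarray(theta, dtype=float) - self._prior_mean) / self._prior_sd
        return float(self._log_prior_const - 0.5 * z @ z)

    def prior_sampler(self, rng: np.random.Generator) -> np.ndarray:
        return self._prior_mean + self._prior_sd * rng.standard_normal(self.dim)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Noiseless BOLD at a parameter vector (raises on divergence)."""
        A, B, C, D, _ = self.unpack(theta)
        return integrate_dcm(self.spec, A=A, B=B, C=C, D=D, method=self.method)

    def _rss(self, theta: np.ndarray) -> np.ndarray | None:
        """Per-region residual sum of squares at theta's connectivity part.

        Returns None when the integration diverges.  Cached because the
        noise log-precisions (the trailing R coordinates) do not enter it.
        """
        theta = np.asarray(theta, dtype=float)
        key = theta[: -self.spec.n_regions].tobytes()
        if key in self._rss_cache:
            # LRU touch: long-lived states must outlive proposal churn
            rss = self._rss_cache.pop(key)
            self._rss_cache[key] = rss
            return rss
        A, B, C, D, _ = self.unpack(theta)
        try:
            pred = integrate_dcm(self.spec, A=A, B=B, C=C, D=D, method=self.method)
            rss = np.sum((self.observed - pred) ** 2, axis=0)
            if not np.all(np.isfinite(rss)):
                rss = None
        except DivergenceError:
            rss = None
        if len(self._rss_cache) >= self._rss_cache_max:
            self._rss_cache.pop(next(iter(self._rss_cache)))
        self._rss_cache[key] = rss
        return rss

    def log_likelihood(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        rss = self._rss(theta)
        if rss is None:
            return -np.inf
        log_lambda = theta[-self.spec.n_regions :]
        n = self.spec.n_scans
        ll = 0.5 * np.sum(
            n * (log_lambda - np.log(2 * np.pi)) - np.exp(log_lambda) * rss
        )
        return float(ll) if np.isfinite(ll) else -np.inf

    def gibbs_step(
        self, theta: np.ndarray, beta: float, rng: np.random.Generator, n_iters: int = 2
    ) -> tuple[np.ndarray, float, float]:
        """Metropolis-within-Gibbs refresh of the noise log-precisions.

        Conditional on the connectivity parameters the residuals are fixed,
        so each region's tempered conditional
        ``beta (n/2 ln lambda - lambda RSS/2) + ln N(ln lambda; mu, 1)``
        is a cheap scalar density; a few Metropolis iterations per region
        decorrelate the log-likelihood without any ODE work.  Returns the
        updated state with its log-likelihood and log-prior.
        """
        theta = np.asarray(theta, dtype=float).copy()
        R = self.spec.n_regions
        rss = self._rss(theta)
        if rss is None:
            return theta, -np.inf, self.log_prior(theta)
        n = self.spec.n_scans
        mu = self.PRIOR_MEAN_LOG_LAMBDA
        x = theta[-R:]
        step = 2.4 / np.sqrt(1.0 + 0.5 * beta * n)
        for _ in range(n_iters):
            for r in range(R):
                cur = beta * 0.5 * (n * x[r] - np.exp(x[r]) * rss[r]) - 0.5 * (x[r] - mu) ** 2
                xp = x[r] + step * rng.standard_normal()
                new = beta * 0.5 * (n * xp - np.exp(xp) * rss[r]) - 0.5 * (xp - mu) ** 2
                if new - cur >= 0 or rng.random() < np.exp(new - cur):
                    x[r] = xp
        theta[-R:] = x
        return theta, self.log_likelihood(theta), self.log_prior(theta)


def block_inputs(
    duration: float,
    input_dt: float = 0.5,
    u1_period: float = 40.0,
    u2_period: float = 120.0,
) -> np.ndarray:
    """Two boxcar stimulus time courses (off-first square waves).

    ``u1`` alternates off/on every ``u1_period / 2`` seconds, ``u2`` every
    ``u2_period / 2`` seconds, so their overlap varies across the run -
    the variation that makes bilinear and nonlinear effects identifiable.
    """
    t = np.arange(0.0, duration, input_dt)
    u1 = ((t // (u1_period / 2)) % 2 == 1).astype(float)
    u2 = ((t // (u2_period / 2)) % 2 == 1).astype(float)
    return np.column_stack([u1, u2])


def make_fixture_models(
    TR: float = 2.0, n_scans: int = 720, input_dt: float = 0.5
) -> list[DCMSpec]:
    """The five synthetic 3-region, 2-input DCMs used for model recovery.

    All models share the backbone u1 -> x1, u2 -> x2 and the forward
    connections x1 -> x3, x2 -> x3, and differ in how the response of x3 is
    shaped: m1 has driving inputs only (the null hypothesis); m2 and m3
    place a bilinear modulation on one forward connection each (u2 on
    x1 -> x3, u1 on x2 -> x3); m4 lets u1 modulate the self-connection of
    x3; m5 gates x1 -> x3 nonlinearly by the activity of x2.

    The numeric connectivity values here are synthetic defaults chosen in
    the typical range of fMRI effective-connectivity studies (fractions of
    1 Hz); see docs/methods.md.
    """
    R, nI = 3, 2
    duration = n_scans * TR
    inputs = block_inputs(duration, input_dt)

    def base():
        A = np.diag([-0.5, -0.5, -0.5]).astype(float)
        A[2, 0] = 0.3  # x1 -> x3
        A[2, 1] = 0.3  # x2 -> x3
        C = np.zeros((R, nI))
        C[0, 0] = 0.3  # u1 -> x1
        C[1, 1] = 0.3  # u2 -> x2
        return A, np.zeros((nI, R, R)), C, np.zeros((R, R, R))

    specs = []
    for k in range(1, 6):
        A, B, C, D = base()
        if k == 2:
            B[1, 2, 0] = 0.5  # u2 modulates x1 -> x3
        elif k == 3:
            B[0, 2, 1] = 0.5  # u1 modulates x2 -> x3
        elif k == 4:
            B[0, 2, 2] = 0.3  # u1 modulates the self-connection of x3
        elif k == 5:
            D[1, 2, 0] = 0.4  # x2 gates x1 -> x3
        specs.append(
            DCMSpec(
                name=f"m{k}",
                A=A,
                B=B,
                C=C,
                D=D,
                inputs=inputs,
                TR=TR,
                n_scans=n_scans,
                input_dt=input_dt,
            )
        )
    return specs
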