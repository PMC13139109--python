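"""Continuous-time first-order VAR (multivariate Ornstein-Uhlenbeck) model.

The latent process obeys ``dx = A (x - mu) dt + G dW`` with drift matrix
``A`` (all eigenvalues with negative real part; units 1/hour), stationary
means ``mu`` on the 0-100 response scale and diffusion covariance
``Q = G G'`` (scale^2/hour).  Observations are ``y = x + e`` with diagonal
measurement-noise variances ``R``.

Exact discretization over a gap ``dt`` gives the transition matrix
``Phi = expm(A dt)`` and innovation covariance
``Q_dt = S_inf - Phi S_inf Phi'`` where the stationary covariance
``S_inf`` solves the Lyapunov equation ``A S + S A' + Q = 0``.  Because
the discretization is exact at any gap, irregularly spaced EMA occasions
need no equal-spacing assumption.

Estimation is maximum likelihood through a Gaussian state-space (Kalman)
filter over the actual timestamps, with parametric-bootstrap uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "DriftModel",
    "FitConfig",
    "FitResult",
    "discretize",
    "stationary_cov",
    "loglik",
    "fit_ctvar",
    "simulate_ctvar",
    "UnstableModelError",
]

_STAB_EPS = 1e-9


class UnstableModelError(ValueError):
    """Drift matrix has an eigenvalue with non-negative real part."""


@dataclass
class DriftModel:
    names: tuple[str, ...]
    A: np.ndarray
    mu: np.ndarray
    Q: np.ndarray
    R: np.ndarray  # diagonal measurement-noise variances, length p

    def __post_init__(self) -> None:
        p = len(self.names)
        self.A = np.asarray(self.A, dtype=float).reshape(p, p)
        self.mu = np.asarray(self.mu, dtype=float).reshape(p)
        self.Q = np.asarray(self.Q, dtype=float).reshape(p, p)
        self.R = np.asarray(self.R, dtype=float).reshape(p)
        if not np.allclose(self.Q, self.Q.T, atol=1e-8):
            raise ValueError("Q must be symmetric")
        if np.any(self.R < 0):
            raise ValueError("measurement-noise variances must be non-negative")

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def stable(self) -> bool:
        return bool(np.max(np.real(np.linalg.eigvals(self.A))) < -_STAB_EPS)

    def require_stable(self) -> None:
        if not self.stable:
            raise UnstableModelError(
                f"drift matrix has max eigenvalue real part "
                f"{np.max(np.real(np.linalg.eigvals(self.A))):.3g} >= 0"
            )

    def stationary_cov(self) -> np.ndarray:
        return stationary_cov(self.A, self.Q)

    def permuted(self, order: list[int]) -> "DriftModel":
        idx = np.asarray(order)
        return DriftModel(
            names=tuple(self.names[i] for i in order),
            A=self.A[np.ix_(idx, idx)],
            mu=self.mu[idx],
            Q=self.Q[np.ix_(idx, idx)],
            R=self.R[idx],
        )


def stationary_cov(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve ``A S + S A' + Q = 0`` for the stationary covariance S."""
    S = linalg.solve_continuous_lyapunov(A, -Q)
    return 0.5 * (S + S.T)


def discretize(model: DriftModel, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretization: ``Phi = expm(A dt)``, ``Q_dt = S - Phi S Phi'``."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    model.require_stable()
    Phi = linalg.expm(model.A * dt)
    S = model.stationary_cov()
    Qdt = S - Phi @ S @ Phi.T
    return Phi, 0.5 * (Qdt + Qdt.T)


class _Propagator:
    """Batch evaluation of Phi(dt) and Q_dt over many gaps.

    Uses one eigendecomposition of A, so per-gap cost is a few small
    matrix products; this is what makes likelihood evaluation over
    hundreds of irregular gaps cheap.
    """

    def __init__(self, A: np.ndarray, Q: np.ndarray):
        self.A = A
        self.Q = Q
        self.w, self.V = np.linalg.eig(A)
        # defective (non-diagonalizable) drifts make V ill-conditioned;
        # fall back to per-gap expm there (closed-form fixtures hit this)
        self.diagonalizable = np.linalg.cond(self.V) < 1e8
        self.Vinv = np.linalg.inv(self.V) if self.diagonalizable else None
        self.S = stationary_cov(A, Q)

    def phi(self, dts: np.ndarray) -> np.ndarray:
        """(n, p, p) array of transition matrices."""
        dts = np.asarray(dts, dtype=float)
        if not self.diagonalizable:
            uniq, inv = np.unique(dts, return_inverse=True)
            mats = np.stack([linalg.expm(self.A * d) for d in uniq])
            return mats[inv]
        E = np.exp(np.multiply.outer(dts, self.w))  # (n, p)
        return np.real(np.einsum("ij,nj,jk->nik", self.V, E, self.Vinv))

    def qdt(self, Phi: np.ndarray) -> np.ndarray:
        Qdt = self.S[None] - np.einsum("nij,jk,nlk->nil", Phi, self.S, Phi)
        return 0.5 * (Qdt + np.transpose(Qdt, (0, 2, 1)))


@dataclass
class FitConfig:
    """Settings for :func:`fit_ctvar`.

    ``measurement_noise='free'`` estimates a diagonal R (the default);
    ``'zero'`` fixes R = 0 so the latent state is treated as observed,
    which also unlocks a much faster complete-data likelihood when the
    series has no missing values.
    """

    min_occasions: int = 30
    bootstrap: int = 0
    measurement_noise: str = "free"  # 'free' | 'zero'
    maxiter: int = 400
    gtol: float = 1e-6
    stability_margin: float = 1e-4

    def __post_init__(self) -> None:
        if self.measurement_noise not in ("free", "zero"):
            raise ValueError("measurement_noise must be 'free' or 'zero'")


@dataclass
class FitResult:
    model: DriftModel
    loglik: float
    converged: bool
    n_occasions: int
    replicates: list[np.ndarray] = field(default_factory=list)  # bootstrap drift matrices
    message: str = ""


# ---------------------------------------------------------------------------
# likelihood


def _as_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        return series
    return series.data  # EMASeries / CompositeSeries


def loglik(model: DriftModel, series) -> float:
    """Exact Gaussian state-space log-likelihood over the actual timestamps.

    Missing components at an occasion are marginalized out by the filter;
    a fully missing occasion therefore contributes nothing.
    """
    df = _as_frame(series)[list(model.names)]
    t = np.asarray(df.index, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two occasions")
    model.require_stable()
    Y = df.to_numpy(dtype=float)
    return _kalman_loglik(model.A, model.mu, model.Q, model.R, t, Y)


def _kalman_loglik(A, mu, Q, R, t, Y) -> float:
    p = len(mu)
    prop = _Propagator(A, Q)
    Phis = prop.phi(np.diff(t))
    Qdts = prop.qdt(Phis)
    S0 = prop.S
    if not np.all(np.isfinite(S0)):
        raise ValueError("degenerate stationary covariance")
    x = mu.copy()
    P = S0
    ll = 0.0
    for k in range(len(t)):
        if k > 0:
            Phi = Phis[k - 1]
            x = mu + Phi @ (x - mu)
            P = Phi @ P @ Phi.T + Qdts[k - 1]
        obs = ~np.isnan(Y[k])
        if not obs.any():
            continue
        yk = Y[k, obs]
        Pm = P[np.ix_(obs, obs)]
        Sk = Pm + np.diag(R[obs])
        try:
            L = np.linalg.cholesky(Sk + 1e-12 * np.eye(obs.sum()))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"degenerate innovation covariance at occasion {k} "
                f"(diag={np.diag(Sk)})"
            ) from exc
        innov = yk - x[obs]
        z = linalg.solve_triangular(L, innov, lower=True)
        ll += -0.5 * (obs.sum() * np.log(2 * np.pi)) - np.log(np.diag(L)).sum() - 0.5 * z @ z
        K = P[:, obs] @ np.linalg.inv(Sk)
        x = x + K @ innov
        P = P - K @ P[obs, :]
        P = 0.5 * (P + P.T)
    return float(ll)


def _complete_loglik(A, mu, Q, t, Y) -> float:
    """Fast path: R = 0 and no missing values -> product of transition
    densities plus the stationary density of the first occasion."""
    prop = _Propagator(A, Q)
    S0 = prop.S
    n, p = Y.shape
    D = Y - mu
    Phis = prop.phi(np.diff(t))
    Qdts = prop.qdt(Phis)
    resid = D[1:] - np.einsum("nij,nj->ni", Phis, D[:-1])
    try:
        Ls = np.linalg.cholesky(Qdts + 1e-12 * np.eye(p))
        L0 = np.linalg.cholesky(S0 + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        return -np.inf
    z = np.linalg.solve(Ls, resid[:, :, None])[..., 0]
    logdets = 2.0 * np.log(np.diagonal(Ls, axis1=1, axis2=2)).sum(axis=1)
    ll = -0.5 * ((n - 1) * p * np.log(2 * np.pi) + logdets.sum() + (z ** 2).sum())
    z0 = linalg.solve_triangular(L0, D[0], lower=True)
    ll += -0.5 * (p * np.log(2 * np.pi)) - np.log(np.diag(L0)).sum() - 0.5 * z0 @ z0
    return float(ll)


# ---------------------------------------------------------------------------
# fitting


def _pack(A, mu, Lq_log, logR, est_R):
    parts = [A.ravel(), mu, Lq_log]
    if est_R:
        parts.append(logR)
    return np.concatenate(parts)


def _tril_to_Q(theta_q, p):
    L = np.zeros((p, p))
    idx = np.tril_indices(p)
    L[idx] = theta_q
    L[np.diag_indices(p)] = np.exp(np.diag(L))
    return L @ L.T


def _Q_to_tril(Q, p):
    L = np.linalg.cholesky(Q + 1e-10 * np.eye(p))
    Llog = L.copy()
    Llog[np.diag_indices(p)] = np.log(np.diag(L))
    return Llog[np.tril_indices(p)]


def _unpack(theta, p, est_R):
    k = 0
    A = theta[k:k + p * p].reshape(p, p); k += p * p
    mu = theta[k:k + p]; k += p
    nq = p * (p + 1) // 2
    Q = _tril_to_Q(theta[k:k + nq], p); k += nq
    R = np.exp(theta[k:k + p]) if est_R else np.zeros(p)
    return A, mu, Q, R


def _initial_params(t, Y, est_R, rng=None):
    """Start values: drift from a matrix-log of a lag regression on
    near-median gaps; Q from the Lyapunov identity at the sample
    covariance; falls back to a diagonal drift of -1/hour."""
    n, p = Y.shape
    dts = np.diff(t)
    med = np.median(dts)
    use = dts <= 1.5 * med
    X0 = Y[:-1][use] - Y.mean(0)
    X1 = Y[1:][use] - Y.mean(0)
    A0 = -np.eye(p)
    if X0.shape[0] > 5 * p:
        Phi_hat, *_ = np.linalg.lstsq(X0, X1, rcond=None)
        Phi_hat = Phi_hat.T
        try:
            cand = np.real(linalg.logm(Phi_hat)) / np.mean(dts[use])
            if np.max(np.real(np.linalg.eigvals(cand))) < -1e-3:
                A0 = cand
        except Exception:
            pass
    S = np.cov(Y.T) if p > 1 else np.atleast_2d(np.var(Y))
    S = S + 1e-3 * np.eye(p)
    Q0 = -(A0 @ S + S @ A0.T)
    if np.min(np.linalg.eigvalsh(0.5 * (Q0 + Q0.T))) <= 1e-6:
        Q0 = 2.0 * np.diag(np.diag(S))
    mu0 = Y.mean(0) if not np.isnan(Y).any() else np.nanmean(Y, axis=0)
    logR0 = np.full(p, np.log(0.05))  # on the standardized scale
    return A0, mu0, 0.5 * (Q0 + Q0.T), logR0


def fit_ctvar(series, config: FitConfig | None = None, seed: int | None = None) -> FitResult:
    """Maximum-likelihood CT-VAR fit with optional parametric bootstrap.

    The data are standardized internally (per node) for optimizer
    conditioning and the estimates mapped back, so the fit is equivariant
    to affine rescaling of the inputs.  Stability is enforced by
    penalizing drift iterates whose leading eigenvalue real part exceeds
    ``-config.stability_margin``.  Non-convergence is flagged on the
    result, not raised.
    """
    config = config or FitConfig()
    df = _as_frame(series)
    names = tuple(df.columns)
    t = np.asarray(df.index, dtype=float)
    Y_raw = df.to_numpy(dtype=float)
    n, p = Y_raw.shape
    if n < config.min_occasions:
        raise ValueError(f"need at least {config.min_occasions} occasions, got {n}")
    sd = np.nanstd(Y_raw, axis=0, ddof=1)
    if np.any(~np.isfinite(sd)) or np.any(sd < 1e-10):
        raise ValueError("degenerate input: at least one constant (or empty) column")
    center = np.nanmean(Y_raw, axis=0)
    Y = (Y_raw - center) / sd

    est_R = config.measurement_noise == "free"
    has_nan = bool(np.isnan(Y).any())
    use_fast = (not est_R) and (not has_nan)

    margin = config.stability_margin

    def negll(theta):
        A, mu, Q, R = _unpack(theta, p, est_R)
        max_re = np.max(np.real(np.linalg.eigvals(A)))
        if max_re > -margin:
            return 1e8 * (1.0 + max_re + margin)
        try:
            if use_fast:
                ll = _complete_loglik(A, mu, Q, t, Y)
            else:
                ll = _kalman_loglik(A, mu, Q, R, t, Y)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    A0, mu0, Q0, logR0 = _initial_params(t, Y, est_R)
    theta0 = _pack(A0, mu0, _Q_to_tril(Q0, p), logR0, est_R)

    res = optimize.minimize(
        negll, theta0, method="L-BFGS-B",
        options={"maxiter": config.maxiter, "gtol": config.gtol, "maxfun": 20 * config.maxiter},
    )
    A, mu, Q, R = _unpack(res.x, p, est_R)
    # map back to the raw scale: x_raw = sd * x_std + center
    D = np.diag(sd)
    Dinv = np.diag(1.0 / sd)
    model = DriftModel(
        names=names,
        A=D @ A @ Dinv,
        mu=center + sd * mu,
        Q=D @ Q @ D,
        R=(sd ** 2) * R,
    )
    converged = bool(res.success) and model.stable
    ll = -float(res.fun)
    fit = FitResult(model=model, loglik=ll, converged=converged,
                    n_occasions=n, message=str(res.message))

    if config.bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot_cfg = FitConfig(
            min_occasions=2, bootstrap=0,
            measurement_noise=config.measurement_noise,
            maxiter=config.maxiter, gtol=config.gtol,
            stability_margin=margin,
        )
        for b in range(config.bootstrap):
            sim = simulate_ctvar(model, t, seed=int(rng.integers(2 ** 31)))
            rep = _refit_warm(sim, model, boot_cfg)
            if rep is not None:
                fit.replicates.append(rep)
    return fit


def _refit_warm(df: pd.DataFrame, start: DriftModel, config: FitConfig) -> np.ndarray | None:
    """Refit a simulated dataset warm-started at the generating estimates;
    returns the drift matrix, or None if the refit is unusable."""
    t = np.asarray(df.index, dtype=float)
    Y_raw = df.to_numpy(dtype=float)
    p = Y_raw.shape[1]
    sd = Y_raw.std(axis=0, ddof=1)
    center = Y_raw.mean(axis=0)
    if np.any(sd < 1e-10):
        return None
    Y = (Y_raw - center) / sd
    est_R = config.measurement_noise == "free"
    D = np.diag(1.0 / sd)
    Dinv = np.diag(sd)
    A0 = D @ start.A @ Dinv
    mu0 = (start.mu - center) / sd
    Q0 = D @ start.Q @ D
    R0 = np.maximum(start.R / (sd ** 2), 1e-6)
    theta0 = _pack(A0, mu0, _Q_to_tril(Q0, p), np.log(R0), est_R)
    margin = config.stability_margin
    use_fast = (not est_R) and (not np.isnan(Y).any())

    def negll(theta):
        A, mu, Q, R = _unpack(theta, p, est_R)
        max_re = np.max(np.real(np.linalg.eigvals(A)))
        if max_re > -margin:
            return 1e8 * (1.0 + max_re + margin)
        try:
            ll = (_complete_loglik(A, mu, Q, t, Y) if use_fast
                  else _kalman_loglik(A, mu, Q, R, t, Y))
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": config.maxiter, "gtol": config.gtol})
    A, *_ = _unpack(res.x, p, est_R)
    A = Dinv @ A @ D
    if np.max(np.real(np.linalg.eigvals(A))) >= 0:
        return None
    return A


# ---------------------------------------------------------------------------
# simulation


def simulate_ctvar(
    model: DriftModel,
    timestamps: np.ndarray,
    seed: int | None = None,
    inputs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact OU sampling at the given (increasing) timestamps.

    Starts from the stationary distribution and adds measurement noise R.
    ``inputs``, if given, is an (n-1, p) array of piecewise-constant
    forcing terms c applied over each gap, entering the update as
    ``A^{-1} (Phi - I) c`` (the exact response to a constant input).
    """
    model.require_stable()
    t = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    rng = np.random.default_rng(seed)
    p = model.p
    prop = _Propagator(model.A, model.Q)
    Phis = prop.phi(np.diff(t))
    Qdts = prop.qdt(Phis)
    jitter = 1e-12 * max(1.0, float(np.trace(prop.S))) * np.eye(p)
    Ls = np.linalg.cholesky(Qdts + jitter)
    L0 = np.linalg.cholesky(prop.S + jitter)
    Ainv = np.linalg.inv(model.A)
    X = np.empty((len(t), p))
    X[0] = model.mu + L0 @ rng.standard_normal(p)
    eye = np.eye(p)
    for k in range(len(t) - 1):
        x = model.mu + Phis[k] @ (X[k] - model.mu)
        if inputs is not None:
            x = x + Ainv @ (Phis[k] - eye) @ inputs[k]
        X[k + 1] = x + Ls[k] @ rng.standard_normal(p)
    if np.any(model.R > 0):
        X = X + np.sqrt(model.R) * rng.standard_normal(X.shape)
    return pd.DataFrame(X, index=t, columns=list(model.names))
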