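"""Conjugate normal inference for the ordering prior.

The model: patient outcomes on arm ``k`` are ``N(mu(k), sigma_k^2)`` with
known variances.  The active-arm means are a priori jointly normal,
``(mu(1), ..., mu(K-1)) ~ N(mu, Omega)``, induced by the consecutive-difference
parametrization ``mu(k+1) = mu(k) - delta(k)``; the control mean has an
independent normal prior.  With known variances the posterior is available in
closed form: given cumulative per-arm sample sizes ``n_j`` and cumulative
means ``Ybar_j``,

    mu_active | data ~ N(Gamma^{-1} a, Gamma^{-1}),
    Gamma = Omega^{-1} + N_j Sigma^{-1},   a = Omega^{-1} mu + Sigma^{-1} N_j Ybar_j,

where ``N_j = diag(n_j)`` and ``Sigma = diag(sigma_k^2)`` is the outcome
covariance of the active arms.  The control posterior is the univariate
conjugate normal with precision ``tau00 + n_0/sigma_0^2``.

All matrix work goes through symmetric positive-definite (Cholesky) solves;
``Gamma`` is never inverted element by element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .design import ConfigError, DesignSpec, PriorSpec

__all__ = [
    "JointPrior",
    "DataState",
    "PosteriorSummary",
    "build_joint_prior",
    "posterior_update",
    "prob_effect_positive",
]

#: relative tolerance for symmetry / positive-definiteness diagnostics
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class JointPrior:
    """Joint normal prior ``N(mu, Omega)`` over the active-arm means."""

    mu: np.ndarray
    Omega: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "Omega", np.asarray(self.Omega, dtype=float))


@dataclass(frozen=True)
class DataState:
    """Cumulative data at an analysis.

    ``nj``/``ybar`` cover the active arms (index 0 is arm 1); arms never
    enrolled carry ``nj = 0`` and their ``ybar`` entries are ignored.
    """

    nj: np.ndarray
    n0: float
    ybar: np.ndarray
    ybar0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "nj", np.asarray(self.nj, dtype=float))
        object.__setattr__(self, "ybar", np.asarray(self.ybar, dtype=float))
        if np.any(self.nj < 0) or self.n0 < 0:
            raise ConfigError("sample sizes must be nonnegative")


@dataclass(frozen=True)
class PosteriorSummary:
    """Closed-form posterior of the active-arm means and the control mean."""

    mean: np.ndarray
    cov: np.ndarray
    ctrl_mean: float
    ctrl_var: float


def build_joint_prior(prior: PriorSpec, design: DesignSpec) -> JointPrior:
    """Construct the joint prior ``N(mu, Omega)`` implied by the difference prior.

    ``mu[s] = mu0_1 - sum_{r<s} delta0[r]`` and ``Omega[s, t] = Var mu0(min(s, t))``
    with ``Var mu0(s) = 1/tau01 + sum_{r<s} 1/tau_d[r]``: consecutive
    differences accumulate variance down the ordering, and two arms share the
    variance of the earlier one.
    """
    prior.validate_for(design)
    m = design.n_active
    mu = prior.mu0_1 - np.concatenate(([0.0], np.cumsum(prior.delta0)))
    var = 1.0 / prior.tau01 + np.concatenate(
        ([0.0], np.cumsum([1.0 / t for t in prior.tau_d]))
    )
    idx = np.arange(m)
    Omega = var[np.minimum(idx[:, None], idx[None, :])]
    return JointPrior(mu=mu, Omega=Omega)


def posterior_update(
    jp: JointPrior, data: DataState, design: DesignSpec, prior: PriorSpec
) -> PosteriorSummary:
    """Exact conjugate posterior given cumulative data.

    Arms with zero accrual contribute zero data precision (their rows of the
    diagonal data term vanish), so matrix shapes are stable across stages and
    frozen arms simply keep their accumulated data.
    """
    m = design.n_active
    if data.nj.shape != (m,) or data.ybar.shape != (m,):
        raise ConfigError(
            f"data vectors must have length K-1={m}, got {data.nj.shape}"
        )
    sig2 = design.sigma_active**2
    Om_cf = cho_factor(jp.Omega, lower=True)
    Om_inv = cho_solve(Om_cf, np.eye(m))
    Gamma = Om_inv + np.diag(data.nj / sig2)
    try:
        G_cf = cho_factor(Gamma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - positive precisions
        raise np.linalg.LinAlgError(
            f"posterior precision matrix not positive definite: {exc}"
        ) from exc
    ybar = np.where(data.nj > 0, data.ybar, 0.0)
    a = Om_inv @ jp.mu + data.nj * ybar / sig2
    mean = cho_solve(G_cf, a)
    cov = cho_solve(G_cf, np.eye(m))
    cov = 0.5 * (cov + cov.T)

    I0 = data.n0 / design.sigma_ctrl**2
    ctrl_prec = prior.tau00 + I0
    ctrl_mean = (prior.mu0_ctrl * prior.tau00 + data.ybar0 * I0) / ctrl_prec
    return PosteriorSummary(
        mean=mean, cov=cov, ctrl_mean=float(ctrl_mean), ctrl_var=1.0 / ctrl_prec
    )


def prob_effect_positive(post: PosteriorSummary, k: int) -> float:
    """Posterior probability that ``theta(k) = mu(k) - mu(0) > 0``.

    ``k`` is the 1-based active-arm index.  Control and active block are
    a posteriori independent (independent priors, separate data), so the
    contrast is normal with variance ``Var mu(k) + Var mu(0)`` and

        P(theta(k) > 0 | data) = Phi((E mu(k) - E mu(0)) / sqrt(v)).
    """
    m = post.mean.shape[0]
    if not 1 <= k <= m:
        raise IndexError(f"arm index {k} out of range 1..{m}")
    i = k - 1
    v = post.cov[i, i] + post.ctrl_var
    return float(norm.cdf((post.mean[i] - post.ctrl_mean) / np.sqrt(v)))
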