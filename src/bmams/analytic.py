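"""Exact operating characteristics by stopping-path enumeration.

The decision at stage ``j`` for arm ``k`` compares the posterior probability
``P(theta(k) > 0 | data)`` with thresholds.  Because the posterior is
conjugate normal, that comparison is a linear event in the observed cumulative
means: writing ``c_i = [Gamma_j^{-1} Sigma^{-1} N_j]_{k,i}``,
``gamma = [Gamma_j^{-1} Omega^{-1} mu]_k`` and ``c_0 = I_j^0/(tau00 + I_j^0)``,

    P(theta(k) > 0 | data) < q
        <=>  S_{k,j} := sum_i c_i Ybar_j^(i) - c_0 Ybar_j^(0) < U_{k,j}(q),
    U_{k,j}(q) = -gamma + mu0_ctrl * tau00/(tau00 + I_j^0) + z_q * sqrt(v_{jk}),

with ``v_{jk}`` the sum of the posterior variances of ``mu(k)`` and ``mu(0)``.
Under true means the ``S_{k,j}`` are jointly normal, so the probability of any
joint stopping pattern is a multivariate-normal rectangle probability.

A *path assignment* gives each active arm a terminal fate (futility or
efficacy at some stage).  Each assignment implies an accrual history (arms
freeze at resolution; control accrues while any arm is active), which in turn
fixes the coefficients of every ``S_{k,j}`` involved.  Summing rectangle
probabilities over all-futility assignments gives the probability of rejecting
nothing; over all-efficacy assignments, the probability of rejecting every
hypothesis; the full set of ``(2J)^(K-1)`` assignments partitions the outcome
space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import multivariate_normal, norm

from .bayes import JointPrior, build_joint_prior
from .bounds import Thresholds
from .design import ConfigError, DesignSpec, PriorSpec, Scenario

__all__ = [
    "ArmFate",
    "AccrualHistory",
    "StatLaw",
    "CoefficientEngine",
    "enumerate_paths",
    "accrual_history",
    "stat_law",
    "joint_covariance",
    "path_probability",
    "oc_analytic",
    "AnalyticOC",
]

#: fixed seed for the randomized-QMC rectangle integrals — the integrator is
#: deterministic by construction so calibration is exactly reproducible
QUADRATURE_SEED = 20230509

#: absolute tolerance for rectangle probabilities
RECT_ABSEPS = 1e-7

#: guard on the number of enumerated assignments, (2J)^(K-1)
MAX_ASSIGNMENTS = 1296  # K=5, J=3


@dataclass(frozen=True)
class ArmFate:
    """Terminal fate of one active arm: efficacy or futility at a given stage."""

    efficacy: bool
    stage: int


PathAssignment = tuple[ArmFate, ...]


def enumerate_paths(K: int, J: int, mode: str = "all") -> list[PathAssignment]:
    """Enumerate joint stopping patterns for ``K - 1`` active arms over ``J`` stages.

    ``mode='failure'`` restricts every arm to futility (the event that no
    hypothesis is rejected decomposes into these ``J^(K-1)`` assignments);
    ``mode='success'`` to efficacy; ``mode='all'`` yields the full partition
    of ``(2J)^(K-1)`` assignments.
    """
    if K < 2 or J < 1:
        raise ConfigError(f"need K >= 2 and J >= 1, got K={K}, J={J}")
    if mode == "failure":
        opts = [ArmFate(False, j) for j in range(1, J + 1)]
    elif mode == "success":
        opts = [ArmFate(True, j) for j in range(1, J + 1)]
    elif mode == "all":
        opts = [ArmFate(e, j) for j in range(1, J + 1) for e in (False, True)]
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    if len(opts) ** (K - 1) > MAX_ASSIGNMENTS:
        raise ConfigError(
            f"{len(opts) ** (K - 1)} assignments exceed the supported limit "
            f"{MAX_ASSIGNMENTS} (K <= 5, J <= 3)"
        )
    return [tuple(p) for p in itertools.product(opts, repeat=K - 1)]


@dataclass(frozen=True)
class AccrualHistory:
    """Cumulative sample sizes implied by a path assignment.

    ``n_active[j-1, i]`` is the cumulative count of active arm ``i+1`` at
    stage ``j`` (frozen after the arm resolves); ``n_ctrl[j-1]`` the control
    count (control accrues while at least one arm is active).
    """

    n_active: np.ndarray
    n_ctrl: np.ndarray
    resolve_stages: tuple[int, ...]

    def at(self, j: int) -> tuple[np.ndarray, float]:
        return self.n_active[j - 1], float(self.n_ctrl[j - 1])

    @property
    def last_stage(self) -> int:
        return max(self.resolve_stages)

    @property
    def total(self) -> float:
        """Total enrolment at trial termination."""
        last = self.last_stage
        return float(self.n_active[last - 1].sum() + self.n_ctrl[last - 1])


def accrual_history(assignment: PathAssignment, design: DesignSpec) -> AccrualHistory:
    resolve = tuple(f.stage for f in assignment)
    if any(not 1 <= s <= design.J for s in resolve):
        raise ConfigError(f"resolution stages {resolve} outside 1..{design.J}")
    stages = np.arange(1, design.J + 1)[:, None]
    n_active = design.n_stage * np.minimum(stages, np.asarray(resolve)[None, :])
    n_ctrl = design.n_stage * np.minimum(stages[:, 0], max(resolve))
    return AccrualHistory(
        n_active=n_active.astype(float),
        n_ctrl=n_ctrl.astype(float),
        resolve_stages=resolve,
    )


@dataclass(frozen=True)
class StageCoefficients:
    """Posterior linear-form coefficients at one accrual state."""

    C: np.ndarray          # C[k-1, i-1] = [Gamma^{-1} Sigma^{-1} N]_{k,i}
    gamma: np.ndarray      # [Gamma^{-1} Omega^{-1} mu]_k
    post_var: np.ndarray   # diag(Gamma^{-1})
    c0: float              # I0 / (tau00 + I0)
    I0: float
    ctrl_shift: float      # mu0_ctrl * tau00 / (tau00 + I0)
    ctrl_var: float        # 1 / (tau00 + I0)


class CoefficientEngine:
    """Caches :class:`StageCoefficients` per cumulative accrual state.

    The coefficients depend on the prior and the cumulative per-arm counts
    only — not on the observed data — so one engine serves every stopping
    path of a design and every simulated replicate.
    """

    def __init__(self, design: DesignSpec, prior: PriorSpec, jp: JointPrior | None = None):
        self.design = design
        self.prior = prior
        self.jp = jp if jp is not None else build_joint_prior(prior, design)
        m = design.n_active
        cf = cho_factor(self.jp.Omega, lower=True)
        self._Om_inv = cho_solve(cf, np.eye(m))
        self._Om_inv_mu = self._Om_inv @ self.jp.mu
        self._sig2 = design.sigma_active**2
        self._cache: dict[tuple, StageCoefficients] = {}

    def at(self, nj, n0: float) -> StageCoefficients:
        nj = np.asarray(nj, dtype=float)
        key = (tuple(nj), float(n0))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        m = self.design.n_active
        data_prec = nj / self._sig2
        Gamma = self._Om_inv + np.diag(data_prec)
        G_cf = cho_factor(Gamma, lower=True)
        G_inv = cho_solve(G_cf, np.eye(m))
        G_inv = 0.5 * (G_inv + G_inv.T)
        C = G_inv * data_prec[None, :]
        gamma = G_inv @ self._Om_inv_mu
        I0 = float(n0) / self.design.sigma_ctrl**2
        prec0 = self.prior.tau00 + I0
        coef = StageCoefficients(
            C=C,
            gamma=gamma,
            post_var=np.diag(G_inv).copy(),
            c0=I0 / prec0,
            I0=I0,
            ctrl_shift=self.prior.mu0_ctrl * self.prior.tau00 / prec0,
            ctrl_var=1.0 / prec0,
        )
        self._cache[key] = coef
        return coef


@dataclass(frozen=True)
class StatLaw:
    """Law of the decision statistic ``S_{k,j}`` under given true means."""

    k: int
    j: int
    c: np.ndarray        # coefficients on the active-arm cumulative means
    c0: float            # coefficient on the control cumulative mean
    gamma: float
    v: float             # Var mu(k)|data + Var mu(0)|data
    mean: float
    var: float
    u_base: float        # -gamma + mu0_ctrl * tau00 / (tau00 + I0)

    def u(self, z_q: float) -> float:
        """Threshold ``U_{k,j}(q)``: the event {posterior prob < q} is {S < u(z_q)}."""
        return self.u_base + z_q * np.sqrt(self.v)


def stat_law(
    k: int,
    j: int,
    accrual: AccrualHistory,
    engine: CoefficientEngine,
    scenario: Scenario,
) -> StatLaw:
    """Coefficients, mean and variance of ``S_{k,j}`` under an accrual history.

    ``k`` is the 1-based active-arm index; the arm must still be unresolved
    before stage ``j`` under the assignment that produced ``accrual``.
    """
    design = engine.design
    nj, n0 = accrual.at(j)
    if accrual.resolve_stages[k - 1] < j:
        raise ConfigError(f"arm {k} resolved before stage {j} under this assignment")
    coef = engine.at(nj, n0)
    c = coef.C[k - 1]
    if n0 <= 0 or np.any((np.abs(c) > 1e-14) & (nj <= 0)):
        raise ConfigError(
            f"zero accrual on an arm with nonzero coefficient at stage {j}"
        )
    v = coef.post_var[k - 1] + coef.ctrl_var
    mean = float(c @ scenario.mu_active - coef.c0 * scenario.mu_ctrl)
    var = float(
        np.sum((c * design.sigma_active) ** 2 / nj)
        + (coef.c0 * design.sigma_ctrl) ** 2 / n0
    )
    return StatLaw(
        k=k,
        j=j,
        c=c,
        c0=coef.c0,
        gamma=float(coef.gamma[k - 1]),
        v=v,
        mean=mean,
        var=var,
        u_base=float(-coef.gamma[k - 1] + coef.ctrl_shift),
    )


def joint_covariance(laws: list[StatLaw], accrual: AccrualHistory, design: DesignSpec) -> np.ndarray:
    """Covariance of the decision statistics listed in ``laws``.

    For ``j <= j*``: ``Cov(Ybar_j^(i), Ybar_{j*}^(i)) = sigma_i^2 / n_{j*}(i)``
    under the accrual history (for an arm still accruing this is the classic
    ``t_j``-scaled group-sequential covariance; a frozen arm's cumulative mean
    simply stops changing), and likewise for control.  The diagonal equals
    each law's marginal variance.
    """
    d = len(laws)
    cov = np.empty((d, d))
    sig2 = design.sigma_active**2
    sig2_0 = design.sigma_ctrl**2
    for a in range(d):
        for b in range(a, d):
            la, lb = laws[a], laws[b]
            j_late = max(la.j, lb.j)
            nj, n0 = accrual.at(j_late)
            val = np.sum(la.c * lb.c * sig2 / nj) + la.c0 * lb.c0 * sig2_0 / n0
            cov[a, b] = cov[b, a] = val
    # symmetric by construction; PSD up to roundoff because it is the
    # covariance of linear functionals of one Gaussian field
    mineig = np.linalg.eigvalsh(cov).min()
    if mineig < -1e-8 * max(1.0, np.abs(np.diag(cov)).max()):
        raise np.linalg.LinAlgError(
            f"joint covariance not positive semidefinite (min eig {mineig:.3e})"
        )
    return cov


def _rect_prob(mean, cov, lower, upper) -> float:
    """P(lower <= X < upper) for X ~ N(mean, cov), to ~1e-7 absolute."""
    mean = np.asarray(mean, dtype=float)
    d = mean.shape[0]
    if d == 1:
        s = np.sqrt(cov[0, 0])
        p = norm.cdf((upper[0] - mean[0]) / s) - norm.cdf((lower[0] - mean[0]) / s)
    else:
        p = multivariate_normal.cdf(
            np.asarray(upper, dtype=float),
            mean=mean,
            cov=np.asarray(cov, dtype=float),
            lower_limit=np.asarray(lower, dtype=float),
            maxpts=1_000_000,
            abseps=RECT_ABSEPS,
            releps=0.0,
            rng=np.random.default_rng(QUADRATURE_SEED),
        )
    return float(min(max(p, 0.0), 1.0))


def path_probability(
    assignment: PathAssignment,
    design: DesignSpec,
    th: Thresholds,
    scenario: Scenario,
    engine: CoefficientEngine,
) -> float:
    """Probability that the trial realizes exactly this joint stopping pattern."""
    accrual = accrual_history(assignment, design)
    z_eta, z_eps = th.z_eta, th.z_eps
    laws: list[StatLaw] = []
    lower: list[float] = []
    upper: list[float] = []
    for idx, fate in enumerate(assignment):
        k = idx + 1
        for j in range(1, fate.stage):
            law = stat_law(k, j, accrual, engine, scenario)
            laws.append(law)
            lower.append(law.u(z_eps[j - 1]))
            upper.append(law.u(z_eta[j - 1]))
        law = stat_law(k, fate.stage, accrual, engine, scenario)
        laws.append(law)
        if fate.efficacy:
            lower.append(law.u(z_eta[fate.stage - 1]))
            upper.append(np.inf)
        else:
            lower.append(-np.inf)
            upper.append(law.u(z_eps[fate.stage - 1]))
    cov = joint_covariance(laws, accrual, design)
    means = np.array([law.mean for law in laws])
    return _rect_prob(means, cov, np.array(lower), np.array(upper))


@dataclass(frozen=True)
class AnalyticOC:
    """Analytic rejection probabilities for one scenario."""

    p_reject_any: float
    p_reject_all: float
    p_reject_arm: tuple[float, ...] | None = None
    path_probs: dict | None = None


def oc_analytic(
    design: DesignSpec,
    prior: PriorSpec,
    th: Thresholds,
    scenario: Scenario,
    *,
    per_arm: bool = False,
    path_dump: bool = False,
) -> AnalyticOC:
    """FWER-type and reject-all probabilities via path enumeration.

    ``p_reject_any = 1 - sum over all-futility assignments`` of the rectangle
    probability of the assignment's inequality system; ``p_reject_all`` sums
    the all-efficacy assignments.  With ``per_arm=True`` the full partition is
    enumerated and per-hypothesis rejection probabilities are accumulated from
    the assignments in which the arm stops for efficacy.
    """
    if th.J != design.J:
        raise ConfigError(f"thresholds have J={th.J}, design has J={design.J}")
    if len(scenario.true_means) != design.K:
        raise ConfigError(
            f"scenario has {len(scenario.true_means)} means, expected K={design.K}"
        )
    engine = CoefficientEngine(design, prior)
    dump: dict = {}

    def total(mode: str) -> float:
        s = 0.0
        for a in enumerate_paths(design.K, design.J, mode):
            p = path_probability(a, design, th, scenario, engine)
            if path_dump:
                dump[a] = p
            s += p
        return s

    p_fail = total("failure")
    p_all = total("success")
    p_arm = None
    if per_arm:
        m = design.n_active
        acc = np.zeros(m)
        for a in enumerate_paths(design.K, design.J, "all"):
            p = path_probability(a, design, th, scenario, engine)
            if path_dump:
                dump[a] = p
            for i, fate in enumerate(a):
                if fate.efficacy:
                    acc[i] += p
        p_arm = tuple(float(x) for x in acc)
    return AnalyticOC(
        p_reject_any=1.0 - p_fail,
        p_reject_all=p_all,
        p_reject_arm=p_arm,
        path_probs=dump if path_dump else None,
    )
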