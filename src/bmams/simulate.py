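"""Monte-Carlo simulation of complete multi-arm multi-stage trials.

Each replicate accrues ``n_stage`` patients per still-active arm (and control)
per stage, updates the exact conjugate posterior on the cumulative data, and
applies the stagewise decision rule.  Arms that stop — for efficacy or
futility — freeze accrual but their accumulated data stay in every later
posterior update; control accrues while at least one active arm does.  An
efficacy stop does not end the trial: the remaining arms continue, so a
decision is reached on every hypothesis.

The frequentist comparator (:func:`simulate_freq_mams`) runs the same trial
mechanics but decides with two-sample z-statistics against explicit z-scale
bounds.  In the vague-prior limit the Bayesian posterior probability equals
the normal CDF of that z-statistic, so the two designs make identical
decisions on shared data — a useful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .analytic import CoefficientEngine
from .bounds import Action, Thresholds
from .design import ConfigError, DesignSpec, PriorSpec, Scenario

__all__ = [
    "ArmStatus",
    "TrialResult",
    "OCSummary",
    "simulate_trial",
    "operating_characteristics",
    "simulate_freq_mams",
    "trials_to_dataframe",
]


@dataclass(frozen=True)
class ArmStatus:
    """Final status of one active arm."""

    arm: int
    rejected: bool          # efficacy claim (null hypothesis rejected)
    stage: int              # stage at which the arm resolved
    enrolled: int


@dataclass(frozen=True)
class TrialResult:
    """One simulated trial: per-arm outcomes, enrolment and the audit trail."""

    arms: tuple[ArmStatus, ...]
    n_ctrl: int
    total_ss: int
    probs: tuple[tuple[float, ...], ...]  # probs[j-1][k-1]; nan once resolved

    @property
    def any_rejected(self) -> bool:
        return any(a.rejected for a in self.arms)

    @property
    def all_rejected(self) -> bool:
        return all(a.rejected for a in self.arms)


@dataclass(frozen=True)
class OCSummary:
    """Monte-Carlo operating characteristics."""

    fwer_any: float
    power_all: float
    power_k: tuple[float, ...]
    ess: float
    max_ss: int
    nsim: int
    se_any: float
    se_all: float
    se_ess: float

    def to_dict(self) -> dict:
        return {
            "fwer_any": self.fwer_any,
            "power_all": self.power_all,
            **{f"power_{k + 1}": p for k, p in enumerate(self.power_k)},
            "ess": self.ess,
            "max_ss": self.max_ss,
            "nsim": self.nsim,
            "se_any": self.se_any,
            "se_all": self.se_all,
            "se_ess": self.se_ess,
        }


def _posterior_probs(engine: CoefficientEngine, nj, n0, ybar, ybar0, active):
    """Posterior probabilities P(theta(k) > 0 | data) for the arms in ``active``.

    Uses the cached linear form of the conjugate posterior: identical to
    running ``posterior_update`` + ``prob_effect_positive`` but one
    coefficient solve per accrual state instead of per replicate.
    """
    coef = engine.at(nj, n0)
    ctrl_mean = coef.ctrl_shift + coef.c0 * ybar0
    out = {}
    for k in active:
        i = k - 1
        mean_k = coef.C[i] @ ybar + coef.gamma[i]
        v = coef.post_var[i] + coef.ctrl_var
        out[k] = float(norm.cdf((mean_k - ctrl_mean) / np.sqrt(v)))
    return out


def simulate_trial(
    design: DesignSpec,
    prior: PriorSpec,
    th: Thresholds,
    scenario: Scenario,
    rng,
    engine: CoefficientEngine | None = None,
) -> TrialResult:
    """Simulate one trial; ``rng`` is a :class:`numpy.random.Generator` or seed."""
    if th.J != design.J:
        raise ConfigError(f"thresholds have J={th.J}, design has J={design.J}")
    rng = np.random.default_rng(rng)
    if engine is None:
        engine = CoefficientEngine(design, prior)
    m = design.n_active
    n = design.n_stage
    mu_act = scenario.mu_active
    sig_act = design.sigma_active
    z_eta, z_eps = th.z_eta, th.z_eps

    sums = np.zeros(m)
    counts = np.zeros(m)
    sum0 = 0.0
    n0 = 0.0
    active = set(range(1, m + 1))
    status: dict[int, ArmStatus] = {}
    audit = []

    for j in range(1, design.J + 1):
        idx = np.array(sorted(active)) - 1
        # batch accrual on active arms and control; increments enter as stage means
        sums[idx] += n * (mu_act[idx] + sig_act[idx] * rng.standard_normal(len(idx)) / np.sqrt(n))
        counts[idx] += n
        sum0 += n * (scenario.mu_ctrl + design.sigma_ctrl * rng.standard_normal() / np.sqrt(n))
        n0 += n

        ybar = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        probs = _posterior_probs(engine, counts, n0, ybar, sum0 / n0, sorted(active))
        audit.append(tuple(probs.get(k, float("nan")) for k in range(1, m + 1)))
        for k, p in probs.items():
            if p >= th.eta[j - 1]:
                status[k] = ArmStatus(arm=k, rejected=True, stage=j, enrolled=int(counts[k - 1]))
                active.discard(k)
            elif p < th.eps[j - 1]:
                status[k] = ArmStatus(arm=k, rejected=False, stage=j, enrolled=int(counts[k - 1]))
                active.discard(k)
        if not active:
            break

    arms = tuple(status[k] for k in range(1, m + 1))
    total = int(sum(a.enrolled for a in arms) + n0)
    return TrialResult(arms=arms, n_ctrl=int(n0), total_ss=total, probs=tuple(audit))


def trials_to_dataframe(results):
    """One row per simulated trial: per-arm decision, stage, and sample sizes."""
    import pandas as pd

    rows = []
    for i, res in enumerate(results):
        row = {"trial": i, "n_ctrl": res.n_ctrl, "total_ss": res.total_ss}
        for a in res.arms:
            row[f"arm{a.arm}_rejected"] = a.rejected
            row[f"arm{a.arm}_stage"] = a.stage
            row[f"arm{a.arm}_n"] = a.enrolled
        rows.append(row)
    return pd.DataFrame(rows)


def _summarize(any_rej, all_rej, per_arm, totals, max_ss) -> OCSummary:
    nsim = len(totals)
    p_any = float(np.mean(any_rej))
    p_all = float(np.mean(all_rej))
    ess = float(np.mean(totals))
    return OCSummary(
        fwer_any=p_any,
        power_all=p_all,
        power_k=tuple(float(x) for x in np.mean(per_arm, axis=0)),
        ess=ess,
        max_ss=max_ss,
        nsim=nsim,
        se_any=float(np.sqrt(p_any * (1 - p_any) / nsim)),
        se_all=float(np.sqrt(p_all * (1 - p_all) / nsim)),
        se_ess=float(np.std(totals, ddof=1) / np.sqrt(nsim)),
    )


def operating_characteristics(
    design: DesignSpec,
    prior: PriorSpec,
    th: Thresholds,
    scenario: Scenario,
    nsim: int,
    seed,
) -> OCSummary:
    """Monte-Carlo operating characteristics over ``nsim`` independent replicates.

    Replicates use independent substreams spawned from the master seed, so
    results are reproducible and any subset of replicates can be re-run
    independently.
    """
    if nsim < 1:
        raise ConfigError("nsim must be >= 1")
    engine = CoefficientEngine(design, prior)
    streams = np.random.SeedSequence(seed).spawn(nsim)
    m = design.n_active
    any_rej = np.empty(nsim, dtype=bool)
    all_rej = np.empty(nsim, dtype=bool)
    per_arm = np.empty((nsim, m), dtype=bool)
    totals = np.empty(nsim)
    for i, ss in enumerate(streams):
        res = simulate_trial(design, prior, th, scenario, np.random.default_rng(ss), engine)
        any_rej[i] = res.any_rejected
        all_rej[i] = res.all_rejected
        per_arm[i] = [a.rejected for a in res.arms]
        totals[i] = res.total_ss
    return _summarize(any_rej, all_rej, per_arm, totals, design.max_ss)


def simulate_freq_mams(
    design: DesignSpec,
    u,
    l,
    scenario: Scenario,
    nsim: int,
    seed,
) -> OCSummary:
    """Frequentist modified-MAMS comparator with explicit z-scale bounds.

    Decisions use the two-sample z-statistic
    ``Z_j^(k) = (Ybar_j^(k) - Ybar_j^(0)) / (sigma * sqrt(1/n_j^(k) + 1/n_j^(0)))``
    against upper bounds ``u_j`` (reject and stop the arm) and lower bounds
    ``l_j`` (drop), with ``u_J = l_J``; arms not crossing a bound continue
    even when another arm has already stopped for efficacy.
    """
    u = np.asarray(u, dtype=float)
    l = np.asarray(l, dtype=float)
    if u.shape != (design.J,) or l.shape != (design.J,):
        raise ConfigError("bounds must have length J")
    if abs(u[-1] - l[-1]) > 1e-12:
        raise ConfigError("final-stage bounds must satisfy u_J = l_J")
    rng_streams = np.random.SeedSequence(seed).spawn(nsim)
    m = design.n_active
    n = design.n_stage
    mu_act = scenario.mu_active
    sig_act = design.sigma_active
    any_rej = np.empty(nsim, dtype=bool)
    all_rej = np.empty(nsim, dtype=bool)
    per_arm = np.empty((nsim, m), dtype=bool)
    totals = np.empty(nsim)
    for i, ss in enumerate(rng_streams):
        rng = np.random.default_rng(ss)
        sums = np.zeros(m)
        counts = np.zeros(m)
        sum0 = 0.0
        n0 = 0.0
        active = set(range(1, m + 1))
        rejected = np.zeros(m, dtype=bool)
        enrolled = np.zeros(m)
        for j in range(1, design.J + 1):
            idx = np.array(sorted(active)) - 1
            sums[idx] += n * (mu_act[idx] + sig_act[idx] * rng.standard_normal(len(idx)) / np.sqrt(n))
            counts[idx] += n
            sum0 += n * (scenario.mu_ctrl + design.sigma_ctrl * rng.standard_normal() / np.sqrt(n))
            n0 += n
            ybar0 = sum0 / n0
            for k in sorted(active):
                ii = k - 1
                z = (sums[ii] / counts[ii] - ybar0) / (
                    np.sqrt(sig_act[ii] ** 2 / counts[ii] + design.sigma_ctrl**2 / n0)
                )
                if z >= u[j - 1]:
                    rejected[ii] = True
                    enrolled[ii] = counts[ii]
                    active.discard(k)
                elif z < l[j - 1]:
                    enrolled[ii] = counts[ii]
                    active.discard(k)
            if not active:
                break
        any_rej[i] = rejected.any()
        all_rej[i] = rejected.all()
        per_arm[i] = rejected
        totals[i] = enrolled.sum() + n0
    return _summarize(any_rej, all_rej, per_arm, totals, design.max_ss)
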