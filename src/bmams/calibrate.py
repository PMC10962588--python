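"""Calibration of the bound parameter and sample size to error/power constraints.

The search solves, over a one-parameter threshold family and the per-arm
per-stage sample size ``n``:

    P(reject at least one hypothesis | each global-null config)  <= alpha,
    P(reject all hypotheses        | each partial-null config)   <= alpha,
    P(reject all hypotheses        | alternative)                >= 1 - beta,

with every probability evaluated analytically (path enumeration + MVN
rectangle integrals).  The family parameter is gridded on the z-scale,
``z1 = Phi^{-1}(eta_1)``, with step 0.001 over ``[1.5, 3.5]`` by default.

Search strategy: the reject-all probability is monotone increasing in ``n``
(verified empirically), so the power-minimal ``n(z1)`` is found by bisection;
raising ``z1`` tightens every bound, so error feasibility at ``n(z1)`` is
monotone in ``z1`` and the constrained optimum — minimal total sample size,
ties broken by the smallest ``eta_1`` — is the smallest feasible grid point,
found by binary search with explicit boundary verification.  A full grid scan
is available for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .analytic import oc_analytic
from .bounds import Thresholds, pocock_thresholds, triangular_thresholds
from .design import ConfigError, DesignSpec, PriorSpec, Scenario

__all__ = ["CalibrationProblem", "CalibratedDesign", "InfeasibleError", "calibrate"]


class InfeasibleError(RuntimeError):
    """No grid point satisfies the constraints; carries the binding constraint."""


@dataclass(frozen=True)
class CalibrationProblem:
    """Error and power requirements for the design search."""

    alpha: float
    beta: float
    theta_alt: tuple[float, ...]
    mu_ctrl: float                       # assumed control mean for the power scenario
    global_nulls: tuple[Scenario, ...]   # constrain P(reject any) <= alpha
    partial_nulls: tuple[Scenario, ...] = ()  # constrain P(reject all) <= alpha
    family: str = "triangular"
    z_grid: tuple[float, float, float] = (1.5, 3.5, 0.001)  # lo, hi, step
    n_range: tuple[int, int] = (2, 1000)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ConfigError("alpha and beta must lie in (0, 1)")
        if not self.global_nulls:
            raise ConfigError("at least one global-null configuration is required")

    @property
    def power_scenario(self) -> Scenario:
        return Scenario.from_effects(self.mu_ctrl, self.theta_alt)


@dataclass(frozen=True)
class CalibratedDesign:
    """Outcome of the search: chosen sample size, thresholds and achieved OCs."""

    n_stage: int
    thresholds: Thresholds
    design: DesignSpec
    power: float
    p_reject_any_null: tuple[float, ...]
    p_reject_all_partial: tuple[float, ...]

    @property
    def max_ss(self) -> int:
        return self.design.max_ss


def _make_thresholds(problem: CalibrationProblem, z1: float, t) -> Thresholds:
    eta1 = float(norm.cdf(z1))
    if problem.family == "triangular":
        return triangular_thresholds(eta1, t)
    if problem.family == "pocock":
        return pocock_thresholds(eta1, float(norm.cdf(z1 / 3.0)), t)
    raise ConfigError(f"unknown bound family {problem.family!r}")


def _power(design: DesignSpec, prior: PriorSpec, th: Thresholds, problem, n: int) -> float:
    d = design.replace(n_stage=int(n))
    return oc_analytic(d, prior, th, problem.power_scenario).p_reject_all


def _min_n_for_power(design, prior, th, problem) -> int | None:
    """Smallest integer n with reject-all power >= 1 - beta (monotone bisection)."""
    lo, hi = problem.n_range
    target = 1.0 - problem.beta
    if _power(design, prior, th, problem, hi) < target:
        return None
    if _power(design, prior, th, problem, lo) >= target:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _power(design, prior, th, problem, mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def _errors_ok(design, prior, th, problem, n: int) -> tuple[bool, tuple, tuple]:
    d = design.replace(n_stage=int(n))
    anys = tuple(
        oc_analytic(d, prior, th, sc).p_reject_any for sc in problem.global_nulls
    )
    alls = tuple(
        oc_analytic(d, prior, th, sc).p_reject_all for sc in problem.partial_nulls
    )
    ok = all(p <= problem.alpha for p in anys) and all(
        p <= problem.alpha for p in alls
    )
    return ok, anys, alls


def calibrate(
    problem: CalibrationProblem,
    design_template: DesignSpec,
    prior: PriorSpec,
    *,
    full_scan: bool = False,
) -> CalibratedDesign:
    """Search the bound-parameter grid and sample size for the cheapest feasible design.

    ``design_template`` supplies K, J, t and sigma; its ``n_stage`` is ignored.
    With ``full_scan=True`` every grid point is evaluated (slow; for audits);
    otherwise binary search over the feasibility frontier is used.
    """
    lo, hi, step = problem.z_grid
    zs = np.arange(lo, hi + 0.5 * step, step)

    cache: dict[int, tuple[int | None, bool]] = {}

    def evaluate(i: int) -> tuple[int | None, bool]:
        if i in cache:
            return cache[i]
        th = _make_thresholds(problem, float(zs[i]), design_template.t)
        n = _min_n_for_power(design_template, prior, th, problem)
        feas = False
        if n is not None:
            feas, _, _ = _errors_ok(design_template, prior, th, problem, n)
        cache[i] = (n, feas)
        return cache[i]

    if full_scan:
        best = None
        for i in range(len(zs)):
            n, feas = evaluate(i)
            if feas and (best is None or n < cache[best][0]):
                best = i
        if best is None:
            raise InfeasibleError(_diagnose(evaluate, len(zs) - 1, problem))
        i_star = best
    else:
        n_hi, feas_hi = evaluate(len(zs) - 1)
        if not feas_hi:
            raise InfeasibleError(_diagnose(evaluate, len(zs) - 1, problem))
        a, b = 0, len(zs) - 1  # invariant: b feasible
        n0, feas0 = evaluate(0)
        if feas0:
            i_star = 0
        else:
            while b - a > 1:
                mid = (a + b) // 2
                _, feas = evaluate(mid)
                if feas:
                    b = mid
                else:
                    a = mid
            i_star = b

    z_star = float(zs[i_star])
    n_star = cache[i_star][0]
    th = _make_thresholds(problem, z_star, design_template.t)
    design = design_template.replace(n_stage=int(n_star))
    ok, anys, alls = _errors_ok(design_template, prior, th, problem, n_star)
    power = _power(design_template, prior, th, problem, n_star)
    if not ok or power < 1.0 - problem.beta - 1e-9:  # pragma: no cover - re-check
        raise InfeasibleError("calibrated point failed re-evaluation")
    return CalibratedDesign(
        n_stage=int(n_star),
        thresholds=th,
        design=design,
        power=power,
        p_reject_any_null=anys,
        p_reject_all_partial=alls,
    )


def _diagnose(evaluate, i: int, problem) -> str:
    n, _ = evaluate(i)
    if n is None:
        return (
            f"power {1 - problem.beta:.3f} unreachable within n <= "
            f"{problem.n_range[1]} at the strictest grid bound"
        )
    return (
        f"error constraints (alpha={problem.alpha}) unsatisfied even at the "
        f"strictest grid bound with n={n}"
    )
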