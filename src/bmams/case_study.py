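"""Bundled configurations for the 3-arm 2-stage asthma case study.

A phase-III add-on-therapy trial in adolescent symptomatic asthma compared
two doses of once-daily tiotropium against placebo on change from baseline in
peak FEV1 (common SD 340 mL), with one interim at half the total sample size
and triangular stopping bounds.  Prior means come from the preceding
phase-II dose-ranging study: control 489 mL, top dose 602 mL, no assumed
difference between doses.  Three prior variants are studied:

* ``U`` — uninformative: every precision ``1e-6``;
* ``D`` — informative prior on the dose-difference, ``tau_d = 5.9e-5``;
* ``C`` — informative prior on control, ``tau00 = 0.00039`` (prior worth
  roughly 20% extra control data).

The calibrated designs (alpha = 0.025 under the global and partial nulls at a
control mean of 489; 80% power at effects (120, 120)) use 102 (U), 96 (D) and
82 (C) patients per arm per stage with stage-1 efficacy thresholds 0.9934,
0.9927 and 0.9906.  The frequentist modified-MAMS comparator uses triangular
z-bounds (2.482, 2.34) with futility bound 0.827 at the same 102 per arm per
stage.
"""

from __future__ import annotations

import numpy as np

from .bounds import Thresholds, triangular_thresholds
from .calibrate import CalibrationProblem
from .design import DesignSpec, PriorSpec, Scenario

__all__ = [
    "SIGMA",
    "MU0_CTRL",
    "MU0_ARM1",
    "THETA_ALT",
    "design_spec",
    "prior_spec",
    "thresholds",
    "calibration_problem",
    "freq_mams_bounds",
    "variant",
]

SIGMA = 340.0
MU0_CTRL = 489.0
MU0_ARM1 = 602.0
THETA_ALT = (120.0, 120.0)
ALPHA = 0.025
BETA = 0.2

#: per-arm per-stage sample size and stage-1 efficacy threshold per variant
VARIANTS = {
    "U": {"n_stage": 102, "eta1": 0.9934, "tau00": 1e-6, "tau01": 1e-6, "tau_d": 1e-6},
    "D": {"n_stage": 96, "eta1": 0.9927, "tau00": 1e-6, "tau01": 1e-6, "tau_d": 5.9e-5},
    "C": {"n_stage": 82, "eta1": 0.9906, "tau00": 0.00039, "tau01": 1e-6, "tau_d": 1e-6},
}

#: frequentist modified-MAMS comparator: (u1, u2) upper and (l1, l2) lower z-bounds
FREQ_MAMS = {"u": (2.482, 2.34), "l": (0.827, 2.34), "n_stage": 102}


def design_spec(n_stage: int = 102) -> DesignSpec:
    return DesignSpec(K=3, J=2, t=(0.5, 1.0), n_stage=n_stage, sigma=(SIGMA,) * 3)


def prior_spec(variant_name: str = "U") -> PriorSpec:
    v = VARIANTS[variant_name]
    return PriorSpec(
        mu0_ctrl=MU0_CTRL,
        tau00=v["tau00"],
        mu0_1=MU0_ARM1,
        tau01=v["tau01"],
        delta0=(0.0,),
        tau_d=(v["tau_d"],),
    )


def thresholds(variant_name: str = "U") -> Thresholds:
    return triangular_thresholds(VARIANTS[variant_name]["eta1"], (0.5, 1.0))


def variant(variant_name: str) -> tuple[DesignSpec, PriorSpec, Thresholds]:
    """Design, prior and thresholds of one case-study variant (U, D or C)."""
    v = VARIANTS[variant_name]
    return design_spec(v["n_stage"]), prior_spec(variant_name), thresholds(variant_name)


def freq_mams_bounds() -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(FREQ_MAMS["u"]), np.asarray(FREQ_MAMS["l"])


def global_null(mu_ctrl: float = MU0_CTRL) -> Scenario:
    """All means equal to ``mu_ctrl``."""
    return Scenario.from_effects(mu_ctrl, (0.0, 0.0))


def partial_nulls(mu_ctrl: float = MU0_CTRL, theta: float = 120.0) -> tuple[Scenario, Scenario]:
    """One arm at the alternative effect, the other at zero."""
    return (
        Scenario.from_effects(mu_ctrl, (theta, 0.0)),
        Scenario.from_effects(mu_ctrl, (0.0, theta)),
    )


def calibration_problem(variant_name: str = "U") -> CalibrationProblem:
    """The case-study design search for one prior variant."""
    return CalibrationProblem(
        alpha=ALPHA,
        beta=BETA,
        theta_alt=THETA_ALT,
        mu_ctrl=MU0_CTRL,
        global_nulls=(global_null(),),
        partial_nulls=partial_nulls(),
        family="triangular",
    )
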