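"""Stagewise efficacy/futility thresholds on the posterior-probability scale.

The decision rule at stage ``j`` compares the posterior probability
``P(theta(k) > 0 | data)`` with an upper (efficacy) threshold ``eta_j`` and a
lower (futility) threshold ``eps_j``; at the final stage ``eta_J = eps_J`` so
every remaining arm resolves.  Threshold families are parametrized by a single
scalar (``eta_1``) so that calibration reduces to a one-dimensional grid
search.

The triangular family is defined on the z-scale: with ``z1 = Phi^{-1}(eta_1)``
and information fractions ``t_j``,

    z_eta_j = z1 * ((1 + t_j) / sqrt(t_j)) * (sqrt(t_1) / (1 + t_1)),
    z_eps_j = z1 * ((3 t_j - 1) / sqrt(t_j)) * (sqrt(t_1) / (1 + t_1)),

mapped back through the normal CDF.  At ``t_J = 1`` the two coincide, closing
the triangle.  For one interim at ``t_1 = 1/2`` this gives the familiar
``z_eps_1 = z1 / 3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import norm

from .design import ConfigError

__all__ = [
    "Thresholds",
    "Action",
    "StageDecision",
    "triangular_thresholds",
    "pocock_thresholds",
    "stage_decision",
]


class Action(str, Enum):
    DROP_FUTILITY = "drop_futility"
    STOP_EFFICACY = "stop_efficacy"
    CONTINUE = "continue"


@dataclass(frozen=True)
class StageDecision:
    """Per-arm action at one analysis together with the probability that produced it."""

    arm: int
    action: Action
    prob: float
    stage: int


@dataclass(frozen=True)
class Thresholds:
    """Stagewise bounds ``eps_j <= eta_j`` on the posterior-probability scale."""

    eta: tuple[float, ...]
    eps: tuple[float, ...]
    family: str = "custom"
    param: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", tuple(float(x) for x in self.eta))
        object.__setattr__(self, "eps", tuple(float(x) for x in self.eps))
        if len(self.eta) != len(self.eps):
            raise ConfigError("eta and eps must have equal length J")
        if any(not 0.0 < x < 1.0 for x in self.eta + self.eps):
            raise ConfigError("thresholds must lie strictly in (0, 1)")
        if any(e > h for e, h in zip(self.eps, self.eta)):
            raise ConfigError("eps_j must not exceed eta_j")
        if abs(self.eta[-1] - self.eps[-1]) > 1e-12:
            raise ConfigError("final-stage thresholds must satisfy eta_J = eps_J")

    @property
    def J(self) -> int:
        return len(self.eta)

    @property
    def z_eta(self) -> np.ndarray:
        """Efficacy bounds on the z-scale."""
        return norm.ppf(np.asarray(self.eta))

    @property
    def z_eps(self) -> np.ndarray:
        """Futility bounds on the z-scale."""
        return norm.ppf(np.asarray(self.eps))

    def table(self):
        """Threshold table (stage, eta, eps, z_eta, z_eps) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": np.arange(1, self.J + 1),
                "eta": self.eta,
                "eps": self.eps,
                "z_eta": self.z_eta,
                "z_eps": self.z_eps,
            }
        )


def triangular_thresholds(eta1: float, t) -> Thresholds:
    """Triangular bound family anchored at the stage-1 efficacy threshold."""
    if not 0.5 < eta1 < 1.0:
        raise ConfigError(f"eta1 must lie in (0.5, 1), got {eta1}")
    t = np.asarray(t, dtype=float)
    z1 = norm.ppf(eta1)
    scale = z1 * np.sqrt(t[0]) / (1.0 + t[0])
    z_eta = scale * (1.0 + t) / np.sqrt(t)
    z_eps = scale * (3.0 * t - 1.0) / np.sqrt(t)
    # final stage closes exactly: (1 + 1) == (3*1 - 1)
    z_eps[-1] = z_eta[-1]
    return Thresholds(
        eta=tuple(norm.cdf(z_eta)),
        eps=tuple(norm.cdf(z_eps)),
        family="triangular",
        param=eta1,
    )


def pocock_thresholds(eta1: float, eps1: float, t) -> Thresholds:
    """Constant z-scale efficacy bound; futility interpolates linearly on the z-scale.

    The efficacy bound is flat at ``Phi^{-1}(eta1)`` and the futility bound
    moves linearly in the information fraction from ``Phi^{-1}(eps1)`` at the
    first analysis up to the (shared) final bound.  The futility shape is a
    package choice, not canonical.
    """
    if not 0.0 < eta1 < 1.0:
        raise ConfigError(f"eta1 must lie in (0, 1), got {eta1}")
    if eps1 > eta1:
        raise ConfigError("eps1 must not exceed eta1")
    t = np.asarray(t, dtype=float)
    J = len(t)
    z_u = norm.ppf(eta1)
    z_eta = np.full(J, z_u)
    if J == 1:
        z_eps = np.array([z_u])
    else:
        z_l = norm.ppf(eps1)
        frac = (t - t[0]) / (1.0 - t[0])
        z_eps = z_l + frac * (z_u - z_l)
    return Thresholds(
        eta=tuple(norm.cdf(z_eta)),
        eps=tuple(norm.cdf(z_eps)),
        family="pocock",
        param=eta1,
    )


def thresholds_from_z(z_eta, z_eps, family: str = "custom", param: float = float("nan")) -> Thresholds:
    """Wrap explicit z-scale bounds (e.g. tabulated frequentist bounds)."""
    return Thresholds(
        eta=tuple(norm.cdf(np.asarray(z_eta, dtype=float))),
        eps=tuple(norm.cdf(np.asarray(z_eps, dtype=float))),
        family=family,
        param=param,
    )


def stage_decision(probs: dict[int, float], th: Thresholds, j: int) -> list[StageDecision]:
    """Apply the stage-``j`` rule to the posterior probabilities of the active arms.

    ``probs`` maps 1-based arm index to ``P(theta(k) > 0 | data)``.  The
    boundary conventions follow the decision rule literally: ``>= eta_j``
    stops for efficacy, ``< eps_j`` drops for futility, otherwise the arm
    continues (impossible at the final stage since ``eta_J = eps_J``).  An
    efficacy stop does not terminate the trial; other arms proceed.
    """
    if not 1 <= j <= th.J:
        raise ConfigError(f"stage {j} out of range 1..{th.J}")
    eta_j, eps_j = th.eta[j - 1], th.eps[j - 1]
    out = []
    for arm, p in sorted(probs.items()):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"posterior probability {p} for arm {arm} outside [0, 1]")
        if p >= eta_j:
            act = Action.STOP_EFFICACY
        elif p < eps_j:
            act = Action.DROP_FUTILITY
        else:
            act = Action.CONTINUE
        out.append(StageDecision(arm=arm, action=act, prob=p, stage=j))
    return out
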