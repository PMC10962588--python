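"""Trial geometry, prior hyperparameters and simulation scenarios.

A multi-arm multi-stage (MAMS) trial compares ``K - 1`` active arms against a
shared control over ``J`` stages.  At each interim analysis arms may be dropped
for futility or declared superior; the remaining arms continue.  The classes
here are plain configuration containers: :class:`DesignSpec` fixes the trial
geometry, :class:`PriorSpec` the hyperparameters of the conjugate normal prior
(with an ordering structure on consecutive treatment-mean differences), and
:class:`Scenario` the true response means a simulation or analytic evaluation
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = ["DesignSpec", "PriorSpec", "Scenario", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a design, prior or scenario configuration is inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Geometry of a multi-arm multi-stage trial with known outcome variances.

    Parameters
    ----------
    K : int
        Number of arms including control; ``K - 1`` active arms indexed
        ``1 .. K-1`` (arm ``0`` is control).
    J : int
        Number of analysis stages.
    t : sequence of float
        Information fractions ``t_1 < ... < t_J = 1`` at which analyses occur.
    n_stage : int
        Patients accrued per arm per stage (equal allocation).
    sigma : sequence of float
        Known outcome standard deviations ``sigma_0 .. sigma_{K-1}`` in
        outcome units (control first).
    """

    K: int
    J: int
    t: tuple[float, ...]
    n_stage: int
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", tuple(float(x) for x in self.t))
        object.__setattr__(self, "sigma", tuple(float(x) for x in self.sigma))
        if self.K < 2:
            raise ConfigError(f"K must be >= 2, got {self.K}")
        if self.J < 1:
            raise ConfigError(f"J must be >= 1, got {self.J}")
        if len(self.t) != self.J:
            raise ConfigError(f"t has length {len(self.t)}, expected J={self.J}")
        if any(b <= a for a, b in zip(self.t, self.t[1:])) or not np.isclose(
            self.t[-1], 1.0
        ):
            raise ConfigError(f"t must be strictly increasing with t_J=1, got {self.t}")
        if self.n_stage < 1:
            raise ConfigError(f"n_stage must be >= 1, got {self.n_stage}")
        if len(self.sigma) != self.K:
            raise ConfigError(
                f"sigma has length {len(self.sigma)}, expected K={self.K}"
            )
        if any(s <= 0 for s in self.sigma):
            raise ConfigError(f"all sigma must be > 0, got {self.sigma}")

    @property
    def n_active(self) -> int:
        """Number of active (non-control) arms."""
        return self.K - 1

    @property
    def sigma_ctrl(self) -> float:
        return self.sigma[0]

    @property
    def sigma_active(self) -> np.ndarray:
        return np.asarray(self.sigma[1:], dtype=float)

    @property
    def max_ss(self) -> int:
        """Maximum total sample size ``K * J * n_stage``."""
        return self.K * self.J * self.n_stage

    def replace(self, **changes) -> "DesignSpec":
        d = asdict(self)
        d.update(changes)
        return DesignSpec(**d)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "J": self.J,
            "t": list(self.t),
            "n_stage": self.n_stage,
            "sigma": list(self.sigma),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**d)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the ordering prior on treatment and control means.

    The active-arm means are linked through consecutive differences: arm 1
    (a priori the largest mean) has prior ``N(mu0_1, 1/tau01)`` and
    ``mu(k+1) = mu(k) - delta(k)`` with ``delta(k) ~ N(delta0[k-1],
    1/tau_d[k-1])``.  The control mean has an independent prior
    ``N(mu0_ctrl, 1/tau00)``.  A precision of ``1e-6`` is the conventional
    "uninformative" setting.
    """

    mu0_ctrl: float
    tau00: float
    mu0_1: float
    tau01: float
    delta0: tuple[float, ...] = ()
    tau_d: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta0", tuple(float(x) for x in self.delta0))
        object.__setattr__(self, "tau_d", tuple(float(x) for x in self.tau_d))
        if self.tau00 <= 0 or self.tau01 <= 0 or any(t <= 0 for t in self.tau_d):
            raise ConfigError("all prior precisions must be strictly positive")
        if len(self.delta0) != len(self.tau_d):
            raise ConfigError(
                f"delta0 (len {len(self.delta0)}) and tau_d (len {len(self.tau_d)}) "
                "must have equal length K-2"
            )

    def validate_for(self, design: DesignSpec) -> None:
        if len(self.delta0) != design.K - 2:
            raise ConfigError(
                f"delta0 has length {len(self.delta0)}, expected K-2={design.K - 2}"
            )

    def replace(self, **changes) -> "PriorSpec":
        d = asdict(self)
        d.update(changes)
        return PriorSpec(**d)

    def to_dict(self) -> dict:
        return {
            "mu0_ctrl": self.mu0_ctrl,
            "tau00": self.tau00,
            "mu0_1": self.mu0_1,
            "tau01": self.tau01,
            "delta0": list(self.delta0),
            "tau_d": list(self.tau_d),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass(frozen=True)
class Scenario:
    """True response means ``(mu(0), mu(1), ..., mu(K-1))`` in outcome units."""

    true_means: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "true_means", tuple(float(x) for x in self.true_means)
        )
        if not all(np.isfinite(self.true_means)):
            raise ConfigError(f"true means must be finite, got {self.true_means}")

    @classmethod
    def from_effects(cls, mu_ctrl: float, theta: Sequence[float]) -> "Scenario":
        """Build from a control mean and treatment effects ``theta(k) = mu(k) - mu(0)``."""
        return cls((mu_ctrl, *(mu_ctrl + th for th in theta)))

    @property
    def mu_ctrl(self) -> float:
        return self.true_means[0]

    @property
    def mu_active(self) -> np.ndarray:
        return np.asarray(self.true_means[1:], dtype=float)

    @property
    def theta(self) -> np.ndarray:
        """Treatment effects versus control."""
        return self.mu_active - self.mu_ctrl

    def to_dict(self) -> dict:
        return {"true_means": list(self.true_means)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        if "true_means" in d:
            return cls(tuple(d["true_means"]))
        return cls.from_effects(d["mu_ctrl"], d["theta"])


def dump_yaml(obj, stream=None):
    """Serialize a spec (or dict of specs) to YAML."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    return yaml.safe_dump(obj, stream, sort_keys=False)


def load_design(source) -> DesignSpec:
    return DesignSpec.from_dict(_load(source))


def load_prior(source) -> PriorSpec:
    return PriorSpec.from_dict(_load(source))


def _load(source) -> dict:
    if isinstance(source, dict):
        return source
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    return yaml.safe_load(str(source))
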