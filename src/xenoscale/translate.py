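"""Allometric scaling of mouse TGI parameters to a human population.

The exponential growth rate and the drug potency cross species by a
power-of-body-weight rule combined with the day-to-month unit change:

    lambda0_human [1/month] = 30 * lambda0_mouse * (BW_h / BW_m)^(-alpha)
    k2_human [L/(mg·month)] = 30 * k2_mouse * (BW_h / BW_m)^(-alpha) * fu_ratio

with alpha = 1/3, BW_h = 70 kg, BW_m = 0.025 kg by default, and fu_ratio
the human:mouse unbound-fraction ratio (1 for both shipped case studies).

Only the typical values are scaled.  The log-scale covariance of the
(lambda0, k2) random effects is the corresponding submatrix of the mouse
covariance, copied verbatim — multiplicative scaling of a lognormal leaves
log-scale spread (hence every geometric CV and correlation) unchanged.
The linear-growth rate lambda1 and the damage-chain rate k1 do not cross
species: the human model has no linear phase and no transit chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xenoscale.popfit import PopulationEstimate

__all__ = [
    "ScalingConfig", "HumanPopulation",
    "scale_growth_rate", "scale_potency", "build_human_distribution",
]


@dataclass(frozen=True)
class ScalingConfig:
    bw_human: float = 70.0     # kg
    bw_mouse: float = 0.025    # kg
    alpha: float = 1.0 / 3.0   # allometric exponent
    day_to_month: float = 30.0
    fu_ratio: float = 1.0      # f_u,human / f_u,mouse

    def __post_init__(self) -> None:
        for name in ("bw_human", "bw_mouse", "day_to_month", "fu_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def factor(self) -> float:
        """day->month conversion times the allometric body-weight factor."""
        return self.day_to_month * (self.bw_human / self.bw_mouse) ** (-self.alpha)


@dataclass(frozen=True)
class HumanPopulation:
    """Scaled multivariate lognormal distribution of (lambda0, k2) in
    humans: typical values plus the 2x2 log-scale covariance."""

    lambda0_pop: float           # 1/month
    k2_pop: float                # L/(mg·month)
    omega: np.ndarray            # 2x2, order (lambda0, k2)

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", om)
        if om.shape != (2, 2):
            raise ValueError("omega must be 2x2")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(om) < -1e-10):
            raise ValueError("omega must be positive semidefinite")
        if self.lambda0_pop <= 0 or self.k2_pop < 0:
            raise ValueError("lambda0_pop must be > 0 and k2_pop >= 0")

    @property
    def corr(self) -> float:
        d = np.sqrt(self.omega[0, 0] * self.omega[1, 1])
        return float(self.omega[0, 1] / d) if d > 0 else 0.0


def scale_growth_rate(lambda0_mouse: float, cfg: ScalingConfig | None = None) -> float:
    """Scale the exponential growth rate [1/day] to humans [1/month]."""
    if lambda0_mouse <= 0:
        raise ValueError("lambda0_mouse must be > 0")
    cfg = cfg or ScalingConfig()
    return cfg.factor * lambda0_mouse


def scale_potency(k2_mouse: float, cfg: ScalingConfig | None = None) -> float:
    """Scale the drug potency [L/(mg·day)] to humans [L/(mg·month)],
    correcting for the cross-species unbound-fraction ratio."""
    if k2_mouse < 0:
        raise ValueError("k2_mouse must be >= 0")
    cfg = cfg or ScalingConfig()
    return cfg.factor * cfg.fu_ratio * k2_mouse


def build_human_distribution(
    popest: PopulationEstimate, cfg: ScalingConfig | None = None
) -> HumanPopulation:
    """Scale a mouse population estimate into the human (lambda0, k2)
    distribution.  Typical values go through the allometric rule; the
    log-scale covariance submatrix passes through untouched."""
    cfg = cfg or ScalingConfig()
    if popest.theta.get("k2") is None or not np.isfinite(popest.theta["k2"]):
        raise ValueError(
            "population estimate lacks k2 (control-only panel?): cannot translate"
        )
    return HumanPopulation(
        lambda0_pop=scale_growth_rate(popest.theta["lambda0"], cfg),
        k2_pop=scale_potency(popest.theta["k2"], cfg),
        omega=popest.lambda0_k2_submatrix().copy(),
    )
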