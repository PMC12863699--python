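"""Equilibrium points and the basic reproduction number.

The system has three candidate steady states:

* PDPF -- prey-disease-predator-free point (Lambda/mu, 0, 0): only
  susceptible prey persist.  Always exists.
* PFP  -- predator-free point with the disease endemic in prey; exists
  exactly when the basic reproduction number R0 = beta*Lambda/((delta+omega)*mu)
  exceeds 1.
* CEP  -- co-existence (interior) point (eta, sigma, kappa) with all three
  populations positive.  The infected-prey coordinate is pinned by the
  predator balance, sigma = d/(n - a*d), and the predator coordinate kappa
  is the unique positive root of a quadratic obtained by eliminating S and I
  from the steady-state system.

Derivation of the quadratic: from the infected-prey balance,
S(P) = [(delta+omega)(1+a*sigma) + m*P] / (beta*(1+a*sigma)); substituting
into the susceptible-prey balance multiplied through by (1+kP) gives
zeta1*P^2 + zeta2*P + zeta3 = 0 with

    zeta1 = k*m*(mu + beta*sigma)
    zeta2 = m*(mu + beta*sigma) + k*(1+a*sigma)*(mu*(delta+omega) + beta*sigma*delta)
    zeta3 = (1+a*sigma)*(mu*(delta+omega) + beta*sigma*delta - beta*Lambda)

zeta1 and zeta2 are positive whenever sigma > 0, so an interior point exists
iff zeta3 < 0, i.e. iff Lambda > delta*sigma and R0 > Lambda/(Lambda - delta*sigma)
-- exactly the parameter region past the predator-invasion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ModelParams, rhs

__all__ = [
    "CEPCoefficients",
    "EquilibriumReport",
    "basic_reproduction_number",
    "pdpf",
    "pfp",
    "cep",
    "cep_coefficients",
    "existence_report",
]


def basic_reproduction_number(params: ModelParams) -> float:
    """R0 = beta*Lambda / ((delta+omega)*mu): expected secondary infections
    produced by one infected prey introduced at the disease-free point."""
    p = params
    return p.beta * p.Lambda / ((p.delta + p.omega) * p.mu)


def pdpf(params: ModelParams) -> np.ndarray:
    """Prey-disease-predator-free point (Lambda/mu, 0, 0)."""
    return np.array([params.Lambda / params.mu, 0.0, 0.0])


def pfp(params: ModelParams) -> Optional[np.ndarray]:
    """Predator-free point (Lambda/(mu*R0), (R0-1)*Lambda/(delta*R0), 0).

    Returns None when R0 <= 1 (at R0 = 1 exactly the point coincides with
    the PDPF and is reported absent-degenerate).
    """
    p = params
    R0 = basic_reproduction_number(p)
    if R0 <= 1.0:
        return None
    return np.array(
        [p.Lambda / (p.mu * R0), (R0 - 1.0) * p.Lambda / (p.delta * R0), 0.0]
    )


@dataclass(frozen=True)
class CEPCoefficients:
    """Coefficients of the interior-point quadratic zeta1*P^2 + zeta2*P + zeta3 = 0."""

    zeta1: float
    zeta2: float
    zeta3: float

    def positive_root(self) -> Optional[float]:
        """Unique positive root, computed in cancellation-free form; None if absent."""
        z1, z2, z3 = self.zeta1, self.zeta2, self.zeta3
        if z3 >= 0.0:
            return None
        if z1 == 0.0:  # k = 0: the quadratic degenerates to a linear equation
            return -z3 / z2
        return -2.0 * z3 / (z2 + np.sqrt(z2 * z2 - 4.0 * z1 * z3))


def cep_coefficients(params: ModelParams) -> Optional[CEPCoefficients]:
    """Quadratic coefficients for the interior point; None when n <= a*d."""
    p = params
    if p.n <= p.a * p.d:
        return None
    sigma = p.d / (p.n - p.a * p.d)
    hol = 1.0 + p.a * sigma
    mb = p.mu + p.beta * sigma
    core = p.mu * (p.delta + p.omega) + p.beta * sigma * p.delta
    return CEPCoefficients(
        zeta1=p.k * p.m * mb,
        zeta2=p.m * mb + p.k * hol * core,
        zeta3=hol * (core - p.beta * p.Lambda),
    )


def cep(params: ModelParams) -> Optional[np.ndarray]:
    """Co-existence point (eta, sigma, kappa), or None when it does not exist."""
    p = params
    coeffs = cep_coefficients(p)
    if coeffs is None:
        return None
    kappa = coeffs.positive_root()
    if kappa is None:
        return None
    sigma = p.d / (p.n - p.a * p.d)
    hol = 1.0 + p.a * sigma
    eta = ((p.delta + p.omega) * hol + p.m * kappa) / (p.beta * hol)
    return np.array([eta, sigma, kappa])


@dataclass
class EquilibriumReport:
    """All equilibria, existence flags, and the existence conditions."""

    params: ModelParams
    R0: float
    pdpf: np.ndarray
    pfp: Optional[np.ndarray]
    cep: Optional[np.ndarray]
    cep_coeffs: Optional[CEPCoefficients]
    pfp_degenerate: bool  # R0 == 1 exactly: PFP coincides with PDPF
    conditions: dict = field(default_factory=dict)

    @property
    def pfp_exists(self) -> bool:
        return self.pfp is not None

    @property
    def cep_exists(self) -> bool:
        return self.cep is not None

    def residuals(self) -> dict:
        out = {"pdpf": float(np.max(np.abs(rhs(self.pdpf, self.params))))}
        if self.pfp is not None:
            out["pfp"] = float(np.max(np.abs(rhs(self.pfp, self.params))))
        if self.cep is not None:
            out["cep"] = float(np.max(np.abs(rhs(self.cep, self.params))))
        return out

    def to_dict(self) -> dict:
        def vec(v):
            return None if v is None else [float(x) for x in v]

        return {
            "R0": float(self.R0),
            "pdpf": vec(self.pdpf),
            "pfp": vec(self.pfp),
            "cep": vec(self.cep),
            "cep_coeffs": None
            if self.cep_coeffs is None
            else {
                "zeta1": self.cep_coeffs.zeta1,
                "zeta2": self.cep_coeffs.zeta2,
                "zeta3": self.cep_coeffs.zeta3,
            },
            "pfp_exists": self.pfp_exists,
            "cep_exists": self.cep_exists,
            "pfp_degenerate": self.pfp_degenerate,
            "conditions": self.conditions,
        }


def existence_report(params: ModelParams) -> EquilibriumReport:
    """Assemble every equilibrium together with its existence conditions.

    At most one interior point exists (the quadratic has exactly one
    positive root when zeta3 < 0, since zeta1, zeta2 >= 0).
    """
    p = params
    R0 = basic_reproduction_number(p)
    coeffs = cep_coefficients(p)
    sigma = p.d / (p.n - p.a * p.d) if p.n > p.a * p.d else None
    conditions = {
        "R0_gt_1": R0 > 1.0,
        "n_gt_ad": p.n > p.a * p.d,
        "sigma": sigma,
        "prey_supports_predator": sigma is not None and p.Lambda > p.delta * sigma,
        "R0_above_invasion": (
            sigma is not None
            and p.Lambda > p.delta * sigma
            and R0 > p.Lambda / (p.Lambda - p.delta * sigma)
        ),
        "zeta3_negative": coeffs is not None and coeffs.zeta3 < 0.0,
    }
    return EquilibriumReport(
        params=p,
        R0=R0,
        pdpf=pdpf(p),
        pfp=pfp(p),
        cep=cep(p),
        cep_coeffs=coeffs,
        pfp_degenerate=(R0 == 1.0),
        conditions=conditions,
    )
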