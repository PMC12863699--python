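"""Local and global stability classification for the fractional system.

Local stability of an equilibrium of a Caputo system of order alpha is
decided by the Matignon condition: the point is locally asymptotically
stable (LAS) iff every Jacobian eigenvalue satisfies |arg(lambda)| >
alpha*pi/2.  The quantity

    margin m(alpha) = alpha*pi/2 - min_j |arg(lambda_j)|

is negative for LAS spectra; its zero crossing (for a complex pair with
positive real part) marks the fractional Hopf point at the critical order
alpha* = (2/pi) * atan(Im/Re).

A fractional Routh-Hurwitz criterion on the cubic characteristic polynomial
lambda^3 + c1 lambda^2 + c2 lambda + c3 provides an alternative, discriminant-
based sufficient test, cross-checked against the direct eigenvalue route.

The global-stability predicates evaluate the Lyapunov-derived sufficient
inequalities for each equilibrium.  They are one-sided: a False result means
"inconclusive for global asymptotic stability", never "not globally stable".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ModelParams, jacobian
from .equilibria import (
    basic_reproduction_number,
    existence_report,
    EquilibriumReport,
)

__all__ = [
    "StabilityReport",
    "RouthHurwitzReport",
    "classify",
    "char_poly_coeffs",
    "routh_hurwitz_fractional",
    "stability_of_equilibria",
    "invasion_eigenvalue",
    "global_pdpf_condition",
    "global_pfp_condition",
    "global_cep_condition",
    "theta_decay_rate",
    "attractor_bound",
]

MARGIN_TOL = 1e-6  # |margin| below this -> "marginal"
ZERO_TOL = 1e-10  # |eigenvalue| below this -> treated as zero


@dataclass
class StabilityReport:
    """Matignon classification of one spectrum at a given order alpha."""

    eigenvalues: np.ndarray
    alpha: float
    min_arg: float  # smallest |arg(lambda)| over the spectrum, radians
    margin: float  # alpha*pi/2 - min_arg; negative <=> LAS
    classification: str  # one of {"LAS", "saddle", "unstable", "marginal"}
    alpha_star: Optional[float] = None  # critical order, when defined

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "alpha": self.alpha,
            "min_arg": self.min_arg,
            "margin": self.margin,
            "classification": self.classification,
            "alpha_star": self.alpha_star,
        }


def _critical_order(eigs: np.ndarray) -> Optional[float]:
    """alpha* = (2/pi) atan(Im/Re), defined only for spectra consisting of a
    negative real eigenvalue plus a complex pair with positive real part."""
    real = [ev for ev in eigs if abs(ev.imag) < ZERO_TOL]
    cplx = [ev for ev in eigs if ev.imag > ZERO_TOL]
    if len(real) != 1 or len(cplx) != 1:
        return None
    if real[0].real >= 0:
        return None
    theta = cplx[0].real
    w = cplx[0].imag
    if theta <= 0:
        return None
    return float(2.0 / np.pi * np.arctan(w / theta))


def classify(eigs, alpha: float, tol: float = MARGIN_TOL) -> StabilityReport:
    """Classify a spectrum by the Matignon cone |arg(lambda)| = alpha*pi/2.

    LAS when every eigenvalue lies outside the cone, unstable when every one
    lies inside, saddle when both sides are populated; near-zero eigenvalues
    or eigenvalues on the cone (within ``tol`` radians) give "marginal".
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    eigs = np.atleast_1d(np.asarray(eigs, dtype=complex))
    args = np.abs(np.angle(eigs))  # principal value, |arg| in [0, pi]
    min_arg = float(np.min(args))
    cone = alpha * np.pi / 2.0
    margin = cone - min_arg
    alpha_star = _critical_order(eigs)

    if np.any(np.abs(eigs) < ZERO_TOL):
        cls = "marginal"
    else:
        inside = args < cone - tol
        outside = args > cone + tol
        if np.any(inside) and np.any(outside):
            cls = "saddle"
        elif np.all(outside):
            cls = "LAS"
        elif np.all(inside):
            cls = "unstable"
        else:
            cls = "marginal"
    return StabilityReport(
        eigenvalues=eigs,
        alpha=alpha,
        min_arg=min_arg,
        margin=float(margin),
        classification=cls,
        alpha_star=alpha_star,
    )


def char_poly_coeffs(J) -> tuple[float, float, float]:
    """(c1, c2, c3) of det(lambda*I - J) = lambda^3 + c1 lambda^2 + c2 lambda + c3.

    c1 = -trace, c2 = sum of principal 2x2 minors, c3 = -det.
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {J.shape}")
    c1 = -np.trace(J)
    minors = (
        J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    )
    c3 = -np.linalg.det(J)
    return float(c1), float(minors), float(c3)


@dataclass
class RouthHurwitzReport:
    """Fractional Routh-Hurwitz evaluation for a cubic characteristic polynomial."""

    c1: float
    c2: float
    c3: float
    alpha: float
    Delta: float
    condition_met: str  # "i" | "ii" | "iii" | "instability" | "none"

    @property
    def stable(self) -> Optional[bool]:
        """True/False when the criterion is decisive, None otherwise."""
        if self.condition_met in ("i", "ii", "iii"):
            return True
        if self.condition_met == "instability":
            return False
        return None

    def to_dict(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "alpha": self.alpha,
            "Delta": self.Delta,
            "condition_met": self.condition_met,
        }


def discriminant(c1: float, c2: float, c3: float) -> float:
    """Discriminant of lambda^3 + c1 lambda^2 + c2 lambda + c3."""
    return (
        18.0 * c1 * c2 * c3
        + (c1 * c2) ** 2
        - 4.0 * c3 * c1**3
        - 4.0 * c2**3
        - 27.0 * c3**2
    )


def routh_hurwitz_fractional(
    c1: float, c2: float, c3: float, alpha: float, tol: float = 1e-9
) -> RouthHurwitzReport:
    """Sufficient stability clauses for a fractional cubic.

    (i)   Delta > 0, c1 > 0, c3 > 0, c1*c2 > c3          (classical Hurwitz)
    (ii)  Delta < 0, c1 >= 0, c2 >= 0, c3 > 0, alpha < 2/3
    (iii) Delta < 0, c1 > 0, c2 > 0, c1*c2 = c3 (within tol)
    instability: Delta < 0, c1 < 0, c2 < 0, alpha > 2/3  (all roots inside cone)
    """
    D = discriminant(c1, c2, c3)
    met = "none"
    if D > 0 and c1 > 0 and c3 > 0 and c1 * c2 > c3:
        met = "i"
    elif D < 0 and c1 >= 0 and c2 >= 0 and c3 > 0 and alpha < 2.0 / 3.0:
        met = "ii"
    elif D < 0 and c1 > 0 and c2 > 0 and abs(c1 * c2 - c3) <= tol * max(1.0, abs(c3)):
        met = "iii"
    elif D < 0 and c1 < 0 and c2 < 0 and alpha > 2.0 / 3.0:
        met = "instability"
    return RouthHurwitzReport(c1=c1, c2=c2, c3=c3, alpha=alpha, Delta=D, condition_met=met)


def invasion_eigenvalue(params: ModelParams) -> Optional[float]:
    """Predator-invasion eigenvalue n*I2/(1+a*I2) - d at the predator-free point.

    Positive means a rare predator can grow on the endemic infected-prey
    supply; its zero in beta is the predator-invasion threshold.  None when
    the predator-free point does not exist (R0 <= 1).
    """
    rep = existence_report(params)
    if rep.pfp is None:
        return None
    I2 = rep.pfp[1]
    return float(params.n * I2 / (1.0 + params.a * I2) - params.d)


def stability_of_equilibria(
    params: ModelParams, report: Optional[EquilibriumReport] = None
) -> dict:
    """Matignon classification of every existing equilibrium.

    Returns a dict keyed by "pdpf"/"pfp"/"cep" with
    (state, StabilityReport, RouthHurwitzReport) entries; the PFP entry also
    carries the predator-invasion eigenvalue.
    """
    rep = report or existence_report(params)
    out = {}
    for name, state in (("pdpf", rep.pdpf), ("pfp", rep.pfp), ("cep", rep.cep)):
        if state is None:
            continue
        J = jacobian(state, params)
        eigs = np.linalg.eigvals(J)
        entry = {
            "state": state,
            "matignon": classify(eigs, params.alpha),
            "routh_hurwitz": routh_hurwitz_fractional(*char_poly_coeffs(J), params.alpha),
        }
        if name == "pfp":
            I2 = state[1]
            entry["invasion_eigenvalue"] = float(
                params.n * I2 / (1.0 + params.a * I2) - params.d
            )
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# Global-stability sufficient conditions (Lyapunov-derived)
# ---------------------------------------------------------------------------


def theta_decay_rate(params: ModelParams) -> float:
    """Decay rate theta = min(mu, delta, d) of the total-biomass bound."""
    return min(params.mu, params.delta, params.d)


def attractor_bound(params: ModelParams, eps_fraction: float = 0.01) -> float:
    """Ultimate bound gamma = Lambda/theta + eps on A = S + I + (m/n)P."""
    base = params.Lambda / theta_decay_rate(params)
    return base * (1.0 + eps_fraction)


@dataclass
class GlobalStabilityReport:
    """Evaluation of one Lyapunov-derived sufficient condition."""

    equilibrium: str
    applicable: bool
    holds: bool
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "equilibrium": self.equilibrium,
            "applicable": self.applicable,
            "holds": self.holds,
            "note": "sufficient condition only: holds=False means inconclusive for GAS",
            "details": self.details,
        }


def global_pdpf_condition(params: ModelParams) -> GlobalStabilityReport:
    """Disease-and-predator extinction condition:
    S~ > omega/beta and Lambda*k*n/(d*m) < R0 < (beta*S~ - omega)/(beta*S~)."""
    p = params
    S_tilde = p.Lambda / p.mu
    R0 = basic_reproduction_number(p)
    lower = p.Lambda * p.k * p.n / (p.d * p.m)
    upper = (p.beta * S_tilde - p.omega) / (p.beta * S_tilde)
    holds = (S_tilde > p.omega / p.beta) and (lower < R0 < upper)
    return GlobalStabilityReport(
        equilibrium="pdpf",
        applicable=True,
        holds=bool(holds),
        details={"S_tilde": S_tilde, "R0": R0, "lower": lower, "upper": upper},
    )


def global_pfp_condition(params: ModelParams) -> GlobalStabilityReport:
    """Predator-extinction condition d > (n/m)*(beta*Lambda*S^*k/delta + m*I^ + m/a)."""
    p = params
    rep = existence_report(p)
    if rep.pfp is None:
        return GlobalStabilityReport("pfp", applicable=False, holds=False,
                                     details={"reason": "PFP absent (R0 <= 1)"})
    S_hat, I_hat = rep.pfp[0], rep.pfp[1]
    bound = (p.n / p.m) * (p.beta * p.Lambda * S_hat * p.k / p.delta + p.m * I_hat + p.m / p.a)
    return GlobalStabilityReport(
        equilibrium="pfp",
        applicable=True,
        holds=bool(p.d > bound),
        details={"S_hat": S_hat, "I_hat": I_hat, "d": p.d, "bound": bound},
    )


def global_cep_condition(
    params: ModelParams, gamma: Optional[float] = None
) -> GlobalStabilityReport:
    """Interior-point condition gamma1 < 0 and gamma2 < 0 and gamma3 < 0, where

        gamma1 = (omega + sigma + beta*gamma - mu) / 2
        gamma2 = (beta*gamma + sigma + eta*gamma - 2*delta - omega) / 2
        gamma3 = (2n + (1+a)*kappa - 2*a*d) / (2a)

    with gamma the ultimate bound on the weighted total population.
    gamma4 (reported, not part of the conjunction) collects the constant
    remainder of the Lyapunov derivative estimate.
    """
    p = params
    rep = existence_report(p)
    if rep.cep is None:
        return GlobalStabilityReport("cep", applicable=False, holds=False,
                                     details={"reason": "CEP absent"})
    eta, sigma, kappa = rep.cep
    g = attractor_bound(p) if gamma is None else float(gamma)
    g1 = 0.5 * (p.omega + sigma + p.beta * g - p.mu)
    g2 = 0.5 * (p.beta * g + sigma + eta * g - 2.0 * p.delta - p.omega)
    g3 = (2.0 * p.n + (1.0 + p.a) * kappa - 2.0 * p.a * p.d) / (2.0 * p.a)
    g4 = 0.5 * (
        (p.mu + p.beta * g) * eta**2
        + sigma * (p.delta + p.omega) ** 2
        + sigma * p.omega**2
        + p.beta**2 * eta * g
        + kappa * p.d**2
        + p.n**2 * kappa / p.a
    ) + g * p.Lambda - p.Lambda * eta / (1.0 + g * p.k)
    return GlobalStabilityReport(
        equilibrium="cep",
        applicable=True,
        holds=bool(g1 < 0 and g2 < 0 and g3 < 0),
        details={"gamma": g, "gamma1": g1, "gamma2": g2, "gamma3": g3, "gamma4": g4},
    )
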