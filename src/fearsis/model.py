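"""Right-hand side and Jacobian of the fear/SIS predator-prey system.

The model tracks susceptible prey ``S``, infected prey ``I`` and predators
``P``.  Susceptible prey are recruited at a constant rate ``Lambda`` which is
suppressed by predator presence through the fear factor ``1/(1+kP)``; the
disease is of SIS type (recovered prey return to the susceptible class at
rate ``omega``); predators consume infected prey only, with a Holling
type-II (saturating) functional response.  Time derivatives are Caputo
fractional derivatives of order ``alpha`` in (0, 1], so all rate parameters
carry units of 1/time^alpha:

    D^a S = Lambda/(1+kP) - mu*S - beta*S*I + omega*I
    D^a I = beta*S*I - (delta+omega)*I - m*I*P/(1+a*I)
    D^a P = n*I*P/(1+a*I) - d*P

Only the rescaled parameterisation above is exposed; the analysis and all
reference numbers are stated in these units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import NamedTuple

import numpy as np

__all__ = ["ModelParams", "StateVec", "fear_factor", "rhs", "jacobian"]

_POSITIVE_FIELDS = ("Lambda", "mu", "beta", "omega", "delta", "m", "a", "n", "d")


@dataclass(frozen=True)
class ModelParams:
    """The eleven rescaled parameters of the Caputo system.

    Lambda : recruitment rate of susceptible prey (density/time^alpha)
    k      : fear level (1/density); k = 0 switches the fear effect off
    mu     : susceptible-prey mortality (1/time^alpha)
    beta   : infection rate (1/(density*time^alpha))
    omega  : recovery rate of infected prey (1/time^alpha)
    delta  : infected-prey mortality (1/time^alpha)
    m      : saturated predation rate on infected prey (1/time^alpha per predator)
    a      : half-saturation constant of the functional response (1/density)
    n      : predator conversion/birth rate from predation (1/time^alpha)
    d      : predator mortality (1/time^alpha)
    alpha  : order of the Caputo derivative, in (0, 1]
    """

    Lambda: float
    k: float
    mu: float
    beta: float
    omega: float
    delta: float
    m: float
    a: float
    n: float
    d: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {v}")
        if not np.isfinite(self.k) or self.k < 0:
            raise ValueError(f"fear level k must be >= 0, got {self.k}")
        if not (0 < self.alpha <= 1):
            raise ValueError(f"fractional order alpha must lie in (0, 1], got {self.alpha}")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(**data)


class StateVec(NamedTuple):
    """One point (S, I, P) of population densities."""

    S: float
    I: float
    P: float


def _as_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (3,):
        raise ValueError(f"state must have 3 components (S, I, P), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"state components must be finite, got {x}")
    return x


def fear_factor(k: float, P: float) -> float:
    """Multiplier 1/(1+kP) applied to prey recruitment.

    Equals 1 when either the fear level ``k`` or the predator density ``P``
    is zero and decreases strictly in ``P`` for ``k > 0``; the range is (0, 1].
    """
    if k < 0 or P < 0:
        raise ValueError(f"fear_factor requires k >= 0 and P >= 0, got k={k}, P={P}")
    return 1.0 / (1.0 + k * P)


def rhs(state, params: ModelParams) -> np.ndarray:
    """Caputo-derivative vector (F1, F2, F3) at the given state."""
    S, I, P = _as_state(state)
    p = params
    hol = 1.0 + p.a * I  # Holling type-II denominator
    F1 = p.Lambda / (1.0 + p.k * P) - p.mu * S - p.beta * S * I + p.omega * I
    F2 = p.beta * S * I - (p.delta + p.omega) * I - p.m * I * P / hol
    F3 = p.n * I * P / hol - p.d * P
    return np.array([F1, F2, F3])


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs` at an arbitrary state.

    The general-state formula is used everywhere, including at equilibria,
    so that eigenvalue computations never rely on simplified special-case
    expressions.
    """
    S, I, P = _as_state(state)
    p = params
    hol = 1.0 + p.a * I
    fear = 1.0 + p.k * P
    return np.array(
        [
            [-p.mu - p.beta * I, p.omega - p.beta * S, -p.Lambda * p.k / fear**2],
            [p.beta * I, p.beta * S - (p.delta + p.omega) - p.m * P / hol**2, -p.m * I / hol],
            [0.0, p.n * P / hol**2, p.n * I / hol - p.d],
        ]
    )
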