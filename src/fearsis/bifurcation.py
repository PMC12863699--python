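"""Forward and Hopf bifurcation location, parameter sweeps, cycle detection.

Two forward (transcritical) thresholds in the infection rate beta have
closed forms: the disease-invasion threshold where R0 crosses 1, and the
predator-invasion threshold where the predator's growth rate on the endemic
infected-prey supply crosses zero.  Fractional Hopf thresholds are located
by root-finding on the Matignon margin m = alpha*pi/2 - min|arg(lambda)| of
the interior equilibrium's spectrum as a function of any model parameter
(including the order alpha itself); the empirical route integrates the
system along a parameter grid and classifies each attractor by the
post-transient oscillation amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, jacobian
from .equilibria import existence_report, cep as _cep, pfp as _pfp, pdpf as _pdpf
from .solver import SolverConfig, Trajectory, simulate, IntegrationError

__all__ = [
    "ThresholdResult",
    "SweepResult",
    "forward_threshold_beta",
    "predator_invasion_threshold_beta",
    "matignon_margin",
    "find_hopf_threshold",
    "detect_limit_cycle",
    "sweep",
    "perturbed_equilibrium",
]

DEFAULT_TRANSIENT_FRACTION = 0.5
DEFAULT_AMPLITUDE_TOL = 1e-2


def forward_threshold_beta(params: ModelParams) -> float:
    """Infection rate at which R0 = 1: beta = (delta+omega)*mu/Lambda.

    Below it only the disease-free point exists and is stable; above it the
    endemic predator-free branch appears (forward bifurcation).
    """
    p = params
    return (p.delta + p.omega) * p.mu / p.Lambda


def predator_invasion_threshold_beta(params: ModelParams) -> Optional[float]:
    """Infection rate at which the predator invades the predator-free point.

    The invasion eigenvalue n*I2/(1+a*I2) - d vanishes when I2 = sigma =
    d/(n - a*d), giving beta = (delta+omega)*mu/(Lambda - delta*sigma); this
    is also the boundary R0 = Lambda/(Lambda - delta*sigma) at which the
    interior point emerges.  None when n <= a*d or Lambda <= delta*sigma
    (the predator can never invade).
    """
    p = params
    if p.n <= p.a * p.d:
        return None
    sigma = p.d / (p.n - p.a * p.d)
    if p.Lambda <= p.delta * sigma:
        return None
    return (p.delta + p.omega) * p.mu / (p.Lambda - p.delta * sigma)


_EQ_FUNCS = {"pdpf": _pdpf, "pfp": _pfp, "cep": _cep}


def matignon_margin(params: ModelParams, which_equilibrium: str = "cep") -> float:
    """m = alpha*pi/2 - min|arg(lambda)| over the Jacobian spectrum at the
    named equilibrium; positive means the Matignon condition is violated."""
    try:
        state = _EQ_FUNCS[which_equilibrium](params)
    except KeyError:
        raise ValueError(f"unknown equilibrium {which_equilibrium!r}") from None
    if state is None:
        raise ValueError(f"equilibrium {which_equilibrium!r} does not exist for these parameters")
    eigs = np.linalg.eigvals(jacobian(state, params))
    return float(params.alpha * np.pi / 2.0 - np.min(np.abs(np.angle(eigs))))


@dataclass
class ThresholdResult:
    """A located bifurcation threshold in one parameter."""

    parameter: str
    value: float
    bracket: tuple[float, float]
    method: str  # "analytic" | "margin-bisection" | "sweep-refinement"
    margin_residual: float
    eigenvalues: Optional[np.ndarray] = None
    margin_slope_sign: Optional[int] = None  # sign of dm/dparam at the root

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "value": self.value,
            "bracket": list(self.bracket),
            "method": self.method,
            "margin_residual": self.margin_residual,
            "eigenvalues": None
            if self.eigenvalues is None
            else [[ev.real, ev.imag] for ev in self.eigenvalues],
            "margin_slope_sign": self.margin_slope_sign,
        }


def find_hopf_threshold(
    params: ModelParams,
    parameter_name: str,
    bracket: tuple[float, float],
    which_equilibrium: str = "cep",
    xtol: float = 1e-6,
) -> ThresholdResult:
    """Root of the Matignon margin in the named parameter over ``bracket``.

    The margin must change sign across the bracket and the equilibrium must
    exist throughout; at the root the spectrum is verified to consist of a
    negative real eigenvalue plus a complex pair with positive real part,
    and the transversality of the margin (nonzero slope) is checked by a
    numerical derivative.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    def margin_at(value: float) -> float:
        p = params.replace(**{parameter_name: value})
        try:
            return matignon_margin(p, which_equilibrium)
        except ValueError as exc:
            raise ValueError(
                f"equilibrium {which_equilibrium!r} lost inside bracket at "
                f"{parameter_name}={value:g}: {exc}"
            ) from exc

    m_lo, m_hi = margin_at(lo), margin_at(hi)
    if np.sign(m_lo) == np.sign(m_hi):
        raise ValueError(
            f"margin does not change sign over bracket: m({lo:g})={m_lo:g}, m({hi:g})={m_hi:g}"
        )
    root = float(brentq(margin_at, lo, hi, xtol=xtol))
    residual = margin_at(root)

    p_root = params.replace(**{parameter_name: root})
    state = _EQ_FUNCS[which_equilibrium](p_root)
    eigs = np.linalg.eigvals(jacobian(state, p_root))
    cplx = eigs[np.abs(eigs.imag) > 1e-10]
    real = eigs[np.abs(eigs.imag) <= 1e-10]
    if not (len(cplx) == 2 and len(real) == 1 and real[0].real < 0 and cplx[0].real > 0):
        raise ValueError(
            f"spectrum at the root is not a Hopf configuration "
            f"(negative real + unstable complex pair): {eigs}"
        )
    dm = margin_at(root + xtol * 10) - margin_at(root - xtol * 10)
    slope_sign = int(np.sign(dm)) if dm != 0 else 0
    return ThresholdResult(
        parameter=parameter_name,
        value=root,
        bracket=(lo, hi),
        method="margin-bisection",
        margin_residual=float(residual),
        eigenvalues=eigs,
        margin_slope_sign=slope_sign,
    )


# ---------------------------------------------------------------------------
# Empirical route: sweeps and limit-cycle detection
# ---------------------------------------------------------------------------


def detect_limit_cycle(
    traj: Trajectory,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    amplitude_tol: float = DEFAULT_AMPLITUDE_TOL,
) -> tuple[str, np.ndarray]:
    """Classify a trajectory tail as "equilibrium" or "cycle".

    The first ``transient_fraction`` of the trajectory is discarded; per
    component the relative amplitude (max-min)/max(1, |mean|) over the tail
    is computed; any component exceeding ``amplitude_tol`` means a cycle.
    """
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must lie in [0, 1)")
    n = traj.states.shape[0]
    start = int(n * transient_fraction)
    tail = traj.states[start:]
    if tail.shape[0] < 100:
        raise ValueError(
            f"trajectory tail has {tail.shape[0]} points; need >= 100 for classification"
        )
    spread = tail.max(axis=0) - tail.min(axis=0)
    scale = np.maximum(1.0, np.abs(tail.mean(axis=0)))
    amplitude = spread / scale
    cls = "cycle" if np.any(amplitude > amplitude_tol) else "equilibrium"
    return cls, amplitude


def perturbed_equilibrium(params: ModelParams, rel: float = 0.05, inoculum: float = 0.1) -> np.ndarray:
    """Default initial condition: the equilibrium of interest (interior if it
    exists, else predator-free, else disease-free) with every positive
    component inflated by ``rel`` and every zero component replaced by a
    small ``inoculum`` so trajectories start in the interior."""
    rep = existence_report(params)
    state = rep.cep if rep.cep is not None else (rep.pfp if rep.pfp is not None else rep.pdpf)
    out = np.where(state > 0, state * (1.0 + rel), inoculum)
    return out.astype(float)


@dataclass
class SweepResult:
    """Attractor classification along a monotone parameter grid."""

    parameter: str
    grid: np.ndarray
    classes: list  # "equilibrium" | "cycle" | "divergent" per grid value
    amplitudes: np.ndarray  # (len(grid), 3) relative amplitudes (nan if divergent)
    minima: np.ndarray  # post-transient per-component minima
    maxima: np.ndarray
    final_states: np.ndarray
    config: SolverConfig = field(default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.parameter: self.grid,
                "class": self.classes,
                "S_min": self.minima[:, 0], "S_max": self.maxima[:, 0],
                "I_min": self.minima[:, 1], "I_max": self.maxima[:, 1],
                "P_min": self.minima[:, 2], "P_max": self.maxima[:, 2],
            }
        )


def sweep(
    params: ModelParams,
    parameter_name: str,
    grid: Sequence[float],
    solver_config: Optional[SolverConfig] = None,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    amplitude_tol: float = DEFAULT_AMPLITUDE_TOL,
    y0=None,
) -> SweepResult:
    """Integrate along a monotone parameter grid with warm-started continuation.

    The first run starts from ``y0`` (default: equilibrium of interest + 5%);
    each subsequent run starts from the previous value's final state, which
    suppresses transients and follows the attractor branch.  Divergent runs
    are flagged and the sweep continues from the last finite state.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 1 or not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be strictly monotone")
    cfg = solver_config or SolverConfig()

    classes, amps, mins, maxs, finals = [], [], [], [], []
    current_y0 = None
    for value in grid:
        p = params.replace(**{parameter_name: value})
        if current_y0 is None:
            current_y0 = np.asarray(y0, dtype=float) if y0 is not None else perturbed_equilibrium(p)
        try:
            traj = simulate(p, current_y0, cfg)
        except IntegrationError as exc:
            classes.append("divergent")
            amps.append([np.nan] * 3)
            mins.append([np.nan] * 3)
            maxs.append([np.nan] * 3)
            finals.append(exc.partial.final_state)
            continue
        cls, amplitude = detect_limit_cycle(traj, transient_fraction, amplitude_tol)
        start = int(traj.states.shape[0] * transient_fraction)
        tail = traj.states[start:]
        classes.append(cls)
        amps.append(amplitude)
        mins.append(tail.min(axis=0))
        maxs.append(tail.max(axis=0))
        finals.append(traj.final_state)
        current_y0 = traj.final_state
    return SweepResult(
        parameter=parameter_name,
        grid=grid,
        classes=classes,
        amplitudes=np.asarray(amps),
        minima=np.asarray(mins),
        maxima=np.asarray(maxs),
        final_states=np.asarray(finals),
        config=cfg,
    )
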