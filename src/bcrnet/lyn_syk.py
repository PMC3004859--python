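"""Receptor-proximal Lyn/Syk initiation model.

Three coupled ODEs describe the concentrations of active Lyn (``Lp``),
activation-susceptible Syk (``Sm``) and active Syk (``Sp``)::

    dLp/dt = k1 + k2*Lp - d1*g(t)*Lp
    dSm/dt = A - k3*Sm*Lp
    dSp/dt = k3*Sm*Lp - d2*Sp

``k1`` is the basal supply of membrane-associated Lyn, ``k2`` its
receptor-dependent self-activation rate, ``k3`` the rate at which active Lyn
activates Syk, and ``d1``/``d2`` the strength of negative regulation (the
receptor-associated phosphatase, SHP-1) on active Lyn and Syk.  Receptor
engagement is modelled as a transient dip in the Lyn-directed negative
regulation, ``g(t) = 1 - alpha*sin(2*pi*(t - t_trigger)/omega)`` over the
non-negative half-period of the sine, after which the phosphatase activity
returns to its resting value.

At rest (``alpha = 0``) the system settles at::

    Lp* = k1/(d1 - k2)      Sm* = A/(k3*Lp*)      Sp* = A/d2

which requires ``d1 > k2``.  The basal active-Lyn level ``Lp*`` therefore
rises as the negative regulation ``d1`` weakens — and the model's central
prediction is that cells with a *higher* basal ``Lp*`` mount a *weaker*
(smaller fold) response to receptor engagement.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

RTOL = 1e-8
ATOL = 1e-10
#: negative solver undershoot beyond this magnitude raises instead of clipping
NEGATIVITY_TOLERANCE = 1e-7

FREE_PARAMETER_NAMES = ("k1", "k2", "k3", "d1", "d2", "A", "alpha")


@dataclass(frozen=True)
class OdeParameters:
    """Rate constants and forcing parameters; times in minutes.

    Defaults place the system in the regime of the published sweeps:
    ``d1`` within the swept band [0.23, 1.2] per minute, ``k3`` and ``d2``
    at the midpoints of their swept ranges, and a 2.5-minute dip in
    phosphatase activity starting 10 minutes into the simulation.
    """

    k1: float = 0.1      # basal membrane-Lyn supply, conc/min
    k2: float = 0.05     # Lyn self-activation, 1/min
    k3: float = 0.005    # Syk activation by Lyn, 1/(conc*min)
    d1: float = 0.25     # negative regulation on active Lyn, 1/min
    d2: float = 0.4      # negative regulation on active Syk, 1/min
    A: float = 0.1       # susceptible-Syk supply, conc/min
    alpha: float = 0.8   # stimulation strength, dimensionless
    omega: float = 5.0   # forcing period, min
    t_trigger: float = 10.0  # stimulation onset, min

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "d1", "d2", "A", "omega", "t_trigger"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.d1 <= self.k2:
            raise ValueError(
                f"d1 must exceed k2 for a finite basal state (d1={self.d1}, k2={self.k2})"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "OdeParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Trajectory:
    """Solution of the model on an output time grid."""

    t: np.ndarray
    Lp: np.ndarray
    Sm: np.ndarray
    Sp: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if any(len(s) != n for s in (self.Lp, self.Sm, self.Sp)):
            raise ValueError("all series must match the time grid length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if min(self.Lp.min(), self.Sm.min(), self.Sp.min()) < 0:
            raise ValueError("state series must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "Lp": self.Lp, "Sm": self.Sm, "Sp": self.Sp})


def forcing(t: float, params: OdeParameters) -> float:
    """Negative-regulation multiplier g(t).

    Unity at rest; during the half-period window after ``t_trigger`` the
    phosphatase activity dips by up to ``alpha`` and then recovers.
    """
    dt = t - params.t_trigger
    if params.alpha == 0.0 or dt < 0 or dt > params.omega / 2 or params.omega == 0:
        return 1.0
    return 1.0 - params.alpha * math.sin(2 * math.pi * dt / params.omega)


def steady_state(params: OdeParameters) -> tuple[float, float, float]:
    """Resting fixed point (Lp*, Sm*, Sp*) at alpha = 0.

    Raises
    ------
    ValueError
        If d1 <= k2 (no finite basal state) or k3/d2 vanish.
    """
    gap = params.d1 - params.k2
    if gap <= 0:
        raise ValueError("no finite basal state: d1 must exceed k2")
    if params.k3 <= 0 or params.d2 <= 0:
        raise ValueError("k3 and d2 must be positive for a full steady state")
    lp = params.k1 / gap
    if lp <= 0:
        raise ValueError("Lp* must be positive to define Sm*")
    return lp, params.A / (params.k3 * lp), params.A / params.d2


def _rhs(t, y, p: OdeParameters):
    lp, sm, sp = y
    g = forcing(t, p)
    return (
        p.k1 + p.k2 * lp - p.d1 * g * lp,
        p.A - p.k3 * sm * lp,
        p.k3 * sm * lp - p.d2 * sp,
    )


def simulate(
    params: OdeParameters,
    init: tuple[float, float, float] | None = None,
    t_end: float = 60.0,
    dt_out: float = 0.1,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model from ``init`` (default: its own resting state).

    Adaptive integration with the maximum step bounded by the forcing
    half-period so the transient dip is always resolved.  Solver undershoot
    below zero smaller than the negativity tolerance is clipped; anything
    larger raises.

    Raises
    ------
    RuntimeError
        On solver failure or tolerance-violating negativity.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = steady_state(params)
    if min(init) < 0:
        raise ValueError("initial state must be non-negative")
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    max_step = params.omega / 20 if (params.alpha > 0 and params.omega > 0) else np.inf
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_grid[-1])),
        init,
        t_eval=t_grid,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = sol.y
    if y.min() < -NEGATIVITY_TOLERANCE:
        raise RuntimeError(
            f"state went negative beyond tolerance (min={y.min():.3e})"
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(t=sol.t, Lp=y[0], Sm=y[1], Sp=y[2])


def peak_response_sweep(
    params: OdeParameters,
    d1_values,
    observable: str = "Lp",
    t_end: float = 60.0,
    dt_out: float = 0.05,
) -> pd.DataFrame:
    """Sweep the Lyn negative-regulation strength and record peak responses.

    Each ``d1`` is simulated from its own resting state; the returned table
    holds, per ``d1``, the basal ``Lp*``, the absolute post-trigger peak of
    the observable, and the normalized peak (peak over its own basal value)
    — the model's measure of the *extent of activation*.
    """
    if observable not in ("Lp", "Sp"):
        raise ValueError("observable must be 'Lp' or 'Sp'")
    rows = []
    for d1 in d1_values:
        p = replace(params, d1=float(d1))
        lp_star, sm_star, sp_star = steady_state(p)
        traj = simulate(p, init=(lp_star, sm_star, sp_star), t_end=t_end, dt_out=dt_out)
        post = traj.t > p.t_trigger
        series = traj.Lp if observable == "Lp" else traj.Sp
        basal = lp_star if observable == "Lp" else sp_star
        peak = float(series[post].max())
        rows.append(
            {
                "d1": float(d1),
                "Lp_star": lp_star,
                "peak": peak,
                "peak_fold": peak / basal,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    estimates: dict[str, float]
    residual_norm: float
    converged: bool


def recover_parameters(
    traj: Trajectory,
    known: OdeParameters,
    free: list[str],
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Least-squares fit of the named free parameters to a trajectory.

    Residuals are taken over all three state series.  Free parameters are
    bounded positive, with ``d1`` additionally bounded above ``k2``; the
    non-convergence of the optimizer is reported in the result rather than
    raised.
    """
    unknown = set(free) - set(FREE_PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    data = np.vstack([traj.Lp, traj.Sm, traj.Sp])
    scale = np.maximum(np.abs(data).max(axis=1, keepdims=True), 1e-12)
    t_end = float(traj.t[-1])
    dt_out = float(traj.t[1] - traj.t[0])

    def build(values: np.ndarray) -> OdeParameters:
        return replace(known, **dict(zip(free, map(float, values))))

    def residuals(values: np.ndarray) -> np.ndarray:
        candidate = build(values)
        # pre-trigger phase sits at the candidate's own resting state
        start = init if init is not None else steady_state(candidate)
        sim = simulate(candidate, init=start, t_end=t_end, dt_out=dt_out)
        model = np.vstack([sim.Lp, sim.Sm, sim.Sp])
        return ((model[:, : data.shape[1]] - data) / scale).ravel()

    if not free:
        res = residuals(np.array([]))
        return FitResult(estimates={}, residual_norm=float(np.linalg.norm(res)), converged=True)

    x0 = np.array([getattr(known, name) for name in free], dtype=float)
    lower = np.array(
        [known.k2 * (1 + 1e-6) + 1e-9 if name == "d1" else 1e-9 for name in free]
    )
    upper = np.array([1.0 if name == "alpha" else np.inf for name in free])
    x0 = np.clip(x0, lower, upper)
    try:
        fit = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
        converged = bool(fit.success)
        estimates = dict(zip(free, map(float, fit.x)))
        norm = float(np.linalg.norm(fit.fun))
    except RuntimeError:
        converged, estimates, norm = False, dict(zip(free, map(float, x0))), float("nan")
    return FitResult(estimates=estimates, residual_norm=norm, converged=converged)
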