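"""Implicit trapezoidal time stepping with fixed-point iteration.

The equation of motion is advanced by the trapezoidal rule

    y_{n+1} = y_n + (Δt/2)(v_n + v_{n+1}),
    v_{n+1} = v_n + (Δt/2)(a_n + a(y_{n+1})),

solved by fixed-point iteration starting from a forward-Euler predictor.
Kinematic constraints — pinned particles held at their reference positions,
rim-layer particles driven radially outward at constant speed — are
re-imposed by projection after every iterate, so they hold exactly at every
accepted step.  A step whose iteration does not reach the tolerance within
the iteration budget is rejected and retried with a smaller Δt; the adaptive
controller grows Δt again when convergence is easy.  In a fracture problem
the stable (convergent) step size is itself a function of time, and the
controller tracks it: the step self-regulates downward by orders of
magnitude while bonds are breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretization import Membrane


class TimestepUnderflowError(RuntimeError):
    """Δt fell below dt_min: the run cannot continue."""


@dataclass
class IntegratorSettings:
    """Fixed-point and step-control parameters.

    ``max_fp_iterations = 8`` and ``fp_tolerance = 1e-6`` follow the study
    conditions; the controller constants are configurable.

    ``dt_max = None`` lets the driver derive an accuracy cap ~0.5·h/c from
    the elastic wave speed c; the trapezoidal rule is unconditionally stable
    but resolves the wave dynamics poorly above that scale.
    """

    max_fp_iterations: int = 8
    fp_tolerance: float = 1e-6
    dt_initial: float = 1e-6
    dt_min: float = 1e-12
    dt_max: float | None = None
    dt_grow: float = 1.2
    dt_shrink: float = 0.5
    easy_iterations: int = 3   # "few": grow dt when converged within this many

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_initial):
            raise ValueError("require 0 < dt_min <= dt_initial")
        if self.dt_max is not None and self.dt_max < self.dt_initial:
            raise ValueError("require dt_initial <= dt_max")
        if not (self.dt_shrink < 1.0 < self.dt_grow):
            raise ValueError("require dt_shrink < 1 < dt_grow")


@dataclass
class SimulationState:
    """Positions, velocities and accelerations of all particles at time t."""

    positions: np.ndarray       # (N, 2) μm
    velocities: np.ndarray      # (N, 2) μm/s
    accelerations: np.ndarray   # (N, 2) μm/s²
    time: float = 0.0
    dt: float = 1e-6
    step_index: int = 0

    @classmethod
    def initial(cls, membrane: Membrane, dt: float) -> "SimulationState":
        n = membrane.n_particles
        return cls(positions=membrane.positions_ref.copy(),
                   velocities=np.zeros((n, 2)),
                   accelerations=np.zeros((n, 2)),
                   time=0.0, dt=dt, step_index=0)


def radial_units(membrane: Membrane, ids: np.ndarray) -> np.ndarray:
    """Outward unit vectors of the *reference* positions of ``ids``."""
    p = membrane.positions_ref[ids]
    r = np.linalg.norm(p, axis=1)
    r[r == 0] = 1.0
    return p / r[:, None]


def rim_kinematics(rate: float, t: float, ramp: float = 0.0) -> tuple[float, float]:
    """Radial displacement and speed of the driven rim at time ``t``.

    With a spin-up ``ramp`` (s) the rim speed grows linearly from 0 to
    ``rate`` over ``[0, ramp]`` and is constant after, which avoids launching
    a velocity-discontinuity shock into the undamped membrane at t = 0.
    Displacement is the exact integral of that profile.
    """
    if ramp <= 0.0 or t >= ramp:
        return rate * (t - 0.5 * ramp), rate
    return rate * t * t / (2.0 * ramp), rate * t / ramp


def apply_boundary_conditions(state: SimulationState, membrane: Membrane,
                              rate: float, ramp: float = 0.0) -> SimulationState:
    """Impose the kinematic constraints on ``state`` (in place).

    Rim-layer particles move radially outward from their reference positions
    at speed ``rate`` (μm/s, after the optional spin-up ramp):
    y = x + d(t)·x̂, v = ḋ(t)·x̂.  Pinned particles sit at their reference
    positions with zero velocity.
    """
    b = membrane.boundary_layer_ids
    if b.size:
        rhat = radial_units(membrane, b)
        disp, speed = rim_kinematics(rate, state.time, ramp)
        state.positions[b] = membrane.positions_ref[b] + disp * rhat
        state.velocities[b] = speed * rhat
        state.accelerations[b] = 0.0
    p = membrane.pinned_ids
    if p.size:
        state.positions[p] = membrane.positions_ref[p]
        state.velocities[p] = 0.0
        state.accelerations[p] = 0.0
    return state


class _ConstraintProjector:
    """Precomputed projection of pins and driven-rim kinematics."""

    def __init__(self, membrane: Membrane, rate: float, ramp: float = 0.0):
        self.membrane = membrane
        self.rate = rate
        self.ramp = ramp
        self.b = membrane.boundary_layer_ids
        self.p = membrane.pinned_ids
        self.rhat = radial_units(membrane, self.b) if self.b.size else None

    def project(self, y: np.ndarray, v: np.ndarray, t: float) -> None:
        mb = self.membrane
        if self.b.size:
            disp, speed = rim_kinematics(self.rate, t, self.ramp)
            y[self.b] = mb.positions_ref[self.b] + disp * self.rhat
            v[self.b] = speed * self.rhat
        if self.p.size:
            y[self.p] = mb.positions_ref[self.p]
            v[self.p] = 0.0


def trapezoidal_step(state: SimulationState, accel_fn, settings: IntegratorSettings,
                     membrane: Membrane, rate: float = 0.0,
                     projector: _ConstraintProjector | None = None):
    """Attempt one trapezoidal step of size ``state.dt``.

    Parameters
    ----------
    accel_fn : callable
        Maps positions (N, 2) → accelerations (N, 2) (force density divided
        by the mass-scaled density).
    rate : float
        Radial speed of the driven rim layer, μm/s.

    Returns
    -------
    (new_state, converged, iterations)
        ``new_state`` is a fresh state at ``t + dt`` when converged; on
        non-convergence the input state is untouched and ``new_state is None``.

    The convergence metric is the maximum over particles of the position
    change between successive iterates, relative to ``|y| + h``.
    """
    if projector is None:
        projector = _ConstraintProjector(membrane, rate)
    dt = state.dt
    t1 = state.time + dt
    y0, v0, a0 = state.positions, state.velocities, state.accelerations
    h = membrane.spacing_h

    # forward-Euler predictor
    y1 = y0 + dt * v0 + 0.5 * dt * dt * a0
    v1 = v0 + dt * a0
    projector.project(y1, v1, t1)

    converged = False
    iterations = 0
    a1 = a0
    for iterations in range(1, settings.max_fp_iterations + 1):
        a1 = accel_fn(y1)
        v1 = v0 + 0.5 * dt * (a0 + a1)
        y_new = y0 + 0.5 * dt * (v0 + v1)
        projector.project(y_new, v1, t1)
        err = np.max(np.abs(y_new - y1).max(axis=1)
                     / (np.abs(y1).max(axis=1) + h))
        y1 = y_new
        if err < settings.fp_tolerance:
            converged = True
            break

    if not converged:
        return None, False, iterations

    new_state = SimulationState(
        positions=y1, velocities=v1.copy(), accelerations=a1.copy(),
        time=t1, dt=dt, step_index=state.step_index + 1)
    return new_state, True, iterations


def adapt_dt(settings: IntegratorSettings, converged: bool, iterations: int,
             dt: float) -> float:
    """Adaptive step-size rule.

    Rejected → shrink (``dt·dt_shrink``, floored at dt_min; underflow raises
    :class:`TimestepUnderflowError`).  Converged within ``easy_iterations`` →
    grow (capped at dt_max).  Otherwise unchanged.
    """
    if not converged:
        new_dt = dt * settings.dt_shrink
        if new_dt < settings.dt_min:
            raise TimestepUnderflowError(
                f"dt {new_dt:g} fell below dt_min {settings.dt_min:g}")
        return max(new_dt, settings.dt_min)
    if iterations <= settings.easy_iterations:
        cap = settings.dt_max if settings.dt_max is not None else np.inf
        return min(dt * settings.dt_grow, cap)
    return dt
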