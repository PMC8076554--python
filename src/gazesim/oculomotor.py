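"""Saccadic plant dynamics and proprioceptive read-out.

The conjugate eye angle theta (heading, elevation) obeys a damped linear
second-order plant: the oculomotor torque is tau = phi - theta - kappa *
theta_dot, the restoring force of a pendulum drawn toward an equilibrium
point phi (the motor command, in the spirit of the equilibrium-point
hypothesis), and J theta_ddot = tau with J the eyeball's moment of
inertia.  One state drives both eyes — conjugacy is enforced by
construction — while the convergence angle omega offsets the two eyes'
heading read-out by +-omega/2.

Proprioception mimics muscle-spindle afferents: II channels report
position (theta, with the omega offset on heading), Ia channels report
velocity.  Signals are in radians / rad s^-1 ("arbitrary units"
neurally — no firing-rate transform is applied).

Both an RK4 integrator (optionally stochastic, with process noise on the
velocity rows and sensory noise on every afferent) and the exact closed
form of the linear plant are provided; the latter doubles as an oracle
for the former.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "PlantParams",
    "OculoState",
    "MotorCommand",
    "ProprioSample",
    "Trajectory",
    "IntegrationError",
    "torque",
    "flow",
    "closed_form_state",
    "integrate_saccade",
    "observe_proprio",
    "lyapunov_energy",
]


class IntegrationError(RuntimeError):
    """Raised when the plant state becomes non-finite during integration."""


def _pair(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(2)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class PlantParams:
    """Plant constants: inertia J, damping kappa, convergence omega, precisions.

    ``process_precision`` and ``sensory_precision`` are the diagonal
    entries of the precision (inverse covariance) matrices of the process
    and sensory noise; the defaults make both noises small but present
    when a seed is supplied.
    """

    inertia: float = 1.0
    damping: float = 2.0
    convergence: float = 0.0
    process_precision: float = 1e4
    sensory_precision: float = 1e4

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("moment of inertia must be positive")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")
        if self.convergence < 0:
            raise ValueError("convergence must be non-negative")
        if self.process_precision <= 0 or self.sensory_precision <= 0:
            raise ValueError("precisions must be strictly positive")


@dataclass(frozen=True)
class OculoState:
    """Conjugate gaze angles and angular velocities, (heading, elevation)."""

    theta: Tuple[float, float] = (0.0, 0.0)
    theta_dot: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", tuple(_pair(self.theta, "theta")))
        object.__setattr__(self, "theta_dot", tuple(_pair(self.theta_dot, "theta_dot")))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.theta, self.theta_dot])

    @staticmethod
    def from_vector(v: np.ndarray) -> "OculoState":
        return OculoState(theta=tuple(v[:2]), theta_dot=tuple(v[2:]))


@dataclass(frozen=True)
class MotorCommand:
    """The equilibrium point phi the eyes are drawn toward."""

    phi: Tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", tuple(_pair(self.phi, "phi")))


@dataclass(frozen=True)
class ProprioSample:
    """II (position) and Ia (velocity) afferents per eye, (heading, elevation).

    The convergence offset applies to the heading channel only, so the
    elevation channels of the two eyes are identical in the noiseless case.
    """

    ii_left: Tuple[float, float]
    ia_left: Tuple[float, float]
    ii_right: Tuple[float, float]
    ia_right: Tuple[float, float]


def torque(command: MotorCommand, state: OculoState, kappa: float) -> np.ndarray:
    """Restoring torque per axis: tau = phi - theta - kappa * theta_dot."""
    return (np.asarray(command.phi) - np.asarray(state.theta)
            - kappa * np.asarray(state.theta_dot))


def flow(state: OculoState, command: MotorCommand, params: PlantParams) -> np.ndarray:
    """State derivative (d theta, d theta_dot) of the plant."""
    tau = torque(command, state, params.damping)
    return np.concatenate([state.theta_dot, tau / params.inertia])


def _closed_form_axis(y0: float, v0: float, J: float, kappa: float, t: float
                      ) -> Tuple[float, float]:
    """Exact solution of J y'' + kappa y' + y = 0 with y(0)=y0, y'(0)=v0."""
    disc = kappa * kappa - 4.0 * J
    if abs(disc) < 1e-12:                       # critically damped
        r = -kappa / (2.0 * J)
        a, b = y0, v0 - r * y0
        e = math.exp(r * t)
        return (a + b * t) * e, (b + r * (a + b * t)) * e
    if disc > 0:                                # overdamped
        sq = math.sqrt(disc)
        r1 = (-kappa + sq) / (2.0 * J)
        r2 = (-kappa - sq) / (2.0 * J)
        b = (v0 - r1 * y0) / (r2 - r1)
        a = y0 - b
        return (a * math.exp(r1 * t) + b * math.exp(r2 * t),
                a * r1 * math.exp(r1 * t) + b * r2 * math.exp(r2 * t))
    # underdamped (includes kappa == 0)
    sigma = -kappa / (2.0 * J)
    wd = math.sqrt(-disc) / (2.0 * J)
    a = y0
    b = (v0 - sigma * y0) / wd
    e = math.exp(sigma * t)
    c, s = math.cos(wd * t), math.sin(wd * t)
    y = e * (a * c + b * s)
    v = e * (sigma * (a * c + b * s) + wd * (-a * s + b * c))
    return y, v


def closed_form_state(state0: OculoState, command: MotorCommand,
                      params: PlantParams, t: float) -> OculoState:
    """Exact plant state at time t via the characteristic roots.

    Handles under-, over- and critically damped regimes per axis (both
    axes share J and kappa, so the regime is common).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    theta, theta_dot = [], []
    for axis in range(2):
        y0 = state0.theta[axis] - command.phi[axis]
        v0 = state0.theta_dot[axis]
        y, v = _closed_form_axis(y0, v0, params.inertia, params.damping, t)
        theta.append(command.phi[axis] + y)
        theta_dot.append(v)
    return OculoState(theta=tuple(theta), theta_dot=tuple(theta_dot))


def observe_proprio(state: OculoState, params: PlantParams,
                    rng: Union[None, int, np.random.Generator] = None) -> ProprioSample:
    """II/Ia afferent read-out of the current state.

    Left-eye heading II = theta_h - omega/2, right = theta_h + omega/2; Ia
    channels carry theta_dot; elevation is shared.  With an rng (or seed),
    iid Gaussian sensory noise at the sensory precision is added to every
    channel.
    """
    th = np.asarray(state.theta)
    td = np.asarray(state.theta_dot)
    half = params.convergence / 2.0
    channels = np.array([
        [th[0] - half, th[1]],   # II left
        [td[0], td[1]],          # Ia left
        [th[0] + half, th[1]],   # II right
        [td[0], td[1]],          # Ia right
    ])
    if rng is not None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        channels = channels + gen.normal(
            0.0, math.sqrt(1.0 / params.sensory_precision), size=channels.shape
        )
    return ProprioSample(
        ii_left=tuple(channels[0]),
        ia_left=tuple(channels[1]),
        ii_right=tuple(channels[2]),
        ia_right=tuple(channels[3]),
    )


def lyapunov_energy(state: OculoState, command: MotorCommand,
                    params: PlantParams) -> float:
    """Plant energy 1/2 J |theta_dot|^2 + 1/2 |theta - phi|^2.

    Non-increasing along noiseless trajectories whenever kappa >= 0.
    """
    err = np.asarray(state.theta) - np.asarray(command.phi)
    vel = np.asarray(state.theta_dot)
    return float(0.5 * params.inertia * vel @ vel + 0.5 * err @ err)


@dataclass
class Trajectory:
    """Time grid with the state and proprioceptive sample at each point."""

    time: np.ndarray
    theta: np.ndarray       # (n, 2)
    theta_dot: np.ndarray   # (n, 2)
    ii_left: np.ndarray     # (n, 2)
    ia_left: np.ndarray
    ii_right: np.ndarray
    ia_right: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        n = len(self.time)
        for name in ("theta", "theta_dot", "ii_left", "ia_left", "ii_right", "ia_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match the time grid")

    def state_at(self, k: int) -> OculoState:
        return OculoState(theta=tuple(self.theta[k]), theta_dot=tuple(self.theta_dot[k]))

    def to_frame(self) -> pd.DataFrame:
        """Tabular export; elevation afferents are shared across the eyes
        in the noiseless case, so a single pair of columns (from the left
        eye) represents them."""
        return pd.DataFrame({
            "time": self.time,
            "theta_h": self.theta[:, 0],
            "theta_e": self.theta[:, 1],
            "dtheta_h": self.theta_dot[:, 0],
            "dtheta_e": self.theta_dot[:, 1],
            "II_left_h": self.ii_left[:, 0],
            "Ia_left_h": self.ia_left[:, 0],
            "II_right_h": self.ii_right[:, 0],
            "Ia_right_h": self.ia_right[:, 0],
            "II_elev": self.ii_left[:, 1],
            "Ia_elev": self.ia_left[:, 1],
        })


def integrate_saccade(state0: OculoState, command: MotorCommand,
                      params: PlantParams, dt: float, T: float,
                      seed: Union[None, int, np.random.Generator] = None) -> Trajectory:
    """Fixed-step RK4 integration of a saccade toward the equilibrium point.

    With ``seed`` (an int or a Generator), zero-mean Gaussian process
    noise of covariance dt / process_precision is added to the velocity
    rows after each step, and sensory noise at the sensory precision to
    every proprioceptive sample; ``seed=None`` is noiseless and
    bit-reproducible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least dt")
    n_steps = int(round(T / dt))
    rng = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def deriv(v: np.ndarray) -> np.ndarray:
        tau = (np.asarray(command.phi) - v[:2]) - params.damping * v[2:]
        return np.concatenate([v[2:], tau / params.inertia])

    time = np.arange(n_steps + 1) * dt
    states = np.empty((n_steps + 1, 4))
    states[0] = state0.as_vector()
    proc_std = math.sqrt(dt / params.process_precision)

    v = states[0].copy()
    for k in range(n_steps):
        k1 = deriv(v)
        k2 = deriv(v + 0.5 * dt * k1)
        k3 = deriv(v + 0.5 * dt * k2)
        k4 = deriv(v + dt * k3)
        v = v + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if rng is not None:
            v[2:] += rng.normal(0.0, proc_std, size=2)
        if not np.all(np.isfinite(v)):
            raise IntegrationError(f"state became non-finite at step {k + 1}")
        states[k + 1] = v

    samples = [
        observe_proprio(OculoState.from_vector(states[k]), params, rng)
        for k in range(n_steps + 1)
    ]
    return Trajectory(
        time=time,
        theta=states[:, :2].copy(),
        theta_dot=states[:, 2:].copy(),
        ii_left=np.array([s.ii_left for s in samples]),
        ia_left=np.array([s.ia_left for s in samples]),
        ii_right=np.array([s.ii_right for s in samples]),
        ia_right=np.array([s.ia_right for s in samples]),
    )
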