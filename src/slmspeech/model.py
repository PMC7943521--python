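"""Forward Sigma-lognormal model.

A complex movement is represented as a time-overlapped vector sum of simple
strokes.  Each stroke has a lognormal speed profile along an arc of a circle:
the speed magnitude is ``D * Lambda(t; t0, mu, sigma)`` where ``Lambda`` is
the lognormal density in ``t - t0``, and the instantaneous direction sweeps
from a starting angle ``theta_s`` to an ending angle ``theta_e`` following the
lognormal's cumulative weight.  The chain of virtual target points (VTPs) is
the sequence of positions each stroke aims at; because strokes overlap in
time, the trajectory does not in general pass through them.

Units: distances in mm, times in s, angles in rad, speeds in mm/s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "LognormalStroke",
    "ActionPlan",
    "SampledSignal",
    "lognormal_speed",
    "angular_progress",
    "stroke_weight",
    "synthesize_velocity",
    "synthesize_trajectory",
    "virtual_targets",
    "snr",
    "lognormal_support",
    "plan_timebase",
]

#: Below this angular difference (rad) a stroke is treated as straight; the
#: arc equations divide by theta_e - theta_s.
STRAIGHT_TOL = 1e-8


@dataclass(frozen=True)
class LognormalStroke:
    """Parameters of one simple movement (one lognormal primitive).

    Parameters
    ----------
    D : float
        Length of the movement along its arc, mm.  Must be positive.
    t0 : float
        Occurrence time of the motor command, s.
    mu : float
        Log time delay (log of the neuromuscular delay, ln-seconds).
    sigma : float
        Log response time (spread of the impulse response), dimensionless.
        Must be positive.
    theta_s, theta_e : float
        Starting and ending angular direction of the arc, rad.
    """

    D: float
    t0: float
    mu: float
    sigma: float
    theta_s: float = 0.0
    theta_e: float = 0.0

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"stroke amplitude D must be > 0, got {self.D}")
        if not (self.sigma > 0):
            raise ValueError(f"stroke sigma must be > 0, got {self.sigma}")
        for name in ("t0", "mu", "theta_s", "theta_e"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"stroke parameter {name} must be finite")

    # -- closed-form characteristics -------------------------------------
    @property
    def peak_time(self) -> float:
        """Time of maximum speed: ``t0 + exp(mu - sigma**2)``."""
        return self.t0 + math.exp(self.mu - self.sigma**2)

    @property
    def peak_speed(self) -> float:
        """Maximum speed: ``D * exp(sigma**2/2 - mu) / (sigma * sqrt(2*pi))``."""
        return (
            self.D
            * math.exp(self.sigma**2 / 2.0 - self.mu)
            / (self.sigma * math.sqrt(2.0 * math.pi))
        )

    @property
    def is_straight(self) -> bool:
        return abs(self.theta_e - self.theta_s) < STRAIGHT_TOL

    def chord(self) -> np.ndarray:
        """Displacement vector from this stroke's start VTP to its end VTP."""
        if self.is_straight:
            return self.D * np.array(
                [math.cos(self.theta_s), math.sin(self.theta_s)]
            )
        return _arc_displacement(self, np.asarray(self.theta_e))

    def as_dict(self) -> dict:
        return {
            "D": self.D,
            "t0": self.t0,
            "mu": self.mu,
            "sigma": self.sigma,
            "theta_s": self.theta_s,
            "theta_e": self.theta_e,
        }


@dataclass(frozen=True)
class ActionPlan:
    """An ordered sequence of strokes plus the initial virtual target point."""

    strokes: tuple[LognormalStroke, ...]
    vtp0: tuple[float, float] = (0.0, 0.0)

    def __init__(
        self,
        strokes: Sequence[LognormalStroke] = (),
        vtp0: Sequence[float] = (0.0, 0.0),
    ) -> None:
        strokes = tuple(strokes)
        t0s = [s.t0 for s in strokes]
        if any(b < a for a, b in zip(t0s, t0s[1:])):
            raise ValueError("strokes must be ordered by non-decreasing t0")
        vtp0 = tuple(float(v) for v in vtp0)
        if len(vtp0) != 2:
            raise ValueError("vtp0 must be a 2-D point")
        object.__setattr__(self, "strokes", strokes)
        object.__setattr__(self, "vtp0", vtp0)

    def __len__(self) -> int:
        return len(self.strokes)

    @property
    def nblog(self) -> int:
        return len(self.strokes)

    def to_json(self) -> str:
        return json.dumps(
            {"vtp0": list(self.vtp0), "strokes": [s.as_dict() for s in self.strokes]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ActionPlan":
        obj = json.loads(text)
        return cls(
            strokes=[LognormalStroke(**s) for s in obj["strokes"]],
            vtp0=tuple(obj.get("vtp0", (0.0, 0.0))),
        )


@dataclass
class SampledSignal:
    """A uniformly sampled signal: speed (1 channel) or planar (2 channels).

    ``samples`` has shape ``(n,)`` for a scalar channel or ``(n, 2)`` for a
    planar signal (x, y components of position or velocity).
    """

    t_start: float
    dt: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or (n, 2)")
        if self.samples.ndim == 2 and self.samples.shape[1] != 2:
            raise ValueError("planar samples must have 2 columns")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.t_start + (self.n - 1) * self.dt

    @property
    def is_planar(self) -> bool:
        return self.samples.ndim == 2

    def speed(self) -> np.ndarray:
        """Per-sample magnitude (Euclidean norm for planar signals)."""
        if self.is_planar:
            return np.linalg.norm(self.samples, axis=1)
        return np.abs(self.samples)

    def same_grid(self, other: "SampledSignal", tol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.dt - other.dt) < tol
            and abs(self.t_start - other.t_start) < tol
        )


# ---------------------------------------------------------------------------
# elementary profiles


def lognormal_speed(t, stroke: LognormalStroke) -> np.ndarray:
    """Speed profile ``D * Lambda(t; t0, mu, sigma)`` of a single stroke.

    Zero for ``t <= t0`` (the value at ``t0`` is the left limit, 0).
    """
    t = np.asarray(t, dtype=float)
    x = t - stroke.t0
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    z = (np.log(xp) - stroke.mu) / stroke.sigma
    out[pos] = (
        stroke.D
        / (stroke.sigma * math.sqrt(2.0 * math.pi) * xp)
        * np.exp(-0.5 * z * z)
    )
    return out


def stroke_weight(t, stroke: LognormalStroke) -> np.ndarray:
    """Completed fraction of the stroke: the lognormal CDF in ``t - t0``."""
    t = np.asarray(t, dtype=float)
    x = t - stroke.t0
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = 0.5 * (
        1.0 + erf((np.log(x[pos]) - stroke.mu) / (stroke.sigma * math.sqrt(2.0)))
    )
    return out


def angular_progress(t, stroke: LognormalStroke) -> np.ndarray:
    """Angular position phi(t), sweeping from theta_s to theta_e.

    phi(t) = theta_s + (theta_e - theta_s)/2 * [1 + erf((ln(t-t0)-mu)/(sigma*sqrt(2)))].
    Equals theta_s for t <= t0 and tends to theta_e as t -> inf.
    """
    w = stroke_weight(t, stroke)
    return stroke.theta_s + (stroke.theta_e - stroke.theta_s) * w


def _arc_displacement(stroke: LognormalStroke, phi: np.ndarray) -> np.ndarray:
    """Displacement from the stroke's start VTP at angular position phi.

    Implements the arc-of-circle term
    ``D/(theta_e-theta_s) * (sin(phi)-sin(theta_s), -cos(phi)+cos(theta_s))``
    with the straight-stroke analytic limit when theta_e ~ theta_s.
    Returns an array of shape phi.shape + (2,).
    """
    phi = np.asarray(phi, dtype=float)
    dth = stroke.theta_e - stroke.theta_s
    if abs(dth) < STRAIGHT_TOL:
        raise ValueError("straight stroke has no arc form; use the chord limit")
    out = np.empty(phi.shape + (2,))
    out[..., 0] = np.sin(phi) - math.sin(stroke.theta_s)
    out[..., 1] = -np.cos(phi) + math.cos(stroke.theta_s)
    return stroke.D / dth * out


def _stroke_displacement(t, stroke: LognormalStroke) -> np.ndarray:
    """Planar displacement of one stroke from its start VTP at times t."""
    w = stroke_weight(t, stroke)
    if stroke.is_straight:
        d = np.empty(np.shape(w) + (2,))
        d[..., 0] = stroke.D * w * math.cos(stroke.theta_s)
        d[..., 1] = stroke.D * w * math.sin(stroke.theta_s)
        return d
    phi = stroke.theta_s + (stroke.theta_e - stroke.theta_s) * w
    return _arc_displacement(stroke, phi)


# ---------------------------------------------------------------------------
# plan-level synthesis


def plan_timebase(
    plan: ActionPlan, dt: float = 0.01, pad: float = 0.0, coverage: float = 4.0
) -> SampledSignal:
    """A time base covering the plan's active support.

    Starts slightly before the first command and ends ``coverage`` log-sigmas
    past the last stroke's mode, rounded up to the grid.
    """
    if len(plan) == 0:
        return SampledSignal(0.0, dt, np.zeros(1))
    t_lo = min(s.t0 for s in plan.strokes) - pad
    t_hi = max(
        s.t0 + math.exp(s.mu + coverage * s.sigma) for s in plan.strokes
    ) + pad
    n = int(math.ceil((t_hi - t_lo) / dt)) + 1
    return SampledSignal(t_lo, dt, np.zeros(n))


def synthesize_velocity(plan: ActionPlan, timebase: SampledSignal) -> SampledSignal:
    """Planar velocity of the plan: vector sum of all stroke velocities."""
    t = timebase.t
    v = np.zeros((t.size, 2))
    for s in plan.strokes:
        mag = lognormal_speed(t, s)
        phi = angular_progress(t, s)
        v[:, 0] += mag * np.cos(phi)
        v[:, 1] += mag * np.sin(phi)
    return SampledSignal(timebase.t_start, timebase.dt, v)


def synthesize_trajectory(plan: ActionPlan, timebase: SampledSignal) -> SampledSignal:
    """Planar trajectory of the plan (sum of overlapped circle arcs) + vtp0."""
    t = timebase.t
    s_r = np.zeros((t.size, 2))
    for s in plan.strokes:
        s_r += _stroke_displacement(t, s)
    s_r += np.asarray(plan.vtp0)
    return SampledSignal(timebase.t_start, timebase.dt, s_r)


def virtual_targets(plan: ActionPlan) -> np.ndarray:
    """The VTP chain, shape (nblog + 1, 2); row 0 is vtp0."""
    out = np.zeros((len(plan) + 1, 2))
    out[0] = plan.vtp0
    for j, s in enumerate(plan.strokes, start=1):
        if s.is_straight:
            chord = s.D * np.array([math.cos(s.theta_s), math.sin(s.theta_s)])
        else:
            chord = _arc_displacement(s, np.asarray(s.theta_e))
        out[j] = out[j - 1] + chord
    return out


# ---------------------------------------------------------------------------
# reconstruction quality


def snr(
    v_o: SampledSignal,
    v_r: SampledSignal,
    cap: float | None = None,
) -> float:
    """Reconstruction signal-to-noise ratio in dB.

    ``20*log10( sum v_o(t)^2 / sum |v_o(t) - v_r(t)|^2 )`` on the shared
    sampling grid (the sampling step cancels between numerator and
    denominator).  For planar signals the residual is the Euclidean norm of
    the component-wise difference.  A zero residual returns ``inf`` unless a
    finite ``cap`` is configured.
    """
    if not v_o.same_grid(v_r):
        raise ValueError("signals must share the same time base")
    if v_o.is_planar != v_r.is_planar:
        # compare magnitudes when channel counts differ
        a, b = v_o.speed(), v_r.speed()
        num = float(np.sum(a**2))
        den = float(np.sum((a - b) ** 2))
    else:
        a, b = v_o.samples, v_r.samples
        num = float(np.sum(v_o.speed() ** 2))
        diff = a - b
        if v_o.is_planar:
            den = float(np.sum(diff**2))
        else:
            den = float(np.sum(diff**2))
    if den == 0.0:
        return float("inf") if cap is None else float(cap)
    if num == 0.0:
        return -float("inf")
    value = 20.0 * math.log10(num / den)
    if cap is not None:
        value = min(value, float(cap))
    return value


def lognormal_support(
    stroke: LognormalStroke, level: float = 0.05
) -> tuple[float, float]:
    """Times where the stroke's speed equals ``level`` times its peak value.

    Found by bracketed root-finding on each side of the mode; these bounds
    delimit the stroke's effective support (conventionally at 5% of peak).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    target = level * stroke.peak_speed
    mode = stroke.peak_time

    def f(t: float) -> float:
        return float(lognormal_speed(np.asarray([t]), stroke)[0]) - target

    # bracket on each side of the mode; the profile is unimodal
    half_width = stroke.sigma * math.sqrt(-2.0 * math.log(level))
    lo_guess = stroke.t0 + math.exp(stroke.mu - stroke.sigma**2 - 2.0 * half_width)
    hi_guess = stroke.t0 + math.exp(stroke.mu - stroke.sigma**2 + 2.0 * half_width)
    t_begin = brentq(f, lo_guess, mode)
    t_end = brentq(f, mode, hi_guess)
    return float(t_begin), float(t_end)
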