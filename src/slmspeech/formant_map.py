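"""Acoustic-to-kinematic mapping.

The first two formants F1(t), F2(t) are mapped linearly onto a planar
kinematic space in which the Sigma-lognormal analysis operates:

    y(t) = c1 * F1(t),    x(t) = c2 * F2(t)

with transfer coefficients ``c1 = k*(1-alpha)`` and ``c2 = k*alpha``.  The
proportion parameter ``alpha`` weights F2 against F1 and is derived from the
speaker's vowel triangle: the /a/-/i/-/u/ extremes of the F1-F2 space are
fitted with an equilateral triangle, and alpha is the value that makes the
/i/-/a/ distance (L1) equal the /i/-/u/ distance (L2).  The scale constant
``k`` (mm/Hz) sets physical units and is fixed from a reference articulatory
distance L2.

The approximate articulator speed is then

    v_f(t) = sqrt( (c2 * dF2/dt)^2 + (c1 * dF1/dt)^2 )

which is the quantity decomposed into lognormal strokes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .model import SampledSignal

__all__ = [
    "FormantTrack",
    "VowelAnchors",
    "KinematicMapParams",
    "VOWEL_ANCHOR_SETS",
    "compute_alpha",
    "compute_k",
    "transfer_coefficients",
    "interpolate_gaps",
    "resample_track",
    "formants_to_trajectory",
    "kinematic_speed",
    "anchors_from_track",
    "FormantKinematicMapper",
]

SQRT3_2 = math.sqrt(3.0) / 2.0

#: Default proportion and scale used when no speaker-specific anchors are
#: available: alpha = 0.3, k = 0.04 mm/Hz (keeps peak speeds near measured
#: articulator speeds of ~200 mm/s).
DEFAULT_ALPHA = 0.3
DEFAULT_K = 0.04
DEFAULT_DT = 0.01


@dataclass(frozen=True)
class VowelAnchors:
    """Corner formants of the vowel triangle: /a/, /i/, /u/ (Hz)."""

    F1a: float
    F1i: float
    F2i: float
    F2u: float

    def __post_init__(self) -> None:
        for name in ("F1a", "F1i", "F2i", "F2u"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"anchor {name} must be positive and finite")
        if self.F1a < self.F1i or self.F2i < self.F2u:
            raise ValueError(
                "vowel-triangle orientation requires F1a >= F1i and F2i >= F2u"
            )


#: Published mean vowel formants usable as anchors.  The American-English
#: sets are the Hillenbrand et al. adult means (Table 5 of that study).
#: The German sets are APPROXIMATE means for the long vowels /a:/, /i:/,
#: /u:/ recalled from secondary literature on the Kiel Corpus of Read
#: Speech; the primary source was not available for verbatim transcription,
#: so treat these two entries as indicative only.
VOWEL_ANCHOR_SETS: Mapping[str, VowelAnchors] = {
    "english_male": VowelAnchors(F1a=768.0, F1i=342.0, F2i=2322.0, F2u=997.0),
    "english_female": VowelAnchors(F1a=936.0, F1i=437.0, F2i=2761.0, F2u=1105.0),
    "german_male_approx": VowelAnchors(F1a=647.0, F1i=292.0, F2i=2236.0, F2u=777.0),
    "german_female_approx": VowelAnchors(F1a=806.0, F1i=341.0, F2i=2588.0, F2u=910.0),
}


@dataclass
class FormantTrack:
    """A (time, F1, F2) series with a voiced mask.

    Unvoiced frames carry NaN formants and ``voiced=False``.  Time must be
    strictly increasing; it is uniform after :func:`resample_track`.
    """

    t: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    voiced: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F1 = np.asarray(self.F1, dtype=float)
        self.F2 = np.asarray(self.F2, dtype=float)
        if self.voiced is None:
            self.voiced = np.isfinite(self.F1) & np.isfinite(self.F2)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        n = self.t.size
        if not (self.F1.size == self.F2.size == self.voiced.size == n):
            raise ValueError("t, F1, F2, voiced must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        bad = self.voiced & ~(
            np.nan_to_num(self.F1, nan=-1.0) > 0
        ) | self.voiced & ~(np.nan_to_num(self.F2, nan=-1.0) > 0)
        if np.any(bad):
            raise ValueError("voiced frames must have positive F1 and F2")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Sampling step; requires a uniform time base."""
        steps = np.diff(self.t)
        if steps.size == 0:
            raise ValueError("track too short to define dt")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("track is not uniformly sampled")
        return float(steps[0])

    @property
    def fully_voiced(self) -> bool:
        return bool(np.all(self.voiced))


@dataclass(frozen=True)
class KinematicMapParams:
    """Parameters of the acoustic-to-kinematic linear map.

    ``c1 = k*(1-alpha)`` weights F1 (vertical axis), ``c2 = k*alpha``
    weights F2 (horizontal axis); ``c1 + c2 = k``.
    """

    alpha: float = DEFAULT_ALPHA
    k: float = DEFAULT_K
    anchors: VowelAnchors | None = None
    L2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (self.k > 0):
            raise ValueError(f"k must be positive, got {self.k}")

    @property
    def c1(self) -> float:
        return self.k * (1.0 - self.alpha)

    @property
    def c2(self) -> float:
        return self.k * self.alpha

    @classmethod
    def from_anchors(
        cls, anchors: VowelAnchors, L2: float = 16.0
    ) -> "KinematicMapParams":
        """Derive alpha from the vowel triangle and k from a target L2 (mm).

        The default L2 of 16 mm is a representative tongue-front excursion
        between /i/ and /u/ for an adult speaker.
        """
        alpha = compute_alpha(anchors.F1a, anchors.F1i, anchors.F2i, anchors.F2u)
        k = compute_k(L2, alpha, anchors.F2i, anchors.F2u)
        return cls(alpha=alpha, k=k, anchors=anchors, L2=L2)

    def triangle_sides(self) -> tuple[float, float]:
        """(L1, L2) of the mapped vowel triangle; requires anchors."""
        if self.anchors is None:
            raise ValueError("no anchors attached to this map")
        a = self.anchors
        h = self.c1 * (a.F1a - a.F1i)
        L1 = 2.0 / math.sqrt(3.0) * h
        L2 = self.c2 * (a.F2i - a.F2u)
        return L1, L2


# ---------------------------------------------------------------------------
# scalar map parameters


def compute_alpha(F1a: float, F1i: float, F2i: float, F2u: float) -> float:
    """Proportion parameter from vowel-triangle anchors.

    alpha = (F1a - F1i) / [ (F1a - F1i) + (sqrt(3)/2) * (F2i - F2u) ],
    the value that makes the /i/-/a/ and /i/-/u/ sides of the mapped
    equilateral vowel triangle equal.  Scale-free in the anchors.
    """
    d1 = F1a - F1i
    d2 = F2i - F2u
    if d1 < 0 or d2 < 0:
        raise ValueError("anchors must satisfy F1a >= F1i and F2i >= F2u")
    den = d1 + SQRT3_2 * d2
    if den == 0:
        raise ValueError("degenerate vowel triangle: all anchor differences zero")
    return d1 / den


def compute_k(L2: float, alpha: float, F2i: float, F2u: float) -> float:
    """Scale constant k = L2 / (alpha * (F2i - F2u)), mm/Hz."""
    den = alpha * (F2i - F2u)
    if den == 0:
        raise ValueError("alpha * (F2i - F2u) must be nonzero")
    return L2 / den


def transfer_coefficients(alpha: float, k: float) -> tuple[float, float]:
    """(c1, c2) = (k*(1-alpha), k*alpha); their sum is k."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if not (k > 0):
        raise ValueError("k must be positive")
    return k * (1.0 - alpha), k * alpha


# ---------------------------------------------------------------------------
# track preparation


def interpolate_gaps(track: FormantTrack) -> FormantTrack:
    """Fill unvoiced gaps by linear interpolation; trim edge gaps.

    Missing formants during unvoiced segments are treated as a movement
    between the neighbouring voiced positions.  Leading/trailing unvoiced
    frames cannot be interpolated and are dropped.
    """
    voiced_idx = np.flatnonzero(track.voiced)
    if voiced_idx.size == 0:
        raise ValueError("track is entirely unvoiced")
    lo, hi = voiced_idx[0], voiced_idx[-1]
    t = track.t[lo : hi + 1]
    voiced = track.voiced[lo : hi + 1]
    F1 = track.F1[lo : hi + 1].copy()
    F2 = track.F2[lo : hi + 1].copy()
    if not np.all(voiced):
        tv = t[voiced]
        F1[~voiced] = np.interp(t[~voiced], tv, F1[voiced])
        F2[~voiced] = np.interp(t[~voiced], tv, F2[voiced])
    return FormantTrack(t=t, F1=F1, F2=F2, voiced=np.ones_like(voiced, dtype=bool))


def resample_track(track: FormantTrack, dt: float = DEFAULT_DT) -> FormantTrack:
    """Linearly resample a gap-free track to a uniform step (default 10 ms)."""
    if not track.fully_voiced:
        raise ValueError("interpolate gaps before resampling")
    n = max(2, int(math.floor((track.t[-1] - track.t[0]) / dt)) + 1)
    t_new = track.t[0] + dt * np.arange(n)
    F1 = np.interp(t_new, track.t, track.F1)
    F2 = np.interp(t_new, track.t, track.F2)
    return FormantTrack(t=t_new, F1=F1, F2=F2)


# ---------------------------------------------------------------------------
# mapping and kinematics


def formants_to_trajectory(
    track: FormantTrack, params: KinematicMapParams
) -> SampledSignal:
    """Planar trajectory x = c2*F2, y = c1*F1, shifted to start at the origin.

    Initial conditions are irrelevant to the lognormal analysis, so the
    track's first mapped point is subtracted.
    """
    if not track.fully_voiced:
        raise ValueError("interpolate gaps before mapping")
    dt = track.dt
    x = params.c2 * track.F2
    y = params.c1 * track.F1
    xy = np.column_stack([x - x[0], y - y[0]])
    return SampledSignal(float(track.t[0]), dt, xy)


def _lowpass(y: np.ndarray, dt: float, cutoff_hz: float) -> np.ndarray:
    nyq = 0.5 / dt
    b, a = butter(4, min(cutoff_hz / nyq, 0.99))
    return filtfilt(b, a, y, axis=0)


def kinematic_speed(
    source: FormantTrack | SampledSignal,
    params: KinematicMapParams | None = None,
    smooth: bool = False,
    cutoff_hz: float = 15.0,
) -> SampledSignal:
    """Planar velocity (and speed via ``.speed()``) of the mapped movement.

    Accepts either a gap-free formant track (mapped on the fly) or an
    already-mapped planar trajectory.  Differentiation is by central
    differences with one-sided differences at the edges.  Optional zero-phase
    low-pass smoothing (articulatory band, default 15 Hz) is applied to the
    position signal before differentiation; off by default.
    """
    if isinstance(source, FormantTrack):
        if params is None:
            raise ValueError("params required when mapping a formant track")
        traj = formants_to_trajectory(source, params)
    else:
        traj = source
        if not traj.is_planar:
            raise ValueError("trajectory signal must be planar")
    if traj.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    xy = traj.samples
    if smooth:
        xy = _lowpass(xy, traj.dt, cutoff_hz)
    v = np.gradient(xy, traj.dt, axis=0)
    return SampledSignal(traj.t_start, traj.dt, v)


def anchors_from_track(
    track: FormantTrack, lo_pct: float = 5.0, hi_pct: float = 95.0
) -> VowelAnchors:
    """Heuristic per-track anchors from formant extrema percentiles.

    /a/ takes the high-F1 extreme, /i/ the low-F1 / high-F2 corner, /u/ the
    low-F2 extreme.  A fallback when no vowel inventory is available; not
    used unless explicitly requested.
    """
    F1 = track.F1[track.voiced]
    F2 = track.F2[track.voiced]
    if F1.size == 0:
        raise ValueError("track has no voiced frames")
    return VowelAnchors(
        F1a=float(np.percentile(F1, hi_pct)),
        F1i=float(np.percentile(F1, lo_pct)),
        F2i=float(np.percentile(F2, hi_pct)),
        F2u=float(np.percentile(F2, lo_pct)),
    )


# ---------------------------------------------------------------------------
# estimator facade


class FormantKinematicMapper(BaseEstimator, TransformerMixin):
    """Transformer from formant tracks to kinematic trajectories/velocities.

    Parameters
    ----------
    alpha, k : float
        Map proportion and scale; used unless ``anchors`` is given.
    anchors : VowelAnchors, str, or "auto", optional
        Vowel-triangle anchors (or a named set from ``VOWEL_ANCHOR_SETS``)
        from which alpha and k are derived; ``"auto"`` estimates per-track
        anchors from formant percentiles during ``fit``.
    L2 : float
        Target /i/-/u/ kinematic distance (mm) used with anchors.
    dt : float
        Resampling step, s.
    smooth : bool
        Zero-phase low-pass the trajectory before differentiation.

    Attributes
    ----------
    params_ : KinematicMapParams
        The resolved map after ``fit``.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        k: float = DEFAULT_K,
        anchors: VowelAnchors | str | None = None,
        L2: float = 16.0,
        dt: float = DEFAULT_DT,
        smooth: bool = False,
        cutoff_hz: float = 15.0,
    ) -> None:
        self.alpha = alpha
        self.k = k
        self.anchors = anchors
        self.L2 = L2
        self.dt = dt
        self.smooth = smooth
        self.cutoff_hz = cutoff_hz

    def fit(self, X: FormantTrack | None = None, y=None) -> "FormantKinematicMapper":
        anchors = self.anchors
        if isinstance(anchors, str) and anchors != "auto":
            anchors = VOWEL_ANCHOR_SETS[anchors]
        if anchors == "auto":
            if X is None:
                raise ValueError("anchors='auto' requires a track at fit time")
            anchors = anchors_from_track(self._prepare(X))
        if anchors is None:
            self.params_ = KinematicMapParams(alpha=self.alpha, k=self.k)
        else:
            self.params_ = KinematicMapParams.from_anchors(anchors, L2=self.L2)
        return self

    def _prepare(self, track: FormantTrack) -> FormantTrack:
        return resample_track(interpolate_gaps(track), dt=self.dt)

    def transform(self, X: FormantTrack) -> SampledSignal:
        """Map a formant track to a planar trajectory (origin-anchored)."""
        if not hasattr(self, "params_"):
            self.fit(X)
        return formants_to_trajectory(self._prepare(X), self.params_)

    def velocity(self, X: FormantTrack) -> SampledSignal:
        """Planar velocity of the mapped movement."""
        return kinematic_speed(
            self.transform(X), smooth=self.smooth, cutoff_hz=self.cutoff_hz
        )
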