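"""Synthetic study material: sound maps, action plans, formant tracks.

The generator emulates the forward picture of speech production used by the
kinematic analysis: a speaker's repertoire of simple sounds occupies sites
on a hexagonal (triangular) lattice bounded by the /a/-/i/-/u/ vowel
triangle in kinematic space; an utterance is a walk over adjacent sites;
each hop is one lognormal stroke; and the resulting trajectory is pushed
through the inverse acoustic map (F1 = y/c1, F2 = x/c2, plus offsets that
place the tracks in a plausible formant band).  Optional additive Gaussian
noise and unvoiced gaps emulate measurement imperfections.  A phoneme-style
segmentation aligned with the strokes is produced alongside, with abstract
sound labels.

Everything is deterministic under a fixed seed, so the whole pipeline can be
exercised without any external corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formant_map import FormantTrack, KinematicMapParams
from .evaluate import PhonemeSegmentation
from .model import (
    ActionPlan,
    LognormalStroke,
    lognormal_support,
    plan_timebase,
    synthesize_trajectory,
)

__all__ = ["SoundMap", "SynthConfig", "sample_action_plan", "plan_to_formant_track"]


@dataclass(frozen=True)
class SoundMap:
    """Labeled sites on a triangular lattice inside the vowel triangle.

    Corners: /u/ at the origin, /i/ at (L2, 0), /a/ at the apex — x grows
    with F2 and y with F1, so /a/ (high F1) sits at the largest y.  The
    lattice subdivides the equilateral triangle with the given spacing.
    """

    L2: float
    spacing: float
    labels: tuple[str, ...]
    sites: np.ndarray = field(repr=False)  # (n_sites, 2), mm

    @classmethod
    def hexagonal(cls, L2: float = 16.0, spacing: float | None = None) -> "SoundMap":
        """Build the default lattice; spacing defaults to L2/4."""
        if spacing is None:
            spacing = L2 / 4.0
        n_div = int(round(L2 / spacing))
        if n_div < 1 or abs(n_div * spacing - L2) > 1e-9 * max(L2, 1.0):
            raise ValueError("spacing must divide L2 into a whole number of steps")
        e1 = np.array([1.0, 0.0]) * spacing
        e2 = np.array([0.5, math.sqrt(3.0) / 2.0]) * spacing
        pts, labels = [], []
        for j in range(n_div + 1):
            for i in range(n_div + 1 - j):
                pts.append(i * e1 + j * e2)
                labels.append(f"s{j}_{i}")
        return cls(
            L2=float(L2),
            spacing=float(spacing),
            labels=tuple(labels),
            sites=np.asarray(pts),
        )

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def corners(self) -> dict[str, np.ndarray]:
        """The /u/, /i/, /a/ corner positions."""
        h = math.sqrt(3.0) / 2.0 * self.L2
        return {
            "u": np.array([0.0, 0.0]),
            "i": np.array([self.L2, 0.0]),
            "a": np.array([self.L2 / 2.0, h]),
        }

    def neighbors(self, index: int) -> list[int]:
        """Indices of sites one lattice step away."""
        d = np.linalg.norm(self.sites - self.sites[index], axis=1)
        close = np.flatnonzero(np.abs(d - self.spacing) < 1e-9 * self.spacing)
        return [int(i) for i in close]


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic utterances.

    Defaults mirror the ranges observed for fluent adult speech: lognormal
    log-delay mu in [-1.9, -1.2] and log-response-time sigma in [0.05, 0.3],
    inter-command gaps of 60-120 ms, a 10 ms sampling step, and the
    alpha=0.3, k=0.04 mm/Hz acoustic map.
    """

    n_strokes: int = 5
    dt0_range: tuple[float, float] = (0.06, 0.12)
    mu_range: tuple[float, float] = (-1.9, -1.2)
    sigma_range: tuple[float, float] = (0.05, 0.3)
    noise_snr: float | None = None  # dB; None = noiseless
    gap_fraction: float = 0.0  # fraction of frames made unvoiced
    seed: int = 0
    dt: float = 0.01
    t0_first: float = 0.1
    f1_floor: float = 300.0  # Hz; tracks are offset so min(F1) hits this
    f2_floor: float = 800.0

    def __post_init__(self) -> None:
        for name in ("dt0_range", "mu_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be a non-empty (lo, hi) range")
        if not (0.0 <= self.gap_fraction < 0.5):
            raise ValueError("gap_fraction must lie in [0, 0.5)")
        if self.n_strokes < 1:
            raise ValueError("n_strokes must be >= 1")


def sample_action_plan(
    sound_map: SoundMap, config: SynthConfig = SynthConfig()
) -> tuple[ActionPlan, list[str]]:
    """Random walk over adjacent sites -> one straight stroke per hop.

    Each hop contributes a stroke with D equal to the hop distance, both
    angles along the hop direction, t0 gaps drawn uniformly from
    ``dt0_range`` and (mu, sigma) from their configured ranges.  Returns the
    plan and the visited target-site labels (one per stroke).
    """
    rng = np.random.default_rng(config.seed)
    current = int(rng.integers(sound_map.n_sites))
    if not sound_map.neighbors(current):
        raise ValueError("sound map has no adjacent sites to walk over")
    vtp0 = tuple(sound_map.sites[current])
    strokes: list[LognormalStroke] = []
    labels: list[str] = []
    t0 = config.t0_first
    for _ in range(config.n_strokes):
        nbrs = sound_map.neighbors(current)
        nxt = int(rng.choice(nbrs))
        hop = sound_map.sites[nxt] - sound_map.sites[current]
        theta = math.atan2(hop[1], hop[0])
        strokes.append(
            LognormalStroke(
                D=float(np.linalg.norm(hop)),
                t0=t0,
                mu=float(rng.uniform(*config.mu_range)),
                sigma=float(rng.uniform(*config.sigma_range)),
                theta_s=theta,
                theta_e=theta,
            )
        )
        labels.append(sound_map.labels[nxt])
        t0 += float(rng.uniform(*config.dt0_range))
        current = nxt
    return ActionPlan(strokes, vtp0=vtp0), labels


def _aligned_segmentation(
    plan: ActionPlan, labels: list[str] | None
) -> PhonemeSegmentation:
    """Intervals spanning successive strokes, boundaries at speed peaks.

    Interior boundaries sit exactly at the stroke peak times (in temporal
    order, which can differ from command order when the neuromuscular
    delays shuffle the modes), so the segmentation's transitions coincide
    with speed peaks and every interval overlaps a stroke's support.
    """
    strokes = plan.strokes
    n = len(strokes)
    if labels is None:
        labels = [f"s{j}" for j in range(1, n + 1)]
    peaks = sorted(s.peak_time for s in strokes)
    bounds = [min(lognormal_support(s)[0] for s in strokes)]
    bounds += peaks[1:]
    bounds.append(max(lognormal_support(s)[1] for s in strokes))
    ivs = [
        (labels[j], bounds[j], bounds[j + 1])
        for j in range(n)
        if bounds[j + 1] > bounds[j] + 1e-12
    ]
    return PhonemeSegmentation(ivs)


def plan_to_formant_track(
    plan: ActionPlan,
    params: KinematicMapParams = KinematicMapParams(),
    config: SynthConfig = SynthConfig(),
    labels: list[str] | None = None,
) -> tuple[FormantTrack, PhonemeSegmentation]:
    """Synthesize a formant track (and aligned segmentation) from a plan.

    The plan's trajectory is mapped back through the inverse acoustic map:
    F1 = y/c1 + offset, F2 = x/c2 + offset, the offsets placing the minima
    at ``f1_floor`` / ``f2_floor``.  Optional additive white Gaussian noise
    at ``noise_snr`` dB (relative to each track's excursion power) and a
    contiguous interior unvoiced gap covering ``gap_fraction`` of the frames.
    """
    if params.c1 <= 0 or params.c2 <= 0:
        raise ValueError("both transfer coefficients must be positive")
    if len(plan) == 0:
        raise ValueError("empty plan")
    rng = np.random.default_rng(config.seed + 1)
    timebase = plan_timebase(plan, dt=config.dt)
    traj = synthesize_trajectory(plan, timebase)
    F1 = traj.samples[:, 1] / params.c1
    F2 = traj.samples[:, 0] / params.c2
    F1 = F1 - F1.min() + config.f1_floor
    F2 = F2 - F2.min() + config.f2_floor
    if config.noise_snr is not None:
        for F in (F1, F2):
            power = float(np.mean((F - F.mean()) ** 2))
            sd = math.sqrt(power / 10.0 ** (config.noise_snr / 10.0))
            F += rng.normal(0.0, sd, size=F.size)
    if np.any(F1 <= 0) or np.any(F2 <= 0):
        raise ValueError("offsets produced non-positive formants")
    n = F1.size
    voiced = np.ones(n, dtype=bool)
    if config.gap_fraction > 0:
        gap_len = int(round(config.gap_fraction * n))
        if gap_len >= 1 and n - gap_len >= 2:
            start = int(rng.integers(1, n - gap_len))
            voiced[start : start + gap_len] = False
    F1 = np.where(voiced, F1, np.nan)
    F2 = np.where(voiced, F2, np.nan)
    track = FormantTrack(t=timebase.t, F1=F1, F2=F2, voiced=voiced)
    return track, _aligned_segmentation(plan, labels)
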