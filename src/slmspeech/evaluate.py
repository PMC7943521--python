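"""Derived neuromotor parameters and lognormal-phoneme evaluation.

Two kinds of summaries are computed from an extracted stroke sequence:

* aggregate neuromotor parameters — mean inter-command time, mean peak
  speed, mean log time delay / response time, mean stroke amplitude — the
  quantities that shift with neuromotor aging;
* the correspondence between lognormal strokes and a phoneme segmentation:
  per-phoneme TP/FP/FN/TN counts based on overlap between phoneme intervals
  and stroke supports (bounds at 5% of each stroke's peak), sentence-level
  TPR/TNR, and the RMS timing error between speed-peak times and phoneme
  transitions.

The mean formulas are implemented literally as printed in the source model
(sums over j>=2 for the inter-command time and the peak speed, with NbLog —
not NbLog-1 — in the denominator); ``conventional_means=True`` switches to
the conventional mean over the available terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import LognormalStroke, lognormal_support

__all__ = [
    "PhonemeSegmentation",
    "DerivedParams",
    "MatchReport",
    "derived_parameters",
    "match_phonemes",
    "timing_error",
    "group_compare",
    "lognormal_support",
]


@dataclass(frozen=True)
class PhonemeSegmentation:
    """Time-ordered, non-overlapping labeled intervals [t_start, t_end)."""

    intervals: tuple[tuple[str, float, float], ...]

    def __init__(self, intervals: Sequence[tuple[str, float, float]]) -> None:
        ivs = sorted(
            ((str(l), float(a), float(b)) for l, a, b in intervals),
            key=lambda iv: iv[1],
        )
        for label, a, b in ivs:
            if not a < b:
                raise ValueError(f"interval {label!r} has t_start >= t_end")
        for (l1, a1, b1), (l2, a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1 - 1e-12:
                raise ValueError(f"intervals {l1!r} and {l2!r} overlap")
        object.__setattr__(self, "intervals", tuple(ivs))

    @property
    def n_phonemes(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return [iv[0] for iv in self.intervals]

    def transitions(self) -> np.ndarray:
        """Interior boundaries between consecutive phonemes (n_phonemes - 1)."""
        return np.asarray([iv[1] for iv in self.intervals[1:]], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["label", "t_start", "t_end"])


@dataclass(frozen=True)
class DerivedParams:
    """Aggregate neuromotor parameters of a stroke sequence."""

    mean_dt0: float  # mean time between successive commands, s
    mean_vp: float  # mean per-stroke peak speed, mm/s
    mean_mu: float  # mean log time delay
    mean_sigma: float  # mean log response time
    mean_D: float  # mean stroke amplitude, mm
    nblog: int
    snr: float  # reconstruction SNR, dB
    short_sequence: bool = False  # True when nblog < 2 made some sums empty

    def as_dict(self) -> dict:
        d = {
            "mean_dt0": self.mean_dt0,
            "mean_vp": self.mean_vp,
            "mean_mu": self.mean_mu,
            "mean_sigma": self.mean_sigma,
            "mean_D": self.mean_D,
            "nblog": self.nblog,
            "snr": None if not math.isfinite(self.snr) else self.snr,
            "short_sequence": self.short_sequence,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def derived_parameters(
    strokes: Sequence[LognormalStroke],
    snr: float = float("nan"),
    conventional_means: bool = False,
) -> DerivedParams:
    """Aggregate parameters of a time-ordered stroke sequence.

    With the literal formulas (default), the inter-command time and peak
    speed sums start at the second stroke but are divided by NbLog; with
    ``conventional_means`` they are divided by the number of summed terms
    (NbLog - 1), and the peak-speed sum starts at the first stroke.
    """
    n = len(strokes)
    if n == 0:
        return DerivedParams(
            math.nan, math.nan, math.nan, math.nan, math.nan, 0, snr, True
        )
    t0 = np.asarray([s.t0 for s in strokes])
    if np.any(np.diff(t0) < 0):
        raise ValueError("strokes must be time-ordered")
    vp = np.asarray([s.peak_speed for s in strokes])
    mu = np.asarray([s.mu for s in strokes])
    sg = np.asarray([s.sigma for s in strokes])
    D = np.asarray([abs(s.D) for s in strokes])

    gaps = np.diff(t0)  # t0_j - t0_(j-1), j = 2..NbLog
    if conventional_means:
        mean_dt0 = float(gaps.mean()) if n >= 2 else 0.0
        mean_vp = float(vp.mean())
    else:
        mean_dt0 = float(gaps.sum() / n)
        mean_vp = float(vp[1:].sum() / n)
    return DerivedParams(
        mean_dt0=mean_dt0,
        mean_vp=mean_vp,
        mean_mu=float(mu.mean()),
        mean_sigma=float(sg.mean()),
        mean_D=float(D.mean()),
        nblog=n,
        snr=snr,
        short_sequence=n < 2,
    )


# ---------------------------------------------------------------------------
# lognormal-phoneme matching


@dataclass(frozen=True)
class MatchReport:
    """Per-phoneme TP/FP/FN/TN counts and sentence-level rates.

    For each phoneme, any stroke whose 5%-of-peak support intersects the
    phoneme interval counts as overlapping; one overlapping stroke (the one
    whose speed peak is nearest the phoneme midpoint) is the assigned TP,
    the remainder are FPs, non-overlapping strokes are TNs, and a phoneme
    with no overlap scores an FN.  TNR uses the printed NbLog - 1
    denominator and may exceed 1; ``tnr_exceeds_one`` flags that instead of
    clipping.
    """

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    assigned: tuple[int | None, ...]  # index of the TP stroke per phoneme
    tpr: float
    tnr: float
    nblog: int
    n_phonemes: int
    eps_t: float = math.nan
    tnr_exceeds_one: bool = False
    tnr_undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
                "assigned_stroke": [a if a is not None else -1 for a in self.assigned],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "tpr": self.tpr,
                "tnr": None if math.isnan(self.tnr) else self.tnr,
                "eps_t": None if math.isnan(self.eps_t) else self.eps_t,
                "nblog": self.nblog,
                "n_phonemes": self.n_phonemes,
                "tnr_exceeds_one": self.tnr_exceeds_one,
                "tnr_undefined": self.tnr_undefined,
                "per_phoneme": self.to_frame().to_dict(orient="list"),
            },
            indent=2,
        )


def match_phonemes(
    strokes: Sequence[LognormalStroke],
    seg: PhonemeSegmentation,
    level: float = 0.05,
    with_timing: bool = True,
) -> MatchReport:
    """Match lognormal strokes to phonemes by support overlap."""
    n_log = len(strokes)
    n_p = seg.n_phonemes
    if n_log < 1 or n_p < 1:
        raise ValueError("need at least one stroke and one phoneme")
    supports = [lognormal_support(s, level) for s in strokes]
    peaks = np.asarray([s.peak_time for s in strokes])

    tp = np.zeros(n_p, dtype=int)
    fp = np.zeros(n_p, dtype=int)
    fn = np.zeros(n_p, dtype=int)
    tn = np.zeros(n_p, dtype=int)
    assigned: list[int | None] = []
    for i, (_, a, b) in enumerate(seg.intervals):
        overlapping = [
            j for j, (lo, hi) in enumerate(supports) if lo < b and hi > a
        ]
        if not overlapping:
            fn[i] = 1
            tn[i] = n_log
            assigned.append(None)
            continue
        mid = 0.5 * (a + b)
        best = min(overlapping, key=lambda j: abs(peaks[j] - mid))
        assigned.append(best)
        tp[i] = 1
        fp[i] = len(overlapping) - 1
        tn[i] = n_log - len(overlapping)

    tpr = float(tp.sum() / n_p)
    tnr_undefined = n_log == 1
    tnr = math.nan if tnr_undefined else float(tn.sum() / (n_log - 1))
    eps = math.nan
    if with_timing and n_p >= 2:
        eps = timing_error(peaks, seg.transitions())
    return MatchReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        assigned=tuple(assigned),
        tpr=tpr,
        tnr=tnr,
        nblog=n_log,
        n_phonemes=n_p,
        eps_t=eps,
        tnr_exceeds_one=(not tnr_undefined) and tnr > 1.0,
        tnr_undefined=tnr_undefined,
    )


def timing_error(
    peak_times: Sequence[float], transitions: Sequence[float]
) -> float:
    """RMS discrepancy between phoneme transitions and speed-peak times.

    Each transition is paired with the nearest peak time; the error is the
    root mean square of the paired differences over the pairs formed.
    """
    peaks = np.asarray(peak_times, dtype=float)
    trans = np.asarray(transitions, dtype=float)
    if peaks.size == 0 or trans.size == 0:
        raise ValueError("peak_times and transitions must be non-empty")
    diffs = trans[:, None] - peaks[None, :]
    nearest = np.take_along_axis(
        diffs, np.argmin(np.abs(diffs), axis=1)[:, None], axis=1
    ).ravel()
    return float(np.sqrt(np.mean(nearest**2)))


# ---------------------------------------------------------------------------
# group statistics


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    alpha_level: float = 0.05,
) -> dict:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise tests.

    Returns a dict with the overall F statistic and p value, and for each
    unordered pair of groups the raw and Bonferroni-adjusted p value
    (raw p times the number of pairs, capped at 1) with a significance flag
    at the given threshold.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        if np.ptp(v) == 0:
            raise ValueError(f"group {name!r} has zero variance")
    def _anova(*samples) -> tuple[float, float]:
        f, p = stats.f_oneway(*samples)
        # floating cancellation can leave a tiny negative F (and a NaN p)
        # when group means coincide exactly; clamp to the F = 0, p = 1 limit
        if not math.isfinite(p):
            f = max(float(f), 0.0)
            n_tot = sum(s.size for s in samples)
            p = float(stats.f.sf(f, len(samples) - 1, n_tot - len(samples)))
        return float(f), float(p)

    f_stat, p_value = _anova(*groups.values())
    names = list(groups)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        _, p_raw = _anova(groups[a], groups[b])
        p_adj = min(1.0, float(p_raw) * m)
        pairwise[f"{a} vs {b}"] = {
            "p_raw": float(p_raw),
            "p_bonferroni": p_adj,
            "significant": bool(p_adj < alpha_level),
        }
    return {
        "f_statistic": float(f_stat),
        "p_value": float(p_value),
        "alpha_level": alpha_level,
        "significant": bool(p_value < alpha_level),
        "pairwise": pairwise,
    }
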