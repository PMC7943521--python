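"""File readers and writers.

Formats handled:

* formant tracks — comma-separated text with header ``time_s,F1_Hz,F2_Hz``
  (empty/NaN fields mark unvoiced frames), and Praat "Formant" objects in
  short text format (frames with fewer than two formants become unvoiced);
* phoneme segmentations — Praat TextGrid interval tiers (long text format)
  and CSV with header ``label,t_start,t_end``;
* stroke tables — CSV, one row per lognormal;
* action plans and reports — JSON.

All delimited text is UTF-8, comma-separated, '.' decimal.  Time stamps are
seconds; phoneme intervals are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import PhonemeSegmentation
from .extract import ExtractionResult
from .formant_map import FormantTrack
from .model import ActionPlan, LognormalStroke, SampledSignal

__all__ = [
    "read_formant_track",
    "write_formant_track",
    "read_praat_formant",
    "read_segmentation",
    "write_textgrid",
    "read_strokes",
    "write_strokes",
    "read_signal",
    "write_signal",
    "read_plan",
    "write_plan",
]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# formant tracks


def read_formant_track(path, format: str = "auto") -> FormantTrack:
    """Read a formant track from CSV or Praat Formant (short text).

    ``format='auto'`` sniffs the Praat header, falling back to CSV.
    """
    path = Path(path)
    if format == "auto":
        with open(path, encoding="utf-8") as fh:
            head = fh.read(64)
        format = "praat" if "ooTextFile" in head else "csv"
    if format == "praat":
        return read_praat_formant(path)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    required = {"time_s", "F1_Hz", "F2_Hz"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(float)
    F1 = df["F1_Hz"].to_numpy(float)
    F2 = df["F2_Hz"].to_numpy(float)
    for i, row_t in enumerate(t):
        if not math.isfinite(row_t):
            raise ParseError(f"{path}: non-finite time at data row {i + 1}")
    return FormantTrack(t=t, F1=F1, F2=F2)


def write_formant_track(track: FormantTrack, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": track.t,
            "F1_Hz": np.where(track.voiced, track.F1, np.nan),
            "F2_Hz": np.where(track.voiced, track.F2, np.nan),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _praat_tokens(text: str) -> list[str]:
    # short text format: one bare value per line after the two header lines
    tokens = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        # long-format lines carry "name = value"; keep the value part
        if "=" in line:
            line = line.split("=", 1)[1].strip()
        tokens.extend(line.replace('"', " ").split())
    return tokens


def read_praat_formant(path) -> FormantTrack:
    """Read a Praat Formant object (short or long text format).

    Keeps the first two formants of each frame; frames reporting fewer than
    two formants are marked unvoiced.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if "ooTextFile" not in text or "Formant" not in text:
        raise ParseError(f"{path}: not a Praat Formant text file")
    body = text.split("\n", 2)[2] if text.count("\n") >= 2 else ""
    toks = [
        tok
        for tok in _praat_tokens(body)
        if re.fullmatch(r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?", tok)
    ]
    try:
        pos = 0

        def take() -> float:
            nonlocal pos
            v = float(toks[pos])
            pos += 1
            return v

        _xmin, _xmax = take(), take()
        nx = int(take())
        dx, x1 = take(), take()
        _max_n_formants = take()
        t = x1 + dx * np.arange(nx)
        F1 = np.full(nx, np.nan)
        F2 = np.full(nx, np.nan)
        for i in range(nx):
            _intensity = take()
            n_formants = int(take())
            freqs = []
            for _ in range(n_formants):
                f, _bw = take(), take()
                freqs.append(f)
            if len(freqs) >= 2 and freqs[0] > 0 and freqs[1] > 0:
                F1[i], F2[i] = freqs[0], freqs[1]
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: truncated or malformed Formant data") from exc
    return FormantTrack(t=t, F1=F1, F2=F2)


# ---------------------------------------------------------------------------
# segmentations


def read_segmentation(path, format: str = "auto", tier: str | None = None) -> PhonemeSegmentation:
    """Read a phoneme segmentation from a TextGrid or CSV file."""
    path = Path(path)
    if format == "auto":
        with open(path, encoding="utf-8") as fh:
            head = fh.read(64)
        format = "textgrid" if "ooTextFile" in head else "csv"
    if format == "textgrid":
        return _read_textgrid(path, tier)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    required = {"label", "t_start", "t_end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return PhonemeSegmentation(
        [(r.label, r.t_start, r.t_end) for r in df.itertuples()]
    )


_TG_INTERVAL = re.compile(
    r"intervals\s*\[\d+\]\s*:?\s*"
    r"xmin\s*=\s*([\d.eE+-]+)\s*"
    r"xmax\s*=\s*([\d.eE+-]+)\s*"
    r'text\s*=\s*"((?:[^"]|"")*)"',
)
_TG_TIER = re.compile(r'class\s*=\s*"(IntervalTier|TextTier)"\s*name\s*=\s*"([^"]*)"')


def _read_textgrid(path: Path, tier: str | None) -> PhonemeSegmentation:
    text = path.read_text(encoding="utf-8")
    if "TextGrid" not in text:
        raise ParseError(f"{path}: not a TextGrid file")
    tiers = list(_TG_TIER.finditer(text))
    if not tiers:
        raise ParseError(f"{path}: no tiers found (only long text format is supported)")
    chosen = None
    for i, m in enumerate(tiers):
        if m.group(1) != "IntervalTier":
            continue
        if tier is None or m.group(2) == tier:
            chosen = (m, tiers[i + 1].start() if i + 1 < len(tiers) else len(text))
            break
    if chosen is None:
        raise ParseError(f"{path}: interval tier {tier!r} not found")
    block = text[chosen[0].start() : chosen[1]]
    intervals = []
    for m in _TG_INTERVAL.finditer(block):
        label = m.group(3).replace('""', '"')
        if label.strip():
            intervals.append((label, float(m.group(1)), float(m.group(2))))
    if not intervals:
        raise ParseError(f"{path}: tier has no labeled intervals")
    return PhonemeSegmentation(intervals)


def write_textgrid(
    seg: PhonemeSegmentation, path, tier_name: str = "sounds"
) -> None:
    """Write a single-interval-tier TextGrid (long text format).

    Gaps between labeled intervals are filled with empty-text intervals so
    the tier is contiguous, as the format requires.
    """
    ivs = seg.intervals
    xmin = ivs[0][1]
    xmax = ivs[-1][2]
    full: list[tuple[str, float, float]] = []
    cursor = xmin
    for label, a, b in ivs:
        if a > cursor:
            full.append(("", cursor, a))
        full.append((label, a, b))
        cursor = b
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.10g}",
        f"xmax = {xmax:.10g}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        f"        xmin = {xmin:.10g}",
        f"        xmax = {xmax:.10g}",
        f"        intervals: size = {len(full)}",
    ]
    for i, (label, a, b) in enumerate(full, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.10g}",
            f"            xmax = {b:.10g}",
            f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# strokes, signals, plans


def write_strokes(result_or_strokes, path) -> None:
    """Write a stroke table (one row per lognormal) as CSV."""
    if isinstance(result_or_strokes, ExtractionResult):
        df = result_or_strokes.to_table()
    else:
        from .model import lognormal_support

        rows = []
        for s in result_or_strokes:
            lo, hi = lognormal_support(s)
            rows.append(
                dict(s.as_dict(), peak_time=s.peak_time, peak_speed=s.peak_speed,
                     support_begin=lo, support_end=hi)
            )
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.12g")


def read_strokes(path) -> list[LognormalStroke]:
    df = pd.read_csv(path)
    required = {"D", "t0", "mu", "sigma", "theta_s", "theta_e"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        LognormalStroke(
            D=r.D, t0=r.t0, mu=r.mu, sigma=r.sigma,
            theta_s=r.theta_s, theta_e=r.theta_e,
        )
        for r in df.itertuples()
    ]


def write_signal(signal: SampledSignal, path, names: tuple[str, ...] | None = None) -> None:
    """Write a sampled signal as CSV: time plus one column per channel."""
    data = {"time_s": signal.t}
    samples = signal.samples if signal.is_planar else signal.samples[:, None]
    if names is None:
        names = ("x", "y") if signal.is_planar else ("value",)
    for i, name in enumerate(names[: samples.shape[1]]):
        data[name] = samples[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_signal(path) -> SampledSignal:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ParseError(f"{path}: expected a time_s column plus channels")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ParseError(f"{path}: time base is not uniform")
    channels = df.drop(columns="time_s").to_numpy(float)
    samples = channels[:, 0] if channels.shape[1] == 1 else channels[:, :2]
    return SampledSignal(float(t[0]), float(steps[0]), samples)


def write_plan(plan: ActionPlan, path) -> None:
    Path(path).write_text(plan.to_json() + "\n", encoding="utf-8")


def read_plan(path) -> ActionPlan:
    return ActionPlan.from_json(Path(path).read_text(encoding="utf-8"))
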