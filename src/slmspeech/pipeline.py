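"""End-to-end analysis: formant track -> strokes -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

from .evaluate import PhonemeSegmentation, derived_parameters, match_phonemes
from .extract import ExtractionConfig, extract
from .formant_map import (
    DEFAULT_ALPHA,
    DEFAULT_DT,
    DEFAULT_K,
    FormantKinematicMapper,
    FormantTrack,
    VOWEL_ANCHOR_SETS,
)
from .synthetic import SynthConfig

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, fully serializable.

    ``anchors`` may name an entry of ``VOWEL_ANCHOR_SETS`` (alpha and k are
    then derived from the vowel triangle); otherwise the literal ``alpha``
    and ``k`` are used.
    """

    alpha: float = DEFAULT_ALPHA
    k: float = DEFAULT_K
    anchors: str | None = None
    L2: float = 16.0
    dt: float = DEFAULT_DT
    smooth: bool = False
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    conventional_means: bool = False
    support_level: float = 0.05
    synthesis: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.support_level < 1.0):
            raise ValueError("support_level must lie strictly in (0, 1)")
        if self.anchors is not None and self.anchors not in VOWEL_ANCHOR_SETS:
            raise ValueError(f"unknown anchor set {self.anchors!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        if "extraction" in obj and isinstance(obj["extraction"], dict):
            obj["extraction"] = ExtractionConfig(**obj["extraction"])
        if "synthesis" in obj and isinstance(obj["synthesis"], dict):
            syn = dict(obj["synthesis"])
            for key in ("dt0_range", "mu_range", "sigma_range"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            obj["synthesis"] = SynthConfig(**syn)
        return cls(**obj)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def mapper(self) -> FormantKinematicMapper:
        return FormantKinematicMapper(
            alpha=self.alpha,
            k=self.k,
            anchors=self.anchors,
            L2=self.L2,
            dt=self.dt,
            smooth=self.smooth,
        )


def run_pipeline(
    track: FormantTrack,
    segmentation: PhonemeSegmentation | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Analyze one formant track end to end and return a JSON-able report.

    Steps: gap interpolation and resampling, acoustic-to-kinematic mapping,
    lognormal extraction, derived neuromotor parameters, and (when a
    segmentation is supplied) lognormal-phoneme matching and timing error.
    """
    mapper = config.mapper().fit(track)
    velocity = mapper.velocity(track)
    result = extract(velocity, config.extraction)
    derived = derived_parameters(
        result.strokes, result.snr, conventional_means=config.conventional_means
    )
    report = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "alpha": mapper.params_.alpha,
        "k": mapper.params_.k,
        "nblog": result.nblog,
        "snr_db": None if math.isinf(result.snr) else result.snr,
        "converged": result.converged,
        "derived": derived.as_dict(),
        "strokes": [s.as_dict() for s in result.strokes],
    }
    if segmentation is not None and result.nblog >= 1:
        match = match_phonemes(
            result.strokes, segmentation, level=config.support_level
        )
        report["match"] = json.loads(match.to_json())
    logger.info(
        "pipeline: config=%s seed=%d nblog=%d snr=%.2f dB",
        report["config_hash"], config.seed, result.nblog, result.snr,
    )
    return report
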