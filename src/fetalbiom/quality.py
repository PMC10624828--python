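"""Quality scoring of candidate standard planes and best-frame selection.

Each candidate frame is scored by a composite of three terms:

* **Q** — mean of the plane's criterion probabilities (for the femoral
  plane, which has no criterion classifier, the angle-conformity
  indicator);
* **Z** — zoom conformity: the structure's area fraction of the image
  reaches the plane's threshold ("occupying more than half of total
  image" for head and abdomen);
* **C** — the backend's detection confidence.

``composite = (w_q*Q + w_z*Z + w_c*C) / (w_q + w_z + w_c)`` and the frame
with the highest composite wins, earliest frame on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigError
from .geometry import AxisMeasurement
from .imaging_io import LabelMask
from .segmentation import SegmentationInstance

#: Default minimum structure-to-image area fractions.  Head and abdomen use
#: the "more than half of total image" rule literally; a thin femur cannot
#: reach half the *area*, so its default is the fraction a well-zoomed
#: femur (span about half the image width) actually covers.
DEFAULT_ZOOM_THRESHOLDS = {"brain": 0.5, "abdomen": 0.5, "femur": 0.05}

DEFAULT_FEMUR_ANGLE_DEG = 45.0


@dataclass(frozen=True)
class ScoreWeights:
    """Nonnegative weights for the Q/Z/C composite; normalized at use."""

    w_quality: float = 1.0
    w_zoom: float = 1.0
    w_confidence: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_quality, self.w_zoom, self.w_confidence) < 0:
            raise ConfigError("score weights must be nonnegative")
        if self.total <= 0:
            raise ConfigError("score weights must not all be zero")

    @property
    def total(self) -> float:
        return self.w_quality + self.w_zoom + self.w_confidence


@dataclass(frozen=True)
class QualityAssessment:
    """Everything that went into one frame's composite score."""

    criterion_probs: dict[str, float] | None
    zoom_ratio: float
    zoom_conform: bool
    angle_conform: bool | None  # None for non-femoral planes
    confidence: float
    composite: float


def zoom_ratio(mask: LabelMask) -> float:
    """Fraction of image pixels covered by the structure."""
    total = mask.grid.size
    return mask.count / total if total else 0.0


def angle_conform(axis: AxisMeasurement, threshold_deg: float = DEFAULT_FEMUR_ANGLE_DEG) -> bool:
    """Femur angle criterion: strictly less than the threshold (default 45 deg)."""
    return abs(axis.angle_deg) < threshold_deg


def composite_score(
    criterion_probs: Mapping[str, float] | None,
    zoom_conform: bool,
    angle_ok: bool | None,
    confidence: float,
    weights: ScoreWeights = ScoreWeights(),
    *,
    raw_zoom: float | None = None,
) -> float:
    """Weighted Q/Z/C composite in [0, 1].

    ``raw_zoom`` switches the Z term from the binary conformity indicator
    to the raw area fraction (config option); the criterion as printed is
    binary, which is the default.
    """
    if criterion_probs is not None:
        vals = list(criterion_probs.values())
        q = sum(vals) / len(vals) if vals else 0.0
    elif angle_ok is not None:
        q = 1.0 if angle_ok else 0.0
    else:
        q = 0.0
    z = float(raw_zoom) if raw_zoom is not None else (1.0 if zoom_conform else 0.0)
    c = float(confidence)
    w = weights
    return (w.w_quality * q + w.w_zoom * z + w.w_confidence * c) / w.total


ScoredFrame = tuple[int, SegmentationInstance, QualityAssessment]


def select_best_frame(scored: Sequence[ScoredFrame]) -> Optional[ScoredFrame]:
    """Argmax of the composite score; earliest frame index on ties.

    Returns ``None`` for an empty candidate list (the no-plane-found
    outcome, which is reportable rather than an error).
    """
    best: Optional[ScoredFrame] = None
    for entry in scored:
        if best is None:
            best = entry
            continue
        if entry[2].composite > best[2].composite or (
            entry[2].composite == best[2].composite and entry[0] < best[0]
        ):
            best = entry
    return best
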