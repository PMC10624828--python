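"""Segmentation/classification backend contract and the phantom reference backend.

The pipeline is agnostic to where masks come from.  Any backend exposes two
functions: ``segment_frame`` (instances with confidences) and
``classify_criteria`` (per-criterion probabilities for head and abdomen
planes).  Trained networks attach through the same adapter; this package
ships only the *oracle* backend, which reads a phantom's planted label
grids — optionally degraded to emulate imperfect segmentation — so the
full pipeline runs without any model weights.

Confidence scores are opaque scalars in [0, 1]; scores from different
backends are not comparable with one another.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .errors import BackendUnavailableError, UnsupportedPlaneError
from .imaging_io import Frame, LabelMask

ABDOMEN_CRITERIA = ("A_KN", "A_PS", "A_SB", "A_SYM")
BRAIN_CRITERIA = ("B_CB", "B_CS", "B_PVV", "B_SYM", "B_TH")

CRITERIA_BY_LABEL: dict[str, tuple[str, ...]] = {
    "abdomen": ABDOMEN_CRITERIA,
    "brain": BRAIN_CRITERIA,
}

# loop kind -> anatomical label measured on that kind of loop
LABEL_FOR_KIND = {
    "cephalic": "brain",
    "abdominal": "abdomen",
    "femoral": "femur",
    "amniotic": "af_pocket",
}


@dataclass(frozen=True)
class SegmentationInstance:
    """One segmented structure on one frame, with a detection confidence."""

    mask: LabelMask
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        if self.mask.label != self.label:
            raise ValueError("instance label must match its mask label")


def validate_criterion_probs(label: str, probs: Mapping[str, float]) -> dict[str, float]:
    """Check that a probability map covers exactly the plane's criterion set."""
    expected = CRITERIA_BY_LABEL.get(label)
    if expected is None:
        raise UnsupportedPlaneError(f"no criterion vocabulary for label {label!r}")
    if set(probs) != set(expected):
        raise ValueError(
            f"criteria for {label!r} must be exactly {sorted(expected)}, "
            f"got {sorted(probs)}"
        )
    out = {}
    for code in expected:
        p = float(probs[code])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for {code} out of [0, 1]: {p}")
        out[code] = p
    return out


@runtime_checkable
class SegmentationBackend(Protocol):
    """The two-function adapter every segmenter/classifier must provide."""

    def segment_frame(self, frame: Frame, kind: str) -> list[SegmentationInstance]: ...

    def classify_criteria(
        self, frame: Frame, instance: SegmentationInstance
    ) -> dict[str, float]: ...


class PhantomBackend:
    """Oracle backend: returns a phantom's planted labels and flags.

    Parameters
    ----------
    frame_labels
        Per-frame lists of planted :class:`LabelMask` instances.
    frame_flags
        Per-frame criterion flag dicts (``code -> bool``).
    frame_confidences
        Per-frame planted detection confidence.
    degrade_px
        Maximum morphological degradation radius; each frame's masks are
        eroded or dilated (sign drawn per frame) by a radius in
        ``{0, ..., degrade_px}`` to emulate boundary error of a real
        segmenter.
    jitter_prob
        Probability of toggling each boundary pixel after the
        morphological step.
    seed
        Seed for the (deterministic) degradation draws.
    """

    def __init__(
        self,
        frame_labels: Sequence[Sequence[LabelMask]],
        frame_flags: Sequence[Mapping[str, bool]],
        frame_confidences: Sequence[float],
        *,
        degrade_px: int = 0,
        jitter_prob: float = 0.0,
        seed: int = 0,
    ) -> None:
        self._labels = [list(masks) for masks in frame_labels]
        self._flags = [dict(f) for f in frame_flags]
        self._confidences = [float(c) for c in frame_confidences]
        self.degrade_px = int(degrade_px)
        self.jitter_prob = float(jitter_prob)
        self.seed = int(seed)

    def _degrade(self, grid: np.ndarray, frame_index: int, inst_index: int) -> np.ndarray:
        if self.degrade_px <= 0 and self.jitter_prob <= 0:
            return grid
        rng = np.random.default_rng((self.seed, frame_index, inst_index))
        out = grid
        if self.degrade_px > 0:
            k = int(rng.integers(0, self.degrade_px + 1))
            if k > 0:
                yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
                selem = (yy * yy + xx * xx) <= k * k
                if rng.random() < 0.5:
                    out = ndimage.binary_erosion(out, structure=selem)
                else:
                    out = ndimage.binary_dilation(out, structure=selem)
        if self.jitter_prob > 0:
            boundary = out ^ ndimage.binary_erosion(out)
            outer = ndimage.binary_dilation(out) ^ out
            flips = (boundary | outer) & (
                rng.random(out.shape) < self.jitter_prob
            )
            out = out ^ flips
        return out

    def segment_frame(self, frame: Frame, kind: str) -> list[SegmentationInstance]:
        if frame.index >= len(self._labels):
            return []
        instances = []
        for j, planted in enumerate(self._labels[frame.index]):
            grid = self._degrade(planted.grid, frame.index, j)
            if not grid.any():
                continue
            instances.append(
                SegmentationInstance(
                    mask=LabelMask(grid, planted.label),
                    label=planted.label,
                    confidence=self._confidences[frame.index],
                )
            )
        return instances

    def classify_criteria(
        self, frame: Frame, instance: SegmentationInstance
    ) -> dict[str, float]:
        expected = CRITERIA_BY_LABEL.get(instance.label)
        if expected is None:
            raise UnsupportedPlaneError(
                f"plane {instance.label!r} has no criterion classifier"
            )
        flags = self._flags[frame.index] if frame.index < len(self._flags) else {}
        probs = {code: (1.0 if flags.get(code, False) else 0.0) for code in expected}
        return validate_criterion_probs(instance.label, probs)


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., SegmentationBackend]] = {}


def register_backend(name: str, factory: Callable[..., SegmentationBackend]) -> None:
    _REGISTRY[name] = factory


def get_backend(spec: str, *args, **kwargs) -> SegmentationBackend:
    """Resolve a backend by registered name or dotted path ``module:attr``."""
    if spec in _REGISTRY:
        return _REGISTRY[spec](*args, **kwargs)
    if ":" in spec:
        mod_name, _, attr = spec.partition(":")
        try:
            module = importlib.import_module(mod_name)
            factory = getattr(module, attr)
        except (ImportError, AttributeError) as exc:
            raise BackendUnavailableError(f"cannot load backend {spec!r}: {exc}") from exc
        return factory(*args, **kwargs)
    raise BackendUnavailableError(
        f"unknown backend {spec!r}; registered: {sorted(_REGISTRY)}"
    )
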