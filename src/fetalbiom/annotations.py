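"""Reconstruction of ground-truth measurements from annotated still images.

Archived ultrasound stills carry the operator's measurements burned into
the pixels: colored cross-glyph caliper pairs, a dotted measurement
ellipse, and a text block with the acronym and value.  This module
detects the overlay graphics (palette matching + glyph template gate),
rebuilds a mask from the dotted ellipse, and parses measurement text
emitted by any OCR engine (the engine itself is an external interface —
only its text lines enter here).

Vendor palettes vary; the defaults (saturated yellow / green / cyan /
magenta, per-channel tolerance 40) are configurable per call.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateFitError
from .geometry import EllipseParams, fit_ellipse_direct, px_to_cm
from .imaging_io import LabelMask

DEFAULT_PALETTE = (
    (255, 255, 0),  # yellow
    (0, 255, 0),    # green
    (0, 255, 255),  # cyan
    (255, 0, 255),  # magenta
)
DEFAULT_TOLERANCE = 40


@dataclass(frozen=True)
class CaliperMark:
    """A detected caliper glyph at sub-pixel centroid position."""

    position: tuple[float, float]  # (row, col)
    color: tuple[int, int, int]
    glyph: str  # "cross" or "x"


@dataclass(frozen=True)
class ParsedMeasurement:
    acronym: str
    value: float
    unit: str  # cm | mm | g | weeks_days

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("measurement value must be positive")


def _palette_mask(image: np.ndarray, palette, tolerance: int) -> np.ndarray:
    img = image.astype(np.int32)
    mask = np.zeros(image.shape[:2], dtype=bool)
    for color in palette:
        diff = np.abs(img[..., :3] - np.asarray(color, dtype=np.int32))
        mask |= (diff <= tolerance).all(axis=-1)
    return mask


def _glyph_template(size: int, glyph: str) -> np.ndarray:
    t = np.zeros((size, size), dtype=float)
    c = size // 2
    if glyph == "cross":
        t[c, :] = 1.0
        t[:, c] = 1.0
    else:  # "x"
        for i in range(size):
            t[i, i] = 1.0
            t[i, size - 1 - i] = 1.0
    return t


def _normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def detect_calipers(
    image: np.ndarray,
    palette=DEFAULT_PALETTE,
    tolerance: int = DEFAULT_TOLERANCE,
    *,
    corr_threshold: float = 0.6,
    min_size: int = 5,
    max_size: int = 400,
) -> list[CaliperMark]:
    """Detect cross/x caliper glyphs among palette-colored pixels.

    Connected components of palette-matched pixels whose shape correlates
    with a cross or x template above ``corr_threshold`` become marks at
    their pixel centroid.  Grayscale input yields an empty list.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        return []
    matched = _palette_mask(image, palette, tolerance)
    labeled, n = ndimage.label(matched, structure=np.ones((3, 3)))
    marks: list[CaliperMark] = []
    for idx in range(1, n + 1):
        comp = labeled == idx
        size = int(comp.sum())
        if not (min_size <= size <= max_size):
            continue
        rows, cols = np.nonzero(comp)
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        side = max(r1 - r0, c1 - c0) + 1
        if side < 3:
            continue
        if side % 2 == 0:
            side += 1
        patch = np.zeros((side, side), dtype=float)
        pr = rows - r0
        pc = cols - c0
        patch[pr, pc] = 1.0
        best_glyph, best_corr = None, 0.0
        for glyph in ("cross", "x"):
            corr = _normalized_correlation(patch, _glyph_template(side, glyph))
            if corr > best_corr:
                best_glyph, best_corr = glyph, corr
        if best_glyph is None or best_corr < corr_threshold:
            continue
        centroid = (float(rows.mean()), float(cols.mean()))
        color = tuple(int(v) for v in np.asarray(image[rows, cols, :3]).mean(axis=0).round())
        marks.append(CaliperMark(position=centroid, color=color, glyph=best_glyph))
    marks.sort(key=lambda m: m.position)
    return marks


def detect_dotted_ellipse(
    image: np.ndarray,
    palette=DEFAULT_PALETTE,
    tolerance: int = DEFAULT_TOLERANCE,
    *,
    max_dot_size: int = 25,
    outlier_px: float = 2.0,
) -> tuple[EllipseParams, LabelMask]:
    """Fit the dotted measurement ellipse burned into an annotated image.

    Dot-cluster centroids feed the direct least-squares fit; a single
    reject-and-refit round drops clusters farther than ``outlier_px``
    from the first fit (stray palette pixels, caliper fragments).  The
    returned mask is the filled fitted ellipse.
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise DegenerateFitError("need a color image to find palette dots")
    matched = _palette_mask(image, palette, tolerance)
    labeled, n = ndimage.label(matched, structure=np.ones((3, 3)))
    centroids = []
    for idx in range(1, n + 1):
        comp = labeled == idx
        if comp.sum() > max_dot_size:
            continue
        rows, cols = np.nonzero(comp)
        centroids.append((float(rows.mean()), float(cols.mean())))
    if len(centroids) < 5:
        raise DegenerateFitError(
            f"only {len(centroids)} dot clusters; need >= 5 for an ellipse"
        )
    pts = np.asarray(centroids)
    ell = fit_ellipse_direct(pts)
    residuals = _radial_residual_px(pts, ell)
    # one reject-refit round; a gross outlier distorts the first fit, so
    # the cut adapts to the residual scale it induces
    cut = max(outlier_px, 3.0 * float(np.median(residuals)))
    keep = residuals <= cut
    if keep.sum() >= 5 and keep.sum() < len(pts):
        ell = fit_ellipse_direct(pts[keep])
    mask = _fill_ellipse(image.shape[:2], ell)
    return ell, LabelMask(mask, "brain")


def _radial_residual_px(pts: np.ndarray, ell: EllipseParams) -> np.ndarray:
    th = np.radians(ell.orientation_deg)
    dr = pts[:, 0] - ell.center_row
    dc = pts[:, 1] - ell.center_col
    u = dc * np.cos(th) + dr * np.sin(th)
    v = -dc * np.sin(th) + dr * np.cos(th)
    r = np.sqrt((u / ell.semi_major_a) ** 2 + (v / ell.semi_minor_b) ** 2)
    return np.abs(r - 1.0) * ell.semi_minor_b


def _fill_ellipse(shape: tuple[int, int], ell: EllipseParams) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    th = np.radians(ell.orientation_deg)
    u = (cols - ell.center_col) * np.cos(th) + (rows - ell.center_row) * np.sin(th)
    v = -(cols - ell.center_col) * np.sin(th) + (rows - ell.center_row) * np.cos(th)
    return (u / ell.semi_major_a) ** 2 + (v / ell.semi_minor_b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# measurement text parsing
# ---------------------------------------------------------------------------

_ACRONYMS = ("HC", "BPD", "AC", "FL", "EFW", "GA", "SDP", "AF")
_UNIT_FOR = {
    "HC": {"cm", "mm"},
    "BPD": {"cm", "mm"},
    "AC": {"cm", "mm"},
    "FL": {"cm", "mm"},
    "SDP": {"cm", "mm"},
    "EFW": {"g"},
    "GA": {"weeks_days"},
}

_NUMERIC_RE = re.compile(
    r"^\s*(?P<acr>[A-Za-z]{1,5})\s*[:=]?\s*(?P<val>\d+(?:[.,]\d+)?)\s*(?P<unit>cm|mm|g)\s*$",
    re.IGNORECASE,
)
_WEEKS_RE = re.compile(
    r"^\s*(?P<acr>[A-Za-z]{1,5})\s*[:=]?\s*(?P<w>\d+)\s*w\s*(?P<d>\d+)\s*d\s*$",
    re.IGNORECASE,
)


def parse_measurement_text(lines: list[str]) -> list[ParsedMeasurement]:
    """Parse OCR text lines of the form ``ACRONYM value unit``.

    Decimal commas are tolerated; ``AF`` is accepted as a synonym for the
    single deepest pocket and normalized to ``SDP``; GA accepts the
    clinical ``<weeks>w<days>d`` form (value reported in days).  Unknown
    acronyms and unit/acronym mismatches are skipped with a warning.
    Order-preserving and idempotent.
    """
    out: list[ParsedMeasurement] = []
    for line in lines:
        m = _NUMERIC_RE.match(line)
        if m:
            acr = m.group("acr").upper()
            if acr == "AF":
                acr = "SDP"
            if acr not in _UNIT_FOR:
                warnings.warn(f"unknown measurement acronym {acr!r}; skipping {line!r}")
                continue
            unit = m.group("unit").lower()
            if unit not in _UNIT_FOR[acr]:
                warnings.warn(f"unit {unit!r} inconsistent with {acr}; skipping {line!r}")
                continue
            value = float(m.group("val").replace(",", "."))
            if value <= 0:
                warnings.warn(f"non-positive value in {line!r}; skipping")
                continue
            out.append(ParsedMeasurement(acr, value, unit))
            continue
        m = _WEEKS_RE.match(line)
        if m:
            acr = m.group("acr").upper()
            if acr != "GA":
                warnings.warn(f"weeks+days form only valid for GA; skipping {line!r}")
                continue
            days = 7 * int(m.group("w")) + int(m.group("d"))
            if days <= 0:
                warnings.warn(f"non-positive GA in {line!r}; skipping")
                continue
            out.append(ParsedMeasurement("GA", float(days), "weeks_days"))
            continue
        if line.strip():
            warnings.warn(f"unparseable measurement line {line!r}; skipping")
    return out


def caliper_pair_length(
    marks: list[CaliperMark], row_spacing_cm: float, col_spacing_cm: float
) -> float:
    """Euclidean distance between exactly two caliper marks, in cm."""
    if len(marks) != 2:
        raise ValueError(f"need exactly two caliper marks, got {len(marks)}")
    (r0, c0), (r1, c1) = marks[0].position, marks[1].position
    dist_px = float(np.hypot(r1 - r0, c1 - c0))
    return px_to_cm(dist_px, row_spacing_cm, col_spacing_cm, axis="isotropic")


def export_review_queue(records: list[dict], path) -> None:
    """Write extracted annotations as a JSON review queue for human validation."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps({"queue": records}, indent=2, sort_keys=True) + "\n")
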