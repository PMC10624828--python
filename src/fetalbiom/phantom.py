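"""Synthetic cine-loop phantoms with exact ground truth.

A phantom emulates one acquisition sweep: the structure of interest
(elliptical head or abdomen cross-section, elongated femur, or a set of
amniotic pockets) drifts through scale across frames, peaking at a
planted best-frame index where — and only where — all plane-quality
criteria are satisfied, the zoom conforms, and the detection confidence
is maximal.  Criterion flags are planted *metadata*, not rendered
anatomy: the pipeline consumes classifier probabilities, so testing the
selection logic requires controllable flags rather than realistic
thalami.

What the phantom does **not** emulate: attenuation, shadowing, probe
geometry, or any wave physics.  Speckle is a multiplicative unit-mean
gamma texture, enough to exercise intensity-agnostic code paths.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import PhantomSpecError
from .geometry import EllipseParams, ellipse_circumference
from .imaging_io import CineLoop, Frame, LabelMask
from .segmentation import ABDOMEN_CRITERIA, BRAIN_CRITERIA

_DEFAULT_SPACING = {"cephalic": 0.05, "abdominal": 0.05, "femoral": 0.03, "amniotic": 0.05}

_INTENSITY = {
    "background": 30,
    "brain": 150,
    "abdomen": 150,
    "femur": 220,
    "uterus": 110,
    "af_pocket": 15,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic cine-loop.

    The geometric defaults are sized so that the best frame conforms to
    the zoom criterion of its structure while every other frame does not
    (the scale trajectory dips to ``scale_min`` at the sweep ends).
    """

    kind: str
    n_frames: int = 11
    shape: tuple[int, int] = (256, 256)
    spacing_cm: Optional[float] = None  # None -> kind-dependent default
    best_frame: Optional[int] = None  # None -> middle frame
    # head/abdomen geometry (pixels, at best-frame scale 1.0)
    ellipse_a_px: float = 120.0
    ellipse_b_px: float = 90.0
    ellipse_theta_deg: float = 15.0
    # femur geometry: cap-tip-to-cap-tip length of a rotated capsule
    femur_length_px: float = 185.0
    femur_angle_deg: float = 20.0
    femur_radius_px: float = 12.0
    # amniotic pockets (requested depths; realized depths snap to the grid)
    pocket_depths_cm: tuple[float, ...] = (3.1, 4.7, 2.2)
    scale_min: float = 0.6
    #: width (in frames) of the Gaussian scale peak around the best frame.
    #: The sweep dwells on the optimal plane only briefly, so the scale
    #: profile is peaked rather than a ramp; this keeps the zoom criterion
    #: discriminative even when masks are degraded by a few pixels.
    scale_sigma_frames: float = 0.6
    speckle: bool = False
    speckle_shape: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_SPACING:
            raise PhantomSpecError(f"unknown loop kind {self.kind!r}")
        if self.n_frames < 1:
            raise PhantomSpecError("need at least one frame")
        k = self.resolved_best_frame
        if not (0 <= k < self.n_frames):
            raise PhantomSpecError("best_frame must lie within the loop")
        if not (0.0 < self.scale_min <= 1.0):
            raise PhantomSpecError("scale_min must be in (0, 1]")
        if min(self.ellipse_a_px, self.ellipse_b_px, self.femur_length_px) <= 0:
            raise PhantomSpecError("geometry must be positive")
        if any(d < 0 for d in self.pocket_depths_cm):
            raise PhantomSpecError("pocket depths must be >= 0")

    @property
    def resolved_best_frame(self) -> int:
        return self.n_frames // 2 if self.best_frame is None else self.best_frame

    @property
    def resolved_spacing_cm(self) -> float:
        return self.spacing_cm if self.spacing_cm is not None else _DEFAULT_SPACING[self.kind]


@dataclass(frozen=True)
class PhantomTruth:
    """Planted geometry, flags and analytic measurements of a phantom."""

    kind: str
    best_frame: int
    spacing_cm: float
    scales: tuple[float, ...]
    flags: tuple[dict, ...]
    confidences: tuple[float, ...]
    hc_cm: Optional[float] = None
    bpd_cm: Optional[float] = None
    ac_cm: Optional[float] = None
    fl_cm: Optional[float] = None
    sdp_cm: Optional[float] = None
    ellipse: Optional[EllipseParams] = None
    femur_length_px: Optional[float] = None
    femur_angle_deg: Optional[float] = None
    pocket_depths_cm: tuple[float, ...] = ()
    sdp_calipers: Optional[tuple[tuple[float, float], tuple[float, float]]] = None


# ---------------------------------------------------------------------------
# rasterizers
# ---------------------------------------------------------------------------


def _raster_ellipse(
    shape: tuple[int, int], cr: float, cc: float, a: float, b: float, theta_deg: float
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    th = math.radians(theta_deg)
    dx = (cols - cc) * math.cos(th) + (rows - cr) * math.sin(th)
    dy = -(cols - cc) * math.sin(th) + (rows - cr) * math.cos(th)
    return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0


def _raster_capsule(
    shape: tuple[int, int], cr: float, cc: float, length: float, angle_deg: float, radius: float
) -> np.ndarray:
    """Capsule (segment dilated by a disc); ``length`` is cap-tip to cap-tip."""
    half = max(length / 2.0 - radius, 0.0)
    th = math.radians(angle_deg)
    dr, dc = math.sin(th), math.cos(th)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    pr = rows - cr
    pc = cols - cc
    t = np.clip(pr * dr + pc * dc, -half, half)
    dist2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    return dist2 <= radius * radius


def _check_inside(grid: np.ndarray, what: str) -> None:
    if grid[0, :].any() or grid[-1, :].any() or grid[:, 0].any() or grid[:, -1].any():
        raise PhantomSpecError(f"{what} exceeds image bounds")


def _scale_profile(n: int, best: int, scale_min: float, sigma: float) -> np.ndarray:
    """Gaussian scale peak at the best frame, floored at ``scale_min``."""
    if n == 1:
        return np.array([1.0])
    dist = np.abs(np.arange(n) - best).astype(float)
    return scale_min + (1.0 - scale_min) * np.exp(-(dist**2) / (2.0 * sigma**2))


def _plant_flags(
    rng: np.random.Generator, n: int, best: int, vocabulary: Sequence[str]
) -> list[dict]:
    flags = []
    for i in range(n):
        if i == best or not vocabulary:
            flags.append({c: True for c in vocabulary})
            continue
        f = {c: bool(rng.random() < 0.7) for c in vocabulary}
        if all(f.values()):
            f[vocabulary[int(rng.integers(len(vocabulary)))]] = False
        flags.append(f)
    return flags


def _confidences(rng: np.random.Generator, n: int, best: int) -> list[float]:
    conf = [float(rng.uniform(0.55, 0.85)) for _ in range(n)]
    conf[best] = 0.95
    return conf


def render_speckle(
    pixels: np.ndarray, seed: int, shape_param: float = 16.0
) -> np.ndarray:
    """Apply multiplicative unit-mean gamma speckle to an intensity grid.

    The gamma noise has shape ``shape_param`` and scale ``1/shape_param``
    (mean 1), so structure boundaries stay at the planted geometry and the
    expected intensity of any region is unchanged.
    """
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape_param, 1.0 / shape_param, size=pixels.shape)
    return np.clip(np.rint(pixels.astype(np.float64) * noise), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_biometry_loop(
    spec: PhantomSpec,
) -> tuple[CineLoop, list[list[LabelMask]], PhantomTruth]:
    """Generate a cephalic, abdominal, or femoral phantom loop.

    Returns the rendered loop, per-frame planted label masks, and the
    analytic truth at the best frame.  Raises
    :class:`~fetalbiom.errors.PhantomSpecError` if the structure leaves
    the image or if the zoom criterion would not single out the planted
    best frame.
    """
    if spec.kind not in ("cephalic", "abdominal", "femoral"):
        raise PhantomSpecError(f"not a biometry kind: {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    n, best = spec.n_frames, spec.resolved_best_frame
    scales = _scale_profile(n, best, spec.scale_min, spec.scale_sigma_frames)
    spacing = spec.resolved_spacing_cm
    shape = spec.shape
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    label = {"cephalic": "brain", "abdominal": "abdomen", "femoral": "femur"}[spec.kind]
    vocab = BRAIN_CRITERIA if label == "brain" else (
        ABDOMEN_CRITERIA if label == "abdomen" else ()
    )
    flags = _plant_flags(rng, n, best, vocab)
    confidences = _confidences(rng, n, best)

    frames: list[Frame] = []
    labels: list[list[LabelMask]] = []
    for i, s in enumerate(scales):
        if spec.kind == "femoral":
            grid = _raster_capsule(
                shape, cr, cc, spec.femur_length_px * s, spec.femur_angle_deg,
                spec.femur_radius_px * s,
            )
        else:
            grid = _raster_ellipse(
                shape, cr, cc, spec.ellipse_a_px * s, spec.ellipse_b_px * s,
                spec.ellipse_theta_deg,
            )
        _check_inside(grid, f"{label} at frame {i}")
        pixels = np.full(shape, _INTENSITY["background"], dtype=np.uint8)
        pixels[grid] = _INTENSITY[label]
        if spec.speckle:
            pixels = render_speckle(pixels, seed=_subseed(spec.seed, i),
                                    shape_param=spec.speckle_shape)
        frames.append(Frame(i, pixels, spacing, spacing))
        labels.append([LabelMask(grid, label)])

    _check_zoom_uniqueness(labels, best, label)

    if spec.kind == "femoral":
        truth = PhantomTruth(
            kind=spec.kind, best_frame=best, spacing_cm=spacing,
            scales=tuple(float(s) for s in scales),
            flags=tuple(flags), confidences=tuple(confidences),
            fl_cm=spec.femur_length_px * spacing,
            femur_length_px=spec.femur_length_px,
            femur_angle_deg=spec.femur_angle_deg,
        )
    else:
        ell = EllipseParams(
            center_row=cr, center_col=cc,
            semi_major_a=spec.ellipse_a_px, semi_minor_b=spec.ellipse_b_px,
            orientation_deg=spec.ellipse_theta_deg,
        )
        circ_cm = ellipse_circumference(ell) * spacing
        truth = PhantomTruth(
            kind=spec.kind, best_frame=best, spacing_cm=spacing,
            scales=tuple(float(s) for s in scales),
            flags=tuple(flags), confidences=tuple(confidences),
            hc_cm=circ_cm if spec.kind == "cephalic" else None,
            bpd_cm=2.0 * spec.ellipse_b_px * spacing if spec.kind == "cephalic" else None,
            ac_cm=circ_cm if spec.kind == "abdominal" else None,
            ellipse=ell,
        )
    loop = CineLoop(tuple(frames), spec.kind, source_id=f"phantom-{spec.kind}-{spec.seed}")
    return loop, labels, truth


def _check_zoom_uniqueness(
    labels: list[list[LabelMask]], best: int, label: str
) -> None:
    from .quality import DEFAULT_ZOOM_THRESHOLDS

    threshold = DEFAULT_ZOOM_THRESHOLDS[label]
    for i, masks in enumerate(labels):
        ratio = masks[0].count / masks[0].grid.size
        if i == best and ratio < threshold:
            raise PhantomSpecError(
                f"best frame zoom ratio {ratio:.3f} below threshold {threshold}"
            )
        if i != best and ratio >= threshold:
            raise PhantomSpecError(
                f"frame {i} zoom ratio {ratio:.3f} conforms but is not the best frame"
            )


def generate_af_loop(
    spec: PhantomSpec,
) -> tuple[CineLoop, list[list[LabelMask]], PhantomTruth]:
    """Generate an amniotic sweep with pockets of exactly known depths.

    Pockets are vertical-ellipse blobs whose rasterized row extent equals
    the requested depth snapped to the pixel grid; each pocket appears on
    one frame (round-robin), several per frame are allowed but must stay
    disjoint.  Truth SDP is the maximum realized depth.
    """
    if spec.kind != "amniotic":
        raise PhantomSpecError(f"generate_af_loop needs kind 'amniotic', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    spacing = spec.resolved_spacing_cm
    shape = spec.shape
    confidences = [float(rng.uniform(0.7, 0.95)) for _ in range(n)]

    per_frame_pockets: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for j, depth in enumerate(spec.pocket_depths_cm):
        per_frame_pockets[j % n].append((j, float(depth)))

    frames: list[Frame] = []
    labels: list[list[LabelMask]] = []
    realized: dict[int, float] = {}
    calipers: dict[int, tuple] = {}
    for i in range(n):
        pixels = np.full(shape, _INTENSITY["uterus"], dtype=np.uint8)
        frame_masks: list[LabelMask] = []
        occupancy = np.zeros(shape, dtype=bool)
        pockets = per_frame_pockets[i]
        for slot, (j, depth_cm) in enumerate(pockets):
            n_rows = int(round(depth_cm / spacing)) + 1
            n_rows = min(n_rows, shape[0] - 4)
            v = (n_rows - 1) / 2.0
            width = float(np.clip(0.4 * n_rows, 8, shape[1] / (len(pockets) + 1) - 6))
            h = width / 2.0
            band = shape[1] / (len(pockets) + 1)
            cc = int(round(band * (slot + 1)))
            cr_center = (shape[0] - 1) / 2.0
            cr = math.floor(cr_center) if n_rows % 2 == 1 else math.floor(cr_center) + 0.5
            grid = _raster_pocket(shape, cr, cc, v, h)
            _check_inside(grid, f"pocket {j} at frame {i}")
            if (grid & occupancy).any():
                raise PhantomSpecError(f"pockets overlap on frame {i}")
            occupancy |= grid
            pixels[grid] = _INTENSITY["af_pocket"]
            frame_masks.append(LabelMask(grid, "af_pocket"))
            realized[j] = (n_rows - 1) * spacing
            calipers[j] = ((cr - v, float(cc)), (cr + v, float(cc)))
        if spec.speckle:
            pixels = render_speckle(pixels, seed=_subseed(spec.seed, i),
                                    shape_param=spec.speckle_shape)
        frames.append(Frame(i, pixels, spacing, spacing))
        labels.append(frame_masks)

    depths = tuple(realized[j] for j in sorted(realized))
    sdp = max(depths) if depths else None
    sdp_cal = calipers[max(realized, key=lambda j: realized[j])] if realized else None
    truth = PhantomTruth(
        kind="amniotic", best_frame=spec.resolved_best_frame, spacing_cm=spacing,
        scales=tuple(1.0 for _ in range(n)),
        flags=tuple({} for _ in range(n)),
        confidences=tuple(confidences),
        sdp_cm=sdp, pocket_depths_cm=depths, sdp_calipers=sdp_cal,
    )
    loop = CineLoop(tuple(frames), "amniotic", source_id=f"phantom-amniotic-{spec.seed}")
    return loop, labels, truth


def _raster_pocket(shape, cr: float, cc: float, v: float, h: float) -> np.ndarray:
    if v <= 0:
        grid = np.zeros(shape, dtype=bool)
        grid[int(round(cr)), int(round(cc))] = True
        return grid
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rows - cr) / v) ** 2 + ((cols - cc) / h) ** 2 <= 1.0


def _subseed(seed: int, index: int) -> int:
    return (seed * 1000003 + index * 7919 + 1) % (2**31)


def generate_loop(spec: PhantomSpec):
    """Dispatch to the biometry or amniotic generator by ``spec.kind``."""
    if spec.kind == "amniotic":
        return generate_af_loop(spec)
    return generate_biometry_loop(spec)


# ---------------------------------------------------------------------------
# annotation rendering (fixture factory for overlay extraction)
# ---------------------------------------------------------------------------

DEFAULT_CALIPER_COLOR = (255, 255, 0)  # saturated yellow
DEFAULT_DOT_COLOR = (0, 255, 255)  # saturated cyan


def render_annotations(
    frame: Frame,
    truth: PhantomTruth,
    *,
    caliper_color: tuple[int, int, int] = DEFAULT_CALIPER_COLOR,
    dot_color: tuple[int, int, int] = DEFAULT_DOT_COLOR,
    n_dots: int = 24,
) -> tuple[np.ndarray, list[str]]:
    """Burn calipers, a dotted measurement ellipse, and text into a frame.

    Emulates the vendor overlays of retrospectively archived images:
    cross-glyph caliper pairs, a dotted ellipse along the fitted outline,
    and measurement text.  Returns the RGB image and the machine-readable
    text lines (also rasterized into the image).
    """
    rgb = np.stack([frame.pixels] * 3, axis=-1).astype(np.uint8)
    lines: list[str] = []
    if truth.ellipse is not None:
        ell = truth.ellipse
        th = math.radians(ell.orientation_deg)
        ts = np.linspace(0.0, 2.0 * math.pi, n_dots, endpoint=False)
        for t in ts:
            x = ell.semi_major_a * math.cos(t)
            y = ell.semi_minor_b * math.sin(t)
            col = ell.center_col + x * math.cos(th) - y * math.sin(th)
            row = ell.center_row + x * math.sin(th) + y * math.cos(th)
            _draw_dot(rgb, row, col, dot_color)
        # BPD caliper pair at the minor-axis endpoints
        dr, dc = math.cos(th), -math.sin(th)
        for sgn in (-1.0, 1.0):
            _draw_cross(
                rgb,
                ell.center_row + sgn * ell.semi_minor_b * dr,
                ell.center_col + sgn * ell.semi_minor_b * dc,
                caliper_color,
            )
        if truth.hc_cm is not None:
            lines.append(f"HC {truth.hc_cm:.2f} cm")
        if truth.bpd_cm is not None:
            lines.append(f"BPD {truth.bpd_cm:.2f} cm")
        if truth.ac_cm is not None:
            lines.append(f"AC {truth.ac_cm:.2f} cm")
    if truth.kind == "femoral" and truth.femur_length_px is not None:
        shape = frame.shape
        cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        th = math.radians(truth.femur_angle_deg or 0.0)
        half = truth.femur_length_px / 2.0
        for sgn in (-1.0, 1.0):
            _draw_cross(
                rgb, cr + sgn * half * math.sin(th), cc + sgn * half * math.cos(th),
                caliper_color,
            )
        if truth.fl_cm is not None:
            lines.append(f"FL {truth.fl_cm:.2f} cm")
    if truth.kind == "amniotic" and truth.sdp_calipers is not None:
        for row, col in truth.sdp_calipers:
            _draw_cross(rgb, row, col, caliper_color)
        if truth.sdp_cm is not None:
            lines.append(f"SDP {truth.sdp_cm:.2f} cm")
    if lines:
        _draw_text(rgb, lines)
    return rgb, lines


def _draw_dot(rgb: np.ndarray, row: float, col: float, color, size: int = 3) -> None:
    r, c = int(round(row)), int(round(col))
    half = size // 2
    r0, r1 = max(r - half, 0), min(r + half + 1, rgb.shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, rgb.shape[1])
    rgb[r0:r1, c0:c1] = color


def _draw_cross(rgb: np.ndarray, row: float, col: float, color, arm: int = 4) -> None:
    r, c = int(round(row)), int(round(col))
    r0, r1 = max(r - arm, 0), min(r + arm + 1, rgb.shape[0])
    c0, c1 = max(c - arm, 0), min(c + arm + 1, rgb.shape[1])
    if 0 <= r < rgb.shape[0]:
        rgb[r, c0:c1] = color
    if 0 <= c < rgb.shape[1]:
        rgb[r0:r1, c] = color


def _draw_text(rgb: np.ndarray, lines: list[str]) -> None:
    from PIL import Image, ImageDraw

    img = Image.fromarray(rgb)
    draw = ImageDraw.Draw(img)
    for i, line in enumerate(lines):
        draw.text((4, 4 + 12 * i), line, fill=(255, 255, 255))
    rgb[:] = np.asarray(img)
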