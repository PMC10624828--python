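"""End-to-end orchestration: cine-loop in, clinical report out.

For each biometry loop the pipeline segments every frame, scores every
candidate plane, selects the highest-scoring frame, and measures on it:

* cephalic — contour, direct least-squares ellipse fit; HC is the ellipse
  perimeter, BPD the full minor-axis diameter (both from the same mask);
* abdominal — same fit; AC is the perimeter;
* femoral — FL is the long side of the minimum-area rotated box.

For the amniotic sweep there is no quality selection: every pocket on
every frame is measured and the deepest one is retained as the single
deepest pocket (SDP), then categorized (oligohydramnios < 2 cm,
polyhydramnios > 8 cm, strict inequalities).

Estimated fetal weight uses the 3-parameter Hadlock log10 polynomial in
AC, FL and BPD (cm -> grams); gestational age uses the Intergrowth-21st
late-pregnancy log-quadratic in HC and FL (days).  Every coefficient
lives in :class:`FormulaConfig` and can be overridden without code
changes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .errors import ConfigError, DegenerateFitError, DomainError, EmptyStructureError
from .geometry import (
    AxisMeasurement,
    DepthMeasurement,
    EllipseParams,
    ellipse_circumference,
    fit_ellipse_direct,
    outer_contour,
    principal_axis,
    px_to_cm,
    vertical_depth,
)
from .imaging_io import CineLoop, dump_report_json
from .quality import (
    DEFAULT_FEMUR_ANGLE_DEG,
    DEFAULT_ZOOM_THRESHOLDS,
    QualityAssessment,
    ScoreWeights,
    angle_conform,
    composite_score,
    select_best_frame,
    zoom_ratio,
)
from .segmentation import LABEL_FOR_KIND, SegmentationBackend, SegmentationInstance

AFV_CATEGORIES = ("oligohydramnios", "normal", "polyhydramnios")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FormulaConfig:
    """Coefficients and thresholds of the clinical formulas.

    Hadlock (3-parameter):
        ``log10 EFW = c0 + c_acfl*AC*FL + c_bpd*BPD + c_ac*AC + c_fl*FL``
        with lengths in cm and EFW in grams.

    Intergrowth (late pregnancy, > 14 weeks):
        ``ln GA = k_hc2*(ln HC)^2 + k_flhc*FL*ln HC + k_0``
        with GA in days and HC/FL in ``intergrowth_unit``.

    Note: with the published intercept ``k_0 = 3.1813`` and mm-scale
    inputs, typical mid-pregnancy biometry yields implausibly low GA; the
    intercept is kept as printed and is overridable here (see the methods
    documentation for the discrepancy discussion).
    """

    c0: float = 1.335
    c_acfl: float = -0.0034
    c_bpd: float = 0.0316
    c_ac: float = 0.0457
    c_fl: float = 0.1623
    k_hc2: float = 0.03243
    k_flhc: float = 0.001644
    k_0: float = 3.1813
    intergrowth_unit: str = "mm"
    oligo_threshold_cm: float = 2.0
    poly_threshold_cm: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.oligo_threshold_cm < self.poly_threshold_cm):
            raise ConfigError("AFV thresholds must satisfy 0 < oligo < poly")
        if self.intergrowth_unit not in ("mm", "cm"):
            raise ConfigError("intergrowth_unit must be 'mm' or 'cm'")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything tunable about scoring and the clinical formulas."""

    weights: ScoreWeights = field(default_factory=ScoreWeights)
    zoom_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZOOM_THRESHOLDS)
    )
    femur_angle_deg: float = DEFAULT_FEMUR_ANGLE_DEG
    zoom_mode: str = "binary"  # or "raw"
    formulas: FormulaConfig = field(default_factory=FormulaConfig)
    default_spacing_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.zoom_mode not in ("binary", "raw"):
            raise ConfigError("zoom_mode must be 'binary' or 'raw'")

    def to_dict(self) -> dict:
        return {
            "weights": {
                "w_quality": self.weights.w_quality,
                "w_zoom": self.weights.w_zoom,
                "w_confidence": self.weights.w_confidence,
            },
            "zoom_thresholds": dict(self.zoom_thresholds),
            "femur_angle_deg": self.femur_angle_deg,
            "zoom_mode": self.zoom_mode,
            "formulas": {
                k: getattr(self.formulas, k)
                for k in (
                    "c0", "c_acfl", "c_bpd", "c_ac", "c_fl",
                    "k_hc2", "k_flhc", "k_0", "intergrowth_unit",
                    "oligo_threshold_cm", "poly_threshold_cm",
                )
            },
            "default_spacing_cm": self.default_spacing_cm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(
            weights=ScoreWeights(**d.get("weights", {})),
            zoom_thresholds=dict(d.get("zoom_thresholds", DEFAULT_ZOOM_THRESHOLDS)),
            femur_angle_deg=float(d.get("femur_angle_deg", DEFAULT_FEMUR_ANGLE_DEG)),
            zoom_mode=d.get("zoom_mode", "binary"),
            formulas=FormulaConfig(**d.get("formulas", {})),
            default_spacing_cm=d.get("default_spacing_cm"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoPlaneFound:
    """Reportable outcome: no measurable standard plane in the loop."""

    kind: str
    reason: str = "no instance detected in any frame"


@dataclass(frozen=True)
class NoPocketFound:
    """Reportable outcome: no amniotic-fluid pocket in the sweep."""

    reason: str = "no pocket detected in any frame"


@dataclass(frozen=True)
class PlaneMeasurement:
    plane: str  # cephalic | abdominal | femoral
    frame_index: int
    quality: QualityAssessment
    ellipse: Optional[EllipseParams] = None
    axis: Optional[AxisMeasurement] = None
    hc_cm: Optional[float] = None
    bpd_cm: Optional[float] = None
    ac_cm: Optional[float] = None
    fl_cm: Optional[float] = None
    calipers: tuple = ()

    def __post_init__(self) -> None:
        if self.plane == "cephalic":
            if self.hc_cm is None or self.bpd_cm is None:
                raise ValueError("cephalic plane requires HC and BPD")
            # minor-axis diameter cannot exceed perimeter / pi
            if self.bpd_cm > self.hc_cm / math.pi + 1e-6:
                raise ValueError("BPD inconsistent with HC (2b <= C/pi)")
        elif self.plane == "abdominal":
            if self.ac_cm is None:
                raise ValueError("abdominal plane requires AC")
        elif self.plane == "femoral":
            if self.fl_cm is None:
                raise ValueError("femoral plane requires FL")
        else:
            raise ValueError(f"unknown plane {self.plane!r}")
        for v in (self.hc_cm, self.bpd_cm, self.ac_cm, self.fl_cm):
            if v is not None and not v > 0:
                raise ValueError("measured lengths must be positive")


@dataclass(frozen=True)
class SDPMeasurement:
    depth_cm: float
    frame_index: int
    pocket: DepthMeasurement
    afv_category: str

    def __post_init__(self) -> None:
        if self.depth_cm < 0:
            raise ValueError("depth must be >= 0")
        if self.afv_category not in AFV_CATEGORIES:
            raise ValueError(f"unknown AFV category {self.afv_category!r}")


# ---------------------------------------------------------------------------
# loop measurement
# ---------------------------------------------------------------------------


def _assess_instance(
    frame_index: int,
    instance: SegmentationInstance,
    backend: SegmentationBackend,
    frame,
    config: PipelineConfig,
) -> tuple[QualityAssessment, Optional[AxisMeasurement]]:
    ratio = zoom_ratio(instance.mask)
    threshold = config.zoom_thresholds.get(instance.label, 0.5)
    zoom_ok = ratio >= threshold
    axis = None
    if instance.label == "femur":
        axis = principal_axis(instance.mask)
        angle_ok: Optional[bool] = angle_conform(axis, config.femur_angle_deg)
        probs = None
    else:
        probs = backend.classify_criteria(frame, instance)
        angle_ok = None
    score = composite_score(
        probs,
        zoom_ok,
        angle_ok,
        instance.confidence,
        config.weights,
        raw_zoom=ratio if config.zoom_mode == "raw" else None,
    )
    qa = QualityAssessment(
        criterion_probs=probs,
        zoom_ratio=ratio,
        zoom_conform=zoom_ok,
        angle_conform=angle_ok,
        confidence=instance.confidence,
        composite=score,
    )
    return qa, axis


def measure_biometry_loop(
    loop: CineLoop,
    backend: SegmentationBackend,
    config: PipelineConfig = PipelineConfig(),
) -> PlaneMeasurement | NoPlaneFound:
    """Select and measure the best standard plane in a biometry loop."""
    if loop.kind not in ("cephalic", "abdominal", "femoral"):
        raise ValueError(f"not a biometry loop kind: {loop.kind!r}")
    wanted = LABEL_FOR_KIND[loop.kind]
    candidates = []  # (frame_index, instance, qa); axis kept alongside
    axes: dict[int, AxisMeasurement] = {}
    for frame in loop:
        for instance in backend.segment_frame(frame, loop.kind):
            if instance.label != wanted:
                continue
            qa, axis = _assess_instance(frame.index, instance, backend, frame, config)
            if axis is not None:
                axes[len(candidates)] = axis
            candidates.append((frame.index, instance, qa))
    if not candidates:
        return NoPlaneFound(loop.kind)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i][2].composite, candidates[i][0]),
    )
    row_cm, col_cm = loop.row_spacing_cm, loop.col_spacing_cm
    last_error: Exception | None = None
    for i in order:
        frame_index, instance, qa = candidates[i]
        try:
            if loop.kind == "femoral":
                axis = axes.get(i) or principal_axis(instance.mask)
                fl = px_to_cm(axis.length_px, row_cm, col_cm, axis="isotropic")
                return PlaneMeasurement(
                    plane="femoral",
                    frame_index=frame_index,
                    quality=qa,
                    axis=axis,
                    fl_cm=fl,
                    calipers=(axis.endpoints,),
                )
            contour = outer_contour(instance.mask)
            ell = fit_ellipse_direct(contour)
            circ_cm = px_to_cm(
                ellipse_circumference(ell), row_cm, col_cm, axis="isotropic"
            )
            calipers = (_minor_axis_endpoints(ell),)
            if loop.kind == "cephalic":
                bpd = px_to_cm(2.0 * ell.semi_minor_b, row_cm, col_cm, axis="isotropic")
                return PlaneMeasurement(
                    plane="cephalic",
                    frame_index=frame_index,
                    quality=qa,
                    ellipse=ell,
                    hc_cm=circ_cm,
                    bpd_cm=bpd,
                    calipers=calipers,
                )
            return PlaneMeasurement(
                plane="abdominal",
                frame_index=frame_index,
                quality=qa,
                ellipse=ell,
                ac_cm=circ_cm,
                calipers=calipers,
            )
        except (EmptyStructureError, DegenerateFitError) as exc:
            last_error = exc  # unmeasurable candidate; fall through to next best
    return NoPlaneFound(loop.kind, reason=f"no measurable instance ({last_error})")


def _minor_axis_endpoints(ell: EllipseParams):
    th = math.radians(ell.orientation_deg)
    # minor axis is perpendicular to the major axis
    dr, dc = math.cos(th), -math.sin(th)
    b = ell.semi_minor_b
    return (
        (ell.center_row - b * dr, ell.center_col - b * dc),
        (ell.center_row + b * dr, ell.center_col + b * dc),
    )


def measure_sdp_loop(
    loop: CineLoop,
    backend: SegmentationBackend,
    config: PipelineConfig = PipelineConfig(),
) -> SDPMeasurement | NoPocketFound:
    """Measure every pocket on every frame; keep the single deepest one."""
    if loop.kind != "amniotic":
        raise ValueError(f"SDP needs an amniotic loop, got {loop.kind!r}")
    best: Optional[tuple[float, int, DepthMeasurement]] = None
    for frame in loop:
        for instance in backend.segment_frame(frame, loop.kind):
            if instance.label != "af_pocket":
                continue
            pocket = vertical_depth(instance.mask)
            depth_cm = px_to_cm(
                pocket.depth_px, loop.row_spacing_cm, loop.col_spacing_cm, axis="row"
            )
            if best is None or depth_cm > best[0]:
                best = (depth_cm, frame.index, pocket)
    if best is None:
        return NoPocketFound()
    depth_cm, frame_index, pocket = best
    return SDPMeasurement(
        depth_cm=depth_cm,
        frame_index=frame_index,
        pocket=pocket,
        afv_category=classify_afv(depth_cm, config.formulas),
    )


# ---------------------------------------------------------------------------
# clinical formulas
# ---------------------------------------------------------------------------


def efw_hadlock(
    ac_cm: float,
    fl_cm: float,
    bpd_cm: float,
    config: FormulaConfig = FormulaConfig(),
    *,
    strict: bool = True,
) -> float:
    """Estimated fetal weight in grams from AC, FL, BPD in cm.

    ``strict=False`` admits zero inputs (outside the clinical domain but
    useful for checking the intercept identity ``10**c0``).
    """
    for name, v in (("AC", ac_cm), ("FL", fl_cm), ("BPD", bpd_cm)):
        if (strict and v <= 0) or v < 0:
            raise DomainError(f"{name} must be positive, got {v}")
    f = config
    exponent = (
        f.c0 + f.c_acfl * ac_cm * fl_cm + f.c_bpd * bpd_cm + f.c_ac * ac_cm + f.c_fl * fl_cm
    )
    return float(10.0 ** exponent)


def ga_intergrowth(
    hc: float, fl: float, config: FormulaConfig = FormulaConfig()
) -> float:
    """Gestational age in days from HC and FL (in ``config.intergrowth_unit``)."""
    if hc <= 0 or fl < 0:
        raise DomainError(f"HC must be positive and FL nonnegative, got {hc}, {fl}")
    ln_hc = math.log(hc)
    return float(math.exp(config.k_hc2 * ln_hc**2 + config.k_flhc * fl * ln_hc + config.k_0))


def ga_weeks_days(ga_days: float) -> str:
    """Render a GA in days as the clinical ``<weeks>w<days>d`` string."""
    weeks = int(ga_days // 7)
    days = round(ga_days - 7 * weeks)
    if days == 7:
        weeks, days = weeks + 1, 0
    return f"{weeks}w{days}d"


def classify_afv(depth_cm: float, config: FormulaConfig = FormulaConfig()) -> str:
    """AFV category from the SDP depth; strict inequalities at 2 and 8 cm."""
    if depth_cm < 0:
        raise DomainError(f"depth must be >= 0, got {depth_cm}")
    if depth_cm < config.oligo_threshold_cm:
        return "oligohydramnios"
    if depth_cm > config.poly_threshold_cm:
        return "polyhydramnios"
    return "normal"


# ---------------------------------------------------------------------------
# report assembly and serialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiometryReport:
    """The clinical output: per-plane measurements, SDP, EFW, GA."""

    planes: dict[str, Optional[PlaneMeasurement]]
    sdp: Optional[SDPMeasurement]
    efw_g: Optional[float]
    ga_days: Optional[float]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "planes": {
                plane: _plane_to_dict(m) for plane, m in sorted(self.planes.items())
            },
            "sdp": _sdp_to_dict(self.sdp),
            "efw_g": self.efw_g,
            "ga_days": self.ga_days,
            "ga_weeks_days": ga_weeks_days(self.ga_days) if self.ga_days is not None else None,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BiometryReport":
        return cls(
            planes={k: _plane_from_dict(k, v) for k, v in d.get("planes", {}).items()},
            sdp=_sdp_from_dict(d.get("sdp")),
            efw_g=d.get("efw_g"),
            ga_days=d.get("ga_days"),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self) -> str:
        return dump_report_json(self.to_dict())


def _qa_to_dict(qa: QualityAssessment) -> dict:
    return {
        "criterion_probs": qa.criterion_probs,
        "zoom_ratio": qa.zoom_ratio,
        "zoom_conform": qa.zoom_conform,
        "angle_conform": qa.angle_conform,
        "confidence": qa.confidence,
        "composite": qa.composite,
    }


def _plane_to_dict(m: Optional[PlaneMeasurement]) -> Optional[dict]:
    if m is None:
        return None
    d: dict = {
        "frame_index": m.frame_index,
        "quality": _qa_to_dict(m.quality),
        "HC_cm": m.hc_cm,
        "BPD_cm": m.bpd_cm,
        "AC_cm": m.ac_cm,
        "FL_cm": m.fl_cm,
        "calipers": [[list(p) for p in pair] for pair in m.calipers],
    }
    d["ellipse"] = (
        None
        if m.ellipse is None
        else {
            "center_row": m.ellipse.center_row,
            "center_col": m.ellipse.center_col,
            "semi_major_a": m.ellipse.semi_major_a,
            "semi_minor_b": m.ellipse.semi_minor_b,
            "orientation_deg": m.ellipse.orientation_deg,
        }
    )
    d["axis"] = (
        None
        if m.axis is None
        else {
            "length_px": m.axis.length_px,
            "angle_deg": m.axis.angle_deg,
            "endpoints": [list(p) for p in m.axis.endpoints],
        }
    )
    return d


def _plane_from_dict(plane: str, d: Optional[Mapping]) -> Optional[PlaneMeasurement]:
    if d is None:
        return None
    qa = QualityAssessment(**d["quality"])
    ell = EllipseParams(**d["ellipse"]) if d.get("ellipse") else None
    ax = (
        AxisMeasurement(
            d["axis"]["length_px"],
            d["axis"]["angle_deg"],
            tuple(tuple(p) for p in d["axis"]["endpoints"]),
        )
        if d.get("axis")
        else None
    )
    return PlaneMeasurement(
        plane=plane,
        frame_index=d["frame_index"],
        quality=qa,
        ellipse=ell,
        axis=ax,
        hc_cm=d.get("HC_cm"),
        bpd_cm=d.get("BPD_cm"),
        ac_cm=d.get("AC_cm"),
        fl_cm=d.get("FL_cm"),
        calipers=tuple(tuple(tuple(p) for p in pair) for pair in d.get("calipers", [])),
    )


def _sdp_to_dict(s: Optional[SDPMeasurement]) -> Optional[dict]:
    if s is None:
        return None
    return {
        "depth_cm": s.depth_cm,
        "frame_index": s.frame_index,
        "afv_category": s.afv_category,
        "pocket": {
            "depth_px": s.pocket.depth_px,
            "top_row": s.pocket.top_row,
            "bottom_row": s.pocket.bottom_row,
            "column_ref": s.pocket.column_ref,
        },
    }


def _sdp_from_dict(d: Optional[Mapping]) -> Optional[SDPMeasurement]:
    if d is None:
        return None
    return SDPMeasurement(
        depth_cm=d["depth_cm"],
        frame_index=d["frame_index"],
        pocket=DepthMeasurement(**d["pocket"]),
        afv_category=d["afv_category"],
    )


def assemble_report(
    measurements: Sequence[
        PlaneMeasurement | SDPMeasurement | NoPlaneFound | NoPocketFound
    ],
    config: PipelineConfig = PipelineConfig(),
    *,
    loop_ids: Sequence[str] = (),
) -> BiometryReport:
    """Combine any subset of per-loop measurements into one report.

    EFW is computed only when AC, FL and BPD are all present; GA only when
    HC and FL are present (HC/FL converted to the configured Intergrowth
    input unit first).
    """
    planes: dict[str, Optional[PlaneMeasurement]] = {
        "cephalic": None,
        "abdominal": None,
        "femoral": None,
    }
    sdp: Optional[SDPMeasurement] = None
    for m in measurements:
        if isinstance(m, PlaneMeasurement) and planes.get(m.plane) is None:
            planes[m.plane] = m
        elif isinstance(m, SDPMeasurement) and sdp is None:
            sdp = m
    hc = planes["cephalic"].hc_cm if planes["cephalic"] else None
    bpd = planes["cephalic"].bpd_cm if planes["cephalic"] else None
    ac = planes["abdominal"].ac_cm if planes["abdominal"] else None
    fl = planes["femoral"].fl_cm if planes["femoral"] else None
    efw = (
        efw_hadlock(ac, fl, bpd, config.formulas)
        if (ac is not None and fl is not None and bpd is not None)
        else None
    )
    if hc is not None and fl is not None:
        unit_scale = 10.0 if config.formulas.intergrowth_unit == "mm" else 1.0
        ga = ga_intergrowth(hc * unit_scale, fl * unit_scale, config.formulas)
    else:
        ga = None
    return BiometryReport(
        planes=planes,
        sdp=sdp,
        efw_g=efw,
        ga_days=ga,
        provenance={
            "config_hash": config.config_hash(),
            "version": __version__,
            "intergrowth_unit": config.formulas.intergrowth_unit,
            "loops": list(loop_ids),
        },
    )
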