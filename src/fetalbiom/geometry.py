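"""Measurable geometry from segmentation masks.

The measurement conventions mirror how a sonographer places calipers:

* head and abdomen outlines are contoured and fitted with a direct
  least-squares ellipse; the circumference (HC, AC) is the exact ellipse
  perimeter and the biparietal diameter is the full minor axis;
* the femur length is the long side of the minimum-area rotated rectangle
  enclosing the bone mask (an axis-aligned box would understate the length
  of an angled femur);
* an amniotic pocket depth is the vertical extent of its axis-aligned
  bounding box.

Lengths are measured between outermost *pixel centers* (``max - min``),
matching caliper-tip placement.  Angles to the image horizontal live in
``(-90, 90]`` degrees; the sign is positive when the axis dips toward
larger row indices as the column increases (screen convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe
from skimage import measure as skmeasure

from .errors import AnisotropicSpacingError, DegenerateFitError, EmptyStructureError
from .imaging_io import LabelMask

__all__ = [
    "EllipseParams",
    "AxisMeasurement",
    "DepthMeasurement",
    "outer_contour",
    "fit_ellipse_direct",
    "ellipse_circumference",
    "principal_axis",
    "vertical_depth",
    "px_to_cm",
]


def _normalize_angle_deg(theta: float) -> float:
    """Map an angle to the half-open interval (-90, 90] degrees."""
    theta = (theta + 90.0) % 180.0 - 90.0
    if theta == -90.0:
        theta = 90.0
    return theta


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center (row, col), semi-axes in px, orientation.

    ``orientation_deg`` is the angle of the major axis to the image
    horizontal, in ``(-90, 90]``.
    """

    center_row: float
    center_col: float
    semi_major_a: float
    semi_minor_b: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not (self.semi_major_a >= self.semi_minor_b > 0):
            raise ValueError("ellipse requires a >= b > 0")
        if not (-90.0 < self.orientation_deg <= 90.0):
            raise ValueError("orientation must lie in (-90, 90]")


@dataclass(frozen=True)
class AxisMeasurement:
    """A caliper pair along a structure's principal axis."""

    length_px: float
    angle_deg: float
    endpoints: tuple[tuple[float, float], tuple[float, float]]  # (row, col) pairs

    def __post_init__(self) -> None:
        if self.length_px < 0:
            raise ValueError("length must be >= 0")
        (r0, c0), (r1, c1) = self.endpoints
        d = float(np.hypot(r1 - r0, c1 - c0))
        if abs(d - self.length_px) > 1e-6:
            raise ValueError("endpoint distance disagrees with length")


@dataclass(frozen=True)
class DepthMeasurement:
    """A vertical caliper pair for an amniotic pocket."""

    depth_px: float
    top_row: float
    bottom_row: float
    column_ref: float

    def __post_init__(self) -> None:
        if self.bottom_row - self.top_row < 0:
            raise ValueError("bottom row must not precede top row")
        if abs((self.bottom_row - self.top_row) - self.depth_px) > 1e-9:
            raise ValueError("depth must equal bottom_row - top_row")


# ---------------------------------------------------------------------------
# contours and ellipse fitting
# ---------------------------------------------------------------------------


def outer_contour(mask: LabelMask) -> np.ndarray:
    """Sub-pixel closed boundary of the largest 8-connected component.

    Returns an ``(n, 2)`` array of ``(row, col)`` points traced at the 0.5
    iso-level of the binary grid (marching squares).  Requires at least 8
    boundary points; smaller structures are not measurable.
    """
    if mask.count == 0:
        raise EmptyStructureError("cannot contour an empty mask")
    labeled = skmeasure.label(mask.grid, connectivity=2)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    component = labeled == int(np.argmax(counts))
    padded = np.pad(component, 1).astype(float)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise EmptyStructureError("no traceable boundary")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if len(contour) < 8:
        raise EmptyStructureError(
            f"boundary has only {len(contour)} points (< 8); structure too small"
        )
    return contour


def fit_ellipse_direct(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit (algebraic, ellipse-specific).

    Minimizes the algebraic conic residual subject to the ellipse
    constraint ``4ac - b^2 = 1``, using the numerically stable partitioned
    eigen-formulation; input points are centered and scaled first so
    near-circular data remain well conditioned.

    Parameters
    ----------
    points
        ``(n, 2)`` array of ``(row, col)`` boundary points, ``n >= 5``,
        not collinear.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise DegenerateFitError("need at least 5 two-dimensional points")
    # work in (x, y) = (col, row); precondition by centering and scaling
    x = pts[:, 1]
    y = pts[:, 0]
    cx, cy = x.mean(), y.mean()
    scale = np.sqrt(((x - cx) ** 2 + (y - cy) ** 2).mean())
    if scale <= 0 or not np.isfinite(scale):
        raise DegenerateFitError("zero scatter: all points coincide")
    xs = (x - cx) / scale
    ys = (y - cy) / scale

    d1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    d2 = np.column_stack([xs, ys, np.ones_like(xs)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("rank-deficient scatter (collinear points?)") from exc
    m = s1 + s2 @ t
    # premultiply by C^{-1} for constraint matrix C = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    # ellipse-specific solution: 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    candidates = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(candidates) == 0:
        raise DegenerateFitError("constrained solution is not an ellipse")
    a1 = np.real(eigvec[:, candidates[0]])
    conic = np.concatenate([a1, t @ a1])  # A, B, C, D, E, F in scaled frame
    params = _conic_to_geometric(conic)
    if params is None:
        raise DegenerateFitError("fitted conic is degenerate")
    xc_s, yc_s, a_s, b_s, theta = params
    return EllipseParams(
        center_row=yc_s * scale + cy,
        center_col=xc_s * scale + cx,
        semi_major_a=a_s * scale,
        semi_minor_b=b_s * scale,
        orientation_deg=_normalize_angle_deg(np.degrees(theta)),
    )


def _conic_to_geometric(conic: np.ndarray):
    """Convert ``A x^2 + B xy + C y^2 + D x + E y + F = 0`` to geometric
    ellipse parameters ``(xc, yc, a, b, theta)``; ``None`` if degenerate."""
    A, B, C, D, E, F = conic
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        return None
    xc = (2.0 * C * D - B * E) / disc
    yc = (2.0 * A * E - B * D) / disc
    num = 2.0 * (A * E * E + C * D * D + F * B * B - B * D * E - 4.0 * A * C * F)
    root = np.sqrt((A - C) ** 2 + B * B)
    arg_plus = num * (A + C + root)
    arg_minus = num * (A + C - root)
    if arg_plus < 0 or arg_minus < 0:
        return None
    axis_plus = -np.sqrt(arg_plus) / disc  # disc < 0, so these are positive
    axis_minus = -np.sqrt(arg_minus) / disc
    if not (np.isfinite(axis_plus) and np.isfinite(axis_minus)) or min(
        axis_plus, axis_minus
    ) <= 0:
        return None
    # major axis = eigenvector of the (positive-definite-normalized)
    # quadratic form belonging to the smaller eigenvalue
    sign = 1.0 if (A + C) > 0 else -1.0
    quad = sign * np.array([[A, B / 2.0], [B / 2.0, C]])
    eigvals, eigvecs = np.linalg.eigh(quad)
    v = eigvecs[:, 0]  # eigh sorts ascending; column 0 <-> smallest eigenvalue
    theta = np.arctan2(v[1], v[0])
    a = max(axis_plus, axis_minus)
    b = min(axis_plus, axis_minus)
    return xc, yc, a, b, theta


def ellipse_circumference(e: EllipseParams) -> float:
    """Exact ellipse perimeter ``4 a E(m)``, ``m = 1 - (b/a)^2``.

    ``E`` is the complete elliptic integral of the second kind, so the
    circle limit gives ``2*pi*r`` and the flat limit ``b -> 0`` gives
    ``4 a``.
    """
    a, b = e.semi_major_a, e.semi_minor_b
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m))


# ---------------------------------------------------------------------------
# axis and depth measurements
# ---------------------------------------------------------------------------


def principal_axis(mask: LabelMask) -> AxisMeasurement:
    """Long axis of the minimum-area rotated rectangle of occupied pixels.

    The returned caliper endpoints are the midpoints of the rectangle's
    two short sides.  When the rectangle is square (axis ambiguous), the
    axis closer to horizontal is chosen.
    """
    occupied = np.argwhere(mask.grid)
    if occupied.size == 0:
        raise EmptyStructureError("cannot measure an empty mask")
    if len(occupied) == 1:
        p = (float(occupied[0, 0]), float(occupied[0, 1]))
        return AxisMeasurement(0.0, 0.0, (p, p))

    from shapely import MultiPoint

    # reduce to the convex hull first (qhull is fast; the min-area
    # rectangle depends only on hull vertices)
    pts_xy = occupied[:, ::-1].astype(np.float64)  # (col, row)
    if len(pts_xy) > 3:
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(pts_xy)
            pts_xy = pts_xy[hull.vertices]
        except QhullError:
            pass  # collinear input; shapely handles the degenerate hull
    mp = MultiPoint([(float(x), float(y)) for x, y in pts_xy])
    mrr = mp.minimum_rotated_rectangle
    if mrr.geom_type == "Point":
        r, c = float(mrr.y), float(mrr.x)
        return AxisMeasurement(0.0, 0.0, ((r, c), (r, c)))
    if mrr.geom_type == "LineString":
        (x0, y0), (x1, y1) = mrr.coords[0], mrr.coords[-1]
        return _axis_from_segment((y0, x0), (y1, x1))

    corners = np.asarray(mrr.exterior.coords)[:4]  # (x, y)
    side_a = corners[1] - corners[0]
    side_b = corners[2] - corners[1]
    len_a = float(np.hypot(*side_a))
    len_b = float(np.hypot(*side_b))
    if abs(len_a - len_b) <= 1e-9:
        # square: take the axis closer to horizontal
        ang_a = abs(_normalize_angle_deg(np.degrees(np.arctan2(side_a[1], side_a[0]))))
        ang_b = abs(_normalize_angle_deg(np.degrees(np.arctan2(side_b[1], side_b[0]))))
        long_first = ang_a <= ang_b
    else:
        long_first = len_a > len_b
    if long_first:
        p0 = (corners[0] + corners[3]) / 2.0  # midpoints of short sides
        p1 = (corners[1] + corners[2]) / 2.0
    else:
        p0 = (corners[0] + corners[1]) / 2.0
        p1 = (corners[3] + corners[2]) / 2.0
    return _axis_from_segment((p0[1], p0[0]), (p1[1], p1[0]))


def _axis_from_segment(p0: tuple[float, float], p1: tuple[float, float]) -> AxisMeasurement:
    (r0, c0), (r1, c1) = p0, p1
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0.0:
        return AxisMeasurement(0.0, 0.0, (p0, p1))
    angle = _normalize_angle_deg(float(np.degrees(np.arctan2(r1 - r0, c1 - c0))))
    # order endpoints left-to-right for determinism
    if (c0, r0) > (c1, r1):
        p0, p1 = p1, p0
    return AxisMeasurement(length, angle, (tuple(p0), tuple(p1)))


def vertical_depth(mask: LabelMask) -> DepthMeasurement:
    """Vertical extent of the axis-aligned bounding box of occupied pixels.

    ``column_ref`` is the column whose own vertical chord is deepest
    (earliest such column on ties); it positions the displayed caliper
    pair, while the depth itself is the bounding-box extent.
    """
    occupied = np.argwhere(mask.grid)
    if occupied.size == 0:
        raise EmptyStructureError("cannot measure an empty mask")
    rows = occupied[:, 0]
    top, bottom = float(rows.min()), float(rows.max())
    cols = occupied[:, 1]
    col_ids = np.unique(cols)
    best_col, best_span = int(col_ids[0]), -1.0
    for c in col_ids:
        rc = rows[cols == c]
        span = float(rc.max() - rc.min())
        if span > best_span:
            best_span, best_col = span, int(c)
    return DepthMeasurement(bottom - top, top, bottom, float(best_col))


def px_to_cm(
    length_px: float,
    row_spacing_cm: float,
    col_spacing_cm: float,
    axis: str = "isotropic",
) -> float:
    """Convert a pixel length to cm.

    Vertical depths use the row spacing, horizontal runs the column
    spacing; oblique lengths (ellipse perimeters, rotated axes) are only
    meaningful with isotropic spacing and raise otherwise.
    """
    if row_spacing_cm <= 0 or col_spacing_cm <= 0:
        raise ValueError("pixel spacing must be positive")
    if axis == "row":
        return length_px * row_spacing_cm
    if axis == "col":
        return length_px * col_spacing_cm
    if axis == "isotropic":
        if abs(row_spacing_cm - col_spacing_cm) > 1e-6:
            raise AnisotropicSpacingError(
                f"isotropic conversion requires equal spacings, got "
                f"row={row_spacing_cm} cm, col={col_spacing_cm} cm"
            )
        return length_px * row_spacing_cm
    raise ValueError(f"unknown axis {axis!r}")
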