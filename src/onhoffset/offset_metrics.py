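"""Per-eye derived measurements of canal-opening misalignment.

From a demarcation set plus CRVT/EOB landmarks this module computes the
quantities used to characterize the offset among the three optic-nerve-head
canal openings:

* ASCO offset -- vector from the fitted BMO center to the fitted ASCO
  center; reported as an angular deviation (nasal horizontal midline = 0
  degrees, positive superior) and an extent in pixels.
* CRVT offset -- same convention for the central retinal vascular trunk.
* shift index -- CRVT distance from the BMO center divided by the distance
  to the BMO margin in the same direction (a/b in [0, 1]); defined as 1.0
  when the CRVT is not visible inside the BMO, in which case its angular
  deviation is undefined.
* offset ratio -- CRVT offset extent over ASCO offset extent; undefined
  when the shift index is 1.0 (the CRVT extent cannot be measured) or when
  the ASCO offset is below a small epsilon.
* direction class (nasal / superior / temporal / inferior) and completeness
  class (complete / incomplete / excluded) of the ASCO demarcation.

All angular measurements use the canonical right-eye frame (+x nasal,
+y superior); left eyes are mirrored at ingestion so that one convention
serves both lateralities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ellipse_fit import FitConfig, FitResult, UnfittableError, fit_ellipse
from .geometry import (
    GeometricEllipse,
    Point2D,
    ellipse_area,
    ray_ellipse_intersection,
)
from .synthetic_eye import DemarcationSet, ScanConfig

__all__ = [
    "AnalysisConfig",
    "EyeLandmarks",
    "OffsetResult",
    "image_to_canonical",
    "canonical_to_image",
    "orient_canonical",
    "angular_deviation",
    "compute_shift_index",
    "compute_offset_ratio",
    "classify_direction",
    "classify_completeness",
    "estimate_asco_area",
    "analyze_eye",
]


@dataclass(frozen=True)
class AnalysisConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    eps_px: float = 0.5  # minimum offset extent for a defined angle/ratio


@dataclass(frozen=True)
class EyeLandmarks:
    """Non-margin landmarks of one eye, in the canonical frame.

    The longest-EOB meridian may be given directly (``eob_meridian``,
    temporal-reference degrees) or as a marked point on the infrared image
    (``eob_point``), in which case the meridian is measured from the fitted
    BMO center during analysis.
    """

    crvt: Point2D | None
    crvt_visible: bool
    bmo_area_device_mm2: float | None = None
    eob_point: Point2D | None = None
    eob_meridian: float | None = None  # temporal-reference, degrees
    eob_length_um: float | None = None


@dataclass(frozen=True)
class OffsetResult:
    """Derived offset metrics of one eye; None marks an undefined quantity,
    with the reason recorded in ``reasons``."""

    eye_id: str
    bmo_center: Point2D
    asco_center: Point2D | None
    asco_offset_angle: float | None  # nasal-reference degrees
    asco_offset_extent: float | None  # px
    crvt_offset_angle: float | None
    crvt_offset_extent: float | None
    shift_index: float
    offset_ratio: float | None
    eob_meridian: float | None
    direction_class: str | None
    completeness: str
    max_gap_deg: float
    asco_area_est_mm2: float | None
    bmo_fit: FitResult | None = None
    asco_fit: FitResult | None = None
    reasons: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# frames and angles


def image_to_canonical(xy: np.ndarray, laterality: str) -> np.ndarray:
    """Map image-space coordinates (y down) into the canonical right-eye
    frame (+x nasal, +y superior).

    Right eyes (OD) flip the y axis; left eyes (OS) additionally mirror x so
    that nasal is +x for both.  Each axis map is its own inverse, so the
    same function converts back (see :func:`canonical_to_image`).
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"unknown laterality {laterality!r}")
    xy = np.asarray(xy, dtype=float)
    out = xy.copy()
    out[..., 1] = -out[..., 1]
    if laterality == "OS":
        out[..., 0] = -out[..., 0]
    return out


def canonical_to_image(xy: np.ndarray, laterality: str) -> np.ndarray:
    """Inverse of :func:`image_to_canonical` (an involution per axis)."""
    return image_to_canonical(xy, laterality)


def orient_canonical(points, laterality: str):
    """Orient image-space points into the canonical right-eye frame.

    Accepts a Point2D or an (n, 2) array; returns the same kind.
    """
    if isinstance(points, Point2D):
        out = image_to_canonical(points.as_array()[None, :], laterality)[0]
        return Point2D(float(out[0]), float(out[1]))
    return image_to_canonical(points, laterality)


def angular_deviation(
    center: Point2D, target: Point2D, reference: str = "nasal"
) -> float:
    """Angle of ``target`` from ``center`` in degrees, in (-180, 180].

    ``reference='nasal'`` sets the nasal horizontal midline to 0 with
    positive angles superior; ``reference='temporal'`` measures from the
    temporal horizontal midline instead (used for the longest externally
    oblique border).  Inputs must already be in the canonical frame.
    """
    dx = target.x - center.x
    dy = target.y - center.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("angular deviation undefined for zero-length offset")
    if reference == "nasal":
        a = math.degrees(math.atan2(dy, dx))
    elif reference == "temporal":
        a = math.degrees(math.atan2(dy, -dx))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return 180.0 if a == -180.0 else a


def classify_direction(angle_nasal_ref: float) -> str:
    """Direction class of an offset angle (nasal-reference degrees).

    Nasal (-45, 45), superior [45, 135], temporal |angle| > 135, inferior
    [-135, -45].  Boundary ties go to the vertical classes (superior /
    inferior) -- a measure-zero choice made for determinism.
    """
    a = angle_nasal_ref
    if not (-180.0 < a <= 180.0):
        raise ValueError("angle must be in (-180, 180]")
    if 45.0 <= a <= 135.0:
        return "superior"
    if -135.0 <= a <= -45.0:
        return "inferior"
    if -45.0 < a < 45.0:
        return "nasal"
    return "temporal"


# --------------------------------------------------------------------------
# scalar metrics


def compute_shift_index(
    bmo: GeometricEllipse, crvt: Point2D | None, crvt_visible: bool
) -> float:
    """Shift index a/b in [0, 1].

    a is the CRVT distance from the BMO center, b the distance from the BMO
    center to the BMO margin in the CRVT direction.  When the CRVT is not
    visible within the BMO the index is defined as exactly 1.0 (and its
    angular deviation is undefined).  A visible CRVT strictly outside the
    BMO is an inconsistent input.
    """
    if not crvt_visible:
        return 1.0
    if crvt is None:
        raise ValueError("visible CRVT requires a position")
    a = math.hypot(crvt.x - bmo.center.x, crvt.y - bmo.center.y)
    if a == 0.0:
        return 0.0  # CRVT at the center: no shift, direction undefined
    theta = math.degrees(math.atan2(crvt.y - bmo.center.y, crvt.x - bmo.center.x))
    margin = ray_ellipse_intersection(bmo, bmo.center, theta)
    b = math.hypot(margin.x - bmo.center.x, margin.y - bmo.center.y)
    si = a / b
    if si > 1.0 + 1e-9:
        raise ValueError("visible CRVT lies outside the BMO boundary")
    return min(si, 1.0)


def compute_offset_ratio(
    crvt_extent: float | None,
    asco_extent: float | None,
    shift_index: float,
    eps: float = 0.5,
) -> float | None:
    """CRVT offset extent over ASCO offset extent; None when undefined.

    Undefined when the shift index is 1.0 (the CRVT offset extent cannot be
    measured) or the ASCO offset extent is below ``eps`` pixels.
    """
    if shift_index >= 1.0 - 1e-12:
        return None
    if crvt_extent is None or asco_extent is None or asco_extent < eps:
        return None
    return crvt_extent / asco_extent


def classify_completeness(
    d: DemarcationSet, scan: ScanConfig | None = None
) -> tuple[str, float]:
    """Completeness class of the ASCO demarcation and the largest gap.

    The gap is the longest circular run of unmarked ASCO half-directions
    times the angular spacing of the unique directions.  Gaps <= 30 degrees
    are 'complete'; gaps > 30 and <= 90 'incomplete'; gaps > 90 'excluded'
    (such eyes were removed from the cohort this convention follows).
    """
    dirs, marked = d.direction_marks("ASCO")
    n = len(dirs)
    if n == 0:
        raise ValueError("no ASCO records")
    spacing = 360.0 / n
    if marked.all():
        return "complete", 0.0
    if not marked.any():
        return "excluded", 360.0
    # longest circular run of False
    ext = np.concatenate([~marked, ~marked])
    best = run = 0
    for v in ext:
        run = run + 1 if v else 0
        best = max(best, run)
    best = min(best, n)
    max_gap = best * spacing
    if max_gap <= 30.0:
        return "complete", max_gap
    if max_gap <= 90.0:
        return "incomplete", max_gap
    return "excluded", max_gap


def estimate_asco_area(
    bmo_area_device_mm2: float,
    bmo_fit: GeometricEllipse,
    asco_fit: GeometricEllipse,
) -> float:
    """ASCO area (mm^2) from the device BMO area scaled by the fitted-area
    ratio; scale invariant in pixel units."""
    if bmo_area_device_mm2 <= 0:
        raise ValueError("device BMO area must be positive")
    return bmo_area_device_mm2 * ellipse_area(asco_fit) / ellipse_area(bmo_fit)


# --------------------------------------------------------------------------
# per-eye pipeline


def analyze_eye(
    d: DemarcationSet,
    landmarks: EyeLandmarks,
    config: AnalysisConfig | None = None,
) -> OffsetResult:
    """Full per-eye measurement pipeline.

    Fits the BMO ellipse (all points; BMO demarcation is complete by
    contract), fits the ASCO ellipse from marked points only (the fit itself
    extrapolates missing arcs -- no imputation), then derives angles,
    extents, shift index, offset ratio, and the direction and completeness
    classes.  Fields that cannot be measured are None with a reason code;
    eyes whose ASCO demarcation falls in the 'excluded' class still report
    all BMO-side metrics.
    """
    cfg = config or AnalysisConfig()
    reasons: list[str] = []

    bmo_fit = fit_ellipse(d.points("BMO"), cfg.fit)
    bmo_center = bmo_fit.ellipse.center

    asco_fit = None
    asco_pts = d.points("ASCO", marked_only=True)
    try:
        asco_fit = fit_ellipse(asco_pts, cfg.fit)
    except UnfittableError:
        reasons.append("asco_unfittable")

    completeness, max_gap = classify_completeness(d)

    asco_center = None
    asco_angle = None
    asco_extent = None
    direction = None
    if asco_fit is not None:
        asco_center = asco_fit.ellipse.center
        asco_extent = math.hypot(
            asco_center.x - bmo_center.x, asco_center.y - bmo_center.y
        )
        if asco_extent >= cfg.eps_px:
            asco_angle = angular_deviation(bmo_center, asco_center, "nasal")
            direction = classify_direction(asco_angle)
        else:
            reasons.append("asco_offset_below_eps")

    crvt_angle = None
    crvt_extent = None
    try:
        shift_index = compute_shift_index(
            bmo_fit.ellipse, landmarks.crvt, landmarks.crvt_visible
        )
    except ValueError:
        # Marked-visible CRVT falling outside the fitted BMO: treat per the
        # outside-the-BMO convention rather than failing the eye.
        shift_index = 1.0
        reasons.append("crvt_outside_fitted_bmo")
    if shift_index >= 1.0 - 1e-12:
        reasons.append("crvt_angle_undefined_shift_index_1")
    elif shift_index == 0.0:
        reasons.append("crvt_at_center")
    else:
        crvt_extent = math.hypot(
            landmarks.crvt.x - bmo_center.x, landmarks.crvt.y - bmo_center.y
        )
        crvt_angle = angular_deviation(bmo_center, landmarks.crvt, "nasal")

    offset_ratio = compute_offset_ratio(
        crvt_extent, asco_extent, shift_index, cfg.eps_px
    )

    eob_meridian = landmarks.eob_meridian
    if eob_meridian is None and landmarks.eob_point is not None:
        eob_meridian = angular_deviation(
            bmo_center, landmarks.eob_point, "temporal"
        )

    asco_area_est = None
    if (
        asco_fit is not None
        and landmarks.bmo_area_device_mm2 is not None
        and landmarks.bmo_area_device_mm2 > 0
    ):
        asco_area_est = estimate_asco_area(
            landmarks.bmo_area_device_mm2, bmo_fit.ellipse, asco_fit.ellipse
        )

    return OffsetResult(
        eye_id=d.eye_id,
        bmo_center=bmo_center,
        asco_center=asco_center,
        asco_offset_angle=asco_angle,
        asco_offset_extent=asco_extent,
        crvt_offset_angle=crvt_angle,
        crvt_offset_extent=crvt_extent,
        shift_index=shift_index,
        offset_ratio=offset_ratio,
        eob_meridian=eob_meridian,
        direction_class=direction,
        completeness=completeness,
        max_gap_deg=max_gap,
        asco_area_est_mm2=asco_area_est,
        bmo_fit=bmo_fit,
        asco_fit=asco_fit,
        reasons=tuple(reasons),
    )
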