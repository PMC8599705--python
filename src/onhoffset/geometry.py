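"""Exact 2-D ellipse geometry.

Representations, conversions, orthogonal point-to-boundary distance, ray
intersection, area, and boundary sampling for the two near-elliptical canal
openings of the optic nerve head (Bruch's membrane opening and anterior
scleral opening) measured on the enface plane.

Conventions
-----------
* Angles are degrees in the public interface (radians internally).
* Coordinate frame is mathematical: +x rightward, +y upward.  Image-space
  inputs (y down) are converted at ingestion (see :mod:`onhoffset.io_cli`).
* Ellipse rotation is counter-clockwise from +x and normalized to [0, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NonEllipseError",
    "Point2D",
    "ConicEllipse",
    "GeometricEllipse",
    "conic_to_geometric",
    "geometric_to_conic",
    "point_ellipse_distance",
    "boundary_distances",
    "ray_ellipse_intersection",
    "ellipse_area",
    "sample_boundary",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class NonEllipseError(ValueError):
    """Raised when conic coefficients do not describe a real, finite ellipse."""


@dataclass(frozen=True)
class Point2D:
    """A point on the enface x-y pixel plane."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ConicEllipse:
    """Implicit second-order curve a*x^2 + b*x*y + c*y^2 + d*x + e*y + f = 0.

    The representation is scale invariant (any nonzero multiple of the
    coefficient vector describes the same curve).  Construction requires the
    elliptic discriminant b^2 - 4ac < 0.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        v = self.coefficients
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite conic coefficients")
        if not np.any(v):
            raise ValueError("all-zero conic coefficients")
        if self.b * self.b - 4.0 * self.a * self.c >= 0.0:
            raise NonEllipseError(
                "discriminant b^2 - 4ac >= 0: not an ellipse"
            )

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.c, self.d, self.e, self.f], dtype=float
        )

    def evaluate(self, x, y):
        """Evaluate the implicit polynomial at (x, y); zero on the curve."""
        return (
            self.a * x * x
            + self.b * x * y
            + self.c * y * y
            + self.d * x
            + self.e * y
            + self.f
        )


@dataclass(frozen=True)
class GeometricEllipse:
    """Center / semi-axes / rotation form of an ellipse.

    ``rotation`` is the angle of the semi-major axis, degrees CCW from +x,
    normalized to [0, 180).  Invariant: semi_major >= semi_minor > 0.
    """

    center: Point2D
    semi_major: float
    semi_minor: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.semi_major)
            and math.isfinite(self.semi_minor)
            and math.isfinite(self.rotation)
        ):
            raise ValueError("non-finite ellipse parameters")
        if not (0.0 < self.semi_minor <= self.semi_major):
            raise ValueError(
                "require semi_major >= semi_minor > 0, got "
                f"{self.semi_major}, {self.semi_minor}"
            )
        object.__setattr__(self, "rotation", self.rotation % 180.0)

    def contains(self, p: Point2D, *, strict: bool = True) -> bool:
        """Whether ``p`` lies inside the ellipse (strictly, by default)."""
        u, v = _frame_coords(self, p.as_array()[None, :])
        q = (u[0] / self.semi_major) ** 2 + (v[0] / self.semi_minor) ** 2
        return q < 1.0 if strict else q <= 1.0


def _frame_coords(g: GeometricEllipse, xy: np.ndarray):
    """Map points into the ellipse frame, folded to the first quadrant."""
    phi = math.radians(g.rotation)
    ct, st = math.cos(phi), math.sin(phi)
    dx = xy[:, 0] - g.center.x
    dy = xy[:, 1] - g.center.y
    u = np.abs(dx * ct + dy * st)
    v = np.abs(-dx * st + dy * ct)
    return u, v


def _golden_distances_numpy(u, v, a, b, n_iter):
    # Squared distance to the first-quadrant arc is unimodal in the
    # parametric angle for first-quadrant points, so golden-section search
    # is exact up to interval width.
    lo = np.zeros_like(u)
    hi = np.full_like(u, 0.5 * np.pi)

    def f(t):
        return (a * np.cos(t) - u) ** 2 + (b * np.sin(t) - v) ** 2

    h = hi - lo
    c1 = hi - _GOLDEN * h
    c2 = lo + _GOLDEN * h
    f1, f2 = f(c1), f(c2)
    for _ in range(n_iter):
        left = f1 < f2
        hi = np.where(left, c2, hi)
        lo = np.where(left, lo, c1)
        h = hi - lo
        c1 = hi - _GOLDEN * h
        c2 = lo + _GOLDEN * h
        f1, f2 = f(c1), f(c2)
    return np.sqrt(f(0.5 * (lo + hi)))


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _golden_distances_jit(u, v, a, b, n_iter):  # pragma: no cover
        out = np.empty(u.shape[0])
        for i in range(u.shape[0]):
            ui = u[i]
            vi = v[i]
            lo = 0.0
            hi = 0.5 * np.pi
            for _ in range(n_iter):
                h = hi - lo
                c1 = hi - _GOLDEN * h
                c2 = lo + _GOLDEN * h
                d1x = a * np.cos(c1) - ui
                d1y = b * np.sin(c1) - vi
                d2x = a * np.cos(c2) - ui
                d2y = b * np.sin(c2) - vi
                if d1x * d1x + d1y * d1y < d2x * d2x + d2y * d2y:
                    hi = c2
                else:
                    lo = c1
            t = 0.5 * (lo + hi)
            ex = a * np.cos(t) - ui
            ey = b * np.sin(t) - vi
            out[i] = np.sqrt(ex * ex + ey * ey)
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def boundary_distances(
    g: GeometricEllipse, xy: np.ndarray, n_iter: int = 64
) -> np.ndarray:
    """Orthogonal distances from each row of ``xy`` (n, 2) to the boundary.

    Distances are the minimal Euclidean (geometric) distances to the ellipse
    curve; interior points measure to the nearest boundary point.  The
    parametric-angle interval after ``n_iter`` golden-section steps is
    ~(pi/2) * 0.618**n_iter; the distance error is quadratic in it.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must have shape (n, 2)")
    u, v = _frame_coords(g, xy)
    if _HAVE_NUMBA:
        return _golden_distances_jit(u, v, g.semi_major, g.semi_minor, n_iter)
    return _golden_distances_numpy(u, v, g.semi_major, g.semi_minor, n_iter)


def point_ellipse_distance(g: GeometricEllipse, p: Point2D) -> float:
    """Minimal Euclidean distance from ``p`` to the ellipse boundary (>= 0)."""
    return float(boundary_distances(g, p.as_array()[None, :])[0])


def geometric_to_conic(g: GeometricEllipse) -> ConicEllipse:
    """Implicit conic coefficients of ``g``, normalized to unit norm, a > 0."""
    phi = math.radians(g.rotation)
    ct, st = math.cos(phi), math.sin(phi)
    ia2 = 1.0 / g.semi_major**2
    ib2 = 1.0 / g.semi_minor**2
    A = ct * ct * ia2 + st * st * ib2
    B = 2.0 * ct * st * (ia2 - ib2)
    C = st * st * ia2 + ct * ct * ib2
    cx, cy = g.center.x, g.center.y
    D = -2.0 * A * cx - B * cy
    E = -B * cx - 2.0 * C * cy
    F = A * cx * cx + B * cx * cy + C * cy * cy - 1.0
    v = np.array([A, B, C, D, E, F])
    v /= np.linalg.norm(v)
    return ConicEllipse(*v)


def conic_to_geometric(c: ConicEllipse) -> GeometricEllipse:
    """Center / axes / rotation of the conic.

    The center solves the gradient-zero linear system of the implicit
    polynomial; axis lengths and rotation come from the eigensystem of the
    quadratic-form matrix.  Degenerate conics (zero or imaginary area) raise
    :class:`NonEllipseError`.
    """
    a, b, cc, d, e, f = c.coefficients
    M = np.array([[a, b / 2.0], [b / 2.0, cc]])
    try:
        center = np.linalg.solve(2.0 * M, [-d, -e])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - disc<0 guards
        raise NonEllipseError("singular quadratic form") from exc
    # Conic value at the center; strictly negative for a real ellipse after
    # sign normalization by the (positive-definite side) quadratic form.
    f0 = f + 0.5 * (d * center[0] + e * center[1])
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals * -f0 <= 0.0):
        raise NonEllipseError("degenerate conic: zero or imaginary area")
    radii = np.sqrt(-f0 / evals)  # larger radius pairs with smaller |eval|
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    major_vec = evecs[:, order[0]]
    rotation = math.degrees(math.atan2(major_vec[1], major_vec[0])) % 180.0
    return GeometricEllipse(
        center=Point2D(float(center[0]), float(center[1])),
        semi_major=float(radii[0]),
        semi_minor=float(radii[1]),
        rotation=rotation,
    )


def ray_ellipse_intersection(
    g: GeometricEllipse, origin: Point2D, direction_deg: float
) -> Point2D:
    """Unique boundary point along the half-line from an interior origin.

    ``direction_deg`` is CCW from +x.  The origin must be strictly inside
    the ellipse (the shift-index construction measures from the fitted BMO
    center, which is interior by definition); otherwise ValueError.
    """
    if not g.contains(origin):
        raise ValueError("ray origin must lie strictly inside the ellipse")
    c = geometric_to_conic(g)
    th = math.radians(direction_deg)
    ux, uy = math.cos(th), math.sin(th)
    ox, oy = origin.x, origin.y
    A = c.a * ux * ux + c.b * ux * uy + c.c * uy * uy
    B = (
        2.0 * c.a * ox * ux
        + c.b * (ox * uy + oy * ux)
        + 2.0 * c.c * oy * uy
        + c.d * ux
        + c.e * uy
    )
    C = c.evaluate(ox, oy)
    disc = B * B - 4.0 * A * C
    t = (-B + math.sqrt(disc)) / (2.0 * A)
    return Point2D(ox + t * ux, oy + t * uy)


def ellipse_area(g: GeometricEllipse) -> float:
    """Area pi * semi_major * semi_minor (px^2)."""
    return math.pi * g.semi_major * g.semi_minor


def sample_boundary(g: GeometricEllipse, angles_deg) -> np.ndarray:
    """Boundary points at parametric angles (degrees), shape (n, 2).

    Parametric convention: the point at parametric angle t is
    ``center + R(rotation) @ (semi_major*cos t, semi_minor*sin t)``, so t is
    measured in the ellipse frame, not the polar angle of the point.
    """
    t = np.radians(np.asarray(angles_deg, dtype=float))
    phi = math.radians(g.rotation)
    ct, st = math.cos(phi), math.sin(phi)
    ex = g.semi_major * np.cos(t)
    ey = g.semi_minor * np.sin(t)
    x = g.center.x + ex * ct - ey * st
    y = g.center.y + ex * st + ey * ct
    return np.column_stack([x, y])
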