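"""Best-fit ellipse estimation from demarcated landmark points.

The canal-opening margins (BMO, ASCO) are demarcated as scattered points on
the enface plane, often covering only part of the boundary because a shifted
opening cannot be captured by every BMO-centered radial scan.  The opening
center is defined as the center of the ellipse minimizing the sum of squared
orthogonal distances to the points (Nelder-Mead over a 5-parameter geometric
form).  The arithmetic centroid of the points is provided as the naive,
arc-coverage-biased comparator: with a missing arc it is pulled toward the
observed points, while the fitted ellipse extrapolates the boundary.

Optimization notes
------------------
* The search variable is (cx, cy, log semi_major, log semi_minor, rotation),
  so every iterate is a valid ellipse; raw conic coefficients can wander into
  hyperbolae under Nelder-Mead.
* Initialization is a numerically stable direct algebraic least-squares
  ellipse fit (constrained so the solution is always an ellipse), with a
  centroid-and-spread fallback for degenerate algebraic systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    GeometricEllipse,
    Point2D,
    boundary_distances,
    conic_to_geometric,
    ConicEllipse,
    NonEllipseError,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "UnfittableError",
    "fit_cost",
    "fit_ellipse",
    "geometric_centroid",
]


class UnfittableError(ValueError):
    """Point set cannot identify an ellipse (too few / collinear points)."""


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the Nelder-Mead ellipse fit.

    ``restarts`` perturbed re-starts are attempted (deterministically, from
    ``seed``) only while the simplex has not converged; the best run is
    reported.  ``cond_threshold`` rejects near-collinear point sets by the
    singular-value ratio of the centered coordinates.
    """

    max_iter: int = 2000
    restarts: int = 3
    seed: int = 0
    cond_threshold: float = 1e10
    fatol: float = 1e-10
    xatol: float = 1e-8
    dist_iters: int = 40


@dataclass(frozen=True)
class FitResult:
    ellipse: GeometricEllipse
    cost: float
    n_points: int
    converged: bool
    n_restarts_used: int


def _as_xy(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, dtype=float)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], Point2D):
            xy = np.array([[p.x, p.y] for p in pts], dtype=float)
        else:
            xy = np.asarray(pts, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be (n, 2) coordinates or Point2D list")
    return xy


def fit_cost(g: GeometricEllipse, points) -> float:
    """Sum of squared orthogonal distances from the points to ``g``."""
    xy = _as_xy(points)
    if len(xy) == 0:
        raise ValueError("empty point list")
    d = boundary_distances(g, xy)
    return float(np.dot(d, d))


def geometric_centroid(points) -> Point2D:
    """Arithmetic mean of the point coordinates (the naive center)."""
    xy = _as_xy(points)
    if len(xy) == 0:
        raise ValueError("empty point list")
    m = xy.mean(axis=0)
    return Point2D(float(m[0]), float(m[1]))


def _algebraic_fit(xy: np.ndarray) -> GeometricEllipse | None:
    """Direct least-squares ellipse fit (ellipse-constrained, conditioned).

    Solves the quadratic-constraint algebraic problem on centered/scaled
    coordinates; returns None when the reduced eigenproblem yields no
    ellipse (degenerate configurations)."""
    x, y = xy[:, 0], xy[:, 1]
    mx, my = x.mean(), y.mean()
    s = max(float(x.std()), float(y.std()), 1e-12)
    xs, ys = (x - mx) / s, (y - my) / s
    D1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError:
        return None
    M = S1 + S2 @ T
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    try:
        evals, evecs = np.linalg.eig(M)
    except np.linalg.LinAlgError:
        return None
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (cond > 0)
    if not np.any(ok):
        return None
    a1 = np.real(evecs[:, np.flatnonzero(ok)[0]])
    A, B, C = a1
    D, E, F = T @ a1
    # Undo the centering/scaling substitution xs=(x-mx)/s, ys=(y-my)/s.
    a = A / s**2
    b = B / s**2
    c = C / s**2
    d = (-2.0 * A * mx - B * my) / s**2 + D / s
    e = (-B * mx - 2.0 * C * my) / s**2 + E / s
    f = (
        (A * mx * mx + B * mx * my + C * my * my) / s**2
        - (D * mx + E * my) / s
        + F
    )
    try:
        return conic_to_geometric(ConicEllipse(a, b, c, d, e, f))
    except (NonEllipseError, ValueError):
        return None


def _fallback_init(xy: np.ndarray) -> GeometricEllipse:
    m = xy.mean(axis=0)
    sx = max(2.0 * float(xy[:, 0].std()), 1e-6)
    sy = max(2.0 * float(xy[:, 1].std()), 1e-6)
    return GeometricEllipse(
        Point2D(float(m[0]), float(m[1])), max(sx, sy), min(sx, sy),
        0.0 if sx >= sy else 90.0,
    )


def _pack(g: GeometricEllipse) -> np.ndarray:
    return np.array(
        [
            g.center.x,
            g.center.y,
            math.log(g.semi_major),
            math.log(g.semi_minor),
            math.radians(g.rotation),
        ]
    )


def _unpack(p: np.ndarray) -> GeometricEllipse:
    a, b = math.exp(p[2]), math.exp(p[3])
    rot = math.degrees(p[4])
    if b > a:
        a, b = b, a
        rot += 90.0
    return GeometricEllipse(Point2D(float(p[0]), float(p[1])), a, b, rot)


def _params_cost(p: np.ndarray, xy: np.ndarray, n_iter: int) -> float:
    d = boundary_distances(_unpack(p), xy, n_iter=n_iter)
    return float(np.dot(d, d))


def fit_ellipse(points, config: FitConfig | None = None) -> FitResult:
    """Ellipse minimizing the squared-orthogonal-distance cost.

    Requires at least 5 non-collinear points (a conic has 5 degrees of
    freedom); raises :class:`UnfittableError` otherwise.  Deterministic
    given ``config`` (restart perturbations are seeded).  The returned cost
    never exceeds the initialization cost.
    """
    cfg = config or FitConfig()
    xy = _as_xy(points)
    if len(xy) < 5:
        raise UnfittableError(f"need >= 5 points, got {len(xy)}")
    sv = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if sv[1] <= 0.0 or sv[0] / sv[1] > cfg.cond_threshold:
        raise UnfittableError("collinear or near-degenerate point set")

    g0 = _algebraic_fit(xy) or _fallback_init(xy)
    p0 = _pack(g0)
    init_cost = _params_cost(p0, xy, cfg.dist_iters)

    best_p, best_cost = p0, init_cost
    converged = False
    rng = np.random.default_rng(cfg.seed)
    n_restarts_used = 0
    start = p0
    for attempt in range(1 + cfg.restarts):
        if attempt > 0:
            n_restarts_used += 1
            scale = np.array([0.02, 0.02, 0.02, 0.02, 0.02])
            start = p0 + rng.normal(0.0, 1.0, 5) * scale * (
                1.0 + abs(p0)
            )
        res = minimize(
            _params_cost,
            start,
            args=(xy, cfg.dist_iters),
            method="Nelder-Mead",
            options={
                "maxiter": cfg.max_iter,
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
            },
        )
        if res.fun < best_cost:
            best_cost = float(res.fun)
            best_p = np.asarray(res.x)
        if res.success:
            converged = True
            break
    return FitResult(
        ellipse=_unpack(best_p),
        cost=float(best_cost),
        n_points=len(xy),
        converged=converged,
        n_restarts_used=n_restarts_used,
    )
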