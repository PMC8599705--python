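"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from onhoffset.geometry import GeometricEllipse, Point2D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_random_ellipse(rng, center_scale=50.0, axis_range=(1.0, 100.0)):
    """A random valid ellipse with axis ratio bounded away from degeneracy."""
    a = rng.uniform(*axis_range)
    b = a * rng.uniform(0.2, 1.0)
    return GeometricEllipse(
        Point2D(
            float(rng.uniform(-center_scale, center_scale)),
            float(rng.uniform(-center_scale, center_scale)),
        ),
        a,
        b,
        float(rng.uniform(0.0, 180.0)),
    )


@pytest.fixture
def random_ellipse():
    return make_random_ellipse


def brute_force_distance(g: GeometricEllipse, p: Point2D, n: int = 10**5):
    """Minimum distance to ``n`` dense parametric boundary samples.

    Independent of the package's golden-section path: evaluates the
    parametric boundary directly and takes the minimum.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    phi = math.radians(g.rotation)
    ct, st = math.cos(phi), math.sin(phi)
    ex = g.semi_major * np.cos(t)
    ey = g.semi_minor * np.sin(t)
    x = g.center.x + ex * ct - ey * st
    y = g.center.y + ex * st + ey * ct
    return float(np.sqrt(np.min((x - p.x) ** 2 + (y - p.y) ** 2)))


@pytest.fixture
def brute_distance():
    return brute_force_distance


def rigid_transform(xy, angle_deg, tx, ty):
    """Rotate points about the origin then translate."""
    th = math.radians(angle_deg)
    R = np.array(
        [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
    )
    return np.asarray(xy, dtype=float) @ R.T + np.array([tx, ty])


def transform_ellipse(g: GeometricEllipse, angle_deg, tx, ty):
    """The same rigid transform applied to an ellipse."""
    c = rigid_transform([[g.center.x, g.center.y]], angle_deg, tx, ty)[0]
    return GeometricEllipse(
        Point2D(float(c[0]), float(c[1])),
        g.semi_major,
        g.semi_minor,
        (g.rotation + angle_deg) % 180.0,
    )
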