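"""Synthetic eyes and BMO-centered radial-scan demarcation.

Generates ground-truth optic-nerve-head geometries -- a Bruch's membrane
opening (BMO) ellipse, an anterior scleral opening (ASCO) ellipse shifted by
a controllable offset vector, and a central retinal vascular trunk (CRVT)
displaced further along the same direction -- and then simulates how the
margins are demarcated on radial OCT scans centered on the BMO.

The sampler reproduces the two structural artifacts of BMO-centered radial
scanning of a shifted ASCO:

* a contiguous angular span in which the ASCO cannot be demarcated at all
  (the scan lines miss the externally oblique region on the side the ASCO
  has moved away from), and
* uneven spacing of the marked ASCO points, clustered where the ASCO margin
  runs close to the BMO center.

Both follow from a single deterministic rule: an ASCO point is markable on a
half-scan only if its radial position exceeds the BMO margin's by more than
``visibility_threshold`` (plus optional random dropout).  Missingness is
therefore monotone in the true ASCO/BMO offset, which is the mechanism the
completeness classification downstream is meant to detect.

All randomness is driven by counter-based seed splitting, so cohorts are
reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    GeometricEllipse,
    Point2D,
    ray_ellipse_intersection,
)

__all__ = [
    "EyeTruth",
    "ScanConfig",
    "DemarcationRecord",
    "DemarcationSet",
    "PopulationModel",
    "generate_eye",
    "simulate_demarcation",
    "generate_cohort",
]


@dataclass(frozen=True)
class EyeTruth:
    """Ground-truth geometry of one synthetic eye (canonical right-eye frame,
    +x nasal, +y superior, pixels)."""

    bmo: GeometricEllipse
    asco: GeometricEllipse
    crvt: Point2D
    crvt_visible: bool
    laterality: str  # "OD" | "OS"
    scale_um_per_px: float
    eob_meridian: float | None = None  # temporal-reference angle, degrees
    eob_length_um: float | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.crvt_visible and not self.bmo.contains(self.crvt, strict=False):
            raise ValueError("visible CRVT must lie inside the BMO")
        ratio = (self.asco.semi_major * self.asco.semi_minor) / (
            self.bmo.semi_major * self.bmo.semi_minor
        )
        if not (1.0 / 3.0 <= ratio <= 3.0):
            raise ValueError("ASCO area must be within a factor 3 of BMO area")

    @property
    def bmo_area_mm2(self) -> float:
        px2 = math.pi * self.bmo.semi_major * self.bmo.semi_minor
        return px2 * (self.scale_um_per_px / 1000.0) ** 2


@dataclass(frozen=True)
class ScanConfig:
    """Radial-scan acquisition and demarcation-noise parameters.

    Defaults follow the acquisition protocol: 24 radial scans in 15-degree
    increments centered on the BMO (each scan is one diameter, i.e. two
    half-directions), 2 px isotropic Gaussian demarcation noise.

    ``visibility_threshold`` (px) is the externally-oblique-border criterion:
    the ASCO is markable on a half-scan only where its radial position
    exceeds the BMO margin's by more than the threshold.  The default -20 px
    (-200 um at 10 um/px) encodes that the anterior scleral surface remains
    traceable until the ASCO margin is buried more than ~200 um radially
    inside the BMO margin; see docs/methods.md for the calibration.
    """

    n_scans: int = 24
    increment_deg: float = 15.0
    noise_sd: float = 2.0
    visibility_threshold: float = -20.0
    dropout_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.increment_deg <= 0:
            raise ValueError("need n_scans >= 1 and a positive increment")
        if self.n_scans * self.increment_deg < 180.0 - 1e-9:
            raise ValueError(
                "scan fan must cover >= 360 degrees of half-directions "
                "(n_scans * increment >= 180)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")


@dataclass(frozen=True)
class DemarcationRecord:
    structure: str  # "BMO" | "ASCO"
    scan_index: int
    half: int  # 0 or 1
    direction_deg: float  # half-direction from the BMO center, canonical
    marked: bool
    point: Point2D | None

    def __post_init__(self) -> None:
        if self.structure not in ("BMO", "ASCO"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.marked and self.point is None:
            raise ValueError("marked record requires a point")
        if not self.marked and self.point is not None:
            raise ValueError("unmarked record must not carry a point")


@dataclass(frozen=True)
class DemarcationSet:
    """All demarcation records of one eye (canonical frame in memory)."""

    eye_id: str
    laterality: str
    scale_um_per_px: float
    records: tuple[DemarcationRecord, ...]

    def __post_init__(self) -> None:
        keys = [(r.structure, r.scan_index, r.half) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (structure, scan, half) record")
        for r in self.records:
            if r.structure == "BMO" and not r.marked:
                raise ValueError(
                    "BMO demarcation must be complete (unmarked BMO record)"
                )
        # canonical record order, so equality and file layout are stable
        object.__setattr__(
            self,
            "records",
            tuple(
                sorted(
                    self.records,
                    key=lambda r: (r.structure, r.scan_index, r.half),
                )
            ),
        )

    def points(self, structure: str, marked_only: bool = True) -> np.ndarray:
        pts = [
            [r.point.x, r.point.y]
            for r in self.records
            if r.structure == structure and (r.marked or not marked_only)
        ]
        return np.array(pts, dtype=float).reshape(-1, 2)

    def direction_marks(self, structure: str = "ASCO"):
        """Unique half-direction angles (sorted) and whether each is marked.

        With the default 24 x 15-degree fan every geometric direction is
        covered by two scan records; a direction counts as marked if any of
        its records is marked.
        """
        marks: dict[float, bool] = {}
        for r in self.records:
            if r.structure != structure:
                continue
            key = round(r.direction_deg % 360.0, 6) % 360.0
            marks[key] = marks.get(key, False) or r.marked
        dirs = np.array(sorted(marks), dtype=float)
        return dirs, np.array([marks[d] for d in dirs], dtype=bool)


@dataclass(frozen=True)
class PopulationModel:
    """Distributions from which synthetic eyes are drawn.

    Area defaults are the cohort means/SDs of the morphometry this package
    emulates (BMO area 2.62 +/- 0.89 mm^2, ASCO area approximately equal to
    BMO area); the offset-direction mixture excludes the inferior sector for
    the ASCO, and the CRVT sits at roughly twice the ASCO offset along the
    same direction (true offset ratio mean 2.0).
    """

    bmo_area_mean_mm2: float = 2.62
    bmo_area_sd_mm2: float = 0.89
    bmo_area_min_mm2: float = 0.5
    asco_bmo_area_ratio_mean: float = 1.0
    asco_bmo_area_ratio_sd: float = 0.10
    axis_ratio_mean: float = 0.87  # semi-minor / semi-major
    axis_ratio_sd: float = 0.05
    # (nasal, superior, temporal) mixture weights; inferior excluded.  The
    # offset direction is a Gaussian mixture centered on the three sector
    # midlines (0, 90, 180 degrees nasal-reference), truncated to stay
    # ``offset_dir_margin_deg`` clear of the inferior sector boundaries.
    offset_dir_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    offset_dir_sd_deg: float = 18.0
    offset_dir_margin_deg: float = 15.0
    direction_fixed_deg: float | None = None
    offset_extent_frac_mean: float = 0.15  # of the BMO effective radius
    offset_extent_shape: float | None = 3.0  # gamma shape; None = fixed
    offset_extent_frac_min: float = 0.05  # floor: tiny offsets have no
    # anatomically meaningful direction
    offset_ratio_mean: float = 2.0
    offset_ratio_sd: float = 0.5
    offset_ratio_min: float = 0.2
    crvt_jitter_sd_px: float = 3.0
    crvt_outside_prob: float = 0.09
    prob_right_eye: float = 0.5
    scale_um_per_px: float = 10.0
    eob_min_length_um: float = 100.0
    eob_angle_noise_sd_deg: float = 8.0

    def __post_init__(self) -> None:
        if min(self.offset_dir_probs) < 0 or sum(self.offset_dir_probs) <= 0:
            raise ValueError("invalid offset direction weights")
        if not (0.0 <= self.crvt_outside_prob <= 1.0):
            raise ValueError("crvt_outside_prob must be a probability")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")


_SECTOR_CENTERS = (0.0, 90.0, 180.0)  # nasal, superior, temporal midlines


def _wrap_angle(a: float) -> float:
    """Map to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _radial_distance(g: GeometricEllipse, origin: Point2D, theta: float):
    p = ray_ellipse_intersection(g, origin, theta)
    return math.hypot(p.x - origin.x, p.y - origin.y), p


def generate_eye(model: PopulationModel, seed) -> EyeTruth:
    """Draw one eye from the population model; deterministic given seed."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        area = -1.0
        while area < model.bmo_area_min_mm2:
            area = model.bmo_area_mean_mm2 + model.bmo_area_sd_mm2 * (
                rng.standard_normal()
            )
        px_per_mm = 1000.0 / model.scale_um_per_px
        r_eff = math.sqrt(area * px_per_mm**2 / math.pi)

        def axes(r, q):
            return r / math.sqrt(q), r * math.sqrt(q)

        q_bmo = float(
            np.clip(
                model.axis_ratio_mean
                + model.axis_ratio_sd * rng.standard_normal(),
                0.6,
                1.0,
            )
        )
        center = Point2D(
            300.0 + 20.0 * rng.standard_normal(),
            300.0 + 20.0 * rng.standard_normal(),
        )
        a_b, b_b = axes(r_eff, q_bmo)
        bmo = GeometricEllipse(center, a_b, b_b, rng.uniform(0.0, 180.0))

        area_ratio = float(
            np.clip(
                model.asco_bmo_area_ratio_mean
                + model.asco_bmo_area_ratio_sd * rng.standard_normal(),
                1.0 / 3.0 + 1e-6,
                3.0 - 1e-6,
            )
        )
        q_asco = float(
            np.clip(
                model.axis_ratio_mean
                + model.axis_ratio_sd * rng.standard_normal(),
                0.6,
                1.0,
            )
        )
        if model.direction_fixed_deg is not None:
            theta = _wrap_angle(model.direction_fixed_deg)
        else:
            w = np.asarray(model.offset_dir_probs, dtype=float)
            lo = -45.0 + model.offset_dir_margin_deg
            hi = 225.0 - model.offset_dir_margin_deg
            while True:  # truncated Gaussian mixture, inferior excluded
                sector = int(rng.choice(3, p=w / w.sum()))
                theta = _SECTOR_CENTERS[sector] + (
                    model.offset_dir_sd_deg * rng.standard_normal()
                )
                if lo <= theta <= hi:
                    break
            theta = _wrap_angle(theta)
        if model.offset_extent_shape is None:
            frac = model.offset_extent_frac_mean
        elif model.offset_extent_frac_mean <= 0:
            frac = 0.0
        else:
            frac = max(
                rng.gamma(
                    model.offset_extent_shape,
                    model.offset_extent_frac_mean / model.offset_extent_shape,
                ),
                model.offset_extent_frac_min,
            )
        delta = frac * r_eff
        ux, uy = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        asco_center = Point2D(center.x + delta * ux, center.y + delta * uy)
        r_eff_asco = r_eff * math.sqrt(area_ratio)
        a_a, b_a = axes(r_eff_asco, q_asco)
        asco = GeometricEllipse(asco_center, a_a, b_a, rng.uniform(0.0, 180.0))

        true_ratio = max(
            model.offset_ratio_mean
            + model.offset_ratio_sd * rng.standard_normal(),
            model.offset_ratio_min,
        )
        jitter = model.crvt_jitter_sd_px * rng.standard_normal(2)
        crvt = Point2D(
            center.x + true_ratio * delta * ux + jitter[0],
            center.y + true_ratio * delta * uy + jitter[1],
        )
        force_outside = rng.random() < model.crvt_outside_prob
        if force_outside:
            b_theta, _ = _radial_distance(bmo, center, theta)
            rad = b_theta * (1.05 + 0.25 * rng.random())
            crvt = Point2D(center.x + rad * ux, center.y + rad * uy)
        crvt_visible = bmo.contains(crvt)

        laterality = "OD" if rng.random() < model.prob_right_eye else "OS"

        if not asco.contains(center):
            continue  # BMO center must see the whole ASCO margin; resample

        # Longest externally oblique border: direction maximizing the radial
        # ASCO-minus-BMO margin distance from the BMO center.
        grid = np.arange(0.0, 360.0, 2.0)
        eob = np.empty_like(grid)
        for i, th in enumerate(grid):
            ra, _ = _radial_distance(asco, center, th)
            rb, _ = _radial_distance(bmo, center, th)
            eob[i] = ra - rb
        k = int(np.argmax(eob))
        eob_len_um = float(eob[k]) * model.scale_um_per_px
        if eob_len_um >= model.eob_min_length_um:
            th = grid[k]
            # temporal-reference angle of the meridian direction
            meridian = _wrap_angle(
                math.degrees(
                    math.atan2(
                        math.sin(math.radians(th)),
                        -math.cos(math.radians(th)),
                    )
                )
                + model.eob_angle_noise_sd_deg * rng.standard_normal()
            )
            eob_meridian, eob_length = meridian, eob_len_um
        else:
            eob_meridian, eob_length = None, None

        try:
            return EyeTruth(
                bmo=bmo,
                asco=asco,
                crvt=crvt,
                crvt_visible=crvt_visible,
                laterality=laterality,
                scale_um_per_px=model.scale_um_per_px,
                eob_meridian=eob_meridian,
                eob_length_um=eob_length,
            )
        except ValueError:
            continue
    raise RuntimeError("could not generate a valid eye in 200 attempts")


def simulate_demarcation(
    eye: EyeTruth, scan: ScanConfig, eye_id: str = "eye0000"
) -> DemarcationSet:
    """Demarcate one eye on a BMO-centered radial-scan fan.

    Per half-direction, the BMO point is the exact ray/ellipse intersection
    plus isotropic Gaussian noise; the ASCO point likewise, but marked only
    when the externally-oblique-border criterion holds (true ASCO radius
    exceeding the true BMO radius by more than the visibility threshold)
    and a Bernoulli(1 - dropout_prob) draw succeeds.  Deterministic given
    ``scan.seed``; random draws are consumed in a fixed per-record order so
    markedness never shifts the noise stream.
    """
    center = eye.bmo.center
    if not (eye.bmo.contains(center) and eye.asco.contains(center)):
        raise ValueError("BMO center must lie strictly inside both ellipses")
    rng = np.random.default_rng(np.random.SeedSequence(scan.seed))
    records: list[DemarcationRecord] = []
    for i in range(scan.n_scans):
        for half in (0, 1):
            theta = (i * scan.increment_deg + 180.0 * half) % 360.0
            rb, bp = _radial_distance(eye.bmo, center, theta)
            ra, ap = _radial_distance(eye.asco, center, theta)
            noise = rng.standard_normal(4) * scan.noise_sd
            u_drop = rng.random()
            records.append(
                DemarcationRecord(
                    "BMO",
                    i,
                    half,
                    theta,
                    True,
                    Point2D(bp.x + noise[0], bp.y + noise[1]),
                )
            )
            visible = (ra - rb) > scan.visibility_threshold
            marked = visible and (u_drop >= scan.dropout_prob)
            records.append(
                DemarcationRecord(
                    "ASCO",
                    i,
                    half,
                    theta,
                    marked,
                    Point2D(ap.x + noise[2], ap.y + noise[3])
                    if marked
                    else None,
                )
            )
    return DemarcationSet(
        eye_id=eye_id,
        laterality=eye.laterality,
        scale_um_per_px=eye.scale_um_per_px,
        records=tuple(records),
    )


def _child_seed(master: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    model: PopulationModel, scan: ScanConfig, n: int, seed: int
) -> list[tuple[EyeTruth, DemarcationSet]]:
    """n independent synthetic eyes with demarcations; reproducible and
    order-independent (per-eye streams by counter-based seed splitting)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        eye = generate_eye(
            model, np.random.SeedSequence(entropy=seed, spawn_key=(i, 0))
        )
        scan_i = replace(scan, seed=_child_seed(seed, i, 1))
        out.append((eye, simulate_demarcation(eye, scan_i, f"eye{i:04d}")))
    return out
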