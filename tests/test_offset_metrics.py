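"""Per-eye metric tests: frames, angles, indices, classes, pipeline."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from onhoffset.geometry import GeometricEllipse, Point2D
from onhoffset.offset_metrics import (
    EyeLandmarks,
    analyze_eye,
    angular_deviation,
    classify_completeness,
    classify_direction,
    compute_offset_ratio,
    compute_shift_index,
    estimate_asco_area,
    image_to_canonical,
    orient_canonical,
)
from onhoffset.synthetic_eye import (
    DemarcationRecord,
    DemarcationSet,
    PopulationModel,
    ScanConfig,
    generate_eye,
    simulate_demarcation,
)
from onhoffset.io_cli import meta_from_truth


class TestOrientation:
    def test_od_image_down_right_is_nasal_inferior(self):
        out = image_to_canonical(np.array([[10.0, 10.0]]), "OD")[0]
        assert tuple(out) == (10.0, -10.0)

    def test_os_mirrors_x(self):
        out = image_to_canonical(np.array([[10.0, 0.0]]), "OS")[0]
        assert out[0] == -10.0

    def test_zero_vector_fixed(self):
        for lat in ("OD", "OS"):
            assert tuple(image_to_canonical(np.zeros((1, 2)), lat)[0]) == (0.0, 0.0)

    def test_involution(self):
        xy = np.array([[3.0, -4.0], [-1.5, 2.5]])
        for lat in ("OD", "OS"):
            np.testing.assert_array_equal(
                image_to_canonical(image_to_canonical(xy, lat), lat), xy
            )

    def test_point_api(self):
        p = orient_canonical(Point2D(1.0, 2.0), "OD")
        assert (p.x, p.y) == (1.0, -2.0)
        with pytest.raises(ValueError):
            orient_canonical(Point2D(0, 0), "LEFT")


class TestAngularDeviation:
    @pytest.mark.parametrize(
        "target, reference, expected",
        [
            (Point2D(10, 0), "nasal", 0.0),
            (Point2D(0, 10), "nasal", 90.0),
            (Point2D(0, -10), "nasal", -90.0),
            (Point2D(-10, 0), "temporal", 0.0),
            (Point2D(-10, 0), "nasal", 180.0),
            (Point2D(0, 10), "temporal", 90.0),
        ],
    )
    def test_reference_conventions(self, target, reference, expected):
        c = Point2D(0.0, 0.0)
        assert angular_deviation(c, target, reference) == pytest.approx(expected)

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            angular_deviation(Point2D(1, 1), Point2D(1, 1))

    def test_range_is_half_open(self, rng):
        c = Point2D(0.0, 0.0)
        for _ in range(200):
            th = rng.uniform(0, 2 * math.pi)
            a = angular_deviation(
                c, Point2D(math.cos(th), math.sin(th)), "nasal"
            )
            assert -180.0 < a <= 180.0


class TestShiftIndex:
    def test_center_is_zero(self):
        g = GeometricEllipse(Point2D(0, 0), 100, 100)
        assert compute_shift_index(g, Point2D(0, 0), True) == 0.0

    def test_circle_half_radius(self):
        g = GeometricEllipse(Point2D(0, 0), 100, 100)
        assert compute_shift_index(g, Point2D(50, 0), True) == pytest.approx(0.5)

    def test_invisible_is_one(self):
        g = GeometricEllipse(Point2D(0, 0), 100, 100)
        assert compute_shift_index(g, None, False) == 1.0

    def test_visible_outside_rejected(self):
        g = GeometricEllipse(Point2D(0, 0), 100, 100)
        with pytest.raises(ValueError):
            compute_shift_index(g, Point2D(150, 0), True)

    def test_ellipse_direction_dependent(self):
        g = GeometricEllipse(Point2D(0, 0), 100, 50)
        assert compute_shift_index(g, Point2D(0, 25), True) == pytest.approx(0.5)
        assert compute_shift_index(g, Point2D(25, 0), True) == pytest.approx(0.25)


class TestOffsetRatio:
    def test_basic(self):
        assert compute_offset_ratio(100.0, 50.0, 0.5) == pytest.approx(2.0)

    def test_absent_at_shift_index_one(self):
        assert compute_offset_ratio(100.0, 50.0, 1.0) is None

    def test_absent_below_eps(self):
        assert compute_offset_ratio(100.0, 0.1, 0.5, eps=0.5) is None


class TestDirectionClass:
    @pytest.mark.parametrize(
        "angle, expected",
        [
            (0.0, "nasal"), (30.0, "nasal"), (-44.9, "nasal"),
            (90.0, "superior"), (45.0, "superior"), (135.0, "superior"),
            (180.0, "temporal"), (-150.0, "temporal"), (150.0, "temporal"),
            (-90.0, "inferior"), (-45.0, "inferior"), (-135.0, "inferior"),
        ],
    )
    def test_sectors_and_boundaries(self, angle, expected):
        assert classify_direction(angle) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(270.0)


def _pattern_set(marked_pattern, n_scans=6, increment=30.0):
    """DemarcationSet with the given ASCO mark pattern on a 12-direction fan."""
    records = []
    for i in range(n_scans):
        for half in (0, 1):
            th = (i * increment + 180 * half) % 360.0
            rad = math.radians(th)
            bp = Point2D(80 * math.cos(rad), 80 * math.sin(rad))
            records.append(DemarcationRecord("BMO", i, half, th, True, bp))
            k = 2 * i + half
            marked = bool(marked_pattern[k])
            ap = (
                Point2D(100 * math.cos(rad), 100 * math.sin(rad))
                if marked
                else None
            )
            records.append(DemarcationRecord("ASCO", i, half, th, marked, ap))
    return DemarcationSet("e0", "OD", 10.0, tuple(records))


def _brute_force_completeness(marked_by_angle):
    """Independent oracle: longest circular unmarked run via rotation."""
    angles = sorted(marked_by_angle)
    flags = [marked_by_angle[a] for a in angles]
    n = len(flags)
    spacing = 360.0 / n
    best = 0
    for start in range(n):
        run = 0
        for k in range(n):
            if not flags[(start + k) % n]:
                run += 1
            else:
                break
        best = max(best, run)
    gap = best * spacing
    if gap <= 30.0:
        return "complete", gap
    if gap <= 90.0:
        return "incomplete", gap
    return "excluded", gap


class TestCompleteness:
    def test_all_marked(self):
        label, gap = classify_completeness(_pattern_set([1] * 12))
        assert (label, gap) == ("complete", 0.0)

    def test_examples_from_thresholds(self):
        # 15-degree grid: 3 consecutive unmarked -> 45 deg -> incomplete;
        # 7 consecutive -> 105 deg -> excluded; built on a 24-direction fan
        def fan(unmarked_angles):
            p = []
            for i in range(12):
                for half in (0, 1):
                    th = (i * 15.0 + 180.0 * half) % 360.0
                    p.append(0 if th in unmarked_angles else 1)
            return _pattern_set(p, n_scans=12, increment=15.0)

        label, gap = classify_completeness(fan({30.0, 45.0, 60.0}))
        assert (label, gap) == ("incomplete", 45.0)
        label, gap = classify_completeness(
            fan({30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 120.0})
        )
        assert (label, gap) == ("excluded", 105.0)
        # two unmarked at 15-degree spacing is exactly 30 -> still complete
        label, gap = classify_completeness(fan({30.0, 45.0}))
        assert (label, gap) == ("complete", 30.0)

    def test_wraparound_counts_as_one_run(self):
        p = [0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0]
        # positions 11,0,1 on the direction circle need to merge -- build
        # the pattern so the unmarked angles are circularly adjacent
        label, gap = classify_completeness(_pattern_set(p))
        oracle = _brute_force_completeness(
            {r.direction_deg: r.marked
             for r in _pattern_set(p).records if r.structure == "ASCO"}
        )
        assert (label, gap) == oracle

    def test_matches_brute_force_all_patterns(self):
        """Exhaustive 2^12 check against the rotation-scan oracle."""
        for bits in itertools.product([0, 1], repeat=12):
            d = _pattern_set(bits)
            marked = {
                r.direction_deg: r.marked
                for r in d.records
                if r.structure == "ASCO"
            }
            expect = _brute_force_completeness(marked)
            got = classify_completeness(d)
            assert got == expect, bits


class TestAscoArea:
    def test_equal_fits(self):
        g = GeometricEllipse(Point2D(0, 0), 10, 8)
        assert estimate_asco_area(2.5, g, g) == pytest.approx(2.5)

    def test_double_area(self):
        b = GeometricEllipse(Point2D(0, 0), 10, 8)
        a = GeometricEllipse(Point2D(0, 0), 20, 8)
        assert estimate_asco_area(2.0, b, a) == pytest.approx(4.0)

    def test_pixel_scale_invariance(self):
        b = GeometricEllipse(Point2D(0, 0), 10, 8, 30)
        a = GeometricEllipse(Point2D(2, 1), 12, 9, 140)
        for k in (0.5, 3.0):
            bk = GeometricEllipse(
                Point2D(0, 0), 10 * k, 8 * k, 30
            )
            ak = GeometricEllipse(Point2D(2 * k, k), 12 * k, 9 * k, 140)
            assert estimate_asco_area(2.0, bk, ak) == pytest.approx(
                estimate_asco_area(2.0, b, a)
            )

    def test_nonpositive_area_rejected(self):
        g = GeometricEllipse(Point2D(0, 0), 10, 8)
        with pytest.raises(ValueError):
            estimate_asco_area(0.0, g, g)


def _fixed_eye(offset_px=40.0, ratio=2.0, direction_deg=0.0, seed=1):
    model = PopulationModel(
        bmo_area_sd_mm2=0.0,
        asco_bmo_area_ratio_sd=0.0,
        axis_ratio_sd=0.0,
        direction_fixed_deg=direction_deg,
        offset_extent_shape=None,
        offset_extent_frac_mean=0.0,
        offset_ratio_mean=ratio,
        offset_ratio_sd=0.0,
        crvt_jitter_sd_px=0.0,
        crvt_outside_prob=0.0,
        eob_angle_noise_sd_deg=0.0,
    )
    probe = generate_eye(model, seed=seed)
    r_eff = math.sqrt(probe.bmo.semi_major * probe.bmo.semi_minor)
    model = replace(model, offset_extent_frac_mean=offset_px / r_eff)
    return generate_eye(model, seed=seed)


def _quiet_scan(**kw):
    base = dict(noise_sd=0.0, dropout_prob=0.0, visibility_threshold=-1e9)
    base.update(kw)
    return ScanConfig(**base)


class TestAnalyzeEye:
    def test_zero_offset_eye(self):
        eye = _fixed_eye(offset_px=0.0)
        d = simulate_demarcation(eye, _quiet_scan())
        res = analyze_eye(d, meta_from_truth(d.eye_id, eye).landmarks())
        assert res.asco_offset_extent <= 1e-6
        assert res.shift_index <= 1e-6
        assert res.completeness == "complete"

    def test_known_offset_recovery(self):
        eye = _fixed_eye(offset_px=40.0, ratio=2.0, direction_deg=0.0)
        d = simulate_demarcation(eye, _quiet_scan())
        res = analyze_eye(d, meta_from_truth(d.eye_id, eye).landmarks())
        assert res.asco_offset_extent == pytest.approx(40.0, abs=0.5)
        assert res.crvt_offset_extent == pytest.approx(80.0, abs=0.5)
        assert res.asco_offset_angle == pytest.approx(0.0, abs=0.5)
        assert res.crvt_offset_angle == pytest.approx(0.0, abs=0.5)
        assert res.offset_ratio == pytest.approx(2.0, abs=0.05)
        assert res.direction_class == "nasal"

    def test_invisible_crvt_conventions(self):
        eye = _fixed_eye(offset_px=20.0)
        eye = replace(
            eye,
            crvt=Point2D(eye.bmo.center.x + 500.0, eye.bmo.center.y),
            crvt_visible=False,
        )
        d = simulate_demarcation(eye, _quiet_scan())
        res = analyze_eye(d, meta_from_truth(d.eye_id, eye).landmarks())
        assert res.shift_index == 1.0
        assert res.crvt_offset_angle is None
        assert res.offset_ratio is None

    def test_excluded_eye_still_reports_bmo_side(self):
        eye = _fixed_eye(offset_px=35.0)
        d = simulate_demarcation(
            eye, _quiet_scan(visibility_threshold=-10.0)
        )
        res = analyze_eye(d, meta_from_truth(d.eye_id, eye).landmarks())
        assert res.completeness in ("incomplete", "excluded")
        assert res.bmo_center is not None
        assert res.shift_index is not None

    def test_mirror_consistency(self):
        """An OS eye and its x-mirrored OD twin yield identical metrics."""
        eye = _fixed_eye(offset_px=30.0, direction_deg=40.0, seed=5)
        d = simulate_demarcation(eye, _quiet_scan(noise_sd=2.0, seed=7))
        lm = meta_from_truth(d.eye_id, eye).landmarks()
        res_od = analyze_eye(d, lm)
        d_os = DemarcationSet(
            d.eye_id, "OS", d.scale_um_per_px, d.records
        )
        res_os = analyze_eye(d_os, lm)
        # canonical-frame payloads are identical; laterality only matters
        # at (de)serialization time
        assert res_os.asco_offset_angle == pytest.approx(
            res_od.asco_offset_angle, abs=1e-8
        )
        assert res_os.asco_offset_extent == pytest.approx(
            res_od.asco_offset_extent, abs=1e-8
        )
        assert res_os.shift_index == pytest.approx(res_od.shift_index, abs=1e-8)

    def test_rotation_equivariance(self):
        """Rotating the whole eye by phi adds phi to nasal-reference angles."""
        phi = 25.0
        eye = _fixed_eye(offset_px=30.0, direction_deg=10.0, seed=3)
        d = simulate_demarcation(eye, _quiet_scan(noise_sd=1.0, seed=11))
        lm = meta_from_truth(d.eye_id, eye).landmarks()
        res = analyze_eye(d, lm)

        c = eye.bmo.center
        th = math.radians(phi)
        R = np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )

        def rot_point(p):
            v = R @ np.array([p.x - c.x, p.y - c.y])
            return Point2D(float(v[0] + c.x), float(v[1] + c.y))

        records = tuple(
            DemarcationRecord(
                r.structure,
                r.scan_index,
                r.half,
                (r.direction_deg + phi) % 360.0,
                r.marked,
                rot_point(r.point) if r.point else None,
            )
            for r in d.records
        )
        d_rot = DemarcationSet(d.eye_id, d.laterality, d.scale_um_per_px, records)
        lm_rot = EyeLandmarks(
            crvt=rot_point(lm.crvt),
            crvt_visible=lm.crvt_visible,
            bmo_area_device_mm2=lm.bmo_area_device_mm2,
        )
        res_rot = analyze_eye(d_rot, lm_rot)
        diff = (res_rot.asco_offset_angle - res.asco_offset_angle) % 360.0
        assert diff == pytest.approx(phi, abs=1e-4)
        diff_c = (res_rot.crvt_offset_angle - res.crvt_offset_angle) % 360.0
        assert diff_c == pytest.approx(phi, abs=1e-4)

    def test_extent_recovery_noiseless_population(self):
        """Noiseless complete demarcations recover the true ASCO offset
        extent to sub-0.1 px across a population draw."""
        model = PopulationModel()
        scan = _quiet_scan()
        worst = 0.0
        for s in range(40):
            eye = generate_eye(model, seed=1000 + s)
            d = simulate_demarcation(eye, scan, f"eye{s:04d}")
            res = analyze_eye(d, meta_from_truth(d.eye_id, eye).landmarks())
            true_ext = math.hypot(
                eye.asco.center.x - eye.bmo.center.x,
                eye.asco.center.y - eye.bmo.center.y,
            )
            worst = max(worst, abs(res.asco_offset_extent - true_ext))
        assert worst < 0.1
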