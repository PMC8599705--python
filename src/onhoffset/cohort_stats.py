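"""Cohort-level summaries and comparison statistics.

Collects per-eye :class:`~onhoffset.offset_metrics.OffsetResult` rows into a
table and computes the statistics used for offset cohorts: mean / SD /
normal-theory 95% confidence intervals (offset ratio overall and per
direction class), Pearson correlations of angular deviations (the angles are
treated as linear quantities on (-180, 180], matching the measurement
convention they come from), Williams' test for comparing two dependent
correlations sharing a variable, and the interobserver coefficient of
variation from a one-way random-effects ANOVA.

Eyes whose ASCO demarcation falls in the 'excluded' completeness class are
dropped before summarizing (they were not part of the cohorts this mirrors),
and eyes with shift index 1.0 never carry an offset ratio (the CRVT offset
extent cannot be measured for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .offset_metrics import OffsetResult

__all__ = [
    "CorrComparison",
    "cohort_table",
    "summarize",
    "correlate_angles",
    "williams_test",
    "interobserver_cv",
]


@dataclass(frozen=True)
class CorrComparison:
    """Williams' test of H0: rho12 = rho13 (variable 1 common)."""

    r12: float
    r13: float
    r23: float
    n: int
    t_stat: float
    p_value: float
    df: int
    variant: str


def cohort_table(results: list[OffsetResult]) -> pd.DataFrame:
    """One row per eye; None fields become NaN for numeric columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "eye_id": r.eye_id,
                "bmo_cx": r.bmo_center.x,
                "bmo_cy": r.bmo_center.y,
                "asco_offset_angle": r.asco_offset_angle,
                "asco_offset_extent": r.asco_offset_extent,
                "crvt_offset_angle": r.crvt_offset_angle,
                "crvt_offset_extent": r.crvt_offset_extent,
                "shift_index": r.shift_index,
                "offset_ratio": r.offset_ratio,
                "eob_meridian": r.eob_meridian,
                "direction_class": r.direction_class,
                "completeness": r.completeness,
                "max_gap_deg": r.max_gap_deg,
                "asco_area_est_mm2": r.asco_area_est_mm2,
            }
        )
    df = pd.DataFrame(rows)
    if df["eye_id"].duplicated().any():
        raise ValueError("duplicate eye ids in cohort")
    return df


def _mean_sd_ci(x: np.ndarray) -> dict:
    """Mean, SD and normal-theory (t-based) 95% CI of a sample."""
    n = len(x)
    m = float(np.mean(x))
    if n < 2:
        return {"n": n, "mean": m, "sd": float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan")}
    sd = float(np.std(x, ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return {"n": n, "mean": m, "sd": sd, "ci_low": m - half,
            "ci_high": m + half}


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary table (one row per variable / stratum).

    Reports mean, SD and 95% CI for the offset ratio overall and within each
    ASCO-offset direction class, plus the main continuous measurements, after
    dropping excluded-class eyes.  Raises if no eye has a defined offset
    ratio.
    """
    d = df[df["completeness"] != "excluded"]
    ratios = d["offset_ratio"].dropna().to_numpy(float)
    if len(ratios) < 2:
        raise ValueError("need >= 2 eyes with a defined offset ratio")
    rows = [{"variable": "offset_ratio", "stratum": "all",
             **_mean_sd_ci(ratios)}]
    for cls, grp in d.groupby("direction_class"):
        vals = grp["offset_ratio"].dropna().to_numpy(float)
        if len(vals):
            rows.append({"variable": "offset_ratio", "stratum": str(cls),
                         **_mean_sd_ci(vals)})
    for var in ("asco_offset_extent", "crvt_offset_extent", "shift_index",
                "asco_area_est_mm2", "max_gap_deg"):
        vals = d[var].dropna().to_numpy(float)
        if len(vals):
            rows.append({"variable": var, "stratum": "all",
                         **_mean_sd_ci(vals)})
    n_inc = int((d["completeness"] == "incomplete").sum())
    rows.append({"variable": "incomplete_fraction", "stratum": "all",
                 "n": len(d), "mean": n_inc / len(d), "sd": float("nan"),
                 "ci_low": float("nan"), "ci_high": float("nan")})
    return pd.DataFrame(rows)


def correlate_angles(x, y) -> float:
    """Pearson correlation of two paired angle series (linear treatment).

    Angles are correlated as plain numbers on their stated reference
    conventions; note that flipping the reference meridian (nasal vs
    temporal zero) flips the sign of the correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D series")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("absent values are not allowed; filter first")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance series")
    return float(stats.pearsonr(x, y)[0])


def _det_r(r12, r13, r23):
    return 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23


def _t2_stat(r12, r13, r23, n):
    """Williams/Steiger t2 statistic (array-friendly)."""
    detR = _det_r(r12, r13, r23)
    rbar = 0.5 * (r12 + r13)
    den = 2.0 * ((n - 1.0) / (n - 3.0)) * detR + rbar**2 * (1.0 - r23) ** 3
    return (r12 - r13) * np.sqrt((n - 1.0) * (1.0 + r23) / den)


def _hotelling_stat(r12, r13, r23, n):
    detR = _det_r(r12, r13, r23)
    return (r12 - r13) * np.sqrt(
        (n - 3.0) * (1.0 + r23) / (2.0 * detR)
    )


def williams_test(
    r12: float, r13: float, r23: float, n: int, variant: str = "t2"
) -> CorrComparison:
    """Compare two dependent correlations sharing variable 1.

    Tests H0: rho12 = rho13 given the three pairwise correlations among
    variables (1, 2, 3) measured on the same n subjects.  The statistic is
    referred to Student's t with n - 3 degrees of freedom, two-sided.
    ``variant='t2'`` is the Williams/Steiger form (default);
    ``variant='hotelling'`` is the older Hotelling t.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    detR = _det_r(r12, r13, r23)
    if detR < -1e-12:
        raise ValueError("correlation triple is not positive semi-definite")
    detR = max(detR, 0.0)
    if variant == "t2":
        t = float(_t2_stat(r12, r13, r23, n))
    elif variant == "hotelling":
        if detR == 0.0:
            raise ValueError("degenerate correlation matrix")
        t = float(_hotelling_stat(r12, r13, r23, n))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    df = n - 3
    p = float(2.0 * stats.t.sf(abs(t), df)) if not math.isnan(t) else 1.0
    return CorrComparison(r12, r13, r23, n, t, min(p, 1.0), df, variant)


def williams_null_calibration(
    n_reps: int = 20000,
    n: int = 100,
    rho12: float = 0.4,
    rho13: float = 0.4,
    rho23: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
    variant: str = "t2",
) -> float:
    """Empirical type-I error of :func:`williams_test` under a trivariate
    normal null with rho12 = rho13.

    Draws ``n_reps`` samples of size ``n`` from the stated correlation
    structure, applies the test to each, and returns the rejection rate at
    ``alpha``; a calibrated test returns approximately ``alpha`` (within
    Monte-Carlo error).  Vectorized; deterministic given ``seed``.
    """
    if not (rho12 == rho13):
        raise ValueError("null requires rho12 == rho13")
    C = np.array(
        [[1.0, rho12, rho13], [rho12, 1.0, rho23], [rho13, rho23, 1.0]]
    )
    L = np.linalg.cholesky(C)
    stat = _t2_stat if variant == "t2" else _hotelling_stat
    rng = np.random.default_rng(seed)
    rejected = 0
    for start in range(0, n_reps, 2000):
        m = min(2000, n_reps - start)
        Z = rng.standard_normal((m, n, 3)) @ L.T
        Z = Z - Z.mean(axis=1, keepdims=True)
        Z = Z / Z.std(axis=1, keepdims=True)
        r12 = (Z[:, :, 0] * Z[:, :, 1]).mean(axis=1)
        r13 = (Z[:, :, 0] * Z[:, :, 2]).mean(axis=1)
        r23 = (Z[:, :, 1] * Z[:, :, 2]).mean(axis=1)
        t = stat(r12, r13, r23, n)
        p = 2.0 * stats.t.sf(np.abs(t), n - 3)
        rejected += int((p < alpha).sum())
    return rejected / n_reps


def interobserver_cv(measurements) -> float:
    """Coefficient of variation from a one-way random-effects ANOVA.

    ``measurements`` is an (n_subjects, n_raters) array of repeated
    measurements of the same quantity.  The within-subject SD is the square
    root of the within-subject mean square; the CV is that SD over the grand
    mean.  Scale-free: multiplying all values by k > 0 leaves it unchanged.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects with >= 2 raters each")
    n, k = x.shape
    grand = float(np.mean(x))
    if abs(grand) < 1e-300:
        raise ValueError("zero grand mean: CV undefined")
    within_ss = float(((x - x.mean(axis=1, keepdims=True)) ** 2).sum())
    ms_within = within_ss / (n * (k - 1))
    return math.sqrt(ms_within) / grand
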