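"""Method-validation statistics.

Covers the validation battery of a screening qNMR method: calibration
linearity, detection/quantification limits by the calibration-line method of
DIN 32645, spike recovery, precision (coefficient of variation, gated on a
Shapiro–Wilk normality test), solution stability over a measurement series,
and regression-based comparison against an independent reference method
(LC-MS/MS) with outlier flagging and a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "CalibrationFit", "LodLoq", "ComparisonResult", "fit_calibration",
    "lod_loq_din32645", "compute_recovery", "precision_cv", "stability_check",
    "compare_with_reference",
]


@dataclass
class CalibrationFit:
    """Ordinary least squares of signal response against concentration.

    ``s_y`` is the residual SD (n−2 dof), ``s_x0 = s_y / |slope|`` the process
    standard deviation and ``cv_percent = 100 · s_x0 / x̄`` the procedural
    coefficient of variation.
    """

    slope: float
    intercept: float
    pearson_r: float
    s_y: float
    s_x0: float
    cv_percent: float
    n: int
    x_mean: float
    q_x: float
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def fit_calibration(x, y) -> CalibrationFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("calibration needs >= 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all x identical")
    res = scipy.stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    s_y = float(np.sqrt(np.sum(resid ** 2) / (x.size - 2)))
    s_x0 = s_y / abs(res.slope) if res.slope != 0 else float("inf")
    x_mean = float(x.mean())
    cv = 100.0 * s_x0 / x_mean if x_mean != 0 else float("inf")
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), s_y=s_y, s_x0=s_x0, cv_percent=cv,
        n=int(x.size), x_mean=x_mean, q_x=float(np.sum((x - x_mean) ** 2)),
        x=x, y=y,
    )


@dataclass
class LodLoq:
    """Detection and quantification limits from a calibration line."""

    lod: float
    loq: float
    alpha_lod: float
    alpha_loq: float
    k: float
    dof: int
    iterations: int


def lod_loq_din32645(fit: CalibrationFit, m_replicates: int = 1,
                     alpha_lod: float = 0.05, alpha_loq: float = 0.025,
                     k: float = 3.0, tol: float = 1e-6,
                     max_iter: int = 100) -> LodLoq:
    """Calibration-line detection/quantification limits.

    LOD = s_x0 · t(1−α_lod; n−2) · sqrt(1/m + 1/n + x̄²/Q_x); the LOQ solves
    LOQ = k · s_x0 · t(1−α_loq; n−2) · sqrt(1/m + 1/n + (LOQ−x̄)²/Q_x) by
    fixed-point iteration from 3·LOD (one-sided quantiles, k = 3).
    """
    dof = fit.n - 2
    if dof < 1:
        raise ValueError("need at least 3 calibration points (dof >= 1)")
    if fit.s_y == 0:
        return LodLoq(0.0, 0.0, alpha_lod, alpha_loq, k, dof, 0)
    t_lod = scipy.stats.t.ppf(1.0 - alpha_lod, dof)
    t_loq = scipy.stats.t.ppf(1.0 - alpha_loq, dof)
    base = 1.0 / m_replicates + 1.0 / fit.n
    lod = fit.s_x0 * t_lod * np.sqrt(base + fit.x_mean ** 2 / fit.q_x)
    loq = 3.0 * lod
    trace = []
    for i in range(max_iter):
        new = k * fit.s_x0 * t_loq * np.sqrt(
            base + (loq - fit.x_mean) ** 2 / fit.q_x)
        trace.append(new)
        if abs(new - loq) < tol:
            return LodLoq(float(lod), float(new), alpha_lod, alpha_loq, k,
                          dof, i + 1)
        loq = new
    raise RuntimeError(f"LOQ iteration did not converge; trace={trace[-5:]}")


def compute_recovery(measured: float, blank: float, spiked: float) -> float:
    """Percent recovery of a spike after blank subtraction."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * (measured - blank) / spiked


def precision_cv(values, gate_alpha: float = 0.05) -> dict:
    """Coefficient of variation with a Shapiro–Wilk normality gate.

    Returns ``cv_percent``, ``normality_pass``, ``shapiro_p`` and a
    ``reliable`` flag (False when the gate fails).  Sample SD (ddof=1).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 replicate values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; CV undefined")
    if np.ptp(v) == 0:
        # constant series: trivially precise, normality test undefined
        return {"cv_percent": 0.0, "normality_pass": True,
                "shapiro_p": 1.0, "reliable": True}
    stat, p = scipy.stats.shapiro(v)
    normal = bool(p >= gate_alpha)
    cv = 100.0 * v.std(ddof=1) / abs(mean)
    return {"cv_percent": float(cv), "normality_pass": normal,
            "shapiro_p": float(p), "reliable": normal}


def stability_check(areas, tolerance_frac: float) -> dict:
    """Stability of a repeatedly measured solution over a series (≤ 60 h).

    Pass iff the maximum relative drift from the series mean stays within
    twice the measurement tolerance (a CV expressed as a fraction).
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 time points")
    mean = a.mean()
    if mean == 0:
        raise ValueError("zero mean area")
    drift = np.abs(a - mean) / abs(mean)
    max_drift = float(drift.max())
    return {"max_drift_frac": max_drift,
            "passed": bool(max_drift <= 2.0 * tolerance_frac)}


@dataclass
class ComparisonResult:
    """NMR vs reference-method regression (y = a·x + b on retained pairs)."""

    slope: float
    intercept: float
    pearson_r: float
    n_pairs: int
    outlier_indices: list
    slope_all: float
    intercept_all: float
    pearson_r_all: float
    t_statistic: float
    p_value: float
    systematic_difference: bool     # rejected at 95% iff True
    relative_deviation_percent: np.ndarray = field(repr=False, default=None)


def compare_with_reference(nmr_mg_kg, ref_mg_kg, lod: float,
                           outlier_threshold: float = 3.0) -> ComparisonResult:
    """Regression comparison of NMR results against reference values.

    Pairs whose reference value is at or below ``lod`` are filtered out.
    Outliers are flagged by internally studentized residual beyond
    ``outlier_threshold`` and excluded from the reported fit (the all-pairs
    fit is reported alongside; nothing is silently dropped).  A two-sided
    paired t-test on the retained differences tests for a systematic offset.
    """
    nmr = np.asarray(nmr_mg_kg, dtype=float)
    ref = np.asarray(ref_mg_kg, dtype=float)
    if nmr.size != ref.size:
        raise ValueError("paired arrays must have equal length")
    keep = ref > lod
    nmr, ref = nmr[keep], ref[keep]
    idx = np.flatnonzero(keep)
    if nmr.size < 3:
        raise ValueError("fewer than 3 pairs above the LOD")

    def ols(x, y):
        r = scipy.stats.linregress(x, y)
        return r.slope, r.intercept, r.rvalue

    a_all, b_all, r_all = ols(ref, nmr)

    def studentized(x, y):
        """Externally studentized residuals of an OLS fit of y on x."""
        n = x.size
        a, b, _ = ols(x, y)
        resid = y - (b + a * x)
        sse = float(np.sum(resid ** 2))
        if n <= 3 or sse == 0:
            return np.zeros_like(resid)
        x_mean = x.mean()
        h = 1.0 / n + (x - x_mean) ** 2 / np.sum((x - x_mean) ** 2)
        one_m_h = np.clip(1.0 - h, 1e-12, None)
        s2_loo = np.clip((sse - resid ** 2 / one_m_h) / (n - 3), 1e-300, None)
        return resid / np.sqrt(s2_loo * one_m_h)

    # sequential deletion: flag the worst studentized residual, refit, repeat
    # (two gross outliers would otherwise mask each other through the pooled
    # residual scatter)
    out_mask = np.zeros(ref.size, dtype=bool)
    while np.count_nonzero(~out_mask) > 3:
        stud = studentized(ref[~out_mask], nmr[~out_mask])
        worst = int(np.argmax(np.abs(stud)))
        if np.abs(stud[worst]) <= outlier_threshold:
            break
        out_mask[np.flatnonzero(~out_mask)[worst]] = True
    outliers = [int(i) for i in idx[out_mask]]

    nmr_c, ref_c = nmr[~out_mask], ref[~out_mask]
    if nmr_c.size < 3:
        raise ValueError("fewer than 3 pairs after outlier exclusion")
    a, b, r = ols(ref_c, nmr_c)
    diffs = nmr_c - ref_c
    if np.ptp(diffs) == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = scipy.stats.ttest_rel(nmr_c, ref_c)
    rel_dev = 100.0 * nmr / ref
    return ComparisonResult(
        slope=float(a), intercept=float(b), pearson_r=float(r),
        n_pairs=int(nmr_c.size), outlier_indices=outliers,
        slope_all=float(a_all), intercept_all=float(b_all),
        pearson_r_all=float(r_all), t_statistic=float(t_stat),
        p_value=float(p), systematic_difference=bool(p < 0.05),
        relative_deviation_percent=rel_dev,
    )
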