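"""Per-signal area extraction.

Two modes are used, matching how each cannabinoid signal sits in the oil
spectrum:

* ``window`` — plain trapezoidal integration over a fixed ppm window, for
  signals that are effectively baseline-separated (CBD 3.88/4.52, the CBN
  signals, the external-standard aromatics);
* ``linefit`` — a constrained doublet fit on a local polynomial baseline, for
  the signals riding on the broad CBD aromatic hump (Δ⁹-THC 6.15, Δ⁸-THC 6.12)
  or close to matrix bands (CBD 4.63).

The Δ⁹/Δ⁸ pair differs by only 0.03 ppm and both drift with CBD content, so
fitted candidates are assigned to the two targets by a deterministic
nearest-target rule with matrix-specific windows (the "swap guard").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import scipy.signal

from .spectra import Spectrum1D

__all__ = [
    "SignalDefinition", "FitResult", "integrate_window",
    "fit_doublet_on_baseline", "assign_delta_thc", "estimate_snr",
    "measure_signal",
]

LINEFIT_LABELS = {"CBD 3", "Δ⁹-THC H-3′", "Δ⁸-THC H-3′"}


@dataclass(frozen=True)
class SignalDefinition:
    """One entry of the signal library.

    ``windows`` maps a matrix kind (``hemp``/``MCT``) to a ``(high_ppm,
    low_ppm)`` integration (window mode) or search (linefit mode) interval.
    ``quantify`` is False for interferent signals that are simulated but never
    converted to a concentration; ``aggregate`` is False for signals reported
    for QC only (CBD 2).  ``drifts`` marks signals whose position moves with
    the CBD content.
    """

    analyte: str
    label: str
    center_ppm: float
    multiplicity: str
    j_hz: float
    n_protons: int
    mode: str                       # "window" | "linefit"
    windows: dict = field(default_factory=dict)
    quantify: bool = True
    aggregate: bool = True
    drifts: bool = False
    fwhm_hz: float | None = None    # None -> simulator's sharp default

    def __post_init__(self):
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.mode not in ("window", "linefit"):
            raise ValueError(f"unknown integration mode {self.mode!r}")
        if self.mode == "linefit" and self.quantify and self.label not in LINEFIT_LABELS:
            raise ValueError(f"linefit mode not expected for {self.label!r}")
        for kind, (hi, lo) in self.windows.items():
            if not (lo <= self.center_ppm <= hi):
                raise ValueError(
                    f"{self.label}: window {kind} ({hi}, {lo}) does not contain "
                    f"center {self.center_ppm}"
                )

    def window(self, matrix_kind: str = "hemp") -> tuple[float, float]:
        if matrix_kind in self.windows:
            return self.windows[matrix_kind]
        return self.windows["hemp"]


@dataclass
class FitResult:
    """Outcome of a constrained doublet fit (or a degenerate placeholder)."""

    area: float
    center_ppm: float
    fwhm_hz: float
    baseline_coef: tuple
    converged: bool
    residual_rms: float
    label: str = ""
    flags: list = field(default_factory=list)


def integrate_window(spec: Spectrum1D, signal: SignalDefinition,
                     matrix_kind: str = "hemp") -> float:
    """Trapezoidal absorption integral over the signal's fixed window."""
    hi, lo = signal.window(matrix_kind)
    return spec.integrate(hi, lo)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian in the units of ``x``."""
    hw = fwhm / 2.0
    return (hw / np.pi) / ((x - center) ** 2 + hw ** 2)


def _doublet(x: np.ndarray, area: float, center: float, fwhm_ppm: float,
             j_ppm: float) -> np.ndarray:
    half = area / 2.0
    return (half * _lorentzian(x, center - j_ppm / 2.0, fwhm_ppm)
            + half * _lorentzian(x, center + j_ppm / 2.0, fwhm_ppm))


def fit_doublet_on_baseline(
    spec: Spectrum1D,
    signal: SignalDefinition,
    search_window: tuple[float, float] | None = None,
    matrix_kind: str = "hemp",
    fit_halfwidth_ppm: float = 0.02,
    baseline_degree: int = 2,
    fwhm_guess_hz: float = 1.5,
) -> FitResult:
    """Fit two equal-area, equal-width Lorentzians split by ``signal.j_hz``
    plus a local polynomial baseline; returns the doublet area with the
    baseline excluded.

    The fitted center is free within ``search_window`` (default: the signal's
    matrix window).  The fit region is the found maximum ± ``fit_halfwidth_ppm``
    so the broad CBD hump is locally well approximated by the polynomial.
    Non-convergence or an amplitude indistinguishable from zero yields
    ``converged=False`` and area 0.
    """
    if signal.mode != "linefit":
        raise ValueError(f"{signal.label!r} is not a linefit signal")
    hi, lo = search_window if search_window is not None else signal.window(matrix_kind)
    sl = spec.window_slice(hi, lo)
    x_all = spec.ppm[sl][::-1]
    y_all = spec.real[sl][::-1]
    if x_all.size < 8:
        return FitResult(0.0, signal.center_ppm, 0.0, (), False, 0.0,
                         signal.label, ["window_too_narrow"])

    # remove a straight line through the window edges, then look for local
    # maxima: the candidate nearest the library position wins, so a taller
    # neighbouring doublet or the hump shoulder at the window edge is not
    # mistaken for the target
    edge = max(2, x_all.size // 20)
    x0, x1 = x_all[:edge].mean(), x_all[-edge:].mean()
    y0, y1 = np.median(y_all[:edge]), np.median(y_all[-edge:])
    slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
    detrended = y_all - (y0 + slope * (x_all - x0))
    peaks, props = scipy.signal.find_peaks(
        detrended, prominence=max(1e-3 * np.ptp(detrended), 1e-300))
    if peaks.size:
        keep_peaks = props["prominences"] >= 0.02 * props["prominences"].max()
        cand_x = x_all[peaks[keep_peaks]]
        center0 = float(cand_x[int(np.argmin(np.abs(cand_x - signal.center_ppm)))])
    else:
        center0 = float(x_all[int(np.argmax(detrended))])

    keep = np.abs(x_all - center0) <= fit_halfwidth_ppm
    x, y = x_all[keep], y_all[keep]
    if x.size < baseline_degree + 4:
        return FitResult(0.0, center0, 0.0, (), False, 0.0,
                         signal.label, ["window_too_narrow"])

    j_ppm = signal.j_hz / spec.sf_mhz
    yscale = max(np.abs(y).max(), 1e-300)
    xm = x.mean()

    params = lmfit.Parameters()
    amp0 = max(float(detrended.max()) * (np.pi * fwhm_guess_hz / spec.sf_mhz), 0.0)
    params.add("area", value=amp0, min=0.0)
    params.add("center", value=center0, min=lo, max=hi)
    params.add("fwhm_hz", value=fwhm_guess_hz, min=0.3, max=8.0)
    for k in range(baseline_degree + 1):
        params.add(f"b{k}", value=float(np.median(y)) if k == 0 else 0.0)

    def residual(p):
        model = _doublet(x, p["area"].value, p["center"].value,
                         p["fwhm_hz"].value / spec.sf_mhz, j_ppm)
        base = sum(p[f"b{k}"].value * (x - xm) ** k
                   for k in range(baseline_degree + 1))
        return (y - model - base) / yscale

    try:
        fit = lmfit.minimize(residual, params, method="leastsq")
    except Exception:
        return FitResult(0.0, center0, 0.0, (), False, 0.0,
                         signal.label, ["fit_error"])

    area = float(fit.params["area"].value)
    stderr = fit.params["area"].stderr
    rms = float(np.sqrt(np.mean(fit.residual ** 2)) * yscale)
    coef = tuple(float(fit.params[f"b{k}"].value)
                 for k in range(baseline_degree + 1))
    flags: list[str] = []
    converged = bool(fit.success)
    # amplitude not significant against the local residual -> treat as absent
    if stderr is not None and np.isfinite(stderr) and area < 3.0 * stderr:
        converged = False
        flags.append("below_noise")
    if not fit.success:
        flags.append("non_convergence")
    if not converged:
        area = 0.0
    return FitResult(area, float(fit.params["center"].value),
                     float(fit.params["fwhm_hz"].value), coef, converged, rms,
                     signal.label, flags)


# assignment targets and per-matrix acceptance half-widths for the swap guard
DELTA_TARGETS = {"delta9-THC": 6.15, "delta8-THC": 6.12}
DELTA_TOLERANCE_PPM = {"hemp": 0.06, "MCT": 0.02}


def assign_delta_thc(fits: list[FitResult], matrix_kind: str = "hemp",
                     targets: dict[str, float] | None = None
                     ) -> dict[str, FitResult]:
    """Assign candidate doublet fits near 6.1–6.2 ppm to Δ⁹- and Δ⁸-THC.

    Each converged fit goes to the target minimizing |fitted center − target|
    within the matrix-specific tolerance.  If two fits fall in one target's
    window the higher-shift fit is Δ⁹ (deterministic tie-break); an unmatched
    target receives a zero-area placeholder.  Two fits equidistant from both
    targets are flagged ambiguous.
    """
    if matrix_kind not in DELTA_TOLERANCE_PPM:
        raise ValueError(f"unknown matrix kind {matrix_kind!r}")
    targets = targets or DELTA_TARGETS
    tol = DELTA_TOLERANCE_PPM[matrix_kind]
    hi_name, lo_name = sorted(targets, key=lambda k: -targets[k])  # Δ⁹, Δ⁸
    # deterministic candidate order: descending shift; two searches that
    # converged onto the same peak (overlapping windows) count once
    cands = []
    for f in sorted((f for f in fits if f.converged), key=lambda f: -f.center_ppm):
        if all(abs(f.center_ppm - c.center_ppm) > 0.004 for c in cands):
            cands.append(f)

    def placeholder(name: str, *flags: str) -> FitResult:
        return FitResult(0.0, targets[name], 0.0, (), False, 0.0, name,
                         list(flags) or ["unassigned"])

    out = {hi_name: placeholder(hi_name), lo_name: placeholder(lo_name)}
    in_tol = [f for f in cands
              if min(abs(f.center_ppm - t) for t in targets.values()) <= tol]
    if len(in_tol) >= 2:
        # two resolved doublets: the higher-shift one is Δ⁹ by construction
        if abs(in_tol[0].center_ppm - targets[hi_name]) <= tol:
            out[hi_name] = in_tol[0]
        if abs(in_tol[1].center_ppm - targets[lo_name]) <= tol:
            out[lo_name] = in_tol[1]
    elif len(in_tol) == 1:
        # lone doublet: nearest target wins; an exact tie goes to the
        # higher-shift target and both entries are flagged ambiguous
        f = in_tol[0]
        d_hi = abs(f.center_ppm - targets[hi_name])
        d_lo = abs(f.center_ppm - targets[lo_name])
        if abs(d_hi - d_lo) < 1e-9:
            out[hi_name] = f
            f.flags.append("ambiguous")
            out[lo_name].flags.append("ambiguous")
        elif d_hi < d_lo:
            out[hi_name] = f
        else:
            out[lo_name] = f
    return out


def estimate_snr(spec: Spectrum1D, signal_window: tuple[float, float],
                 noise_window: tuple[float, float],
                 min_snr: float = 250.0) -> tuple[float, list]:
    """Signal-to-noise as peak maximum over twice the noise-region SD.

    Returns ``(ratio, flags)``; ratio is ``inf`` (flagged degenerate) for a
    noise-free region, and values below ``min_snr`` carry a ``low_snr`` flag.
    """
    s_hi, s_lo = max(signal_window), min(signal_window)
    n_hi, n_lo = max(noise_window), min(noise_window)
    if s_hi > n_lo and n_hi > s_lo:
        raise ValueError("signal and noise windows overlap")
    peak = float(spec.real[spec.window_slice(s_hi, s_lo)].max())
    sd = float(np.std(spec.real[spec.window_slice(n_hi, n_lo)]))
    flags: list[str] = []
    if sd == 0.0:
        flags.append("degenerate_noise_region")
        return float("inf"), flags
    ratio = peak / (2.0 * sd)
    if ratio < min_snr:
        flags.append("low_snr")
    return ratio, flags


def measure_signal(spec: Spectrum1D, signal: SignalDefinition,
                   matrix_kind: str = "hemp") -> FitResult:
    """Dispatch a signal to window integration or the doublet fit."""
    if signal.mode == "linefit":
        return fit_doublet_on_baseline(spec, signal, matrix_kind=matrix_kind)
    area = integrate_window(spec, signal, matrix_kind)
    return FitResult(area=float(area), center_ppm=signal.center_ppm,
                     fwhm_hz=0.0, baseline_coef=(), converged=True,
                     residual_rms=0.0, label=signal.label)
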