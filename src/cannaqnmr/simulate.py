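"""Synthetic CBD-oil spectra with the statistical structure the method assumes.

The generator emulates the features of the real measurement that the
downstream stages must survive:

* sharp cannabinoid multiplets between 3 and 8.3 ppm (binomial intensity
  ratios within a multiplet, amplitude ∝ molar concentration × proton count ×
  NS × RG × saturation factor);
* the broad CBD aromatic hump near 6.2 ppm (2 protons, ~40 Hz wide) that
  underlies the Δ⁹/Δ⁸-THC doublets;
* intense triglyceride matrix bands at 0.8–3.0 and 5.29–5.39 ppm (hemp seed
  oil) or the reduced MCT pattern, attenuated by the seven-band multiple
  suppression;
* a TMS reference singlet at 0 ppm (modeled as a pseudo-analyte so a truly
  blank composition yields a truly blank FID);
* complex Gaussian white noise in the time domain;
* optional linear drift of the Δ⁹/Δ⁸/hump positions with CBD content;
* partial-saturation attenuation of the long-T1 external-standard signals,
  modeled by default as exactly the reciprocal of the published empirical
  correction factors so the round trip through PULCON is closed-form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .integration import SignalDefinition
from .spectra import FID, NOMINAL_SF_MHZ, AcquisitionParameters, default_acquisition

__all__ = [
    "LineshapeParams", "SampleComposition", "SuppressionBand",
    "DEFAULT_SUPPRESSION_BANDS", "MOLAR_MASS_G_MOL", "build_signal_library",
    "synthesize_fid", "simulate_qr", "apply_suppression",
    "generate_calibration_set", "oil_matrix",
]

#: molar masses (g/mol) from molecular formulas
MOLAR_MASS_G_MOL = {
    "CBD": 314.47,          # C21H30O2
    "delta9-THC": 314.47,   # C21H30O2
    "delta8-THC": 314.47,   # C21H30O2
    "CBN": 310.44,          # C21H26O2
    "CBG": 316.48,          # C21H32O2
    "CBDA": 358.47,         # C22H30O4
    "THCA": 358.47,         # C22H30O4
    "TCNB": 260.89,         # C6HCl4NO2
    "EB": 106.17,           # C8H10
    "TMS": 88.22,           # C4H12Si
}


@dataclass
class LineshapeParams:
    """Lineshape and noise model of the simulator.

    ``noise_sigma`` is the SD of the complex white noise per FID point; the
    default puts a 140 mg/L Δ⁹-THC doublet near S/N ≈ 50 after default
    processing, i.e. in the method's practical detection regime.
    ``shift_drift_ppm_per_gL`` moves the Δ⁹/Δ⁸/hump centers linearly with the
    CBD concentration (g/L), emulating the observed matrix-dependent drift.
    """

    fwhm_hz: float = 1.2
    hump_fwhm_hz: float = 40.0
    noise_sigma: float = 72.0
    shift_drift_ppm_per_gL: float = 0.0

    def __post_init__(self):
        if self.fwhm_hz <= 0 or self.hump_fwhm_hz <= 0:
            raise ValueError("linewidths must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SampleComposition:
    """What is in the tube: analyte concentrations and the carrier matrix.

    ``concentrations`` holds mg/L of sample solution keyed by analyte name
    (``TMS`` may appear as a pseudo-analyte for the reference singlet).
    ``saturation`` holds per-component multiplicative attenuations in (0, 1].
    """

    concentrations: dict = field(default_factory=dict)
    matrix_kind: str = "none"       # "hemp" | "MCT" | "none"
    matrix_intensity: float = 1.0
    saturation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix_kind not in ("hemp", "MCT", "none"):
            raise ValueError(f"unknown matrix kind {self.matrix_kind!r}")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")
        for name, s in self.saturation.items():
            if not (0.0 < s <= 1.0):
                raise ValueError(f"saturation factor for {name!r} outside (0, 1]")

    def with_analyte(self, name: str, mg_per_l: float) -> "SampleComposition":
        conc = dict(self.concentrations)
        conc[name] = mg_per_l
        return dataclasses.replace(self, concentrations=conc)


#: 0.05 % (v/v) TMS in the 0.6 mL solvent, expressed as mg/L
TMS_MG_PER_L = 324.0


def oil_matrix(matrix_kind: str = "hemp", matrix_intensity: float = 1.0,
               cbd_mg_per_l: float = 0.0) -> SampleComposition:
    """A carrier-oil matrix composition with the TMS reference included."""
    conc = {"TMS": TMS_MG_PER_L}
    if cbd_mg_per_l > 0:
        conc["CBD"] = cbd_mg_per_l
    return SampleComposition(concentrations=conc, matrix_kind=matrix_kind,
                             matrix_intensity=matrix_intensity)


@dataclass(frozen=True)
class SuppressionBand:
    """A selectively saturated frequency band, edges in Hz from 0 ppm."""

    lo_hz: float
    hi_hz: float
    residual_fraction: float = 0.01

    def __post_init__(self):
        if self.lo_hz >= self.hi_hz:
            raise ValueError("band requires lo_hz < hi_hz")
        if not (0.0 <= self.residual_fraction <= 1.0):
            raise ValueError("residual_fraction must lie in [0, 1]")


#: the seven triglyceride suppression bands of the acquisition scheme
DEFAULT_SUPPRESSION_BANDS = (
    SuppressionBand(347.0, 357.0),    # 0.87-0.89 ppm
    SuppressionBand(504.0, 524.0),    # 1.26-1.31 ppm
    SuppressionBand(640.0, 650.0),    # 1.60-1.63 ppm
    SuppressionBand(803.0, 823.0),    # 2.01-2.06 ppm
    SuppressionBand(919.0, 929.0),    # 2.30-2.32 ppm
    SuppressionBand(1102.0, 1112.0),  # 2.75-2.78 ppm
    SuppressionBand(2116.0, 2156.0),  # 5.29-5.39 ppm
)


# ---------------------------------------------------------------------------
# signal library

def _win(center: float, half: float) -> tuple[float, float]:
    return (round(center + half, 4), round(center - half, 4))


def build_signal_library(matrix_kind: str = "hemp") -> list[SignalDefinition]:
    """The quantification and interferent signals of the method.

    Quantification signals (1 proton each): CBD 3.88/4.52/4.63, Δ⁹-THC 6.15,
    Δ⁸-THC 6.12, CBN 7.05/7.13/8.21.  Interferents (never quantified): the CBD
    5.56 singlet and broad ~6.2 ppm hump, the Δ⁹-THC 6.33 quintet, and the
    CBG/CBDA/THCA resonances on top of the hump, plus CBN 6.31/6.41.
    Window-mode windows are center ± 0.04 ppm; linefit search windows are
    center ± 0.06 ppm, narrowed to ± 0.02 ppm for the Δ⁸/Δ⁹ pair in MCT oils
    where signal swapping was observed.
    """
    if matrix_kind not in ("hemp", "MCT"):
        raise ValueError(f"unknown matrix kind {matrix_kind!r}")

    thc_windows = lambda c: {"hemp": _win(c, 0.06), "MCT": _win(c, 0.02)}
    lib = [
        SignalDefinition("CBD", "CBD 1", 3.88, "m", 6.5, 1, "window",
                         {"hemp": _win(3.88, 0.04)}),
        SignalDefinition("CBD", "CBD 2", 4.52, "d", 1.5, 1, "window",
                         {"hemp": _win(4.52, 0.04)}, aggregate=False),
        SignalDefinition("CBD", "CBD 3", 4.63, "d", 1.5, 1, "linefit",
                         {"hemp": _win(4.63, 0.06)}),
        SignalDefinition("delta9-THC", "Δ⁹-THC H-3′", 6.15, "d", 1.7, 1,
                         "linefit", thc_windows(6.15), drifts=True),
        SignalDefinition("delta8-THC", "Δ⁸-THC H-3′", 6.12, "d", 1.7, 1,
                         "linefit", thc_windows(6.12), drifts=True),
        SignalDefinition("CBN", "CBN H-2", 7.05, "d", 8.0, 1, "window",
                         {"hemp": _win(7.05, 0.04)}),
        SignalDefinition("CBN", "CBN H-5", 7.13, "d", 8.0, 1, "window",
                         {"hemp": _win(7.13, 0.04)}),
        SignalDefinition("CBN", "CBN H-4", 8.21, "s", 0.0, 1, "window",
                         {"hemp": _win(8.21, 0.04)}),
        # interferents -------------------------------------------------------
        SignalDefinition("CBD", "CBD 5.56", 5.56, "s", 0.0, 1, "window",
                         {"hemp": _win(5.56, 0.04)}, quantify=False),
        SignalDefinition("CBD", "CBD hump", 6.20, "br", 0.0, 2, "window",
                         {"hemp": _win(6.20, 0.25)}, quantify=False,
                         drifts=True),
        SignalDefinition("delta9-THC", "Δ⁹-THC 6.33", 6.33, "quint", 1.6, 1,
                         "window", {"hemp": _win(6.33, 0.04)}, quantify=False,
                         drifts=True),
        SignalDefinition("CBG", "CBG 6.24", 6.24, "s", 0.0, 2, "window",
                         {"hemp": _win(6.24, 0.04)}, quantify=False, drifts=True),
        SignalDefinition("CBDA", "CBDA 6.23", 6.23, "s", 0.0, 1, "window",
                         {"hemp": _win(6.23, 0.04)}, quantify=False, drifts=True),
        SignalDefinition("THCA", "THCA 6.228", 6.228, "s", 0.0, 1, "window",
                         {"hemp": _win(6.228, 0.04)}, quantify=False, drifts=True),
        SignalDefinition("CBN", "CBN 6.31", 6.31, "d", 8.0, 1, "window",
                         {"hemp": _win(6.31, 0.04)}, quantify=False),
        SignalDefinition("CBN", "CBN 6.41", 6.41, "d", 8.0, 1, "window",
                         {"hemp": _win(6.41, 0.04)}, quantify=False),
        SignalDefinition("TMS", "TMS", 0.0, "s", 0.0, 12, "window",
                         {"hemp": _win(0.0, 0.05)}, quantify=False),
    ]
    return lib


# multiplet line patterns: (offset in units of J, relative weight)
_MULTIPLET_LINES = {
    "s": [(0.0, 1.0)],
    "br": [(0.0, 1.0)],
    "d": [(-0.5, 1.0), (0.5, 1.0)],
    "t": [(-1.0, 1.0), (0.0, 2.0), (1.0, 1.0)],
    "quint": [(-2.0, 1.0), (-1.0, 4.0), (0.0, 6.0), (1.0, 4.0), (2.0, 1.0)],
    # unresolved multiplet: narrow symmetric 3-line cluster
    "m": [(-0.5, 1.0), (0.0, 1.0), (0.5, 1.0)],
}

# triglyceride band model: ppm center, FWHM (Hz), relative amplitude
_MATRIX_BANDS = {
    "hemp": [
        (0.8800, 10.0, 4.0e4),   # terminal CH3
        (1.2850, 14.0, 1.0e5),   # (CH2)n
        (1.6125, 10.0, 1.5e4),   # CH2-CH2-CO
        (2.0325, 12.0, 2.5e4),   # allylic CH2
        (2.3100, 10.0, 1.2e4),   # CH2-CO
        (2.7675, 10.0, 1.0e4),   # bis-allylic CH2
        (5.3400, 12.0, 1.2e4),   # olefinic CH + glycerol CH
    ],
    # MCT oil: saturated medium chains, no bis-allylic/olefinic bands
    "MCT": [
        (0.8800, 10.0, 5.0e4),
        (1.2850, 14.0, 1.2e5),
        (1.6125, 10.0, 1.5e4),
        (2.0325, 12.0, 5.0e3),
        (2.3100, 10.0, 1.4e4),
    ],
    "none": [],
}


def _emission_lines(composition: SampleComposition, acq: AcquisitionParameters,
                    lineshape: LineshapeParams,
                    library: list[SignalDefinition] | None = None):
    """Yield (frequency offset Hz, amplitude, fwhm Hz, shape) per transition.

    Analyte lines decay exponentially (Lorentzian lineshape); the triglyceride
    matrix bands decay Gaussian so their energy is confined to the suppression
    bands, as for the real broad multiplet envelopes."""
    lib = library if library is not None else build_signal_library("hemp")
    by_analyte: dict[str, list[SignalDefinition]] = {}
    for sig in lib:
        by_analyte.setdefault(sig.analyte, []).append(sig)

    cbd_g_per_l = composition.concentrations.get("CBD", 0.0) / 1000.0
    drift = lineshape.shift_drift_ppm_per_gL * cbd_g_per_l

    for analyte, conc in composition.concentrations.items():
        if conc <= 0:
            continue
        if analyte not in MOLAR_MASS_G_MOL:
            raise ValueError(f"no molar mass known for analyte {analyte!r}")
        sat = composition.saturation.get(analyte, 1.0)
        molar = conc / MOLAR_MASS_G_MOL[analyte]      # mmol/L
        for sig in by_analyte.get(analyte, []):
            amp_total = molar * sig.n_protons * sat * acq.ns * acq.rg
            fwhm = sig.fwhm_hz
            if fwhm is None:
                fwhm = (lineshape.hump_fwhm_hz if sig.multiplicity == "br"
                        else lineshape.fwhm_hz)
            center = sig.center_ppm + (drift if sig.drifts else 0.0)
            lines = _MULTIPLET_LINES[sig.multiplicity]
            wsum = sum(w for _, w in lines)
            for off_j, w in lines:
                delta = center + off_j * sig.j_hz / acq.sf_mhz
                nu = (delta - acq.o1_ppm) * acq.sf_mhz
                yield nu, amp_total * w / wsum, fwhm, "lorentzian"

    for center, fwhm, rel in _MATRIX_BANDS[composition.matrix_kind]:
        amp = rel * composition.matrix_intensity * acq.ns * acq.rg / 1024.0
        nu = (center - acq.o1_ppm) * acq.sf_mhz
        yield nu, amp, fwhm, "gaussian"


def synthesize_fid(composition: SampleComposition,
                   acq: AcquisitionParameters | None = None,
                   lineshape: LineshapeParams | None = None,
                   seed: int = 0,
                   library: list[SignalDefinition] | None = None) -> FID:
    """Sum of decaying complex exponentials plus complex white noise.

    Deterministic given ``seed``.  Each transition contributes
    ``a * exp(2πi ν t) * exp(-t / T2*)`` with ``T2* = 1 / (π FWHM)`` and the
    amplitude proportional to molar concentration × proton count × saturation
    × NS × RG.
    """
    acq = acq or default_acquisition()
    lineshape = lineshape or LineshapeParams()
    t = np.arange(acq.n_complex) * acq.dwell_s
    data = np.zeros(acq.n_complex, dtype=np.complex128)
    for nu, amp, fwhm, shape in _emission_lines(composition, acq, lineshape, library):
        if shape == "gaussian":
            envelope = np.exp(-(np.pi * fwhm * t) ** 2 / (4.0 * np.log(2.0)))
        else:
            envelope = np.exp(-np.pi * fwhm * t)
        data += amp * np.exp(2j * np.pi * nu * t) * envelope
    if lineshape.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += lineshape.noise_sigma * (
            rng.standard_normal(acq.n_complex)
            + 1j * rng.standard_normal(acq.n_complex)
        )
    return FID(data, acq.replace())


def simulate_qr(qr, acq: AcquisitionParameters | None = None, seed: int = 0,
                noise_sigma: float = 0.0, fwhm_hz: float = 1.2,
                physical_saturation: bool = False) -> FID:
    """Simulate the external-standard (QR) spectrum of TCNB + ethylbenzene.

    Each component is attenuated by exactly ``1/κ`` (default) so the published
    correction factors invert the simulated partial saturation bit-exactly;
    with ``physical_saturation=True`` the attenuation is ``1 − exp(−TR/T1)``
    with ``TR = AQ + D1`` instead.  Only the aromatic signals inside the
    defined integration ranges are emitted (the aliphatic EB signals fall into
    suppression bands and are never used).
    """
    acq = acq or default_acquisition()
    # line positions: TCNB singlet mid-window; EB 3-proton aromatic cluster
    positions = {
        "TCNB": [(7.735, 1.0)],
        "EB": [(7.14, 1.0), (7.16, 1.0), (7.18, 1.0)],
    }
    t = np.arange(acq.n_complex) * acq.dwell_s
    data = np.zeros(acq.n_complex, dtype=np.complex128)
    r2 = np.pi * fwhm_hz
    for name, comp in qr.components.items():
        if comp.kappa is None or comp.t1_s is None:
            raise ValueError(f"QR component {name!r} missing kappa or T1")
        if physical_saturation:
            tr = acq.aq_s + acq.d1_s
            sat = 1.0 - np.exp(-tr / comp.t1_s)
        else:
            sat = 1.0 / comp.kappa
        molar = comp.mass_concentration_mg_l / comp.molar_mass
        amp_total = molar * comp.n_protons * sat * acq.ns * acq.rg
        lines = positions.get(name)
        if lines is None:
            lines = [((comp.signal_range_ppm[0] + comp.signal_range_ppm[1]) / 2.0, 1.0)]
        wsum = sum(w for _, w in lines)
        for delta, w in lines:
            nu = (delta - acq.o1_ppm) * acq.sf_mhz
            data += amp_total * w / wsum * np.exp((2j * np.pi * nu - r2) * t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += noise_sigma * (rng.standard_normal(acq.n_complex)
                               + 1j * rng.standard_normal(acq.n_complex))
    return FID(data, acq.replace())


def apply_suppression(fid: FID, bands=DEFAULT_SUPPRESSION_BANDS,
                      nominal_sf_mhz: float = NOMINAL_SF_MHZ,
                      edge_hz: float = 2.0) -> FID:
    """Attenuate the frequency content inside each band to its residual.

    Band edges are Hz from the 0 ppm reference at the nominal frequency;
    implemented as FFT → mask → inverse FFT.  The attenuation profile reaches
    its residual via raised-cosine skirts of width ``edge_hz`` placed *inside*
    the band, so content outside the bands is untouched to numerical precision
    and the notch's time-domain impulse response decays quickly (a hard boxcar
    notch would ring across the whole FID and bleed back on zero filling).
    An empty band list is the identity.
    """
    bands = list(bands)
    if not bands:
        return fid.copy()
    acq = fid.acq
    n = fid.data.size
    # Mask the conjugate-symmetric (two-sided) extension: its spectrum is
    # purely absorptive, so the notch removes only in-band absorption and
    # leaves the dispersion tails of out-of-band signals intact — as physical
    # band saturation does.  A mask on the causal FID alone would also clip
    # the 1/f dispersion tails of every distant signal.
    z = np.zeros(2 * n, dtype=np.complex128)
    z[:n] = fid.data
    z[n + 1:] = np.conj(fid.data[1:][::-1])
    s = np.fft.fft(z)
    f = np.fft.fftfreq(2 * n, acq.dwell_s)
    hz = (acq.o1_ppm * acq.sf_mhz) + f        # Hz from 0 ppm at actual SF
    scale = acq.sf_mhz / nominal_sf_mhz       # band table is at the nominal SF
    lo_axis, hi_axis = hz.min(), hz.max()
    gain = np.ones_like(hz)
    for band in bands:
        lo, hi = band.lo_hz * scale, band.hi_hz * scale
        if hi < lo_axis or lo > hi_axis:
            raise ValueError(
                f"suppression band {band.lo_hz}-{band.hi_hz} Hz outside the "
                "spectral window")
        w = min(edge_hz, 0.25 * (hi - lo))
        inside = (hz >= lo) & (hz <= hi)
        depth = np.ones_like(hz)
        # 1 at the band edge, residual from lo+w to hi-w, cosine in between
        d_edge = np.minimum(hz - lo, hi - hz)
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.clip(d_edge / w, 0.0, 1.0))
        depth[inside] = 1.0 - (1.0 - band.residual_fraction) * ramp[inside]
        gain = np.minimum(gain, np.where(inside, depth, 1.0))
    out = np.fft.ifft(s * gain)[:n]
    return FID(out, acq.replace())


def generate_calibration_set(
    analyte: str,
    levels,
    matrix: SampleComposition | None = None,
    seed: int = 0,
    acq: AcquisitionParameters | None = None,
    lineshape: LineshapeParams | None = None,
    area_noise_frac: float = 0.0,
    suppression=DEFAULT_SUPPRESSION_BANDS,
) -> list[tuple[float, FID]]:
    """One suppressed FID per spiking level, matrix constant across levels.

    ``area_noise_frac`` adds multiplicative measurement scatter to the spiked
    analyte's response (1 + frac·N(0,1) per level), on top of any time-domain
    noise from ``lineshape``.  Reproducible per seed; at least 3 levels are
    required (5+ for a downstream detection-limit estimate).
    """
    levels = list(levels)
    if len(levels) < 3:
        raise ValueError("need at least 3 calibration levels")
    matrix = matrix if matrix is not None else oil_matrix("hemp")
    acq = acq or default_acquisition()
    lineshape = lineshape or LineshapeParams()
    ss = np.random.SeedSequence(seed)
    fid_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(levels))]
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for level, fid_seed in zip(levels, fid_seeds):
        factor = 1.0 + area_noise_frac * jitter_rng.standard_normal() \
            if area_noise_frac > 0 else 1.0
        comp = matrix.with_analyte(analyte, level * factor)
        fid = synthesize_fid(comp, acq, lineshape, seed=fid_seed)
        if suppression:
            fid = apply_suppression(fid, suppression)
        out.append((float(level), fid))
    return out
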