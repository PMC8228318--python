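"""PULCON / ERETIC external-standard quantification.

The principle of reciprocity lets an external standard measured in its own
tube calibrate the absolute response of the spectrometer: the signal area per
proton per unit molar concentration, normalized by scans, receiver gain and
the 90° pulse length, is an instrument constant (the ERETIC factor).  Here the
factor is derived from a TCNB + ethylbenzene reference whose long-T1 aromatic
signals are attenuated by partial saturation under the 14 s repetition time;
the published empirical correction factors κ (1.30 for TCNB, 1.22 for EB)
restore the fully-relaxed response:

    f_c = A_c · κ_c · P1_QR / (n_c · C_c/M_c · NS_QR · RG_QR)        (per component)
    f   = mean(f_TCNB, f_EB)

A sample signal of area A then yields the mass concentration

    ρ [mg/L] = A · P1_s / (f · n · NS_s · RG_s) · M

valid only when QR and sample share the spectrometer frequency and the
300.0 K acquisition temperature (both enforced).  Concentrations convert to
sample content via the simplified relation

    w [mg/kg] = ρ · V_total / m_sample,   V_total = V_solvent + m_sample/ρ_oil

with the method constants m = 100 mg, V_solvent = 0.6 mL and an average oil
density of 0.89 g/mL (volume contraction on mixing neglected).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .integration import FitResult, SignalDefinition, assign_delta_thc, measure_signal
from .spectra import AcquisitionParameters, Spectrum1D

__all__ = [
    "QRComponent", "QRStandard", "default_qr", "EreticFactor", "QuantReport",
    "compute_eretic_factor", "pulcon_mass_concentration",
    "convert_to_mg_per_kg", "quantify_sample", "control_sample_check",
    "DEFAULT_LOD_MG_KG", "DEFAULT_LOQ_MG_KG",
]

# method constants of the mg/kg conversion
SAMPLE_MASS_MG = 100.0
SOLVENT_VOLUME_ML = 0.6
OIL_DENSITY_G_ML = 0.89


@dataclass(frozen=True)
class QRComponent:
    mass_concentration_mg_l: float
    molar_mass: float
    n_protons: int
    signal_range_ppm: tuple   # (high_ppm, low_ppm)
    kappa: float | None
    t1_s: float | None

    def __post_init__(self):
        if self.mass_concentration_mg_l <= 0:
            raise ValueError("QR concentration must be positive")
        if self.kappa is not None and self.kappa < 1.0:
            raise ValueError("correction factor kappa must be >= 1")


@dataclass(frozen=True)
class QRStandard:
    """The TCNB/EB quantification reference."""

    components: dict

    def __getitem__(self, name: str) -> QRComponent:
        return self.components[name]


def default_qr() -> QRStandard:
    """TCNB 4662 mg/L (singlet 7.64–7.83 ppm, κ=1.30, T1=10.9 s) and
    ethylbenzene 3506 mg/L (3-proton aromatic multiplet 7.0162–7.2341 ppm,
    κ=1.22, T1=8.8 s) in CDCl3."""
    return QRStandard(components={
        "TCNB": QRComponent(4662.0, 260.89, 1, (7.83, 7.64), 1.30, 10.9),
        "EB": QRComponent(3506.0, 106.17, 3, (7.2341, 7.0162), 1.22, 8.8),
    })


@dataclass
class EreticFactor:
    """Instrument response per proton per mmol/L, P1/NS/RG-normalized."""

    value: float
    component_values: dict
    acq_qr: AcquisitionParameters

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("ERETIC factor must be positive")


def compute_eretic_factor(qr_spec: Spectrum1D, qr: QRStandard,
                          acq_qr: AcquisitionParameters,
                          components: list[str] | None = None) -> EreticFactor:
    """Derive the ERETIC factor from the QR spectrum.

    ``components`` restricts the average to a subset (used for cross-wise
    round-trip checks); default is the mean over TCNB and EB.
    """
    names = components or list(qr.components)
    values = {}
    for name in names:
        comp = qr.components[name]
        area = qr_spec.integrate(*comp.signal_range_ppm)
        if area <= 0:
            raise ValueError(f"non-positive QR area for {name!r}")
        molar = comp.mass_concentration_mg_l / comp.molar_mass
        values[name] = (area * comp.kappa * acq_qr.p1_us
                        / (comp.n_protons * molar * acq_qr.ns * acq_qr.rg))
    return EreticFactor(value=float(np.mean(list(values.values()))),
                        component_values=values, acq_qr=acq_qr.replace())


def _check_context(acq_sample: AcquisitionParameters,
                   acq_qr: AcquisitionParameters) -> None:
    if not np.isclose(acq_sample.sf_mhz, acq_qr.sf_mhz, rtol=1e-9):
        raise ValueError("PULCON requires QR and sample on the same spectrometer "
                         f"frequency ({acq_qr.sf_mhz} vs {acq_sample.sf_mhz} MHz)")
    for acq in (acq_sample, acq_qr):
        if abs(acq.temperature_k - 300.0) > 0.5:
            raise ValueError("PULCON relation used here assumes 300.0 K "
                             f"acquisition, got {acq.temperature_k} K")


def pulcon_mass_concentration(area: float, n_protons: int, molar_mass: float,
                              acq_sample: AcquisitionParameters,
                              f: EreticFactor,
                              saturation_correction: float = 1.0) -> float:
    """Convert a signal area to mg/L of sample solution.

    ``saturation_correction`` multiplies the area for signals acquired under
    partial saturation (κ of the standards when they are themselves
    quantified); the cannabinoid signals relax fully within the repetition
    time and use the default 1.
    """
    _check_context(acq_sample, f.acq_qr)
    if area <= 0:
        return 0.0
    molar = area * saturation_correction * acq_sample.p1_us / (
        f.value * n_protons * acq_sample.ns * acq_sample.rg)
    return molar * molar_mass


def convert_to_mg_per_kg(rho_mg_l: float,
                         m_sample_mg: float = SAMPLE_MASS_MG,
                         v_solvent_ml: float = SOLVENT_VOLUME_ML,
                         oil_density_g_ml: float = OIL_DENSITY_G_ML) -> float:
    """mg/L of solution -> mg/kg of sample, volumes summed without contraction."""
    if m_sample_mg <= 0:
        raise ValueError("sample mass must be positive")
    if v_solvent_ml <= 0 or oil_density_g_ml <= 0:
        raise ValueError("volume and density must be positive")
    v_total_ml = v_solvent_ml + (m_sample_mg / 1000.0) / oil_density_g_ml
    return rho_mg_l * v_total_ml / m_sample_mg * 1000.0


#: validated screening limits (mg/kg sample) per signal
DEFAULT_LOD_MG_KG = {
    "CBD 1": 346.0, "CBD 2": 134.0, "CBD 3": 307.0,
    "Δ⁹-THC H-3′": 608.0, "Δ⁸-THC H-3′": 250.0,
    "CBN H-2": 517.0, "CBN H-5": 623.0, "CBN H-4": 504.0,
}
DEFAULT_LOQ_MG_KG = {
    "CBD 1": 1092.0, "CBD 2": 445.0, "CBD 3": 979.0,
    "Δ⁹-THC H-3′": 1858.0, "Δ⁸-THC H-3′": 816.0,
    "CBN H-2": 1604.0, "CBN H-5": 1897.0, "CBN H-4": 1568.0,
}


@dataclass
class QuantReport:
    """Per-signal and per-analyte quantities with explicit censoring flags."""

    signals: list                  # dicts: label, analyte, mode, area, mg_l, mg_kg, ...
    analytes: dict                 # analyte -> {"mg_l", "mg_kg", "flag"}
    constants: dict
    matrix_kind: str

    def to_json(self, **kwargs) -> str:
        """Serialize; contents in mg/kg and mg/L are given to 3 significant
        figures, censoring flags always explicit (never missing values)."""
        def sig3(v):
            if isinstance(v, float) and v != 0.0 and np.isfinite(v):
                return float(f"{v:.3g}")
            return v

        def walk(obj):
            if isinstance(obj, dict):
                return {k: (sig3(v) if k in ("mg_kg", "mg_l") else walk(v))
                        for k, v in obj.items()}
            if isinstance(obj, list):
                return [walk(v) for v in obj]
            return obj

        return json.dumps({"matrix_kind": self.matrix_kind,
                           "constants": self.constants,
                           "signals": walk(self.signals),
                           "analytes": walk(self.analytes)}, **kwargs)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.signals)


def _censor(mg_kg: float, label: str, lod_table: dict, loq_table: dict):
    lod = lod_table.get(label)
    loq = loq_table.get(label)
    if lod is not None and mg_kg < lod:
        return 0.0, "below_lod"
    if loq is not None and mg_kg < loq:
        return mg_kg, "qualitative"
    return mg_kg, "quantitative"


def quantify_sample(spec: Spectrum1D, library: list[SignalDefinition],
                    f: EreticFactor,
                    acq_sample: AcquisitionParameters | None = None,
                    matrix_kind: str = "hemp",
                    molar_masses: dict | None = None,
                    lod_table: dict | None = None,
                    loq_table: dict | None = None) -> QuantReport:
    """Measure every quantification signal, convert to mg/kg, censor and
    aggregate.

    Censoring: values below the signal's LOD are set to exactly 0 and flagged
    ``below_lod``; values between LOD and LOQ are flagged ``qualitative``.
    Aggregation: CBD is the mean of CBD 1 (3.88 ppm) and CBD 3 (4.63 ppm);
    CBD 2 is reported for QC only.  Δ⁹/Δ⁸-THC come from the swap-guarded
    doublet assignment; CBN is the mean of its uncensored signals.
    """
    from .simulate import MOLAR_MASS_G_MOL
    if f is None:
        raise ValueError("an ERETIC factor from a QR spectrum is required")
    acq_sample = acq_sample or spec.acq
    if acq_sample is None:
        raise ValueError("sample acquisition parameters unavailable")
    molar_masses = molar_masses or MOLAR_MASS_G_MOL
    lod_table = DEFAULT_LOD_MG_KG if lod_table is None else lod_table
    loq_table = DEFAULT_LOQ_MG_KG if loq_table is None else loq_table

    quant = [s for s in library if s.quantify]
    thc = [s for s in quant if s.analyte in ("delta9-THC", "delta8-THC")]
    other = [s for s in quant if s not in thc]

    results: dict[str, FitResult] = {}
    for sig in other:
        results[sig.label] = measure_signal(spec, sig, matrix_kind)
    thc_fits = [measure_signal(spec, sig, matrix_kind) for sig in thc]
    assigned = assign_delta_thc(thc_fits, matrix_kind)
    for sig in thc:
        results[sig.label] = assigned["delta9-THC" if sig.analyte == "delta9-THC"
                                      else "delta8-THC"]

    rows = []
    per_signal_mg_kg: dict[str, tuple[float, str]] = {}
    for sig in quant:
        res = results[sig.label]
        area = res.area if res.converged or sig.mode == "window" else 0.0
        mg_l = pulcon_mass_concentration(area, sig.n_protons,
                                         molar_masses[sig.analyte],
                                         acq_sample, f)
        mg_kg_raw = convert_to_mg_per_kg(mg_l)
        mg_kg, flag = _censor(mg_kg_raw, sig.label, lod_table, loq_table)
        per_signal_mg_kg[sig.label] = (mg_kg, flag)
        rows.append({
            "label": sig.label, "analyte": sig.analyte, "mode": sig.mode,
            "area": res.area, "center_ppm": res.center_ppm,
            "converged": res.converged, "mg_l": mg_l, "mg_kg": mg_kg,
            "flag": flag, "fit_flags": list(res.flags),
            "used_in_aggregate": sig.aggregate,
        })

    def aggregate(labels: list[str]) -> tuple[float, str]:
        vals = [per_signal_mg_kg[l] for l in labels if l in per_signal_mg_kg]
        usable = [v for v, fl in vals if fl != "below_lod"]
        if not usable:
            return 0.0, "below_lod"
        flagset = {fl for v, fl in vals if fl != "below_lod"}
        return float(np.mean(usable)), ("qualitative" if "qualitative" in flagset
                                        else "quantitative")

    analytes = {}
    for name, labels in (("CBD", ["CBD 1", "CBD 3"]),
                         ("delta9-THC", ["Δ⁹-THC H-3′"]),
                         ("delta8-THC", ["Δ⁸-THC H-3′"]),
                         ("CBN", ["CBN H-2", "CBN H-5", "CBN H-4"])):
        mg_kg, flag = aggregate(labels)
        v_total_ml = SOLVENT_VOLUME_ML + SAMPLE_MASS_MG / 1000.0 / OIL_DENSITY_G_ML
        analytes[name] = {"mg_kg": mg_kg,
                          "mg_l": mg_kg * SAMPLE_MASS_MG / v_total_ml / 1000.0,
                          "flag": flag}

    constants = {"m_sample_mg": SAMPLE_MASS_MG,
                 "v_solvent_ml": SOLVENT_VOLUME_ML,
                 "oil_density_g_ml": OIL_DENSITY_G_ML,
                 "eretic_factor": f.value}
    return QuantReport(signals=rows, analytes=analytes, constants=constants,
                       matrix_kind=matrix_kind)


def control_sample_check(result: float, control_mean: float,
                         control_sd: float) -> bool:
    """Pass iff the control result lies within twice the precision SD."""
    if control_sd <= 0:
        raise ValueError("control SD must be positive")
    return abs(result - control_mean) <= 2.0 * control_sd
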