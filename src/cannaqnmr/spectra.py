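"""Core containers shared across the pipeline.

An :class:`FID` is the complex time-domain signal together with the acquisition
metadata needed to interpret it (dwell time, carrier position, scans, gain,
pulse length).  A :class:`Spectrum1D` is its processed frequency-domain
counterpart on a descending ppm axis, carrying a provenance trail of every
processing step applied.

The time-domain size convention follows Bruker: ``td`` counts real+imaginary
points, so an FID holds ``td // 2`` complex samples and the acquisition time is
``td / (2 * sw_hz)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParameters", "FID", "Spectrum1D", "default_acquisition"]

# nominal proton frequency used for Hz <-> ppm of tabulated constants
NOMINAL_SF_MHZ = 400.0


@dataclass
class AcquisitionParameters:
    """Per-experiment metadata carried from FID to report.

    Defaults reproduce the multiple-suppression quantification experiment:
    a 400 MHz instrument, 131,072 time-domain points over 20.5617 ppm
    (acquisition time ~7.97 s), 64 scans at receiver gain 16, relaxation
    delay 6 s, exponential line broadening 0.30 Hz, 300.0 K.
    """

    sf_mhz: float = NOMINAL_SF_MHZ
    td: int = 131072            # time-domain points, real + imaginary
    si: int = 262144            # processed (zero-filled) real size
    sw_ppm: float = 20.5617
    ns: int = 64
    ds: int = 4
    rg: float = 16.0
    p1_us: float = 8.0
    d1_s: float = 6.0
    lb_hz: float = 0.30
    temperature_k: float = 300.0
    o1_ppm: float = 6.175       # carrier / centre of the spectral window
    aq_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("sf_mhz", "td", "si", "sw_ppm", "ns", "rg", "p1_us",
                     "d1_s", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"acquisition parameter {name!r} must be positive")
        if self.lb_hz < 0:
            raise ValueError("lb_hz must be >= 0")
        if self.td % 2:
            raise ValueError("td counts real+imaginary points and must be even")
        if self.si < self.td:
            raise ValueError("si must be >= td")
        nominal_aq = self.td / (2.0 * self.sw_hz)
        if self.aq_s is None:
            self.aq_s = nominal_aq
        elif abs(self.aq_s - nominal_aq) > 0.02 * nominal_aq:
            raise ValueError(
                f"aq_s={self.aq_s} inconsistent with td/(2*sw_hz)={nominal_aq:.6f}"
            )

    @property
    def sw_hz(self) -> float:
        return self.sw_ppm * self.sf_mhz

    @property
    def dwell_s(self) -> float:
        """Complex dwell time in seconds."""
        return 1.0 / self.sw_hz

    @property
    def n_complex(self) -> int:
        return self.td // 2

    def replace(self, **kwargs) -> "AcquisitionParameters":
        if {"td", "sw_ppm", "sf_mhz"} & kwargs.keys() and "aq_s" not in kwargs:
            kwargs["aq_s"] = None     # recompute from the new timing
        return dataclasses.replace(self, **kwargs)


def default_acquisition(**overrides) -> AcquisitionParameters:
    """The quantification experiment's acquisition parameters, optionally overridden."""
    return AcquisitionParameters(**overrides)


@dataclass
class FID:
    """Complex free induction decay plus its acquisition parameters."""

    data: np.ndarray
    acq: AcquisitionParameters

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise ValueError("FID data must be one-dimensional")
        if self.data.size != self.acq.n_complex:
            raise ValueError(
                f"FID holds {self.data.size} complex points but acq.td/2 = {self.acq.n_complex}"
            )

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.data.size) * self.acq.dwell_s

    def copy(self) -> "FID":
        return FID(self.data.copy(), self.acq.replace())


@dataclass
class Spectrum1D:
    """Frequency-domain spectrum on a strictly descending ppm axis."""

    real: np.ndarray
    imag: np.ndarray
    ppm: np.ndarray
    sf_mhz: float
    acq: AcquisitionParameters | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.real = np.asarray(self.real, dtype=np.float64)
        self.imag = np.asarray(self.imag, dtype=np.float64)
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        if not (self.real.shape == self.imag.shape == self.ppm.shape):
            raise ValueError("real, imag and ppm must have identical shapes")
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")

    @property
    def complex(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @property
    def n_points(self) -> int:
        return self.real.size

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def window_slice(self, high_ppm: float, low_ppm: float) -> slice:
        """Index slice covering the closed ppm interval (high, low)."""
        if high_ppm < low_ppm:
            high_ppm, low_ppm = low_ppm, high_ppm
        if high_ppm > self.ppm[0] or low_ppm < self.ppm[-1]:
            raise ValueError(
                f"window ({high_ppm}, {low_ppm}) ppm outside axis "
                f"[{self.ppm[-1]:.3f}, {self.ppm[0]:.3f}]"
            )
        # axis is descending
        i0 = int(np.searchsorted(-self.ppm, -high_ppm, side="left"))
        i1 = int(np.searchsorted(-self.ppm, -low_ppm, side="right"))
        return slice(i0, i1)

    def integrate(self, high_ppm: float, low_ppm: float) -> float:
        """Trapezoidal integral of the absorption (real) part over a ppm window."""
        sl = self.window_slice(high_ppm, low_ppm)
        x = self.ppm[sl][::-1]
        y = self.real[sl][::-1]
        return float(np.trapezoid(y, x))

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(
            self.real.copy(), self.imag.copy(), self.ppm.copy(), self.sf_mhz,
            self.acq.replace() if self.acq is not None else None,
            [dict(p) for p in self.provenance],
        )
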