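"""File formats: Bruker-style FID directories, JCAMP-DX spectra, YAML configs.

The Bruker-style reader consumes a directory holding a binary ``fid`` plus a
JCAMP-like ``acqus`` key-value file; byte order and number format follow the
``BYTORDA``/``DTYPA`` flags (int32 or float64).  The JCAMP-DX writer/reader
covers a plain AFFN ``(X++(Y..Y))`` real spectrum — enough for interoperation
tests and for exporting processed spectra, not a full implementation of the
standard.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import yaml

from .integration import SignalDefinition
from .spectra import FID, AcquisitionParameters, Spectrum1D

__all__ = [
    "write_bruker", "read_fid", "write_jcamp", "read_jcamp",
    "signal_library_to_yaml", "signal_library_from_yaml",
]

_REQUIRED_KEYS = ("SFO1", "TD", "SW", "NS", "RG", "P1", "D1")


def write_bruker(dirpath, fid: FID) -> Path:
    """Write a Bruker-style ``fid`` + ``acqus`` directory (float64, little-endian)."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    acq = fid.acq
    lines = [
        "##TITLE= cannaqnmr simulated acquisition",
        "##JCAMPDX= 5.0",
        f"##$SFO1= {acq.sf_mhz!r}",
        f"##$TD= {acq.td}",
        f"##$SW= {acq.sw_ppm!r}",
        f"##$NS= {acq.ns}",
        f"##$DS= {acq.ds}",
        f"##$RG= {acq.rg!r}",
        f"##$P1= {acq.p1_us!r}",
        f"##$D1= {acq.d1_s!r}",
        f"##$SI= {acq.si}",
        f"##$LB= {acq.lb_hz!r}",
        f"##$TE= {acq.temperature_k!r}",
        f"##$O1= {acq.o1_ppm * acq.sf_mhz!r}",
        "##$BYTORDA= 0",
        "##$DTYPA= 2",
        "##END=",
    ]
    (d / "acqus").write_text("\n".join(lines) + "\n")
    interleaved = np.empty(2 * fid.data.size, dtype="<f8")
    interleaved[0::2] = fid.data.real
    interleaved[1::2] = fid.data.imag
    (d / "fid").write_bytes(interleaved.tobytes())
    return d


def _parse_acqus(path: Path) -> dict:
    params = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line.startswith("##"):
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.lstrip("#$").strip()
        params[key] = value.strip()
    return params


def read_fid(path) -> tuple[FID, AcquisitionParameters]:
    """Read a Bruker-style directory (``fid`` + ``acqus``) back into an FID.

    Required acqus keys: SFO1, TD, SW, NS, RG, P1, D1; optional keys fall back
    to defaults with a warning.  A truncated binary raises.
    """
    d = Path(path)
    acqus = d / "acqus"
    if not acqus.exists():
        raise FileNotFoundError(f"no acqus file in {d}")
    params = _parse_acqus(acqus)
    for key in _REQUIRED_KEYS:
        if key not in params:
            raise KeyError(f"required acqus key missing: {key}")

    def opt(key, default, cast=float):
        if key in params:
            return cast(params[key])
        warnings.warn(f"acqus key {key} missing; defaulting to {default}")
        return default

    sf = float(params["SFO1"])
    td = int(float(params["TD"]))
    acq = AcquisitionParameters(
        sf_mhz=sf, td=td, si=int(opt("SI", 2 * td, float)),
        sw_ppm=float(params["SW"]), ns=int(float(params["NS"])),
        ds=int(opt("DS", 4, float)), rg=float(params["RG"]),
        p1_us=float(params["P1"]), d1_s=float(params["D1"]),
        lb_hz=opt("LB", 0.30), temperature_k=opt("TE", 300.0),
        o1_ppm=opt("O1", 6.175 * sf) / sf,
    )
    bytorda = int(float(params.get("BYTORDA", "0")))
    dtypa = int(float(params.get("DTYPA", "0")))
    dtype = ("<" if bytorda == 0 else ">") + ("f8" if dtypa == 2 else "i4")
    raw = np.frombuffer((d / "fid").read_bytes(), dtype=dtype)
    if raw.size != td:
        raise ValueError(f"fid holds {raw.size} points, acqus TD={td}")
    data = raw[0::2].astype(np.float64) + 1j * raw[1::2].astype(np.float64)
    return FID(data, acq), acq


def write_jcamp(path, spec: Spectrum1D, title: str = "cannaqnmr spectrum") -> Path:
    """Write the real part of a processed spectrum as AFFN JCAMP-DX."""
    p = Path(path)
    y = spec.real
    ymax = np.abs(y).max()
    yfactor = ymax / 2 ** 30 if ymax > 0 else 1.0
    header = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.01",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= XYDATA",
        f"##.OBSERVE FREQUENCY= {float(spec.sf_mhz)!r}",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY",
        f"##NPOINTS= {spec.n_points}",
        f"##FIRSTX= {float(spec.ppm[0])!r}",
        f"##LASTX= {float(spec.ppm[-1])!r}",
        f"##YFACTOR= {float(yfactor)!r}",
        "##XYDATA= (X++(Y..Y))",
    ]
    scaled = np.round(y / yfactor).astype(np.int64)
    body = []
    per_line = 8
    for i in range(0, scaled.size, per_line):
        chunk = scaled[i:i + per_line]
        body.append(f"{float(spec.ppm[i])!r} " + " ".join(str(v) for v in chunk))
    p.write_text("\n".join(header + body + ["##END="]) + "\n")
    return p


def read_jcamp(path) -> Spectrum1D:
    """Read a spectrum written by :func:`write_jcamp`."""
    lines = Path(path).read_text().splitlines()
    meta = {}
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("##XYDATA"):
            data_start = i + 1
            break
        if line.startswith("##"):
            key, _, value = line.partition("=")
            meta[key.strip("# ").strip()] = value.strip()
    if data_start is None:
        raise ValueError("no XYDATA block found")
    npoints = int(meta["NPOINTS"])
    firstx, lastx = float(meta["FIRSTX"]), float(meta["LASTX"])
    yfactor = float(meta["YFACTOR"])
    ys: list[float] = []
    for line in lines[data_start:]:
        if line.startswith("##"):
            break
        parts = line.split()
        ys.extend(float(v) * yfactor for v in parts[1:])
    if len(ys) != npoints:
        raise ValueError(f"expected {npoints} points, parsed {len(ys)}")
    ppm = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ys)
    return Spectrum1D(real=y, imag=np.zeros_like(y), ppm=ppm,
                      sf_mhz=float(meta.get(".OBSERVE FREQUENCY", 400.0)))


def signal_library_to_yaml(library: list[SignalDefinition], path,
                           molar_masses: dict | None = None) -> Path:
    """Dump the signal library (and molar masses) as a human-editable config."""
    from .simulate import MOLAR_MASS_G_MOL
    doc = {
        "molar_masses_g_mol": dict(molar_masses or MOLAR_MASS_G_MOL),
        "signals": [
            {
                "analyte": s.analyte, "label": s.label,
                "center_ppm": s.center_ppm, "multiplicity": s.multiplicity,
                "j_hz": s.j_hz, "n_protons": s.n_protons, "mode": s.mode,
                "windows": {k: list(v) for k, v in s.windows.items()},
                "quantify": s.quantify, "aggregate": s.aggregate,
                "drifts": s.drifts,
            }
            for s in library
        ],
    }
    p = Path(path)
    p.write_text(yaml.safe_dump(doc, allow_unicode=True, sort_keys=False))
    return p


def signal_library_from_yaml(path) -> tuple[list[SignalDefinition], dict]:
    doc = yaml.safe_load(Path(path).read_text())
    lib = [
        SignalDefinition(
            analyte=s["analyte"], label=s["label"],
            center_ppm=float(s["center_ppm"]), multiplicity=s["multiplicity"],
            j_hz=float(s["j_hz"]), n_protons=int(s["n_protons"]),
            mode=s["mode"],
            windows={k: tuple(v) for k, v in s["windows"].items()},
            quantify=bool(s.get("quantify", True)),
            aggregate=bool(s.get("aggregate", True)),
            drifts=bool(s.get("drifts", False)),
        )
        for s in doc["signals"]
    ]
    return lib, dict(doc.get("molar_masses_g_mol", {}))
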