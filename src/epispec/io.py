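"""File I/O and run configuration.

Canonical interchange is two-column CSV with ``# key: value`` metadata
header lines; JCAMP-DX (XYDATA ``(X++(Y..Y))`` dialect, AFFN numerics) is
supported read-only for instrument exports. Writes are deterministic:
identical objects produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .spectrum import CDSpectrum, Spectrum

FTIR_HEADER = "wavenumber_cm-1,absorbance"
CD_HEADER = "wavelength_nm,ellipticity_mdeg"

_META_KEYS = (
    "sample_id", "replicate", "f", "processing_state", "derivative_order",
    "condition", "variant", "seed", "config_hash", "n_averaged",
)


def _format_meta_value(v: Any) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_meta_value(s: str) -> Any:
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s == "None":
        return None
    return s


def write_spectrum(
    s: Spectrum | CDSpectrum, path: str | Path, format: str = "csv"
) -> None:
    """Write a spectrum as CSV (6-decimal fixed format) or JCAMP-DX."""
    path = Path(path)
    if format == "csv":
        text = _spectrum_to_csv(s)
    elif format == "jcamp":
        text = _spectrum_to_jcamp(s)
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text(text)


def _spectrum_to_csv(s: Spectrum | CDSpectrum) -> str:
    buf = _io.StringIO()
    kind = "cd" if isinstance(s, CDSpectrum) else "ftir"
    buf.write(f"# kind: {kind}\n")
    for k in _META_KEYS:
        if k in s.meta and s.meta[k] is not None:
            buf.write(f"# {k}: {_format_meta_value(s.meta[k])}\n")
    buf.write((CD_HEADER if kind == "cd" else FTIR_HEADER) + "\n")
    for x, y in zip(s.axis, s.values):
        buf.write(f"{x:.6f},{y:.6f}\n")
    return buf.getvalue()


def read_spectrum(path: str | Path, kind: str = "ftir") -> Spectrum | CDSpectrum:
    """Read a two-column CSV or JCAMP-DX file into the internal convention
    (FT-IR axis descending, CD axis ascending)."""
    path = Path(path)
    if kind not in ("ftir", "cd"):
        raise ValueError("kind must be 'ftir' or 'cd'")
    text = path.read_text()
    if text.lstrip().startswith("##"):
        axis, values, meta = _parse_jcamp(text)
    else:
        axis, values, meta = _parse_csv(text, kind)
    axis = np.asarray(axis, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.diff(axis)
    if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{path}: non-monotone axis")
    if kind == "ftir":
        if axis.size > 1 and axis[0] < axis[-1]:
            axis, values = axis[::-1], values[::-1]
        meta.setdefault("processing_state", "raw")
        return Spectrum(axis, values, meta)
    if axis.size > 1 and axis[0] > axis[-1]:
        axis, values = axis[::-1], values[::-1]
    meta.setdefault("derivative_order", 0)
    return CDSpectrum(axis, values, meta)


def _parse_csv(text: str, kind: str) -> tuple[list[float], list[float], dict]:
    meta: dict[str, Any] = {}
    xs: list[float] = []
    ys: list[float] = []
    saw_header = False
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*([\w-]+)\s*:\s*(.*)$", line)
            if m and m.group(1) != "kind":
                meta[m.group(1)] = _parse_meta_value(m.group(2))
            continue
        if not saw_header:
            expected = CD_HEADER if kind == "cd" else FTIR_HEADER
            if line.replace(" ", "") != expected:
                raise ValueError(
                    f"line {lineno}: malformed header {line!r}; expected {expected!r}"
                )
            saw_header = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two comma-separated columns")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    if not saw_header:
        raise ValueError("missing column-header line")
    return xs, ys, meta


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, (X++(Y..Y)) AFFN dialect)
# ---------------------------------------------------------------------------

def _parse_jcamp(text: str) -> tuple[list[float], list[float], dict]:
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise ValueError(f"unsupported XYDATA dialect {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            labels[key] = value
            in_data = False
        elif in_data:
            data_lines.append(line)

    def need(key: str) -> float:
        if key not in labels:
            raise ValueError(f"JCAMP file missing ##{key}=")
        return float(labels[key])

    firstx, lastx = need("FIRSTX"), need("LASTX")
    npoints = int(need("NPOINTS"))
    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))
    if npoints < 2:
        raise ValueError("JCAMP NPOINTS must be >= 2")
    implied_dx = (lastx - firstx) / (npoints - 1)
    if "DELTAX" in labels:
        deltax = float(labels["DELTAX"])
        if abs(deltax - implied_dx) > 1e-6 * max(1.0, abs(implied_dx)):
            raise ValueError(
                "inconsistent JCAMP header: DELTAX="
                f"{deltax} but (LASTX-FIRSTX)/(NPOINTS-1)={implied_dx}"
            )
    ys: list[float] = []
    for line in data_lines:
        nums = line.replace(",", " ").split()
        if not nums:
            continue
        # first number on the line is the X check value
        ys.extend(float(v) * yfactor for v in nums[1:])
    if len(ys) != npoints:
        raise ValueError(
            f"JCAMP data holds {len(ys)} Y values but NPOINTS={npoints}"
        )
    xs = list(np.linspace(firstx * xfactor, lastx * xfactor, npoints))
    meta = {"title": labels.get("TITLE", "")}
    return xs, ys, meta


def _spectrum_to_jcamp(s: Spectrum | CDSpectrum) -> str:
    kind = "cd" if isinstance(s, CDSpectrum) else "ftir"
    xunits = "NANOMETERS" if kind == "cd" else "1/CM"
    yunits = "ELLIPTICITY" if kind == "cd" else "ABSORBANCE"
    buf = _io.StringIO()
    buf.write("##TITLE= " + str(s.meta.get("sample_id", "epispec spectrum")) + "\n")
    buf.write("##JCAMP-DX= 4.24\n##DATA TYPE= " +
              ("CIRCULAR DICHROISM" if kind == "cd" else "INFRARED SPECTRUM") + "\n")
    buf.write(f"##XUNITS= {xunits}\n##YUNITS= {yunits}\n")
    buf.write("##XFACTOR= 1\n##YFACTOR= 1\n")
    buf.write(f"##FIRSTX= {s.axis[0]:.6f}\n##LASTX= {s.axis[-1]:.6f}\n")
    buf.write(f"##NPOINTS= {s.axis.size}\n")
    buf.write(f"##DELTAX= {(s.axis[-1] - s.axis[0]) / (s.axis.size - 1):.6f}\n")
    buf.write("##XYDATA= (X++(Y..Y))\n")
    per_line = 6
    for i in range(0, s.axis.size, per_line):
        chunk = s.values[i:i + per_line]
        buf.write(f"{s.axis[i]:.6f} " + " ".join(f"{y:.6f}" for y in chunk) + "\n")
    buf.write("##END=\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of an end-to-end run.

    Stage parameters are stored as plain dicts mirroring the stage config
    dataclasses so a single YAML document round-trips the whole run; the
    content hash stamps every output file header for reproducibility.
    """

    seed: int = 0
    n_replicates: int = 3
    n_acquisitions: int = 4  # sequential scans averaged per replicate
    variant: str = "synthetic_oligo"
    generator: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    windows: str = "default"
    apex_mode: str = "auto"  # band_intensity apex selection
    cd_reference: str = "cellular_control"
    cd_test: str = "cellular_mettl3_kd"
    knockdown_factor: float = 0.8
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """First 12 hex digits of the SHA-256 of the canonical YAML form."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
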