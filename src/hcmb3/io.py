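"""Reading and writing half-circular angle samples.

Input is either delimited text (comma/tab/whitespace autodetected, ``#``
comment lines ignored) or an XLSX sheet, one angle per row, with the unit
(radians or degrees) declared explicitly.  After conversion every value must
lie in [0, pi); offending rows are reported by number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .distribution import rng as _rng, validate_params

__all__ = ["AngleFileSpec", "read_angles", "generate_fixture"]


@dataclass(frozen=True)
class AngleFileSpec:
    path: Union[str, Path]
    format: str = "auto"  # "delimited", "xlsx" or "auto" (by extension)
    unit: str = "radians"  # "radians" or "degrees"
    column: Union[int, str] = 0

    def resolved_format(self) -> str:
        if self.format != "auto":
            if self.format not in ("delimited", "xlsx"):
                raise ValueError(f"unknown format {self.format!r}")
            return self.format
        return "xlsx" if str(self.path).lower().endswith((".xlsx", ".xls")) else "delimited"


def _to_radians(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "radians":
        return values
    if unit == "degrees":
        return np.deg2rad(values)
    raise ValueError(f"unknown unit {unit!r}; use 'radians' or 'degrees'")


def read_angles(spec: AngleFileSpec) -> np.ndarray:
    """Read an angle sample (radians, values in [0, pi)) per the file spec."""
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = spec.resolved_format()
    if fmt == "xlsx":
        df = pd.read_excel(path)
        col = df[spec.column] if isinstance(spec.column, str) else df.iloc[:, int(spec.column)]
        raw = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    else:
        if isinstance(spec.column, str):
            raise ValueError("named columns require xlsx input; use a column index")
        # explicit delimiter detection: the sniffer misreads one-column files
        sep = r"\s+"
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    for cand in (",", "\t", ";"):
                        if cand in line:
                            sep = cand
                            break
                    break
        try:
            # C engine + round_trip keeps written floats bit-exact on re-read
            df = pd.read_csv(path, sep=sep, engine="c", comment="#", header=None,
                             float_precision="round_trip", skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty file") from None
        raw = pd.to_numeric(df.iloc[:, int(spec.column)], errors="coerce").to_numpy(dtype=float)
    if raw.size == 0:
        raise ValueError(f"{path}: no data rows")
    bad = np.nonzero(~np.isfinite(raw))[0]
    if bad.size:
        raise ValueError(f"{path}: unparseable value(s) at data row(s) {(bad + 1).tolist()}")
    theta = _to_radians(raw, spec.unit)
    out = np.nonzero((theta < 0) | (theta >= np.pi))[0]
    if out.size:
        raise ValueError(
            f"{path}: angle(s) outside [0, pi) after unit conversion at data "
            f"row(s) {(out + 1).tolist()}: {raw[out][:5].tolist()}"
        )
    return theta


def generate_fixture(params, n: int, seed: int, out: Union[str, Path, AngleFileSpec]) -> Path:
    """Write a seeded synthetic angle sample as a delimited fixture file.

    The header comments record the generating parameters and seed, so the file
    is self-describing and bit-identical for a fixed seed.  Returns the path.
    """
    p = validate_params(params)
    path = Path(out.path if isinstance(out, AngleFileSpec) else out)
    theta = _rng(n, p, seed)
    with open(path, "w") as fh:
        fh.write(f"# hcmb3 fixture: alpha={p.alpha!r} beta={p.beta!r} gamma={p.gamma!r} "
                 f"n={int(n)} seed={int(seed)} unit=radians\n")
        for v in theta:
            fh.write(f"{float(v)!r}\n")
    return path


def read_fixture_metadata(path) -> dict:
    """Parse the params/seed header written by :func:`generate_fixture`."""
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                try:
                    meta[k] = float(v) if k in ("alpha", "beta", "gamma") else (
                        int(v) if k in ("n", "seed") else v)
                except ValueError:
                    meta[k] = v
    return meta
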