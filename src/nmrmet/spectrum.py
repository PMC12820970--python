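"""One-dimensional NMR spectrum container and plain-text I/O.

A :class:`Spectrum1D` holds a processed, real-valued 1D ^1H spectrum: a
strictly monotone chemical-shift axis in ppm (stored descending, the NMR
display convention), an intensity vector of equal length, and sample
metadata (tissue, diet group, extract phase, tissue wet weight).

Two on-disk formats are supported, both plain text:

* two-column ``ppm intensity`` (whitespace- or comma-delimited, ``#``
  comments allowed), written with descending ppm;
* a minimal JCAMP-DX-style file whose data live in an
  ``##XYDATA= (XY..XY)`` block of ``x, y`` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Spectrum1D", "SpectrumParseError", "read_spectrum", "write_spectrum"]

TISSUES = ("heart", "kidney", "muscle")
GROUPS = ("SC", "HF")
PHASES = ("aqueous", "lipophilic")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; carries the line number."""


@dataclass
class Spectrum1D:
    """A processed 1D spectrum with ppm axis stored in descending order."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        d = np.diff(self.ppm)
        if np.any(d == 0) or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if np.all(d > 0):  # enforce descending storage
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        w = self.meta.get("weight_g")
        if w is not None and not w > 0:
            raise ValueError(f"weight_g must be positive, got {w}")

    def __len__(self) -> int:
        return self.ppm.size

    @property
    def step(self) -> float:
        """Mean axis step in ppm (positive)."""
        return float(abs(self.ppm[0] - self.ppm[-1]) / (len(self) - 1))

    def copy(self, **meta_updates: Any) -> "Spectrum1D":
        new_meta = {**self.meta, **meta_updates}
        return replace(self, ppm=self.ppm.copy(), intensity=self.intensity.copy(), meta=new_meta)

    def window_slice(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask of axis points with lo_ppm <= ppm <= hi_ppm."""
        return (self.ppm >= lo_ppm) & (self.ppm <= hi_ppm)

    def integral(self, lo_ppm: float | None = None, hi_ppm: float | None = None) -> float:
        """Numeric integral (sum × step) over a ppm window, default full axis."""
        if lo_ppm is None and hi_ppm is None:
            vals = self.intensity
        else:
            lo = -np.inf if lo_ppm is None else lo_ppm
            hi = np.inf if hi_ppm is None else hi_ppm
            vals = self.intensity[self.window_slice(lo, hi)]
        return float(vals.sum() * self.step)


def _parse_two_column(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumParseError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{i}: non-numeric value ({exc})") from None
    if not xs:
        raise SpectrumParseError(f"{path}: no data rows")
    return np.array(xs), np.array(ys)


def _parse_jcamp(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse an ``##XYDATA= (XY..XY)`` block of explicit x, y pairs."""
    xs: list[float] = []
    ys: list[float] = []
    in_block = False
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.upper().startswith("##XYDATA"):
            in_block = True
            continue
        if in_block:
            if line.startswith("##"):  # next label ends the block
                break
            if not line:
                continue
            for pair in line.split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                parts = pair.replace(",", " ").split()
                if len(parts) != 2:
                    raise SpectrumParseError(
                        f"{path}:{i}: malformed XYDATA pair {pair!r}"
                    )
                try:
                    xs.append(float(parts[0]))
                    ys.append(float(parts[1]))
                except ValueError:
                    raise SpectrumParseError(f"{path}:{i}: non-numeric XYDATA") from None
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA block found")
    return np.array(xs), np.array(ys)


def read_spectrum(path: str | Path, meta: dict[str, Any] | None = None) -> Spectrum1D:
    """Read a spectrum from two-column text or a JCAMP-DX-style XYDATA file.

    The stored axis is re-sorted to descending ppm; duplicate or
    non-monotone axes raise :class:`SpectrumParseError` naming the file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    is_jcamp = any(ln.lstrip().startswith("##") for ln in lines[:5])
    if is_jcamp:
        x, y = _parse_jcamp(lines, str(path))
    else:
        x, y = _parse_two_column(lines, str(path))
    order = np.argsort(-x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) >= 0):
        raise SpectrumParseError(f"{path}: ppm axis not strictly monotone")
    return Spectrum1D(x, y, dict(meta or {}))


def write_spectrum(s: Spectrum1D, path: str | Path, fmt: str = "xy") -> None:
    """Write a spectrum as two-column text (``xy``) or JCAMP-DX-style (``jcamp``)."""
    path = Path(path)
    if fmt == "xy":
        header = "# ppm\tintensity\n"
        body = "".join(f"{p:.9f}\t{v:.12e}\n" for p, v in zip(s.ppm, s.intensity))
        path.write_text(header + body)
    elif fmt == "jcamp":
        out = [
            "##TITLE= nmrmet spectrum",
            "##JCAMP-DX= 5.01",
            "##DATA TYPE= NMR SPECTRUM",
            "##XUNITS= PPM",
            "##YUNITS= ARBITRARY",
            f"##NPOINTS= {len(s)}",
            "##XYDATA= (XY..XY)",
        ]
        out += [f"{p:.9f}, {v:.12e}" for p, v in zip(s.ppm, s.intensity)]
        out.append("##END=")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
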