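"""Tabulated lineal-energy spectra and their moments.

Lineal energy y is the energy deposited in a microscopic domain by a single
event divided by the domain's mean chord length (keV/um).  A spectrum is a
probability density f(y) tabulated on a strictly increasing grid; its
frequency-mean y_F = int y f dy / int f dy and dose-mean
y_D = int y^2 f dy / int y f dy are the moments the survival model consumes.
Integrals use the trapezoid rule on the supplied grid; a single-row
spectrum is treated as a point mass (y_F = y_D = y0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LinealEnergySpectrum",
    "SpectrumMoments",
    "read_spectrum",
    "write_spectrum",
    "spectrum_moments",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumMoments:
    """Frequency-mean (y_F) and dose-mean (y_D) lineal energy, keV/um.
    y_D >= y_F always (Cauchy-Schwarz), with equality only for a point mass."""

    y_f: float
    y_d: float


class LinealEnergySpectrum:
    """Probability density f(y) over lineal energy y (keV/um).

    The density is normalized on construction so that its trapezoid
    integral over the grid is 1 (a single-point spectrum carries weight 1
    as a point mass).
    """

    def __init__(self, y_grid, density):
        y = np.asarray(y_grid, dtype=float)
        f = np.asarray(density, dtype=float)
        if y.ndim != 1 or f.shape != y.shape:
            raise ValueError("y_grid and density must be 1-D arrays of equal length")
        if y.size < 1:
            raise ValueError("spectrum needs at least one point")
        if np.any(y <= 0):
            raise ValueError("all lineal-energy values must be positive")
        if np.any(np.diff(y) <= 0):
            bad = int(np.argmax(np.diff(y) <= 0)) + 2
            raise ValueError(f"non-increasing grid at row {bad}")
        if np.any(f < 0):
            raise ValueError("density values must be non-negative")
        total = self._integral(y, f)
        if total <= 0:
            raise ValueError("spectrum has zero total weight")
        self.y_grid = y
        self.density = f / total
        if not np.isclose(total, 1.0):
            log.info("spectrum normalized by factor %.6g", 1.0 / total)

    @staticmethod
    def _integral(y: np.ndarray, f: np.ndarray) -> float:
        if y.size == 1:  # point-mass convention
            return float(f[0])
        return float(np.trapezoid(f, y))

    def integral(self, weight: np.ndarray | None = None) -> float:
        f = self.density if weight is None else self.density * weight
        return self._integral(self.y_grid, f)

    def moments(self) -> SpectrumMoments:
        """Frequency- and dose-mean lineal energy by trapezoid quadrature."""
        y = self.y_grid
        m0 = self.integral()
        m1 = self.integral(y)
        m2 = self.integral(y**2)
        if m0 <= 0 or m1 <= 0:
            raise ValueError("spectrum has zero total weight")
        return SpectrumMoments(y_f=m1 / m0, y_d=m2 / m1)


def spectrum_moments(spec: LinealEnergySpectrum) -> SpectrumMoments:
    """Functional alias for :meth:`LinealEnergySpectrum.moments`."""
    return spec.moments()


def read_spectrum(path: str | Path) -> LinealEnergySpectrum:
    """Read a two-column CSV (y [keV/um], density) into a normalized spectrum.

    Lines starting with '#' are comments; a single non-numeric first row is
    accepted as a header.  Malformed rows are rejected with the offending
    line number.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 or not rows:
                    continue  # header row
                raise ValueError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    y, f = (np.array(col) for col in zip(*rows))
    try:
        return LinealEnergySpectrum(y, f)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_spectrum(spec: LinealEnergySpectrum, path: str | Path) -> None:
    """Write the normalized spectrum as a two-column CSV with a header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("y_kev_um,density\n")
        for y, f in zip(spec.y_grid, spec.density):
            fh.write(f"{float(y)!r},{float(f)!r}\n")
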