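"""Wavelength grids, spectra, radiometric/photometric normalization and chromaticity.

All spectral quantities in this package live on a uniform wavelength grid.
The canonical grid is 390–780 nm in 2 nm steps, matching the tabulation of
the standard-observer functions the calculations are built on.  Integrals
over wavelength are computed as a left-Riemann sum ``value · Δλ`` on the
uniform grid, the convention used for tabulated spectra; the test-suite
oracles use the identical rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CANONICAL_GRID",
    "KM_LM_PER_W",
    "Chromaticity",
    "GridMismatchError",
    "SpectralError",
    "Spectrum",
    "WavelengthGrid",
    "cie1964_xy",
    "luminance_of",
    "normalize_auc",
    "resample",
    "scale_to_luminance",
]

#: Maximum luminous efficacy of photopic vision, lm/W (exact by definition
#: of the candela).  Converts radiance weighted by V(λ) into cd/m².
KM_LM_PER_W = 683.0

#: Units a :class:`Spectrum` may declare.  Optical densities are the only
#: kind allowed to be negative.
UNIT_RELATIVE = "relative"
UNIT_RADIANCE = "W/(m^2*sr*nm)"
UNIT_SENSITIVITY = "sensitivity"
UNIT_OPTICAL_DENSITY = "optical_density"
_KNOWN_UNITS = (UNIT_RELATIVE, UNIT_RADIANCE, UNIT_SENSITIVITY, UNIT_OPTICAL_DENSITY)


class SpectralError(ValueError):
    """A spectrum violates its contract (empty overlap, all-zero input, ...)."""


class GridMismatchError(SpectralError):
    """Two spectra that must share a wavelength grid do not."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start, start+step, ..., stop`` (inclusive), in nm."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(f"grid stop must exceed start, got [{self.start}, {self.stop}]")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(stop - start) = {self.stop - self.start} is not an integer "
                f"multiple of step = {self.step}"
            )

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self))


#: 390–780 nm, 2 nm steps — the grid of the bundled standard-observer tables;
#: imported spectra are resampled onto it on load.
CANONICAL_GRID = WavelengthGrid(390.0, 780.0, 2.0)


@dataclass(frozen=True)
class Spectrum:
    """Values of a spectral quantity on a uniform wavelength grid.

    Parameters
    ----------
    grid
        The wavelength grid the values are tabulated on.
    values
        One value per grid point.  Must be finite; must be non-negative
        unless ``unit`` is ``"optical_density"``.
    unit
        Semantic unit: ``"relative"`` (arbitrary intensity), ``"W/(m^2*sr*nm)"``
        (spectral radiance), ``"sensitivity"`` (dimensionless) or
        ``"optical_density"``.
    """

    grid: WavelengthGrid
    values: np.ndarray
    unit: str = UNIT_RELATIVE

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) != len(self.grid):
            raise ValueError(
                f"values length {vals.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.unit not in _KNOWN_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_KNOWN_UNITS}")
        if self.unit != UNIT_OPTICAL_DENSITY and np.any(vals < 0):
            raise ValueError(f"{self.unit} spectrum must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def auc(self) -> float:
        """Area under the curve, ``Σ value·Δλ`` (left-Riemann sum)."""
        return float(np.sum(self.values) * self.grid.step)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, self.unit if unit is None else unit)


@dataclass(frozen=True)
class Chromaticity:
    """CIE 1964 10° chromaticity coordinates (x₁₀, y₁₀)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-12:
            raise ValueError(f"invalid chromaticity ({self.x}, {self.y})")


def _require_same_grid(a: Spectrum, b: Spectrum, what: str) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"{what}: spectra are on different grids "
            f"({a.grid.start}-{a.grid.stop}/{a.grid.step} vs "
            f"{b.grid.start}-{b.grid.stop}/{b.grid.step} nm)"
        )


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``target``.

    Points of the target grid outside the source support are set to 0 (a
    light source emits nothing where it was not measured).  The unit is
    preserved.

    Raises
    ------
    SpectralError
        If the source and target wavelength ranges do not overlap at all.
    """
    src = spectrum.grid
    if src.stop < target.start or src.start > target.stop:
        raise SpectralError(
            f"source range {src.start}-{src.stop} nm does not overlap "
            f"target range {target.start}-{target.stop} nm"
        )
    if src == target:
        return spectrum
    out = np.interp(
        target.wavelengths, spectrum.wavelengths, spectrum.values, left=0.0, right=0.0
    )
    return Spectrum(target, out, spectrum.unit)


def normalize_auc(spectrum: Spectrum) -> Spectrum:
    """Rescale so the numerical integral over wavelength equals 1 W/(m²·sr).

    The input's absolute unit is irrelevant — any positive scalar multiple of
    the same spectral shape yields the identical output — so emission spectra
    may be imported in arbitrary intensity units.  The result is declared as
    spectral radiance.

    Raises
    ------
    SpectralError
        If the spectrum has no strictly positive value.
    """
    auc = spectrum.auc()
    if auc <= 0 or not np.any(spectrum.values > 0):
        raise SpectralError("cannot AUC-normalize a spectrum with no positive values")
    return Spectrum(spectrum.grid, spectrum.values / auc, UNIT_RADIANCE)


def luminance_of(spd: Spectrum, vlambda: Spectrum) -> float:
    """Photopic luminance of a spectral radiance distribution, in cd/m².

    ``K_m · Σ spd(λ)·V(λ)·Δλ`` with K_m = 683 lm/W.
    """
    _require_same_grid(spd, vlambda, "luminance_of")
    return KM_LM_PER_W * float(np.sum(spd.values * vlambda.values) * spd.grid.step)


def scale_to_luminance(normalized: Spectrum, luminance: float, vlambda: Spectrum) -> Spectrum:
    """Scale an AUC-normalized emission spectrum to a target luminance.

    Raises
    ------
    ValueError
        If ``luminance`` is not strictly positive.  A primary at zero
        luminance would effectively be a device with one fewer primary and
        must instead be dropped from the device description.
    """
    if luminance <= 0:
        raise ValueError(
            f"primary luminance must be > 0 cd/m^2 (got {luminance}); "
            "no primary can be set to zero luminance"
        )
    base = luminance_of(normalized, vlambda)
    if base <= 0:
        raise SpectralError("spectrum has zero luminance; cannot scale to a luminance")
    return normalized.with_values(normalized.values * (luminance / base), UNIT_RADIANCE)


def cie1964_xy(spd: Spectrum, cmfs: tuple[Spectrum, Spectrum, Spectrum]) -> Chromaticity:
    """CIE 1964 10° chromaticity of a spectral power distribution.

    ``cmfs`` are the (x̄₁₀, ȳ₁₀, z̄₁₀) colour-matching functions on the same
    grid as ``spd``.
    """
    xyz = []
    for cmf in cmfs:
        _require_same_grid(spd, cmf, "cie1964_xy")
        xyz.append(float(np.sum(spd.values * cmf.values) * spd.grid.step))
    total = sum(xyz)
    if total <= 0:
        raise SpectralError("chromaticity undefined for an all-zero spectrum")
    return Chromaticity(xyz[0] / total, xyz[1] / total)
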