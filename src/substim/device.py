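"""Multiprimary stimulator model and the photoreceptor-excitation (A-) matrix.

A device has 3–5 independently controllable primaries, each described by an
AUC-normalized emission spectrum, a mean luminance and a usable luminance
range.  At the mean setting, the excitation of photoreceptor class *p* by
primary *j* is

    a[p][j] = Σ_λ R_p(λ) · E_j(λ) · Δλ

with R_p the fundamental and E_j the emission spectrum scaled to the
primary's mean luminance.  When every primary is modulated sinusoidally
with Michelson contrast c_j around its mean, the excitation of class *p*
modulates with Michelson contrast

    C_p = Σ_j w[p][j] · c_j,     w[p][j] = a[p][j] / Σ_k a[p][k],

so each *row* (photoreceptor) of the normalized matrix W sums to 1.  A
device with n primaries can control exactly n photoreceptor classes; the
square block of W over the controlled set is inverted by the solver, while
the full five-row matrix is kept to evaluate the uncontrolled classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observer import PHOTORECEPTORS, Observer
from .spectra import (
    GridMismatchError,
    Spectrum,
    UNIT_RADIANCE,
    luminance_of,
    scale_to_luminance,
)

__all__ = [
    "AMatrix",
    "DegeneratePrimariesError",
    "Device",
    "Primary",
    "build_a_matrix",
    "controlled_set",
    "excitation",
    "mean_spd",
]

#: Condition number above which the controlled block is treated as singular.
CONDITION_LIMIT = 1e8


class DegeneratePrimariesError(ValueError):
    """The primaries are too spectrally similar to solve for contrasts."""


@dataclass(frozen=True)
class Primary:
    """One independently controllable light source of the stimulator.

    ``emission`` must be AUC-normalized (integral 1 W/(m²·sr)); ``lum_range``
    is the luminance interval, in cd/m², the hardware can actually produce.
    """

    name: str
    emission: Spectrum
    mean_luminance: float
    lum_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.lum_range
        if self.mean_luminance <= 0:
            raise ValueError(
                f"primary {self.name!r}: mean luminance must be > 0 cd/m^2 "
                f"(got {self.mean_luminance}); no primary can be set to zero luminance"
            )
        if lo < 0 or lo > self.mean_luminance or self.mean_luminance > hi:
            raise ValueError(
                f"primary {self.name!r}: need 0 <= min <= mean <= max, got "
                f"min={lo}, mean={self.mean_luminance}, max={hi}"
            )
        if abs(self.emission.auc() - 1.0) > 1e-6:
            raise ValueError(
                f"primary {self.name!r}: emission spectrum must be AUC-normalized "
                f"(integral = {self.emission.auc():.6g}, expected 1)"
            )


@dataclass(frozen=True)
class Device:
    """An ordered set of 3–5 primaries plus the luminance-calibration V(λ)."""

    primaries: tuple[Primary, ...]
    vlambda: Spectrum

    def __post_init__(self) -> None:
        object.__setattr__(self, "primaries", tuple(self.primaries))
        n = len(self.primaries)
        if not 3 <= n <= 5:
            raise ValueError(
                f"a device needs at least 3 and at most 5 primaries, got {n}"
            )
        grids = {p.emission.grid for p in self.primaries} | {self.vlambda.grid}
        if len(grids) != 1:
            raise GridMismatchError("all primary spectra and V(lambda) must share one grid")
        _check_spectral_distinctness(self.primaries)

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.primaries)

    @property
    def mean_luminances(self) -> np.ndarray:
        return np.array([p.mean_luminance for p in self.primaries])

    def scaled_spds(self) -> list[Spectrum]:
        """Each primary's emission scaled to its mean luminance."""
        return [
            scale_to_luminance(p.emission, p.mean_luminance, self.vlambda)
            for p in self.primaries
        ]


def _check_spectral_distinctness(primaries: tuple[Primary, ...]) -> None:
    """Reject pairs of primaries that are (near-)scalar multiples of each other."""
    mat = np.array([p.emission.values for p in primaries])
    norms = np.linalg.norm(mat, axis=1)
    cos = (mat @ mat.T) / np.outer(norms, norms)
    n = len(primaries)
    for i in range(n):
        for j in range(i + 1, n):
            if cos[i, j] > 1.0 - 1e-10:
                raise DegeneratePrimariesError(
                    f"primaries {primaries[i].name!r} and {primaries[j].name!r} have "
                    "linearly dependent emission spectra"
                )


def excitation(fund: Spectrum, spd: Spectrum) -> float:
    """Photoreceptor excitation ``Σ fund(λ)·spd(λ)·Δλ`` (arbitrary units)."""
    if fund.grid != spd.grid:
        raise GridMismatchError("fundamental and SPD must share a wavelength grid")
    return float(np.sum(fund.values * spd.values) * fund.grid.step)


def controlled_set(n_primaries: int) -> tuple[str, ...]:
    """Photoreceptor classes an n-primary device can control.

    Three primaries control the cones (L, M, S); a fourth adds rods; a fifth
    adds melanopsin.  Classes outside the controlled set cannot be silenced
    and are only evaluated during validation.
    """
    if not 3 <= n_primaries <= 5:
        raise ValueError(
            f"devices with 3-5 primaries are supported, got {n_primaries}"
        )
    return PHOTORECEPTORS[:n_primaries]


@dataclass(frozen=True)
class AMatrix:
    """Excitation matrix of a device/observer pair.

    ``raw`` and ``normalized`` are 5×n with rows ordered like
    ``all_photoreceptors`` and columns like ``primaries``; ``normalized``
    rows sum to 1.  ``controlled`` names the square sub-matrix used by the
    solver.
    """

    raw: np.ndarray
    normalized: np.ndarray
    controlled: tuple[str, ...]
    all_photoreceptors: tuple[str, ...]
    primaries: tuple[str, ...]

    @property
    def controlled_block(self) -> np.ndarray:
        """Square normalized block over the controlled photoreceptors."""
        idx = [self.all_photoreceptors.index(p) for p in self.controlled]
        return self.normalized[idx, :]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.controlled_block))


def build_a_matrix(device: Device, observer: Observer) -> AMatrix:
    """Compute raw and contrast-normalized excitation matrices.

    Raises
    ------
    DegeneratePrimariesError
        If the controlled block's condition number exceeds 1e8, naming the
        most collinear pair of primaries.
    """
    if observer.grid != device.vlambda.grid:
        raise GridMismatchError("observer fundamentals must be on the device grid")
    spds = device.scaled_spds()
    raw = np.array(
        [[excitation(observer.fundamentals[p], spd) for spd in spds] for p in PHOTORECEPTORS]
    )
    row_sums = raw.sum(axis=1)
    if np.any(row_sums <= 0):
        dead = [p for p, s in zip(PHOTORECEPTORS, row_sums) if s <= 0]
        raise ValueError(f"photoreceptors {dead} receive no excitation from this device")
    normalized = raw / row_sums[:, None]
    ctrl = controlled_set(device.n_primaries)
    matrix = AMatrix(
        raw=raw,
        normalized=normalized,
        controlled=ctrl,
        all_photoreceptors=PHOTORECEPTORS,
        primaries=device.names,
    )
    cond = matrix.condition_number
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        i, j = _most_collinear_pair(raw)
        raise DegeneratePrimariesError(
            f"controlled A-matrix is near-singular (condition number {cond:.3g} > "
            f"{CONDITION_LIMIT:.0e}); primaries {device.names[i]!r} and "
            f"{device.names[j]!r} are the most collinear pair"
        )
    return matrix


def _most_collinear_pair(raw: np.ndarray) -> tuple[int, int]:
    cols = raw / np.linalg.norm(raw, axis=0, keepdims=True)
    cos = np.abs(cols.T @ cols)
    np.fill_diagonal(cos, -np.inf)
    i, j = np.unravel_index(int(np.argmax(cos)), cos.shape)
    return (min(i, j), max(i, j))


def mean_spd(device: Device) -> Spectrum:
    """Spectral power distribution of the device at its mean settings.

    The sum over primaries of each emission spectrum scaled to its mean
    luminance; the stimulus is modulated around this distribution.
    """
    total = np.zeros(len(device.vlambda.grid))
    for spd in device.scaled_spds():
        total += spd.values
    return Spectrum(device.vlambda.grid, total, UNIT_RADIANCE)


def total_luminance(device: Device) -> float:
    """Luminance of the mean SPD, equal to the sum of primary luminances."""
    return luminance_of(mean_spd(device), device.vlambda)
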