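"""Photoreceptor fundamentals and their individual modification.

The standard observer is described by five corneal spectral sensitivities
("fundamentals"): the L-, M- and S-cone 10° fundamentals, the scotopic
luminous efficiency function for rods, and the melanopsin fundamental of
the ipRGCs.  The tabulated cone fundamentals assume a macular pigment peak
optical density (MPOD) of 0.3 and a lens age of 40 years; deviations from
those baselines in an individual observer are modelled by multiplying each
fundamental by ``10^(−ΔD(λ))`` where ΔD is the change in pre-receptoral
optical density, and λ-max shifts of the L- and M-cone pigments (e.g. from
opsin-gene polymorphisms) by translating the fundamental along the
wavelength axis.

These modifications are for *validating* a stimulus — estimating the
residual contrasts an individual observer would experience — never for
calculating it; stimulus calculation always uses the standard observer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, WavelengthGrid

__all__ = [
    "DEFAULT_LENS_AGE",
    "DEFAULT_MPOD",
    "PHOTORECEPTORS",
    "DensityTemplate",
    "Observer",
    "apply_lens_age",
    "apply_macular",
    "build_modified_observer",
    "lens_density",
    "shift_lambda_max",
]

#: Photoreceptor labels in controlled-set order: a 3-primary device controls
#: the first three, a 4-primary device the first four, a 5-primary device all.
PHOTORECEPTORS = ("L", "M", "S", "rod", "mel")

#: Baselines embedded in the tabulated 10° fundamentals.
DEFAULT_MPOD = 0.3
DEFAULT_LENS_AGE = 40.0

#: Lower end of the lens-ageing model's domain, years.
MIN_LENS_AGE = 20.0


@dataclass(frozen=True)
class DensityTemplate:
    """Spectral templates of the pre-receptoral filters.

    ``macular`` is the macular pigment optical density spectrum normalized to
    a peak of 1, so it scales linearly with peak MPOD.  ``lens_tl1`` and
    ``lens_tl2`` are the age-dependent and age-independent components of the
    lens optical density model.
    """

    macular: Spectrum
    lens_tl1: Spectrum
    lens_tl2: Spectrum

    def __post_init__(self) -> None:
        peak = float(np.max(self.macular.values))
        if abs(peak - 1.0) > 1e-6:
            raise ValueError(
                f"macular template must be peak-normalized to 1 (peak = {peak})"
            )
        for name in ("macular", "lens_tl1", "lens_tl2"):
            if np.any(getattr(self, name).values < 0):
                raise ValueError(f"{name} optical densities must be >= 0")


@dataclass(frozen=True)
class Observer:
    """The five photoreceptor fundamentals plus modification parameters.

    ``fundamentals`` maps each label in :data:`PHOTORECEPTORS` to a
    sensitivity spectrum on the canonical grid.  ``mpod``, ``lens_age``,
    ``shift_L`` and ``shift_M`` record the physiological parameters the
    fundamentals currently embody; the defaults describe the baseline
    standard observer.
    """

    fundamentals: dict[str, Spectrum]
    mpod: float = DEFAULT_MPOD
    lens_age: float = DEFAULT_LENS_AGE
    shift_L: float = 0.0
    shift_M: float = 0.0

    def __post_init__(self) -> None:
        missing = [p for p in PHOTORECEPTORS if p not in self.fundamentals]
        if missing:
            raise ValueError(f"observer is missing fundamentals for {missing}")
        grids = {f.grid for f in self.fundamentals.values()}
        if len(grids) != 1:
            raise ValueError("all fundamentals must share one wavelength grid")

    @property
    def grid(self) -> WavelengthGrid:
        return next(iter(self.fundamentals.values())).grid

    @property
    def params(self) -> dict[str, float]:
        return {
            "mpod": self.mpod,
            "lens_age": self.lens_age,
            "shift_L": self.shift_L,
            "shift_M": self.shift_M,
        }


def apply_macular(
    fund: Spectrum,
    target_mpod: float,
    base_mpod: float = DEFAULT_MPOD,
    template: DensityTemplate | None = None,
    *,
    macular: Spectrum | None = None,
) -> Spectrum:
    """Re-express a fundamental for a different peak macular pigment density.

    Returns ``fund(λ) · 10^(−(target − base)·D_mac(λ))`` where ``D_mac`` is
    the peak-normalized macular density template.  A target below the
    baseline *increases* sensitivity where the pigment absorbs.
    """
    if target_mpod < 0:
        raise ValueError(f"macular pigment optical density must be >= 0, got {target_mpod}")
    if target_mpod == base_mpod:
        return fund
    if macular is None:
        if template is None:
            raise ValueError("either a DensityTemplate or a macular spectrum is required")
        macular = template.macular
    factor = 10.0 ** (-(target_mpod - base_mpod) * macular.values)
    return fund.with_values(fund.values * factor)


def lens_density(template: DensityTemplate, age: float) -> np.ndarray:
    """Lens optical density spectrum at a given age, in OD units.

    ``TL1(λ)·(1 + 0.02·(A − 32)) + TL2(λ)`` for 20 ≤ A ≤ 60 and
    ``TL1(λ)·(1.56 + 0.0667·(A − 60)) + TL2(λ)`` above 60; the two branches
    agree at A = 60.
    """
    if age < MIN_LENS_AGE:
        raise ValueError(f"lens model is defined for ages >= {MIN_LENS_AGE}, got {age}")
    tl1 = template.lens_tl1.values
    tl2 = template.lens_tl2.values
    if age <= 60.0:
        scale = 1.0 + 0.02 * (age - 32.0)
    else:
        scale = 1.56 + 0.0667 * (age - 60.0)
    return tl1 * scale + tl2


def apply_lens_age(
    fund: Spectrum,
    age: float,
    base_age: float = DEFAULT_LENS_AGE,
    template: DensityTemplate | None = None,
) -> Spectrum:
    """Re-express a fundamental for a different lens age.

    Returns ``fund(λ)·10^(−(D(λ, age) − D(λ, base_age)))`` with the lens
    density model of :func:`lens_density`.
    """
    if age < MIN_LENS_AGE:
        raise ValueError(f"lens model is defined for ages >= {MIN_LENS_AGE}, got {age}")
    if age == base_age:
        return fund
    if template is None:
        raise ValueError("a DensityTemplate is required")
    delta = lens_density(template, age) - lens_density(template, base_age)
    return fund.with_values(fund.values * 10.0 ** (-delta))


def shift_lambda_max(fund: Spectrum, delta: float) -> Spectrum:
    """Translate a fundamental by ``delta`` nm along the wavelength axis.

    ``output(λ) = fund(λ − delta)`` by linear interpolation on the grid;
    wavelengths that fall outside the grid read 0.  Positive delta shifts
    the peak toward longer wavelengths.  Applied at the corneal level, which
    for the small shifts of opsin polymorphisms is an adequate approximation
    to shifting the underlying photopigment template.
    """
    if abs(delta) > 20.0:
        raise ValueError(f"lambda-max shift must be within +/-20 nm, got {delta}")
    if delta == 0.0:
        return fund
    wl = fund.wavelengths
    out = np.interp(wl - delta, wl, fund.values, left=0.0, right=0.0)
    return fund.with_values(out)


def build_modified_observer(
    base: Observer,
    mpod: float | None = None,
    lens_age: float | None = None,
    shift_L: float | None = None,
    shift_M: float | None = None,
    template: DensityTemplate | None = None,
) -> Observer:
    """Construct an individually modified observer from the baseline one.

    Macular and lens density changes apply to all five fundamentals — the
    pre-receptoral filters attenuate all light reaching the retina — while
    λ-max shifts apply only to the L and M cones.  With all parameters at
    their defaults the base observer is returned unchanged.
    """
    mpod = base.mpod if mpod is None else mpod
    lens_age = base.lens_age if lens_age is None else lens_age
    shift_L = base.shift_L if shift_L is None else shift_L
    shift_M = base.shift_M if shift_M is None else shift_M

    funds: dict[str, Spectrum] = {}
    for name, fund in base.fundamentals.items():
        f = fund
        if name == "L" and shift_L != base.shift_L:
            f = shift_lambda_max(f, shift_L - base.shift_L)
        elif name == "M" and shift_M != base.shift_M:
            f = shift_lambda_max(f, shift_M - base.shift_M)
        f = apply_macular(f, mpod, base.mpod, template)
        f = apply_lens_age(f, lens_age, base.lens_age, template)
        funds[name] = f
    return Observer(funds, mpod=mpod, lens_age=lens_age, shift_L=shift_L, shift_M=shift_M)
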