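"""Synthetic devices, observers and a brute-force oracle.

Everything here is generated in code so the whole package can be exercised
with no measured spectra and no download of the standard-observer tables:
Gaussian LED emission spectra, Gaussian-template photoreceptor fundamentals
(nomogram-style stand-ins for the real cone/rod/melanopsin fundamentals),
synthetic pre-receptoral density templates, and a deliberately naive solver
(per-wavelength Python loops plus hand-written Gaussian elimination) used
only as an independent reference in tests.

The default synthetic device mirrors a practical 4-primary full-field
stimulator: blue/green/amber/red LEDs at 460/520/590/640 nm with mean
luminances 4/40/100/80 cd/m² — the luminance pattern (short-wavelength
primaries low, long-wavelength high) that typically yields feasible rod and
cone contrasts.
"""

from __future__ import annotations

import math

import numpy as np

from .device import Device, Primary
from .observer import DensityTemplate, Observer
from .solver import ContrastRequest
from .spectra import (
    CANONICAL_GRID,
    Spectrum,
    UNIT_OPTICAL_DENSITY,
    UNIT_SENSITIVITY,
    WavelengthGrid,
    normalize_auc,
)

__all__ = [
    "FUNDAMENTAL_PEAKS",
    "default_device",
    "gaussian_led",
    "oracle_solve",
    "random_device",
    "random_silent_request",
    "synthetic_cmfs",
    "synthetic_density_template",
    "synthetic_fundamental",
    "synthetic_observer",
    "synthetic_vlambda",
]

#: λ-max of the synthetic fundamentals, nm (S, rod, mel, M, L — ordered here
#: by wavelength of peak; the Observer container uses L/M/S/rod/mel labels).
FUNDAMENTAL_PEAKS = {"S": 440.0, "mel": 480.0, "rod": 500.0, "M": 530.0, "L": 560.0}

_DEFAULT_FUND_FWHM = 90.0  # nm, comparable in breadth to real fundamentals


def _gaussian(wl: np.ndarray, peak: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


def gaussian_led(peak: float, fwhm: float, grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """AUC-normalized Gaussian emission spectrum of a synthetic LED."""
    if fwhm <= 0:
        raise ValueError(f"FWHM must be > 0 nm, got {fwhm}")
    shape = _gaussian(grid.wavelengths, peak, fwhm)
    return normalize_auc(Spectrum(grid, shape))


def synthetic_fundamental(
    lambda_max: float,
    width: float = _DEFAULT_FUND_FWHM,
    grid: WavelengthGrid = CANONICAL_GRID,
) -> Spectrum:
    """Smooth unimodal sensitivity template, peak-normalized to 1."""
    if width <= 0:
        raise ValueError(f"width must be > 0 nm, got {width}")
    shape = _gaussian(grid.wavelengths, lambda_max, width)
    return Spectrum(grid, shape / shape.max(), UNIT_SENSITIVITY)


def synthetic_observer(grid: WavelengthGrid = CANONICAL_GRID) -> Observer:
    """Baseline synthetic observer with the five preset fundamentals."""
    funds = {
        name: synthetic_fundamental(peak, grid=grid)
        for name, peak in FUNDAMENTAL_PEAKS.items()
    }
    return Observer(funds)


def synthetic_vlambda(grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """Photopic luminous-efficiency stand-in: unit peak at 555 nm."""
    shape = _gaussian(grid.wavelengths, 555.0, 100.0)
    return Spectrum(grid, shape / shape.max(), UNIT_SENSITIVITY)


def synthetic_density_template(grid: WavelengthGrid = CANONICAL_GRID) -> DensityTemplate:
    """Synthetic pre-receptoral filter templates.

    Macular pigment: Gaussian absorbance peaking (exactly 1) near 460 nm.
    Lens: two smooth short-wavelength absorbance components falling with
    wavelength, the first age-dependent, the second age-independent.
    """
    wl = grid.wavelengths
    mac = _gaussian(wl, 460.0, 60.0)
    mac = mac / mac.max()
    tl1 = 0.4 * np.exp(-(wl - grid.start) / 60.0)
    tl2 = 0.2 * np.exp(-(wl - grid.start) / 90.0)
    return DensityTemplate(
        macular=Spectrum(grid, mac, UNIT_OPTICAL_DENSITY),
        lens_tl1=Spectrum(grid, tl1, UNIT_OPTICAL_DENSITY),
        lens_tl2=Spectrum(grid, tl2, UNIT_OPTICAL_DENSITY),
    )


def synthetic_cmfs(
    grid: WavelengthGrid = CANONICAL_GRID,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Synthetic 10° colour-matching functions (x̄, ȳ, z̄).

    Shapes mimic the real CMFs (bimodal x̄, mid-wavelength ȳ, short-wavelength
    z̄); each is scaled to unit area so an equal-energy spectrum maps to the
    white point x = y = 1/3.
    """
    wl = grid.wavelengths
    xbar = 0.8 * _gaussian(wl, 600.0, 80.0) + 0.2 * _gaussian(wl, 445.0, 40.0)
    ybar = _gaussian(wl, 555.0, 100.0)
    zbar = _gaussian(wl, 445.0, 50.0)
    out = []
    for shape in (xbar, ybar, zbar):
        area = shape.sum() * grid.step
        out.append(Spectrum(grid, shape / area, UNIT_SENSITIVITY))
    return tuple(out)


#: Default synthetic 4-primary device: (name, peak nm, FWHM nm, mean cd/m²).
DEFAULT_PRIMARIES = (
    ("blue", 460.0, 20.0, 4.0),
    ("green", 520.0, 20.0, 40.0),
    ("amber", 590.0, 20.0, 100.0),
    ("red", 640.0, 20.0, 80.0),
)


def default_device(grid: WavelengthGrid = CANONICAL_GRID) -> Device:
    """The packaged 4-primary example device (blue/green/amber/red)."""
    vlam = synthetic_vlambda(grid)
    primaries = tuple(
        Primary(
            name=name,
            emission=gaussian_led(peak, fwhm, grid),
            mean_luminance=lum,
            lum_range=(0.0, 2.0 * lum),
        )
        for name, peak, fwhm, lum in DEFAULT_PRIMARIES
    )
    return Device(primaries, vlam)


def random_device(
    seed: int | np.random.Generator,
    n_primaries: int = 4,
    grid: WavelengthGrid = CANONICAL_GRID,
) -> Device:
    """A randomized but well-separated n-primary device (deterministic per seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 3 <= n_primaries <= 5:
        raise ValueError("devices with 3-5 primaries are supported")
    # evenly spaced peak slots with random jitter keeps the primaries distinct
    slots = np.linspace(440.0, 650.0, n_primaries)
    peaks = slots + rng.uniform(-12.0, 12.0, size=n_primaries)
    fwhms = rng.uniform(15.0, 30.0, size=n_primaries)
    lums = rng.uniform(5.0, 120.0, size=n_primaries)
    vlam = synthetic_vlambda(grid)
    primaries = tuple(
        Primary(
            name=f"P{j + 1}",
            emission=gaussian_led(float(peaks[j]), float(fwhms[j]), grid),
            mean_luminance=float(lums[j]),
            lum_range=(0.0, 2.5 * float(lums[j])),
        )
        for j in range(n_primaries)
    )
    return Device(primaries, vlam)


def random_silent_request(
    rng: np.random.Generator,
    controlled: tuple[str, ...],
    n_silenced: int | None = None,
) -> ContrastRequest:
    """Random request with at least one silenced (exactly-zero) class."""
    n = len(controlled)
    if n_silenced is None:
        n_silenced = int(rng.integers(1, n))
    if not 1 <= n_silenced <= n - 1:
        raise ValueError("need between 1 and n-1 silenced classes")
    silenced = rng.choice(n, size=n_silenced, replace=False)
    desired = {}
    for i, name in enumerate(controlled):
        if i in silenced:
            desired[name] = 0.0
        else:
            magnitude = rng.uniform(0.05, 0.5)
            desired[name] = float(magnitude * rng.choice([-1.0, 1.0]))
    return ContrastRequest(desired)


# ---------------------------------------------------------------------------
# Brute-force oracle — independent of the main code path, used only in tests
# and cross-checks.  Per-sample Python loops; hand-written Gaussian
# elimination (no numpy.linalg).
# ---------------------------------------------------------------------------


def _oracle_integral(a: list[float], b: list[float], step: float) -> float:
    total = 0.0
    for x, y in zip(a, b):
        total += x * y
    return total * step


def _oracle_gauss_solve(matrix: list[list[float]], rhs: list[float]) -> list[float]:
    """Gaussian elimination with partial pivoting, written independently."""
    n = len(matrix)
    a = [row[:] + [rhs[i]] for i, row in enumerate(matrix)]
    for col in range(n):
        pivot_row = col
        for r in range(col + 1, n):
            if abs(a[r][col]) > abs(a[pivot_row][col]):
                pivot_row = r
        if abs(a[pivot_row][col]) < 1e-12:
            raise ValueError("oracle: matrix is singular to working precision")
        a[col], a[pivot_row] = a[pivot_row], a[col]
        for r in range(col + 1, n):
            factor = a[r][col] / a[col][col]
            for k in range(col, n + 1):
                a[r][k] -= factor * a[col][k]
    x = [0.0] * n
    for i in range(n - 1, -1, -1):
        s = a[i][n]
        for k in range(i + 1, n):
            s -= a[i][k] * x[k]
        x[i] = s / a[i][i]
    return x


def oracle_solve(device: Device, observer: Observer, request: ContrastRequest) -> np.ndarray:
    """Reference solve by naive summation and hand-rolled elimination.

    Recomputes luminance scaling, excitations, normalization and the linear
    solve from first principles without touching the main code path (or
    numpy.linalg); exists purely for equivalence testing.
    """
    step = device.vlambda.grid.step
    vlam = device.vlambda.values.tolist()
    n = device.n_primaries
    from .device import controlled_set  # label rule shared by contract
    from .spectra import KM_LM_PER_W

    controlled = controlled_set(n)

    spds: list[list[float]] = []
    for primary in device.primaries:
        emission = primary.emission.values.tolist()
        base_lum = KM_LM_PER_W * _oracle_integral(emission, vlam, step)
        factor = primary.mean_luminance / base_lum
        spds.append([v * factor for v in emission])

    w_rows: list[list[float]] = []
    for name in controlled:
        fund = observer.fundamentals[name].values.tolist()
        row = [_oracle_integral(fund, spd, step) for spd in spds]
        total = sum(row)
        w_rows.append([v / total for v in row])

    target = [request.desired[name] for name in controlled]
    return np.array(_oracle_gauss_solve(w_rows, target))
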