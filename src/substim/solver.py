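"""Solve for the primary contrasts that realize desired photoreceptor contrasts.

Given the normalized excitation matrix W over the controlled photoreceptor
set and a vector C of desired photoreceptor Michelson contrasts (zero for
every silenced class), the per-primary contrasts are ``c = W⁻¹·C``.  Because
the contrast relation is linear, multiplying all primary contrasts by one
factor multiplies every photoreceptor contrast by the same factor; the
``maximize`` operation exploits this to rescale a stimulus so the most
modulated primary reaches exactly 100% contrast.

Feasibility is a hardware question: each primary must stay inside its
luminance range over the whole modulation cycle, and contrasts above 100%
are physically impossible.  Very small primary contrasts are flagged as
warnings because a device's luminance resolution may not resolve them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .device import AMatrix, Device

__all__ = [
    "ContrastRequest",
    "StimulusSolution",
    "UncontrolledPhotoreceptorError",
    "check_feasibility",
    "maximize",
    "solve_contrasts",
    "waveform",
]

#: Default advisory threshold below which a nonzero primary contrast is
#: flagged as possibly below the device's luminance resolution (fraction).
RESOLUTION_WARN_THRESHOLD = 0.005

_FORWARD_TOL = 1e-10


class UncontrolledPhotoreceptorError(ValueError):
    """The request names a photoreceptor the device cannot control."""


@dataclass(frozen=True)
class ContrastRequest:
    """Desired photoreceptor contrasts over the controlled set.

    Values are signed Michelson contrast fractions in [−1, 1]; negative
    values mean counterphase modulation.  Silenced classes are exactly 0.
    """

    desired: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.desired.items():
            if abs(value) > 1:
                raise ValueError(
                    f"desired contrast for {name} is {value}; |contrast| must be <= 1"
                )

    def vector(self, controlled: tuple[str, ...]) -> np.ndarray:
        extra = set(self.desired) - set(controlled)
        if extra:
            n = len(controlled)
            raise UncontrolledPhotoreceptorError(
                f"request names photoreceptor(s) {sorted(extra)} that a {n}-primary "
                f"device cannot control; {n} primaries control exactly "
                f"{', '.join(controlled)} (3 primaries: L,M,S; 4: +rod; 5: +mel)"
            )
        missing = set(controlled) - set(self.desired)
        if missing:
            raise ValueError(
                f"request must cover the whole controlled set; missing {sorted(missing)}"
            )
        return np.array([self.desired[p] for p in controlled], dtype=float)


def solve_contrasts(amatrix: AMatrix, request: ContrastRequest) -> np.ndarray:
    """Invert the controlled block: returns ``c = W⁻¹·C`` per primary.

    The forward product ``W·c`` is checked to reproduce the request to
    1e-10; a failure indicates a numerically unusable matrix.
    """
    target = request.vector(amatrix.controlled)
    w = amatrix.controlled_block
    try:
        c = np.linalg.solve(w, target)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"controlled A-matrix block is singular: {exc}") from exc
    residual = np.max(np.abs(w @ c - target))
    if residual > _FORWARD_TOL:
        raise ValueError(
            f"solve did not reproduce the requested contrasts (residual {residual:.3g})"
        )
    return c


def maximize(c: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale so the largest primary contrast magnitude is exactly 1.

    Returns the scaled vector and the factor applied.  All photoreceptor
    contrasts scale by the same factor (linearity of the contrast relation),
    so silenced classes stay silent.
    """
    c = np.asarray(c, dtype=float)
    peak = np.max(np.abs(c))
    if peak == 0:
        raise ValueError("cannot maximize an all-zero contrast vector")
    return c / peak, 1.0 / peak


@dataclass(frozen=True)
class StimulusSolution:
    """Per-primary modulation settings and their technical feasibility.

    ``min_luminance``/``max_luminance`` are the luminance envelope
    ``L_j·(1 ∓ |c_j|)`` reached over a modulation cycle (phase-independent
    by using |c_j|).  A primary is feasible iff |c_j| ≤ 1 and the envelope
    stays inside its configured luminance range.
    """

    primary_names: tuple[str, ...]
    primary_contrasts: np.ndarray
    scale_applied: float
    min_luminance: np.ndarray
    max_luminance: np.ndarray
    feasible_primary: tuple[bool, ...]
    feasible: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        """Result table in the fixed export schema (contrasts in percent)."""
        return pd.DataFrame(
            {
                "primary": list(self.primary_names),
                "Contrast (%)": [100.0 * v for v in self.primary_contrasts],
                "MinLuminance (cd/m^2)": list(self.min_luminance),
                "MaxLuminance (cd/m^2)": list(self.max_luminance),
                "feasible": list(self.feasible_primary),
            }
        )


def check_feasibility(
    c: np.ndarray,
    device: Device,
    resolution_warn_threshold: float = RESOLUTION_WARN_THRESHOLD,
    scale_applied: float = 1.0,
) -> StimulusSolution:
    """Evaluate the luminance envelope and flag technically infeasible primaries.

    Feasibility is reported, never raised: contrasts above 100% or envelopes
    leaving the configured luminance range mark the primary (and the overall
    solution) infeasible.  Nonzero contrasts below
    ``resolution_warn_threshold`` produce advisory warnings only.
    """
    c = np.asarray(c, dtype=float)
    if len(c) != device.n_primaries:
        raise ValueError(
            f"contrast vector has {len(c)} entries for {device.n_primaries} primaries"
        )
    means = device.mean_luminances
    amp = np.abs(c)
    min_lum = means * (1.0 - amp)
    max_lum = means * (1.0 + amp)
    flags: list[bool] = []
    warnings: list[str] = []
    for j, primary in enumerate(device.primaries):
        lo, hi = primary.lum_range
        ok = amp[j] <= 1.0 and min_lum[j] >= lo and max_lum[j] <= hi
        flags.append(bool(ok))
        if amp[j] > 1.0:
            warnings.append(
                f"{primary.name}: contrast {100 * c[j]:.1f}% exceeds 100% and is "
                "technically not feasible; consider rescaling (maximize)"
            )
        elif not ok:
            warnings.append(
                f"{primary.name}: luminance envelope [{min_lum[j]:.2f}, "
                f"{max_lum[j]:.2f}] cd/m^2 leaves the configured range [{lo}, {hi}]"
            )
        if 0 < amp[j] < resolution_warn_threshold:
            warnings.append(
                f"{primary.name}: contrast {100 * c[j]:.3f}% is very small and may be "
                "below the device's luminance resolution"
            )
    return StimulusSolution(
        primary_names=device.names,
        primary_contrasts=c,
        scale_applied=scale_applied,
        min_luminance=min_lum,
        max_luminance=max_lum,
        feasible_primary=tuple(flags),
        feasible=all(flags),
        warnings=tuple(warnings),
    )


def waveform(
    device: Device,
    c: np.ndarray,
    frequency: float,
    n_samples: int,
    duration: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal per-primary luminance time series.

    Returns ``(t, L)`` with ``L[j, i] = L_j·(1 + c_j·sin(2π·f·t_i))``;
    phase 0 at t = 0, so negative contrasts modulate in exact counterphase.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")
    if n_samples < 2:
        raise ValueError(f"need at least 2 samples, got {n_samples}")
    c = np.asarray(c, dtype=float)
    t = np.linspace(0.0, duration, n_samples)
    means = device.mean_luminances
    lum = means[:, None] * (1.0 + c[:, None] * np.sin(2.0 * np.pi * frequency * t)[None, :])
    return t, lum
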