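"""Forward evaluation of achieved photoreceptor contrasts for a solved stimulus.

A solved stimulus fixes the per-primary contrasts.  What each photoreceptor
class actually experiences — including the classes the device could not
control, and under an individually modified observer — is the forward
product ``C′ = W′·c`` of the full five-row normalized excitation matrix
with the primary-contrast vector.  The per-primary terms ``w′[p][j]·c_j``
("contributions") show how modulation in each primary adds to or cancels
against the others; in a silent substitution the contributions in a
silenced row are individually nonzero but sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import Device, build_a_matrix, controlled_set
from .observer import PHOTORECEPTORS, Observer

__all__ = ["ValidationReport", "achieved_contrasts", "contribution_matrix"]


@dataclass(frozen=True)
class ValidationReport:
    """Achieved contrasts of all five photoreceptor classes.

    ``achieved[p]`` is the signed Michelson contrast of class *p*'s
    excitation modulation (sign preserved so counterphase intrusion is
    visible).  ``contribution[p][j] = w′[p][j]·c_j``; each row sums to the
    achieved contrast.  ``uncontrolled`` names the classes the device could
    not silence, whose values here are intrusions, not requests.
    """

    achieved: dict[str, float]
    observer_params: dict[str, float]
    contribution: np.ndarray
    photoreceptors: tuple[str, ...]
    primaries: tuple[str, ...]
    controlled: tuple[str, ...]

    @property
    def uncontrolled(self) -> tuple[str, ...]:
        return tuple(p for p in self.photoreceptors if p not in self.controlled)

    def to_frame(self) -> pd.DataFrame:
        """Report table: achieved contrast (%) per class, controlled flag."""
        return pd.DataFrame(
            {
                "photoreceptor": list(self.photoreceptors),
                "Contrast (%)": [100.0 * self.achieved[p] for p in self.photoreceptors],
                "controlled": [p in self.controlled for p in self.photoreceptors],
            }
        )

    def contribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contribution, index=list(self.photoreceptors), columns=list(self.primaries)
        )


def contribution_matrix(device: Device, c: np.ndarray, observer: Observer) -> np.ndarray:
    """Per-primary excitation-modulation contributions ``w′[p][j]·c_j`` (5×n)."""
    c = np.asarray(c, dtype=float)
    matrix = build_a_matrix(device, observer)
    return matrix.normalized * c[None, :]


def achieved_contrasts(device: Device, c: np.ndarray, observer: Observer) -> ValidationReport:
    """Forward-evaluate a primary contrast vector against a (modified) observer.

    With the unmodified standard observer, the achieved contrasts over the
    controlled set equal the solver's request; with modified fundamentals,
    or over the uncontrolled classes of a 3- or 4-primary device, the
    residuals quantify how imperfectly the stimulus isolates its target.
    """
    c = np.asarray(c, dtype=float)
    if len(c) != device.n_primaries:
        raise ValueError(
            f"contrast vector has {len(c)} entries for {device.n_primaries} primaries"
        )
    if np.any(np.abs(c) > 1.0 + 1e-12):
        raise ValueError("primary contrasts must satisfy |c_j| <= 1 for validation")
    contribution = contribution_matrix(device, c, observer)
    achieved = contribution.sum(axis=1)
    return ValidationReport(
        achieved={p: float(v) for p, v in zip(PHOTORECEPTORS, achieved)},
        observer_params=observer.params,
        contribution=contribution,
        photoreceptors=PHOTORECEPTORS,
        primaries=device.names,
        controlled=controlled_set(device.n_primaries),
    )
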