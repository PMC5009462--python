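"""Electron-dose calculus for raster exposure.

Converts instrument-level exposure settings (beam voltage, beam current,
pixel dwell time, point pitch, number of passes) into the quantities every
dose-response analysis is plotted against: the areal electron dose in C/m²
and the beam current density in pA/nm².

Conventions
-----------
* The point pitch follows the overlap convention ``PP = d · (1 − overlap)``,
  so a 50 % beam overlap means the pitch is half the beam diameter.
* The areal dose assumes square pixel tiling: the charge delivered per
  exposure point, ``I · DT · N``, is spread over one pitch cell ``PP²``.
* The current density is the mean density over the nominal beam disc
  (top-hat profile of the stated diameter) — an approximation, since the
  true beam profile is instrument specific.

User-facing units are the instrument's (keV, pA, ns, nm); conversions to SI
happen internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeamSettings",
    "point_pitch_from_overlap",
    "areal_dose",
    "current_density",
    "dose_matrix",
]

#: C per pA·ns: 1 pA · 1 ns = 1e-12 A · 1e-9 s
_COULOMB_PER_PA_NS = 1e-21
#: m² per nm²
_M2_PER_NM2 = 1e-18


class BeamConfigError(ValueError):
    """Raised when exposure settings are missing or inconsistent."""


def point_pitch_from_overlap(beam_diameter_nm: float, overlap_fraction: float) -> float:
    """Point pitch (nm) for a given beam diameter and beam-overlap fraction.

    ``PP = d · (1 − overlap)``; 50 % overlap gives ``PP = d/2``.
    """
    if beam_diameter_nm <= 0:
        raise BeamConfigError(f"beam diameter must be > 0, got {beam_diameter_nm}")
    if not 0.0 <= overlap_fraction < 1.0:
        raise BeamConfigError(
            f"overlap fraction must be in [0, 1), got {overlap_fraction}"
        )
    return beam_diameter_nm * (1.0 - overlap_fraction)


@dataclass(frozen=True)
class BeamSettings:
    """One exposure condition of the patterning engine.

    Parameters
    ----------
    beam_energy_keV : primary electron energy (> 0).
    beam_current_pA : beam current (> 0).
    dwell_time_ns : pixel dwell time (> 0).
    n_passes : number of raster passes (frames), integer ≥ 1.
    beam_diameter_nm : nominal beam diameter; optional, required for the
        current density and for deriving the pitch from the overlap.
    point_pitch_nm : spacing of consecutive exposure points; optional,
        derived from ``beam_diameter_nm`` and ``overlap_fraction`` when
        absent.
    overlap_fraction : beam-overlap convention used to derive the pitch,
        default 0.5 (the 50 % overlap setting).
    """

    beam_energy_keV: float
    beam_current_pA: float
    dwell_time_ns: float
    n_passes: int = 1
    beam_diameter_nm: float | None = None
    point_pitch_nm: float | None = None
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("beam_energy_keV", "beam_current_pA", "dwell_time_ns"):
            value = getattr(self, name)
            if not value > 0:
                raise BeamConfigError(f"{name} must be > 0, got {value}")
        if int(self.n_passes) != self.n_passes or self.n_passes < 1:
            raise BeamConfigError(f"n_passes must be an integer >= 1, got {self.n_passes}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise BeamConfigError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        if self.beam_diameter_nm is not None and self.beam_diameter_nm <= 0:
            raise BeamConfigError("beam_diameter_nm must be > 0")
        if self.point_pitch_nm is not None and self.point_pitch_nm <= 0:
            raise BeamConfigError("point_pitch_nm must be > 0")
        if self.beam_diameter_nm is not None and self.point_pitch_nm is not None:
            implied = point_pitch_from_overlap(self.beam_diameter_nm, self.overlap_fraction)
            if abs(self.point_pitch_nm - implied) > 0.01 * implied:
                raise BeamConfigError(
                    f"point_pitch_nm={self.point_pitch_nm} inconsistent with "
                    f"diameter {self.beam_diameter_nm} at overlap "
                    f"{self.overlap_fraction} (implies {implied:.4g} nm)"
                )

    @property
    def pitch_nm(self) -> float:
        """Resolved point pitch in nm (explicit value or overlap-derived)."""
        if self.point_pitch_nm is not None:
            return self.point_pitch_nm
        if self.beam_diameter_nm is not None:
            return point_pitch_from_overlap(self.beam_diameter_nm, self.overlap_fraction)
        raise BeamConfigError(
            "point pitch unresolvable: provide point_pitch_nm or beam_diameter_nm"
        )

    def with_(self, **kwargs) -> "BeamSettings":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_config(cls, config: Mapping) -> "BeamSettings":
        """Build settings from a config mapping (YAML/JSON-style keys)."""
        known = {
            "beam_energy_keV",
            "beam_current_pA",
            "dwell_time_ns",
            "n_passes",
            "beam_diameter_nm",
            "point_pitch_nm",
            "overlap_fraction",
        }
        unknown = set(config) - known
        if unknown:
            raise BeamConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(config))


def areal_dose(settings: BeamSettings) -> float:
    """Areal electron dose in C/m² delivered by one exposure condition.

    ``D = I · DT · N / PP²`` — the charge per exposure point spread over one
    square pitch cell. Linear in current, dwell time and pass count;
    inverse-quadratic in the pitch.
    """
    pitch = settings.pitch_nm
    charge_C = (
        settings.beam_current_pA * settings.dwell_time_ns * settings.n_passes
    ) * _COULOMB_PER_PA_NS
    return charge_C / (pitch * pitch * _M2_PER_NM2)


def current_density(settings: BeamSettings) -> float:
    """Mean beam current density in pA/nm² over the nominal beam disc.

    ``J = I / (π (d/2)²)`` with the stated beam diameter ``d``; assumes a
    top-hat profile.
    """
    if settings.beam_diameter_nm is None:
        raise BeamConfigError("current density requires beam_diameter_nm")
    r = settings.beam_diameter_nm / 2.0
    return settings.beam_current_pA / (math.pi * r * r)


def dose_matrix(
    dwell_times_ns: Sequence[float],
    pass_counts: Sequence[int],
    base: BeamSettings,
) -> pd.DataFrame:
    """Grid of areal doses over dwell-time × pass-count combinations.

    Emulates the exposure design of a parameter-sweep matrix of fields:
    rows are dwell times (ns), columns are pass counts, values areal dose in
    C/m² computed with the base settings' current and pitch.
    """
    if len(dwell_times_ns) == 0 or len(pass_counts) == 0:
        raise BeamConfigError("dwell_times_ns and pass_counts must be non-empty")
    doses = np.empty((len(dwell_times_ns), len(pass_counts)))
    for i, dt in enumerate(dwell_times_ns):
        for j, n in enumerate(pass_counts):
            doses[i, j] = areal_dose(base.with_(dwell_time_ns=dt, n_passes=int(n)))
    return pd.DataFrame(
        doses,
        index=pd.Index(list(dwell_times_ns), name="dwell_time_ns"),
        columns=pd.Index(list(pass_counts), name="n_passes"),
    )
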