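"""Luminance-increment <-> attenuation-dB conversions.

Differential light sensitivity (DLS) is reported on an inverted log
("attenuation") scale::

    DLS_dB = 10 * log10(dL_max / dL_jnd)

where ``dL_jnd`` is the just-noticeable luminance increment over the
background and ``dL_max`` the brightest displayable pedestal.  Higher dB
means a dimmer increment sufficed, i.e. greater sensitivity.  Two scales
coexist: the gaze-perimeter scale (dL_max = 225 cd/m^2, 0-34 dB) and the
Humphrey Field Analyzer (HFA) scale (dL_max = 3183.1 cd/m^2).  HFA values
are rescaled by converting to linear units and re-expressing them on the
225 cd/m^2 scale; rescaled values that come out negative (increments too
intense for the screen) are rounded up to zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LuminanceConfig",
    "Scale",
    "SensitivityDb",
    "dls_from_increment",
    "increment_from_db",
    "increment_from_hfa_db",
    "hfa_to_screen_db",
    "cdm2_from_asb",
]

#: apostilb -> cd/m^2 (1 asb = 1/pi cd/m^2); test helper only.
CDM2_PER_ASB = 1.0 / math.pi


def cdm2_from_asb(asb: float) -> float:
    """Convert apostilb to cd/m^2 (test/interop helper)."""
    return asb * CDM2_PER_ASB


class Scale(str, enum.Enum):
    SCREEN = "screen"
    HFA = "hfa"


@dataclass(frozen=True)
class LuminanceConfig:
    """Fixed photometric constants of the two devices.

    Attributes
    ----------
    background_cd_m2:
        Background luminance L_B, cd/m^2 (fixed at 10).
    max_increment_cd_m2:
        Brightest displayable pedestal dL_max on the screen, cd/m^2.
    hfa_max_increment_cd_m2:
        Brightest displayable pedestal dL'_max of the HFA, cd/m^2.
    db_domain_max:
        Upper end of the integer dB test domain.
    """

    background_cd_m2: float = 10.0
    max_increment_cd_m2: float = 225.0
    hfa_max_increment_cd_m2: float = 3183.1
    db_domain_max: float = 34.0

    def __post_init__(self) -> None:
        if self.background_cd_m2 <= 0:
            raise ValueError("background luminance must be positive")
        if self.max_increment_cd_m2 <= 0 or self.hfa_max_increment_cd_m2 <= 0:
            raise ValueError("maximum increments must be positive")
        if self.db_domain_max < 0:
            raise ValueError("db_domain_max must be >= 0")

    def target_luminance(self, delta_l: float) -> float:
        """Target luminance L_targ = L_B + dL for an increment dL."""
        return self.background_cd_m2 + delta_l


@dataclass(frozen=True)
class SensitivityDb:
    """A sensitivity value in dB of attenuation, tagged with its scale."""

    value: float
    scale: Scale = Scale.SCREEN

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("sensitivity must be finite")


def dls_from_increment(delta_l_jnd, config: LuminanceConfig = LuminanceConfig()):
    """Raw attenuation dB for a just-noticeable increment (no clamping).

    ``10 * log10(dL_max / dL_jnd)``.  Accepts scalars or arrays.
    """
    delta_l_jnd = np.asarray(delta_l_jnd, dtype=float)
    if np.any(delta_l_jnd <= 0):
        raise ValueError("luminance increment must be positive")
    out = 10.0 * np.log10(config.max_increment_cd_m2 / delta_l_jnd)
    return float(out) if out.ndim == 0 else out


def increment_from_db(dls_db, config: LuminanceConfig = LuminanceConfig()):
    """Inverse of :func:`dls_from_increment`: dL = dL_max * 10**(-dB/10)."""
    dls_db = np.asarray(dls_db, dtype=float)
    out = config.max_increment_cd_m2 * 10.0 ** (-dls_db / 10.0)
    return float(out) if out.ndim == 0 else out


def increment_from_hfa_db(dls_hfa_db, config: LuminanceConfig = LuminanceConfig()):
    """Linear increment (cd/m^2) for a raw HFA dB value.

    ``dL' = dL'_max * 10**(-dB'/10)``; negative HFA dB is a domain error.
    """
    dls_hfa_db = np.asarray(dls_hfa_db, dtype=float)
    if np.any(dls_hfa_db < 0):
        raise ValueError("HFA dB values must be non-negative")
    out = config.hfa_max_increment_cd_m2 * 10.0 ** (-dls_hfa_db / 10.0)
    return float(out) if out.ndim == 0 else out


def hfa_to_screen_db(dls_hfa_db, config: LuminanceConfig = LuminanceConfig()):
    """Rescale raw HFA dB onto the screen's 0-34 dB attenuation scale.

    Converts to linear units, re-expresses them against the screen's
    dL_max, then rounds negative results up to 0 (and caps at the dB-domain
    maximum, which is inert for physiological HFA values).
    """
    raw = dls_from_increment(increment_from_hfa_db(dls_hfa_db, config), config)
    out = np.clip(raw, 0.0, config.db_domain_max)
    return float(out) if np.ndim(out) == 0 else out
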