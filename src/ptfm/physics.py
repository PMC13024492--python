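"""Frequency-mass relations for piezoelectric thin-film microbalances.

A resonant microbalance converts adsorbed mass into a downward shift of its
resonant frequency.  For a rigid, thin, uniformly distributed load the shift
follows the Sauerbrey relation

    dF = -2 f0^2 dm / (A sqrt(rho_q * mu_q)),

with f0 the unloaded fundamental frequency (Hz), A the piezoelectrically
active area (cm^2), rho_q and mu_q the substrate density (g/cm^3) and shear
modulus (g cm^-1 s^-2), and dm the adsorbed mass (g).  For a polymer film
resonator (e.g. PVDF) in thickness-extensional mode the analogous small-load
relation in terms of areal mass loading dmA (g/cm^2) is

    dF = -f0 * dmA / (2 rho t),

valid while dmA is much smaller than the film's areal mass density rho*t.

All internal computation is CGS (g, cm, s, Hz); the public mass interfaces
use micrograms and the geometry interfaces millimetres/micrometres where
those are the practical bench units.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

from .errors import ConfigurationError, DomainError, ValidityWarning

__all__ = [
    "ResonatorSpec",
    "MassLoad",
    "SensitivityResult",
    "sauerbrey_shift",
    "theoretical_sensitivity",
    "empirical_sensitivity",
    "film_shift",
    "quality_factor",
    "bandwidth_from_q",
    "invert_mass",
    "UG_PER_G",
]

UG_PER_G = 1e6

#: Fraction of the film areal mass density (rho*t) beyond which the
#: small-load assumption of the film-shift relation is flagged.
THIN_LOAD_FRACTION = 0.1

_REL_TOL = 1e-6


@dataclass(frozen=True)
class ResonatorSpec:
    """Physical description of the resonant sensing element.

    Parameters
    ----------
    f0_hz:
        Unloaded fundamental resonant frequency, Hz.
    q:
        Quality factor (dimensionless); redundant with ``bandwidth_hz``.
    area_cm2:
        Piezoelectrically active area, cm^2.  Derivable from ``diameter_mm``
        for a circular active region.
    diameter_mm:
        Active-region diameter, mm.
    rho_g_cm3:
        Film material density, g/cm^3 (film-shift relation).
    thickness_um:
        Film thickness, micrometres (film-shift relation).
    rho_q, mu_q:
        Substrate density (g/cm^3) and shear modulus (g cm^-1 s^-2) for the
        Sauerbrey relation.
    bandwidth_hz:
        Half-power bandwidth, Hz; derivable from ``q`` and vice versa.
    """

    f0_hz: float
    q: Optional[float] = None
    area_cm2: Optional[float] = None
    diameter_mm: Optional[float] = None
    rho_g_cm3: Optional[float] = None
    thickness_um: Optional[float] = None
    rho_q: Optional[float] = None
    mu_q: Optional[float] = None
    bandwidth_hz: Optional[float] = None

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ConfigurationError("f0_hz must be positive")
        for name in ("q", "area_cm2", "diameter_mm", "rho_g_cm3",
                     "thickness_um", "rho_q", "mu_q", "bandwidth_hz"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v!r}")
        if self.q is not None and self.bandwidth_hz is not None:
            q_from_bw = self.f0_hz / self.bandwidth_hz
            if abs(self.q - q_from_bw) / self.q >= _REL_TOL:
                raise ConfigurationError(
                    f"q={self.q} inconsistent with f0/bandwidth={q_from_bw:.6g}")
        if self.area_cm2 is not None and self.diameter_mm is not None:
            a_from_d = math.pi * (self.diameter_mm / 20.0) ** 2
            if abs(self.area_cm2 - a_from_d) / self.area_cm2 >= _REL_TOL:
                raise ConfigurationError(
                    f"area_cm2={self.area_cm2} inconsistent with diameter_mm "
                    f"(pi*(d/20)^2 = {a_from_d:.6g})")

    # -- derived geometry ---------------------------------------------------

    @property
    def area(self) -> float:
        """Active area in cm^2, derived from the diameter when not given."""
        if self.area_cm2 is not None:
            return self.area_cm2
        if self.diameter_mm is not None:
            return math.pi * (self.diameter_mm / 20.0) ** 2
        raise ConfigurationError("neither area_cm2 nor diameter_mm is set")

    @property
    def thickness_cm(self) -> float:
        if self.thickness_um is None:
            raise ConfigurationError("thickness_um is not set")
        return self.thickness_um * 1e-4

    @property
    def quality(self) -> float:
        """Quality factor, derived from the bandwidth when not given."""
        if self.q is not None:
            return self.q
        if self.bandwidth_hz is not None:
            return self.f0_hz / self.bandwidth_hz
        raise ConfigurationError("neither q nor bandwidth_hz is set")

    @property
    def half_power_bandwidth(self) -> float:
        """Half-power (-3 dB) bandwidth in Hz, f0/Q when not given."""
        if self.bandwidth_hz is not None:
            return self.bandwidth_hz
        if self.q is not None:
            return self.f0_hz / self.q
        raise ConfigurationError("neither q nor bandwidth_hz is set")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in asdict(self).items() if v is not None},
                          indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ResonatorSpec":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class MassLoad:
    """An adsorbed mass, as total micrograms and/or areal loading in g/cm^2."""

    delta_m_ug: Optional[float] = None
    delta_mA: Optional[float] = None

    def __post_init__(self):
        if self.delta_m_ug is None and self.delta_mA is None:
            raise ConfigurationError("MassLoad needs delta_m_ug or delta_mA")
        if self.delta_m_ug is not None and self.delta_m_ug < 0:
            raise DomainError("delta_m_ug must be nonnegative")
        if self.delta_mA is not None and self.delta_mA < 0:
            raise DomainError("delta_mA must be nonnegative")

    def total_ug(self, area_cm2: float) -> float:
        if self.delta_m_ug is not None:
            return self.delta_m_ug
        return self.delta_mA * area_cm2 * UG_PER_G

    def areal_g_cm2(self, area_cm2: float) -> float:
        if self.delta_mA is not None:
            return self.delta_mA
        return self.delta_m_ug / UG_PER_G / area_cm2


@dataclass(frozen=True)
class SensitivityResult:
    """A mass sensitivity with its unit recorded explicitly."""

    value: float
    units: str  # "Hz/ug" or "Hz/(g/cm^2)"


def _as_load(load) -> MassLoad:
    if isinstance(load, MassLoad):
        return load
    return MassLoad(delta_m_ug=float(load))


def sauerbrey_shift(spec: ResonatorSpec, load) -> float:
    """Sauerbrey frequency shift (Hz, <= 0) for a total mass load.

    ``load`` is a :class:`MassLoad` or a plain mass in micrograms.
    Requires ``rho_q`` and ``mu_q`` (substrate constants) plus the area.
    """
    load = _as_load(load)
    if spec.rho_q is None or spec.mu_q is None:
        raise ConfigurationError("sauerbrey_shift needs rho_q and mu_q")
    area = spec.area
    dm_g = load.total_ug(area) / UG_PER_G
    return -2.0 * spec.f0_hz ** 2 * dm_g / (area * math.sqrt(spec.rho_q * spec.mu_q))


def theoretical_sensitivity(spec: ResonatorSpec, per: str = "ug") -> SensitivityResult:
    """Theoretical mass sensitivity S_M = 2 f0^2 / (A sqrt(rho_q mu_q)).

    ``per="ug"`` returns Hz per microgram of total load (the bench unit);
    ``per="areal"`` returns Hz per g/cm^2 of areal loading.
    """
    if spec.rho_q is None or spec.mu_q is None:
        raise ConfigurationError("theoretical_sensitivity needs rho_q and mu_q")
    area = spec.area
    s_areal = 2.0 * spec.f0_hz ** 2 / math.sqrt(spec.rho_q * spec.mu_q)
    if per == "areal":
        return SensitivityResult(s_areal, "Hz/(g/cm^2)")
    if per == "ug":
        return SensitivityResult(s_areal / area / UG_PER_G, "Hz/ug")
    raise ConfigurationError(f"unknown sensitivity unit {per!r}")


def empirical_sensitivity(delta_f_hz: float, delta_m_ug: float) -> SensitivityResult:
    """Empirical sensitivity S_m = -dF/dm from one measured (shift, mass) pair."""
    if delta_m_ug == 0:
        raise DomainError("empirical sensitivity undefined for delta_m = 0")
    return SensitivityResult(-delta_f_hz / delta_m_ug, "Hz/ug")


def film_shift(spec: ResonatorSpec, load) -> float:
    """Thin-film frequency shift dF = -f0 dmA / (2 rho t), Hz.

    ``load`` is a :class:`MassLoad` or a plain areal loading in g/cm^2.
    Warns when the load exceeds 10% of the film areal mass density rho*t,
    where the small-load linearization starts to strain.
    """
    if isinstance(load, MassLoad):
        dmA = load.areal_g_cm2(spec.area) if load.delta_mA is None else load.delta_mA
    else:
        dmA = float(load)
        if dmA < 0:
            raise DomainError("areal loading must be nonnegative")
    if spec.rho_g_cm3 is None or spec.thickness_um is None:
        raise ConfigurationError("film_shift needs rho_g_cm3 and thickness_um")
    rho_t = spec.rho_g_cm3 * spec.thickness_cm
    if rho_t == 0:
        raise ConfigurationError("rho*t must be nonzero")
    if dmA >= THIN_LOAD_FRACTION * rho_t:
        warnings.warn(
            f"areal loading {dmA:.3g} g/cm^2 is not small against rho*t = "
            f"{rho_t:.3g} g/cm^2; the linear small-load relation is strained",
            ValidityWarning, stacklevel=2)
    return -spec.f0_hz * dmA / (2.0 * rho_t)


def quality_factor(f0_hz: float, bandwidth_hz: float) -> float:
    """Q = f0 / half-power bandwidth."""
    if f0_hz <= 0 or bandwidth_hz <= 0:
        raise DomainError("f0 and bandwidth must be positive")
    return f0_hz / bandwidth_hz


def bandwidth_from_q(f0_hz: float, q: float) -> float:
    """Half-power bandwidth f0 / Q; inverse of :func:`quality_factor`."""
    if f0_hz <= 0 or q <= 0:
        raise DomainError("f0 and Q must be positive")
    return f0_hz / q


def invert_mass(delta_f_hz: float, sensitivity) -> float:
    """Recover the mass (micrograms) from a shift and a known sensitivity.

    ``sensitivity`` is an S_m value in Hz/ug (or a :class:`SensitivityResult`).
    """
    s = sensitivity.value if isinstance(sensitivity, SensitivityResult) else float(sensitivity)
    if s <= 0:
        raise DomainError("sensitivity must be positive")
    return -delta_f_hz / s
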