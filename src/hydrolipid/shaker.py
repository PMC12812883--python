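"""Closed-form hydrodynamic forcing and protocol constants.

Orbital shakers impose a swirling flow on small culture tubes; the mean
turbulent energy dissipation rate per unit fluid mass, ε (W kg⁻¹), is the
standard scalar summary of that forcing and is computed here from the
empirical shake-flask correlation

    ε = 1.94 · n³ D⁴ / V_f^(2/3) · Re^(−0.2),   Re = ρ_f n D² / μ_f

with n the platform rotational speed (s⁻¹), D the vessel inner diameter
(m), V_f the working volume (m³), and ρ_f, μ_f the fluid density and
dynamic viscosity.  The Reynolds correction enters with a negative
exponent — a physically decreasing correction for increasingly turbulent
flow.

The module also holds the small protocol calculators that accompany the
culturing workflow: millifluidic chamber volume, dye dilution, and the
irradiance → photon-flux conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from scipy import constants as _const

__all__ = [
    "ShakerSystem",
    "ChamberGeometry",
    "StainingMix",
    "LightSource",
    "energy_dissipation",
    "photon_flux",
    "final_concentration",
    "chamber_volume",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ShakerSystem:
    """Geometry and fluid parameters of an orbital-shaker culture tube.

    Parameters are SI throughout; ``n`` may be given in rpm via the
    explicit ``n_unit`` tag (silent unit guessing is the most likely bug
    for this correlation, so the unit must be stated).

    Parameters
    ----------
    n : float
        Platform rotational speed, in the unit named by ``n_unit``.
    D : float
        Tube inner diameter, m.
    V_f : float
        Working liquid volume, m³.
    rho_f : float
        Fluid density, kg m⁻³.
    mu_f : float
        Dynamic viscosity, Pa s.
    d_o : float, optional
        Shaker orbit diameter, m (recorded but not used by the
        correlation).
    H : float, optional
        Liquid column height, m.
    n_unit : {"per_s", "rpm"}
        Unit of ``n``.
    """

    n: float
    D: float
    V_f: float
    rho_f: float
    mu_f: float
    d_o: float | None = None
    H: float | None = None
    n_unit: str = "per_s"

    def __post_init__(self) -> None:
        if self.n_unit not in ("per_s", "rpm"):
            raise ValueError(f"n_unit must be 'per_s' or 'rpm', got {self.n_unit!r}")
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n!r}")
        _require_positive(D=self.D, V_f=self.V_f, rho_f=self.rho_f, mu_f=self.mu_f)
        for name in ("d_o", "H"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive if given")

    @property
    def n_per_s(self) -> float:
        """Rotational speed in s⁻¹ regardless of the entry unit."""
        return self.n / 60.0 if self.n_unit == "rpm" else self.n

    @property
    def reynolds(self) -> float:
        """Rotational Reynolds number ρ_f n D² / μ_f."""
        return self.rho_f * self.n_per_s * self.D**2 / self.mu_f


@dataclass(frozen=True)
class ChamberGeometry:
    """Millifluidic counting-chamber dimensions (mm); volume in µL.

    1 mm³ ≡ 1 µL, so the volume is the plain product of the dimensions.
    """

    length_mm: float
    width_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        _require_positive(
            length_mm=self.length_mm, width_mm=self.width_mm, depth_mm=self.depth_mm
        )

    @property
    def volume_ul(self) -> float:
        return self.length_mm * self.width_mm * self.depth_mm


@dataclass(frozen=True)
class StainingMix:
    """A dye aliquot diluted into one or more added volumes."""

    dye_volume_ul: float
    dye_stock_uM: float
    added_volumes_ul: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _require_positive(dye_volume_ul=self.dye_volume_ul, dye_stock_uM=self.dye_stock_uM)
        for v in self.added_volumes_ul:
            _require_positive(added_volume_ul=v)


@dataclass(frozen=True)
class LightSource:
    """A monochromatic approximation of the incubator illumination."""

    irradiance_mw_cm2: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.irradiance_mw_cm2 < 0:
            raise ValueError("irradiance_mw_cm2 must be non-negative")
        _require_positive(wavelength_nm=self.wavelength_nm)


def energy_dissipation(sys: ShakerSystem) -> float:
    """Mean energy dissipation rate ε (W kg⁻¹) of the orbital-shaken tube.

    Evaluates ε = 1.94 n³ D⁴ / V_f^(2/3) · Re^(−0.2).  Returns 0 for a
    stationary platform (n = 0).

    Examples
    --------
    >>> sys = ShakerSystem(n=110, D=0.023, V_f=27e-6, rho_f=1025,
    ...                    mu_f=1.1e-3, n_unit="rpm")
    >>> round(energy_dissipation(sys) * 1e4, 2)
    9.53
    """
    n = sys.n_per_s
    if n == 0:
        return 0.0
    return 1.94 * n**3 * sys.D**4 / sys.V_f ** (2.0 / 3.0) * sys.reynolds ** (-0.2)


def photon_flux(src: LightSource) -> float:
    """Convert irradiance to photon flux, µmol photons m⁻² s⁻¹.

    Treats the source as monochromatic:  flux = I·λ/(N_A·h·c) · 10⁶ with
    I in W m⁻².
    """
    irradiance_w_m2 = src.irradiance_mw_cm2 * 10.0  # mW cm⁻² → W m⁻²
    wavelength_m = src.wavelength_nm * 1e-9
    per_photon_j = _const.h * _const.c / wavelength_m
    return irradiance_w_m2 / per_photon_j / _const.N_A * 1e6


def final_concentration(mix: StainingMix) -> float:
    """Final dye concentration (µM) after dilution into the added volumes."""
    if len(mix.added_volumes_ul) == 0:
        warnings.warn(
            "no added volumes: final concentration equals the stock concentration",
            stacklevel=2,
        )
        return mix.dye_stock_uM
    total = mix.dye_volume_ul + math.fsum(mix.added_volumes_ul)
    return mix.dye_stock_uM * mix.dye_volume_ul / total


def chamber_volume(geom: ChamberGeometry) -> float:
    """Chamber volume in µL (product of the mm dimensions)."""
    return geom.volume_ul
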