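"""Closed-form dielectric-mixture model for parallel-plate grain moisture sensing.

A parallel-plate capacitor whose detection volume is filled with a packed bed
of grain reads out the effective relative permittivity of the bed.  That
permittivity is the volume-weighted mixture of three phases -- dry cereal
matter (relative permittivity ~3), water (~81) and inter-grain air (~1) -- so
plate capacitance rises steeply with the water fraction and can be used as a
moisture transducer.

Writing ``w`` for the wet-basis moisture mass fraction (mass of water over
total grain mass) and eliminating the phase volumes, the mixture law collapses
to a three-parameter rational form

    C(w) = A / (w/(1-w) + B) + D + F

where ``A, B, D, F`` are structural constants fixed by the sensor geometry
(plate area ``S``, spacing ``d``, pore ratio ``e``) and the material constants
(densities and permittivities of water and dry cereal).  ``A`` is negative
whenever water is more polarizable than the dry matter, which makes ``C``
strictly increasing in ``w`` and therefore invertible in closed form:

    G = A / (C - D - F) - B,      w = G / (1 + G)

Both directions are exact; no fitting is involved.  A separate empirical
straight-line calibration (:func:`linear_calibration`) maps moisture percent
to sensor-scale capacitance (pF) under fixed reference conditions (22 degC,
volume duty cycle 1/3); the physical farad-scale model and the sensor-scale
calibration are never mixed within one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VACUUM_PERMITTIVITY",
    "CALIBRATION_SLOPE_PF_PER_PERCENT",
    "CALIBRATION_INTERCEPT_PF",
    "SensorGeometry",
    "MaterialConstants",
    "StructuralConstants",
    "MoistureFraction",
    "structural_constants",
    "capacitance_from_moisture",
    "moisture_from_capacitance",
    "capacitance_bounds",
    "linear_calibration",
]

VACUUM_PERMITTIVITY = 8.854187818e-12
"""Vacuum permittivity epsilon_0 in F/m."""

#: Empirical sensor-scale calibration C = slope * W% + intercept, valid only at
#: 22 degC ambient temperature and volume duty cycle 1/3.
CALIBRATION_SLOPE_PF_PER_PERCENT = 0.30744
CALIBRATION_INTERCEPT_PF = 17.28085


@dataclass(frozen=True)
class SensorGeometry:
    """Geometry of the parallel-plate detection cell.

    Parameters
    ----------
    plate_area : float
        Relative plate area ``S`` in m^2.  Default is the 150 mm x 100 mm
        detection plate (0.015 m^2).
    plate_spacing : float
        Plate spacing ``d`` in m.  The physical sensor's spacing is not
        reported; 0.10 m is a configurable placeholder, not a calibrated
        value.
    pore_ratio : float
        Fraction ``e`` in [0, 1) of the detection volume occupied by
        inter-grain air.  Not reported for the physical sensor; 0.40 is a
        configurable placeholder typical of packed cereal beds.
    """

    plate_area: float = 0.015
    plate_spacing: float = 0.10
    pore_ratio: float = 0.40

    def __post_init__(self) -> None:
        if not self.plate_area > 0:
            raise ValueError(f"plate_area must be > 0, got {self.plate_area}")
        if not self.plate_spacing > 0:
            raise ValueError(f"plate_spacing must be > 0, got {self.plate_spacing}")
        if not 0 <= self.pore_ratio < 1:
            raise ValueError(f"pore_ratio must lie in [0, 1), got {self.pore_ratio}")


@dataclass(frozen=True)
class MaterialConstants:
    """Densities and relative permittivities of the three phases.

    Defaults are the reference values for dry foxtail millet, water and air:
    rho_cereal = 600 kg/m^3, rho_water = 1000 kg/m^3, eps_cereal = 3,
    eps_water = 81, eps_air = 1.00053.
    """

    eps0: float = VACUUM_PERMITTIVITY
    eps_cereal: float = 3.0
    eps_water: float = 81.0
    eps_air: float = 1.00053
    rho_cereal: float = 600.0
    rho_water: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("eps0", "eps_cereal", "eps_water", "eps_air", "rho_cereal", "rho_water"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.eps_water > self.eps_cereal:
            raise ValueError(
                f"eps_water ({self.eps_water}) must exceed eps_cereal ({self.eps_cereal})"
            )
        if not self.eps_cereal > self.eps_air:
            raise ValueError(
                f"eps_cereal ({self.eps_cereal}) must exceed eps_air ({self.eps_air})"
            )
        if not self.eps_air >= 1:
            raise ValueError(f"eps_air must be >= 1, got {self.eps_air}")


@dataclass(frozen=True)
class StructuralConstants:
    """The four structural constants of the rational capacitance-moisture law.

    ``A`` and ``D`` and ``F_const`` carry farads; ``B`` is dimensionless
    (the water/cereal density ratio).  ``F_const`` is the air-phase term,
    named to avoid colliding with the benchmark function names.
    """

    A: float
    B: float
    D: float
    F_const: float


@dataclass(frozen=True)
class MoistureFraction:
    """Wet-basis moisture mass fraction, stored as a fraction in [0, 1).

    File I/O renders moisture as percent; this container keeps the internal
    fractional convention explicit.
    """

    w: float

    def __post_init__(self) -> None:
        if not 0 <= self.w < 1:
            raise ValueError(f"moisture fraction must lie in [0, 1), got {self.w}")

    @property
    def percent(self) -> float:
        return 100.0 * self.w

    @classmethod
    def from_percent(cls, w_percent: float) -> "MoistureFraction":
        return cls(w_percent / 100.0)


def structural_constants(
    geometry: SensorGeometry = SensorGeometry(),
    materials: MaterialConstants = MaterialConstants(),
) -> StructuralConstants:
    """Compute the structural constants ``A, B, D, F`` of the sensor.

    With ``k = S * eps0 / d`` and solid fraction ``1 - e``:

    - ``A = k * rho_water * (1-e) * (eps_cereal - eps_water) / rho_cereal``
      (negative whenever water is the more polarizable phase),
    - ``B = rho_water / rho_cereal``,
    - ``D = k * (1-e) * eps_water``,
    - ``F = k * e * eps_air``.
    """
    k = geometry.plate_area * materials.eps0 / geometry.plate_spacing
    solid = 1.0 - geometry.pore_ratio
    a = k * materials.rho_water * solid * (materials.eps_cereal - materials.eps_water) / materials.rho_cereal
    b = materials.rho_water / materials.rho_cereal
    d = k * solid * materials.eps_water
    f = k * geometry.pore_ratio * materials.eps_air
    return StructuralConstants(A=a, B=b, D=d, F_const=f)


def capacitance_bounds(sc: StructuralConstants) -> tuple[float, float]:
    """Attainable capacitance interval ``(C_dry, C_saturated)`` in farads.

    ``C_dry = A/B + D + F`` is the w=0 (grain + air) limit and
    ``C_sat = D + F`` is the w->1 (water + air) limit; every physical
    moisture fraction maps into ``[C_dry, C_sat)``.
    """
    c_dry = sc.A / sc.B + sc.D + sc.F_const
    c_sat = sc.D + sc.F_const
    return c_dry, c_sat


def capacitance_from_moisture(w, sc: StructuralConstants):
    """Capacitance in farads for wet-basis moisture fraction(s) ``w``.

    Strictly increasing in ``w`` on [0, 1) because ``A < 0`` while the
    denominator ``w/(1-w) + B`` increases.  Accepts scalars or arrays.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any((w_arr < 0) | (w_arr >= 1)):
        raise ValueError("moisture fraction must lie in [0, 1)")
    c = sc.A / (w_arr / (1.0 - w_arr) + sc.B) + sc.D + sc.F_const
    return float(c) if np.isscalar(w) or w_arr.ndim == 0 else c


def moisture_from_capacitance(c, sc: StructuralConstants):
    """Exact inverse of :func:`capacitance_from_moisture`.

    ``G = A/(C - D - F) - B`` and ``w = G/(1+G)``.  ``c`` must lie in the
    attainable interval ``[C_dry, C_sat)``; the dry endpoint maps to w = 0.
    Accepts scalars or arrays.
    """
    c_arr = np.asarray(c, dtype=float)
    c_dry, c_sat = capacitance_bounds(sc)
    if np.any((c_arr < c_dry) | (c_arr >= c_sat)):
        raise ValueError(
            f"capacitance outside the attainable interval [{c_dry!r}, {c_sat!r}) F"
        )
    g = sc.A / (c_arr - sc.D - sc.F_const) - sc.B
    w = g / (1.0 + g)
    return float(w) if np.isscalar(c) or c_arr.ndim == 0 else w


def linear_calibration(w_percent):
    """Sensor-scale (pF) capacitance for moisture in percent.

    Empirical straight line ``C = 0.30744 * W + 17.28085`` fitted at 22 degC
    and volume duty cycle 1/3; it is only valid under those reference
    conditions.  Accepts scalars or arrays.
    """
    w_arr = np.asarray(w_percent, dtype=float)
    if np.any((w_arr < 0) | (w_arr > 100)):
        raise ValueError("moisture percent must lie in [0, 100]")
    c = CALIBRATION_SLOPE_PF_PER_PERCENT * w_arr + CALIBRATION_INTERCEPT_PF
    return float(c) if np.isscalar(w_percent) or w_arr.ndim == 0 else c
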