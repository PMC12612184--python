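"""Spherical-cap geometry and keratometric conversion for inflated chip wells.

A well of radius ``a`` whose membrane is inflated into a spherical cap is
described by the *chord angle* ``phi`` — the angle, measured at the rim,
between the flat baseline and the chord running from the rim to the dome
apex.  For a spherical cap this chord angle is exactly half of the cap
half-angle ``theta`` subtended at the sphere centre (``tan phi = h/a =
tan(theta/2)``), which fixes the whole geometry:

    theta = 2 * phi
    R     = a / sin(theta)          radius of curvature
    h     = R * (1 - cos(theta))    apex height (= a * tan(phi))
    V     = (pi*h/6) * (3*a**2 + h**2)   cap volume
    D     = 337.5 / R               keratometric optical power

The constant 337.5 D*mm is the standard keratometric calibration
``1000 * (n_k - 1)`` with keratometric refractive index ``n_k = 1.3375``;
it is what clinical keratometers use to report corneal power in diopters.

A flat well (``phi = 0``) is a valid degenerate geometry with infinite
radius of curvature and zero power, matching the flat control condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "KERATOMETRIC_CONSTANT",
    "DomeGeometry",
    "angle_to_geometry",
    "radius_to_diopters",
    "diopters_to_radius",
    "diopters_to_angle",
    "cap_volume",
    "round_display",
]

#: Keratometric calibration constant, D*mm: 1000 * (1.3375 - 1).
KERATOMETRIC_CONSTANT = 337.5

#: Chord angles above this would push the cap past a hemisphere.
MAX_CHORD_ANGLE_DEG = 45.0


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half-up for display (clinical keratometry prints e.g. 42.19)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DomeGeometry:
    """Complete spherical-cap state of one inflated well.

    Lengths in mm, angles in degrees, power in diopters, volume in µL
    (1 mm^3 = 1 µL).  ``radius_mm`` is ``inf`` and ``power_diopters`` 0
    for a flat well.
    """

    well_radius_mm: float
    chord_angle_deg: float
    half_angle_deg: float
    radius_mm: float
    apex_height_mm: float
    power_diopters: float
    cap_volume_ul: float

    @property
    def power_display(self) -> float:
        """Optical power rounded half-up to 2 decimals, as printed clinically."""
        return round_display(self.power_diopters, 2)


def _validate_well_radius(a: float) -> None:
    if not (a > 0):
        raise ValueError(f"well radius must be positive, got {a}")


def _validate_chord_angle(phi_deg: float) -> None:
    if not (0 <= phi_deg < MAX_CHORD_ANGLE_DEG):
        raise ValueError(
            f"chord angle must lie in [0, {MAX_CHORD_ANGLE_DEG}) degrees "
            f"(cap at most a hemisphere), got {phi_deg}"
        )


def angle_to_geometry(phi_deg: float, well_radius_mm: float = 4.0) -> DomeGeometry:
    """Convert a measured chord angle to the full dome geometry.

    Parameters
    ----------
    phi_deg : float
        Baseline-to-apex-chord angle in degrees, ``0 <= phi < 45``.
    well_radius_mm : float
        Radius ``a`` of the circular well, mm (default 4 mm).

    Returns
    -------
    DomeGeometry
    """
    _validate_well_radius(well_radius_mm)
    _validate_chord_angle(phi_deg)
    a = well_radius_mm
    theta_deg = 2.0 * phi_deg
    if phi_deg == 0:
        return DomeGeometry(a, 0.0, 0.0, math.inf, 0.0, 0.0, 0.0)
    theta = math.radians(theta_deg)
    radius = a / math.sin(theta)
    h = radius * (1.0 - math.cos(theta))
    power = KERATOMETRIC_CONSTANT / radius
    volume = (math.pi * h / 6.0) * (3.0 * a * a + h * h)
    return DomeGeometry(a, phi_deg, theta_deg, radius, h, power, volume)


def radius_to_diopters(radius_mm: float) -> float:
    """Keratometric power ``D = 337.5 / R`` for a radius of curvature in mm."""
    if not (radius_mm > 0):
        raise ValueError(f"radius of curvature must be positive, got {radius_mm}")
    return KERATOMETRIC_CONSTANT / radius_mm


def diopters_to_radius(power_d: float) -> float:
    """Inverse keratometric conversion, ``R = 337.5 / D`` (mm)."""
    if not (power_d > 0):
        raise ValueError(f"power must be positive, got {power_d}")
    return KERATOMETRIC_CONSTANT / power_d


def diopters_to_angle(power_d: float, well_radius_mm: float = 4.0) -> float:
    """Chord angle (deg) that produces a given keratometric power on a well.

    Inverse of :func:`angle_to_geometry`; the round trip recovers the power
    to better than 1e-9 relative.  ``power_d = 0`` maps to a flat well.
    """
    _validate_well_radius(well_radius_mm)
    if power_d == 0:
        return 0.0
    if power_d < 0:
        raise ValueError(f"power must be nonnegative, got {power_d}")
    # Cap at most a hemisphere: R >= a, i.e. D <= K/a.
    max_power = KERATOMETRIC_CONSTANT / well_radius_mm
    if power_d > max_power:
        raise ValueError(
            f"power {power_d} D exceeds the hemisphere limit "
            f"{max_power} D for a {well_radius_mm} mm well"
        )
    radius = KERATOMETRIC_CONSTANT / power_d
    theta = math.asin(well_radius_mm / radius)
    return math.degrees(theta) / 2.0


def cap_volume(phi_deg: float, well_radius_mm: float = 4.0) -> float:
    """Volume (µL) of the spherical cap displaced by an inflated well.

    ``V = (pi*h/6) * (3 a^2 + h^2)`` with ``h = a tan(phi)``; strictly
    increasing in ``phi`` at fixed ``a``.  Note that this is the per-well
    displaced volume only — the chip's injected syringe volume additionally
    includes manifold dead volume shared across wells, which must be
    calibrated empirically.
    """
    return angle_to_geometry(phi_deg, well_radius_mm).cap_volume_ul
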