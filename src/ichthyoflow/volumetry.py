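"""Closed-form volume models for larvae and eggs.

The larva body is modelled as a cylinder whose projected (lateral) area is
``A_L`` and whose length is the standard length ``L_L``; the implied diameter
is ``A_L / L_L`` and the volume

    V_L = (A_L^2 / L_L) * pi / 4 .

Yolk sac and eye are modelled as prolate spheroids from measured width ``W``
(equatorial diameter) and length ``L`` (polar diameter):

    V = (4/3) * pi * (W/2)^2 * (L/2) .

The structural volume is the body volume minus the yolk volume,
``V_S = V_L - V_Y``. Eggs are modelled as spheres of diameter
``D_E = (L_E + W_E) / 2``, the mean of the measured major and minor axes:

    V_E = (4/3) * pi * (D_E/2)^3 .
"""

from __future__ import annotations

import math
import warnings


def larva_total_volume(body_area_mm2: float, standard_length_mm: float) -> float:
    """Cylinder-model total body volume V_L in mm^3.

    Parameters
    ----------
    body_area_mm2 : float
        Projected body area A_L, mm^2. Must be positive.
    standard_length_mm : float
        Standard length L_L, mm. Must be positive.
    """
    if not (body_area_mm2 > 0):
        raise ValueError(f"body area must be positive, got {body_area_mm2!r}")
    if not (standard_length_mm > 0):
        raise ValueError(
            f"standard length must be positive, got {standard_length_mm!r}"
        )
    return math.pi * body_area_mm2 ** 2 / (4.0 * standard_length_mm)


def prolate_spheroid_volume(width_mm: float, length_mm: float) -> float:
    """Prolate-spheroid volume from width (minor) and length (major), mm^3.

    Used for both the yolk sac (V_Y) and the eye (V_E). If ``width > length``
    the two are swapped with a warning (minor axis must not exceed major).
    """
    if not (width_mm > 0 and length_mm > 0):
        raise ValueError("spheroid axes must be positive")
    if width_mm > length_mm:
        warnings.warn(
            "spheroid width exceeds length; swapping axes", stacklevel=2
        )
        width_mm, length_mm = length_mm, width_mm
    return (4.0 / 3.0) * math.pi * (width_mm / 2.0) ** 2 * (length_mm / 2.0)


def structural_volume(
    total_volume_mm3: float, yolk_volume_mm3: float
) -> tuple[float, bool]:
    """Structural volume V_S = V_L - V_Y, mm^3.

    Returns ``(value, suspect)``: a negative result is retained (it audits a
    segmentation fault) but flagged suspect rather than clipped.
    """
    if total_volume_mm3 < 0 or yolk_volume_mm3 < 0:
        raise ValueError("volumes must be non-negative")
    value = total_volume_mm3 - yolk_volume_mm3
    return value, value < 0


def egg_diameter(
    egg_major_mm: float,
    egg_minor_mm: float,
    eccentricity_warn_ratio: float = 0.95,
) -> tuple[float, float, bool]:
    """Mean egg diameter D_E and radius R_E from the measured axes.

    Returns ``(D_E, R_E, eccentric)`` where ``eccentric`` is True when
    ``minor/major`` falls below ``eccentricity_warn_ratio`` — cod eggs are
    nearly circular in projection, so a strongly elliptical fit suggests a
    bad segmentation.
    """
    if not (egg_major_mm > 0 and egg_minor_mm > 0):
        raise ValueError("egg axes must be positive")
    if egg_minor_mm > egg_major_mm:
        egg_major_mm, egg_minor_mm = egg_minor_mm, egg_major_mm
    d = (egg_major_mm + egg_minor_mm) / 2.0
    eccentric = (egg_minor_mm / egg_major_mm) < eccentricity_warn_ratio
    return d, d / 2.0, eccentric


def egg_volume(egg_diameter_mm: float) -> float:
    """Sphere-model egg volume V_E = (4/3) pi R_E^3, mm^3."""
    if not (egg_diameter_mm > 0):
        raise ValueError(f"egg diameter must be positive, got {egg_diameter_mm!r}")
    r = egg_diameter_mm / 2.0
    return (4.0 / 3.0) * math.pi * r ** 3
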