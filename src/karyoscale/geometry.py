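"""Volume conversions for cell and nucleus measurements.

Microscopy datasets report size in heterogeneous units: projected
cross-sectional area (μm²), diameter (μm), or length × width (μm) of an
elongated cell. All downstream analyses work on volumes (μm³), so these
helpers convert each reported unit to a volume under the shape assumption
appropriate to it: a sphere for area/diameter measurements, a prolate
spheroid for length × width pairs.

Inputs are μm-based and outputs are μm³; no other unit handling is done.
"""

from __future__ import annotations

import math

__all__ = [
    "volume_from_area",
    "volume_from_diameter",
    "prolate_spheroid_volume",
]


def volume_from_area(area: float) -> float:
    """Volume of the sphere whose great-circle cross-section has ``area``.

    Computes V = (4/3)·π·(√(A/π))³, i.e. the radius is recovered from the
    projected circular area and plugged into the sphere volume.

    Parameters
    ----------
    area : float
        Cross-sectional area in μm², strictly positive.

    Returns
    -------
    float
        Sphere volume in μm³.
    """
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    radius = math.sqrt(area / math.pi)
    return (4.0 / 3.0) * math.pi * radius**3


def volume_from_diameter(diameter: float) -> float:
    """Sphere volume from a diameter: V = (4/3)·π·(D/2)³.

    A zero diameter is allowed and yields zero volume (degenerate cell).
    """
    if diameter < 0:
        raise ValueError(f"diameter must be >= 0, got {diameter}")
    return (4.0 / 3.0) * math.pi * (diameter / 2.0) ** 3


def prolate_spheroid_volume(length: float, width: float) -> float:
    """Prolate spheroid volume: V = (4/3)·π·(L/2)·(W/2)².

    The major axis is ``length`` and both minor axes equal ``width`` — the
    standard shape model for elongated cells such as *Dunaliella*. A width
    exceeding the length is rejected rather than silently swapped, because
    swapped columns usually indicate an upstream data error.
    """
    if length <= 0 or width <= 0:
        raise ValueError(f"length and width must be > 0, got {length}, {width}")
    if width > length:
        raise ValueError(
            f"width ({width}) exceeds length ({length}); prolate spheroid "
            "requires length >= width — check the input columns"
        )
    return (4.0 / 3.0) * math.pi * (length / 2.0) * (width / 2.0) ** 2
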