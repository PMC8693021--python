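"""Parametrised chamber geometry: well, L-shaped wire electrodes, meniscus.

Lengths are in millimetres and volumes in millilitres at this interface
(converted to SI only inside the field solver).  The liquid surface is a flat
base at height ``b`` plus a capillary meniscus rising towards the well wall,

.. math:: h(r) = h_0 \\left(e^{-(R-r)/c} + e^{-(R+r)/c}\\right),

where ``h_0`` is the maximum meniscus height relative to the centre and ``c``
its decay length.  The base height for a prescribed medium volume is found by
bisection to a 0.1 uL volume tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = ["ChamberGeometry", "meniscus_height", "meniscus_volume",
           "liquid_volume", "solve_fill_height"]


@dataclass
class ChamberGeometry:
    """Geometry of one well of the stimulation chamber (mm / mL).

    The two platinum wire electrodes are L-shaped: a horizontal bottom part
    of length ``bottom_length`` resting ``h_1`` / ``h_2`` above the well
    bottom, and a vertical part rising to the lid.  The horizontal parts run
    parallel to each other, ``electrode_spacing`` apart, symmetric about the
    well centre.
    """

    well_radius: float = 17.4
    wire_radius: float = 0.5
    electrode_spacing: float = 24.0
    bottom_length: float = 21.65
    electrode_height_1: float = 0.755
    electrode_height_2: float = 0.755
    meniscus_height_max: float = 2.15
    meniscus_decay: float = 2.0
    medium_volume: float = 3.5  # mL
    vertical_length: float = 18.0

    def __post_init__(self) -> None:
        for name in ("well_radius", "wire_radius", "electrode_spacing",
                     "bottom_length", "meniscus_decay", "medium_volume",
                     "vertical_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.meniscus_height_max < 0:
            raise ValueError("meniscus_height_max must be >= 0")
        if self.electrode_height_1 < 0 or self.electrode_height_2 < 0:
            raise ValueError("electrode heights must be >= 0")
        if self.electrode_spacing + 2 * self.wire_radius >= 2 * self.well_radius:
            raise ValueError("electrodes do not fit inside the well")
        half = self.bottom_length / 2.0
        reach = math.hypot(self.electrode_spacing / 2.0 + self.wire_radius,
                           half + self.wire_radius)
        if reach >= self.well_radius:
            raise ValueError("electrode bottom part extends beyond the well wall")

    def check_submerged(self, base_height: float) -> None:
        """Warn when an electrode's bottom part would break the surface."""
        top1 = self.electrode_height_1 + 2 * self.wire_radius
        top2 = self.electrode_height_2 + 2 * self.wire_radius
        if base_height < max(top1, top2):
            warnings.warn(
                f"fill height {base_height:.2f} mm leaves an electrode "
                "partially above the liquid surface",
                stacklevel=2,
            )


def meniscus_height(r, geometry: ChamberGeometry):
    """Meniscus elevation ``h(r)`` above the flat base, mm.

    ``r`` is the radial distance from the well centre, 0 <= r <= R.
    """
    r = np.asarray(r, dtype=float)
    R, c, h0 = geometry.well_radius, geometry.meniscus_decay, geometry.meniscus_height_max
    if np.any(r < 0) or np.any(r > R):
        raise ValueError("r must lie in [0, well_radius]")
    out = h0 * (np.exp(-(R - r) / c) + np.exp(-(R + r) / c))
    return float(out) if out.ndim == 0 else out


def meniscus_volume(geometry: ChamberGeometry) -> float:
    """Volume of the meniscus cap, ``2 pi int_0^R h(r) r dr``, in mm^3."""
    R = geometry.well_radius
    val, _ = integrate.quad(
        lambda r: meniscus_height(r, geometry) * r, 0.0, R, epsabs=1e-6, epsrel=1e-10
    )
    return 2.0 * math.pi * val


def liquid_volume(base_height: float, geometry: ChamberGeometry) -> float:
    """Medium volume (mm^3) for a flat base height ``b``: cylinder + meniscus."""
    if base_height < 0:
        raise ValueError("base height must be >= 0")
    return math.pi * geometry.well_radius**2 * base_height + meniscus_volume(geometry)


def solve_fill_height(
    geometry: ChamberGeometry,
    tolerance_uL: float = 0.1,
    max_height: float = 30.0,
) -> float:
    """Base height ``b`` (mm) whose liquid volume matches the target volume.

    Bisection on ``b`` with the volume evaluated by adaptive quadrature of
    the meniscus profile; stops when the volume error drops below
    ``tolerance_uL`` (1 uL = 1 mm^3).
    """
    target = geometry.medium_volume * 1000.0  # mL -> mm^3
    v_men = meniscus_volume(geometry)
    area = math.pi * geometry.well_radius**2

    def err(b):
        return area * b + v_men - target

    lo, hi = 0.0, max_height
    if err(lo) > tolerance_uL or err(hi) < -tolerance_uL:
        raise ValueError(
            f"target volume {geometry.medium_volume} mL not bracketed by base "
            f"heights [0, {max_height}] mm"
        )
    # bisect until the *volume* error bound is below tolerance
    while (hi - lo) * area > tolerance_uL:
        mid = 0.5 * (lo + hi)
        if err(mid) > 0:
            hi = mid
        else:
            lo = mid
    b = 0.5 * (lo + hi)
    geometry.check_submerged(b)
    return b
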