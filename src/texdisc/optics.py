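"""Fiber-optic irradiance helpers for optogenetic inhibition experiments.

Small deterministic conversions: laser power delivered through a multimode
fiber tip to an irradiance (power density), and the opsin-activation metric
used to relate inhibition strength to behavioral effect (expression area times
the user-supplied irradiance-loss factor from tip to tissue; the tissue
light-scattering model itself is outside this package and enters only through
that factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class FiberSpec:
    """Optic fiber implant: output power (mW), core diameter (um), NA."""

    power_mw: float
    core_diameter_um: float
    numerical_aperture: float = 0.5

    def __post_init__(self):
        if self.power_mw < 0:
            raise ParameterError("power must be >= 0")
        if self.core_diameter_um <= 0:
            raise ParameterError("core diameter must be > 0")
        if not (0.0 < self.numerical_aperture < 1.0):
            raise ParameterError("numerical aperture must lie in (0, 1)")


def tip_irradiance(fiber: FiberSpec) -> float:
    """Irradiance at the fiber tip in mW/mm^2: power / core area."""
    radius_mm = fiber.core_diameter_um / 2.0 / 1000.0
    return fiber.power_mw / (np.pi * radius_mm ** 2)


def activation_estimate(expression_area_mm2: float,
                        irradiance_loss_fraction: float) -> float:
    """Opsin terminal-activation metric: expression area x loss fraction.

    ``irradiance_loss_fraction`` is the fraction of tip irradiance remaining
    at the expression site, from any external attenuation model; must lie in
    (0, 1].  Monotone in both arguments.
    """
    if not (0.0 < irradiance_loss_fraction <= 1.0):
        raise ParameterError("irradiance loss fraction must lie in (0, 1]")
    if expression_area_mm2 < 0:
        raise ParameterError("expression area must be >= 0")
    return expression_area_mm2 * irradiance_loss_fraction
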