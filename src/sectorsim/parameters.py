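"""Physical and numerical parameters of the cell-group model.

Units follow the micro-scale convention used throughout the package:
lengths in µm, time in h, concentrations in g/L (= fg/µm³), biomass of a
single agent in fg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

Condition = Literal["SURFACE", "RADIAL"]


@dataclass(frozen=True)
class ParameterSet:
    """Physical/biological constants plus domain geometry and numerics.

    Parameters
    ----------
    G_bulk:
        Bulk (far-field) growth-substrate concentration [g/L]. The bulk
        liquid acts as an infinite source of substrate.
    D_G, D_E:
        Diffusivities of substrate and secreted enzyme [µm²/h].
    Y:
        Yield: mass of biomass produced per mass of substrate consumed
        (dimensionless).
    mu_max:
        Maximum specific growth rate [1/h].
    rho:
        Biomass density of a cell [g/L].
    h:
        Height of the diffusion boundary layer [µm]; concentrations beyond
        h from the biomass front are held at their bulk values.
    K_G:
        Half-saturation (Monod) constant for growth on substrate [g/L].
    r_div:
        Critical division radius [µm]; agents exceeding it split in two.
    width, height:
        Domain size [µm].
    spacing:
        Solute-lattice node spacing [µm]; must not exceed the cell
        diameter 2·r_div.
    slice_thickness:
        Nominal thickness [µm] of the 2-D slice, converting the volumetric
        biomass density rho into the areal density used by disk agents.
    max_front_height:
        Stopping rule: the simulation ends once the biomass front reaches
        this height [µm].
    dt_frac:
        Euler step policy: the global time step satisfies
        max(mu)·dt <= dt_frac.
    dt_max:
        Upper bound on the time step [h] when growth is very slow.
    condition:
        "SURFACE" (substrate from above, periodic lateral boundaries) or
        "RADIAL" (substrate from all sides, open domain).
    """

    G_bulk: float = 0.03125
    D_G: float = 8.0e6
    D_E: float = 3.6e5
    Y: float = 0.5
    mu_max: float = 1.0
    rho: float = 200.0
    h: float = 5.0
    K_G: float = 1.0e-4
    r_div: float = 1.0
    width: float = 80.0
    height: float = 50.0
    spacing: float = 1.0
    slice_thickness: float = 1.0
    max_front_height: float = 40.0
    dt_frac: float = 0.05
    dt_max: float = 1.0
    condition: Condition = "SURFACE"

    def __post_init__(self) -> None:
        positive = (
            "G_bulk D_G D_E Y mu_max rho h K_G r_div width height "
            "spacing slice_thickness max_front_height dt_frac dt_max"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if self.spacing > 2.0 * self.r_div + 1e-12:
            raise ValueError("grid spacing must not exceed the cell diameter")
        if self.max_front_height > self.height - self.h:
            raise ValueError("max_front_height must be <= height - h")
        if self.condition not in ("SURFACE", "RADIAL"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def rho_area(self) -> float:
        """Areal biomass density [fg/µm²] of a disk agent."""
        return self.rho * self.slice_thickness

    @property
    def biomass_at_division(self) -> float:
        """Agent biomass [fg] at the critical division radius."""
        return self.rho_area * math.pi * self.r_div**2

    @property
    def periodic_x(self) -> bool:
        return self.condition == "SURFACE"

    def with_delta(self, delta: float, vary: str = "G_bulk") -> "ParameterSet":
        """Return a copy whose active-layer number equals ``delta``.

        Exactly one of the constituents of δ is rescaled: ``vary`` selects
        "G_bulk" (default), "mu_max" or "D_G".
        """
        if delta <= 0:
            raise ValueError("delta must be positive")
        base = delta_number(self)
        factor = (delta / base) ** 2
        if vary == "G_bulk":
            return replace(self, G_bulk=self.G_bulk * factor)
        if vary == "D_G":
            return replace(self, D_G=self.D_G * factor)
        if vary == "mu_max":
            return replace(self, mu_max=self.mu_max / factor)
        raise ValueError("vary must be one of 'G_bulk', 'mu_max', 'D_G'")


def delta_number(params: ParameterSet) -> float:
    """Dimensionless active-layer number δ (inverse Thiele modulus).

    δ = (1/h)·sqrt(G_bulk·D_G·Y / (μ_max·ρ)). Small δ means a thin active
    layer: substrate is depleted close to the group's front. δ² is the
    coefficient that multiplies the dimensionless Laplacian when the
    steady-state substrate equation is scaled by G_bulk, ρ and h.
    """
    return (1.0 / params.h) * math.sqrt(
        params.G_bulk * params.D_G * params.Y / (params.mu_max * params.rho)
    )
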