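"""Growth kinetics and the cooperative secreted-enzyme phenotype.

The growth law is Monod (Michaelis-Menten) in the local substrate
concentration, modulated by the social phenotype:

    mu = mu_max * (1 - C*R_E) * benefit(E) * G / (K_G + G)

Cooperators constitutively secrete a diffusible enzyme at rate ``R_E``
(g enzyme per g biomass per h) and pay an unconditional fold cost
``C*R_E``. Wherever the local enzyme concentration reaches the threshold
``tau``, *every* strain — cooperator or exploiter — multiplies its growth
rate by ``1 + B`` (a fold *increase* of B). The asymmetry — cost paid only
by producers, benefit shared by all — is what makes exploitation possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "StrainPhenotype",
    "specific_growth_rate",
    "substrate_sink_rate",
    "enzyme_source_rate",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class StrainPhenotype:
    """A heritable phenotype shared by all cells of a strain.

    ``benefit_mode`` selects how the fold benefit is applied once local
    enzyme exceeds ``tau``: ``"one_plus_b"`` multiplies the growth rate by
    (1 + B) — a fold increase of B — while ``"literal"`` multiplies by B
    directly (useful for sensitivity checks; with B < 1 the "benefit"
    would then be a penalty).
    """

    name: str
    cooperator: bool = False
    R_E: float = 0.0
    B: float = 3.0
    C: float = 0.3
    tau: float = 0.002
    mu_max: float = 1.0
    K_G: float = 1.0e-4
    Y: float = 0.5
    benefit_mode: str = "one_plus_b"

    def __post_init__(self) -> None:
        if self.R_E < 0:
            raise ValueError("enzyme production rate R_E must be >= 0")
        if not self.cooperator and self.R_E != 0:
            raise ValueError("an exploiter must have R_E = 0")
        if self.C * self.R_E >= 1:
            raise ValueError(
                f"cost C*R_E = {self.C * self.R_E:g} >= 1: growth multiplier "
                "would be non-positive (configuration error)"
            )
        if self.mu_max <= 0 or self.K_G <= 0 or self.Y <= 0:
            raise ValueError("mu_max, K_G and Y must be strictly positive")
        if self.benefit_mode not in ("one_plus_b", "literal"):
            raise ValueError("benefit_mode must be 'one_plus_b' or 'literal'")

    @property
    def cost_multiplier(self) -> float:
        """Unconditional growth multiplier 1 - C*R_E paid by producers."""
        return 1.0 - self.C * self.R_E

    def benefit_factor(self, E_local: ArrayLike) -> ArrayLike:
        """Growth multiplier from local enzyme: step function at tau."""
        above = np.asarray(E_local) >= self.tau
        gain = (1.0 + self.B) if self.benefit_mode == "one_plus_b" else self.B
        out = np.where(above, gain, 1.0)
        return out if out.ndim else float(out)


def specific_growth_rate(
    strain: StrainPhenotype, G_local: ArrayLike, E_local: ArrayLike
) -> ArrayLike:
    """Specific growth rate mu [1/h] under local substrate and enzyme.

    Vectorized over ``G_local``/``E_local``. Negative inputs are invalid;
    the result is clamped at 0 (no maintenance or decay term).
    """
    G = np.asarray(G_local, dtype=float)
    if np.any(G < 0) or np.any(np.asarray(E_local) < 0):
        raise ValueError("local concentrations must be non-negative")
    monod = G / (strain.K_G + G)
    mu = strain.mu_max * strain.cost_multiplier * strain.benefit_factor(E_local) * monod
    mu = np.maximum(mu, 0.0)
    return mu if mu.ndim else float(mu)


def substrate_sink_rate(mu: ArrayLike, X_node: ArrayLike, Y: float) -> ArrayLike:
    """Local substrate consumption rate mu·X/Y [g/L/h] (returned positive)."""
    if Y <= 0:
        raise ValueError("yield Y must be strictly positive")
    mu = np.asarray(mu, dtype=float)
    X = np.asarray(X_node, dtype=float)
    if np.any(mu < 0) or np.any(X < 0):
        raise ValueError("mu and X_node must be non-negative")
    out = mu * X / Y
    return out if out.ndim else float(out)


def enzyme_source_rate(
    strain: StrainPhenotype, X_node: ArrayLike, activity: ArrayLike = 1.0
) -> ArrayLike:
    """Enzyme source R_E·activity·X [g/L/h] for a strain's biomass.

    Secretion is constitutive in the genetic sense (not regulated by any
    cue) but scales with the cell's metabolic activity ``activity``
    (the Monod factor G/(K_G+G) in the simulation loop): substrate-starved
    biomass secretes nothing, mirroring the cost side, where the C·R_E
    penalty is likewise paid only through growth. ``activity`` defaults
    to 1 (fully active biomass).
    """
    X = np.asarray(X_node, dtype=float)
    act = np.asarray(activity, dtype=float)
    if np.any(X < 0) or np.any(act < 0) or np.any(act > 1):
        raise ValueError("X_node must be >= 0 and activity within [0, 1]")
    rate = strain.R_E if strain.cooperator else 0.0
    out = rate * act * X
    return out if out.ndim else float(out)
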