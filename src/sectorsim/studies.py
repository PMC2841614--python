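"""Desk-scale study designs: regimes, δ-collapse, competition, neutrality.

These drivers define the package's standard reduced-scale renditions of
the headline experiments on an 80 µm wide periodic surface-growth domain
(1 µm division-radius cells, 1 µm solute lattice, h = 5 µm boundary
layer). Morphology studies grow to 60 µm so lineage sectors coarsen well
past the 20 µm segregation neighborhood; competition studies grow to
50 µm. Problem sizes are package choices made so a full study battery
runs in minutes on one CPU; docs/methods.md discusses what does and does
not transfer from this scale.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .experiments import (
    ScenarioConfig, run_competition, run_segregation_sweep, run_simulation,
)
from .kinetics import StrainPhenotype
from .parameters import ParameterSet

__all__ = [
    "neutral_config", "competition_config",
    "regime_study", "collapse_study", "competition_study",
    "neutrality_study", "mass_balance_run",
]

MORPHOLOGY_PARAMS = {"height": 70.0, "max_front_height": 60.0}
COMPETITION_PARAMS = {"height": 60.0, "max_front_height": 50.0}
ITER_CAP = 8000


def neutral_config(**overrides) -> ScenarioConfig:
    """1:1 red/blue neutral-marker scenario (colors share one phenotype)."""
    params = ParameterSet(**overrides.pop("params", {}))
    wild = StrainPhenotype("wild", mu_max=params.mu_max, K_G=params.K_G, Y=params.Y)
    return ScenarioConfig(
        params=params,
        strains=(wild,),
        color_fractions={"RED": 0.5, "BLUE": 0.5},
        color_strain={"RED": "wild", "BLUE": "wild"},
        **overrides,
    )


def competition_config(B: float = 3.0, C: float = 0.3, tau: float = 0.002,
                       R_E: float = 1.0, **overrides) -> ScenarioConfig:
    """Cooperator (blue, enzyme-secreting) vs exploiter (red) at 1:1."""
    params = ParameterSet(**overrides.pop("params", {}))
    common = dict(mu_max=params.mu_max, K_G=params.K_G, Y=params.Y,
                  B=B, C=C, tau=tau)
    coop = StrainPhenotype("cooperator", cooperator=True, R_E=R_E, **common)
    expl = StrainPhenotype("exploiter", cooperator=False, R_E=0.0, **common)
    return ScenarioConfig(
        params=params,
        strains=(coop, expl),
        color_fractions={"BLUE": 0.5, "RED": 0.5},
        color_strain={"BLUE": "cooperator", "RED": "exploiter"},
        **overrides,
    )


def regime_study(base_seed: int, deltas=(1.0, 2.0, 10.0),
                 replicates: int = 10) -> pd.DataFrame:
    """Three structure regimes: δ set via G_bulk, neutral 1:1 markers."""
    cfg = neutral_config(params=dict(MORPHOLOGY_PARAMS),
                         max_iterations=ITER_CAP)
    return run_segregation_sweep(
        cfg, deltas, vary="G_bulk", replicates=replicates, base_seed=base_seed,
    )


def collapse_study(base_seed: int, delta: float = 2.0,
                   replicates: int = 10) -> pd.DataFrame:
    """One δ reached three ways (G_bulk, μ_max, D_G) from the δ=5 baseline."""
    cfg = neutral_config(params=dict(MORPHOLOGY_PARAMS),
                         max_iterations=ITER_CAP)
    tables = []
    for i, vary in enumerate(("G_bulk", "mu_max", "D_G")):
        tables.append(run_segregation_sweep(
            cfg, [delta], vary=vary, replicates=replicates,
            base_seed=base_seed + i,
        ))
    return pd.concat(tables, ignore_index=True)


def competition_study(base_seed: int, deltas=(10.0, 1.0),
                      R_E_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
                      replicates: int = 10) -> pd.DataFrame:
    """Cooperator relative fitness across enzyme production rates and δ."""
    cfg = competition_config(params=dict(COMPETITION_PARAMS),
                             max_iterations=ITER_CAP)
    return run_competition(
        cfg, R_E_grid, deltas, replicates=replicates, base_seed=base_seed,
    )


def neutrality_study(base_seed: int, deltas=(10.0, 1.0),
                     replicates: int = 15) -> pd.DataFrame:
    """R_E = 0 control: strains identical, so fitness differences are drift."""
    cfg = competition_config(params=dict(COMPETITION_PARAMS),
                             max_iterations=ITER_CAP)
    return run_competition(
        cfg, [0.0], deltas, replicates=replicates, base_seed=base_seed,
    )


def mass_balance_run(seed: int, n_iterations: int = 200):
    """Neutral δ=2 run capped at ``n_iterations``, for the yield check."""
    cfg = neutral_config(params={"height": 130.0, "max_front_height": 120.0})
    cfg = replace(
        cfg,
        params=cfg.params.with_delta(2.0, "G_bulk"),
        max_iterations=n_iterations,
    )
    return run_simulation(cfg, seed)
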