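"""Deterministic synthetic configurations and analytic oracles for testing.

Fixtures construct cell groups with hand-prescribed geometry and per-cell
substrate values, so metric and solver tests never depend on a full
simulation run. The 1-D slab profile is the closed-form steady state of
diffusion with a zeroth-order sink, used as the solver's analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .agents import CellGroup

__all__ = ["FixtureSpec", "make_fixture", "analytic_slab_profile"]

KINDS = ("MONOLAYER", "CHECKERBOARD", "HALF_HALF", "SLAB_1D", "TOWERS")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic test configuration.

    ``g_rule`` assigns a local substrate value to each cell: ``("uniform",
    G0)`` or ``("linear_y", G_bottom, G_top)`` (linear gradient in y over
    the occupied height). Geometry is a lattice of ``rows`` × ``cols``
    cells of radius ``r`` at center spacing ``2 r * pitch``.
    """

    kind: str
    rows: int = 6
    cols: int = 6
    r: float = 1.0
    pitch: float = 1.0
    rho_area: float = 200.0
    g_rule: tuple = ("uniform", 1.0)
    gap_cols: int = 4  # TOWERS: empty columns between the two towers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.r <= 0 or self.pitch < 1.0:
            raise ValueError("need r > 0 and pitch >= 1 (no overlap)")


def _lattice(spec: FixtureSpec):
    step = 2.0 * spec.r * spec.pitch
    ii, jj = np.meshgrid(np.arange(spec.cols), np.arange(spec.rows))
    x = (ii.ravel() + 0.5) * step
    y = (jj.ravel() + 0.5) * step
    return x, y, ii.ravel(), jj.ravel()


def _g_values(spec: FixtureSpec, y: np.ndarray) -> np.ndarray:
    rule = spec.g_rule
    if rule[0] == "uniform":
        return np.full(y.size, float(rule[1]))
    if rule[0] == "linear_y":
        lo, hi = float(rule[1]), float(rule[2])
        t = (y - y.min()) / max(y.max() - y.min(), 1e-300)
        return lo + (hi - lo) * t
    raise ValueError(f"unknown g_rule {rule[0]!r}")


def make_fixture(spec: FixtureSpec) -> tuple[CellGroup, np.ndarray]:
    """Build (cells, per-cell substrate values) for the given recipe.

    Color layouts: MONOLAYER is all RED (single bottom row ignored aside,
    the lattice may still have several rows); CHECKERBOARD alternates
    RED/BLUE by lattice parity; HALF_HALF splits at the lateral midline;
    TOWERS places two monochromatic columns separated by ``gap_cols``
    empty columns. SLAB_1D is a uniform film for solver tests.
    """
    x, y, ii, jj = _lattice(spec)
    if spec.kind == "MONOLAYER":
        keep = jj == 0
        x, y, ii, jj = x[keep], y[keep], ii[keep], jj[keep]
        color = np.zeros(x.size, dtype=np.int64)
    elif spec.kind == "CHECKERBOARD":
        color = ((ii + jj) % 2).astype(np.int64)
    elif spec.kind == "HALF_HALF":
        color = (ii >= spec.cols / 2).astype(np.int64)
    elif spec.kind == "SLAB_1D":
        color = np.zeros(x.size, dtype=np.int64)
    elif spec.kind == "TOWERS":
        left = ii < spec.cols
        xs = [x, x + (spec.cols + spec.gap_cols) * 2 * spec.r * spec.pitch]
        x = np.concatenate(xs)
        y = np.concatenate([y, y])
        color = np.concatenate(
            [np.zeros(left.size, np.int64), np.ones(left.size, np.int64)]
        )
    biomass = np.full(x.size, spec.rho_area * math.pi * spec.r**2)
    cells = CellGroup(
        x=x.astype(float),
        y=y.astype(float),
        biomass=biomass,
        color=color,
        strain=np.zeros(x.size, dtype=np.int64),
        ids=np.arange(x.size, dtype=np.int64),
        growth_rate=np.zeros(x.size),
        active=np.ones(x.size, dtype=bool),
        rho_area=spec.rho_area,
        color_names=("RED", "BLUE"),
        next_id=x.size,
    )
    return cells, _g_values(spec, cells.y)


def analytic_slab_profile(G0: float, k: float, D: float, L: float, y) -> np.ndarray:
    """Steady 1-D film with zeroth-order sink: G(y) = G0 − (k/2D)(L² − y²).

    Dirichlet G(L) = G0 at the top, no-flux at y = 0; clipped at 0 where
    the formula would go negative (substrate fully depleted).
    """
    if D <= 0 or L <= 0 or G0 < 0 or k < 0:
        raise ValueError("parameters must be positive (k, G0 non-negative)")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > L):
        raise ValueError("y must lie within [0, L]")
    out = np.maximum(G0 - (k / (2.0 * D)) * (L**2 - y**2), 0.0)
    return out if out.ndim else float(out)
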