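"""Node-centered solute lattices and the steady-state reaction-diffusion solve.

The quasi-steady-state assumption — solute diffusion is much faster than
cell growth — means every growth step sees a fully relaxed concentration
field. The solver contract is therefore a residual bound on

    D * laplacian(C) + r(C) = 0

with Dirichlet values on the bulk region (infinite source for substrate,
perfect sink for enzyme), a no-flux floor, and periodic or no-flux lateral
boundaries. Internally each outer cycle freezes the rate law's linearized
coefficients and solves the resulting sparse linear system directly
(5-point stencil, sparse LU); the contract is the residual, not the
iteration scheme.

Grid convention: ``values[j, i]`` with node (0, 0) at the lower left and
node centers at ((i + 0.5)·spacing, (j + 0.5)·spacing), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import distance_transform_edt, minimum_filter1d
from scipy.sparse.linalg import splu

__all__ = [
    "Grid2D",
    "SoluteField",
    "BiomassField",
    "MichaelisMentenSink",
    "ZerothOrderSink",
    "ConstantSource",
    "rasterize_biomass",
    "compute_bulk_mask",
    "solve_reaction_diffusion",
    "residual_field",
    "sample_concentration",
]


@dataclass(frozen=True)
class Grid2D:
    nx: int
    ny: int
    spacing: float
    periodic_x: bool = True

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.nx * self.ny < 4:
            raise ValueError("grid must have at least 4 nodes")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def width(self) -> float:
        return self.nx * self.spacing

    @property
    def height(self) -> float:
        return self.ny * self.spacing

    def node_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of node centers, each shaped (ny, nx)."""
        xc = (np.arange(self.nx) + 0.5) * self.spacing
        yc = (np.arange(self.ny) + 0.5) * self.spacing
        return np.meshgrid(xc, yc)


@dataclass
class SoluteField:
    """One solute's concentration lattice with its bulk boundary handling."""

    kind: str  # "SUBSTRATE" | "ENZYME"
    values: np.ndarray
    bulk_value: float
    bulk_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("SUBSTRATE", "ENZYME"):
            raise ValueError("kind must be SUBSTRATE or ENZYME")
        if self.kind == "ENZYME" and self.bulk_value != 0.0:
            raise ValueError("the bulk is a perfect sink for enzyme (bulk_value 0)")
        if self.values.shape != self.bulk_mask.shape:
            raise ValueError("values and bulk_mask shapes differ")

    def enforce_bulk(self) -> None:
        self.values[self.bulk_mask] = self.bulk_value


@dataclass
class BiomassField:
    """Per-strain biomass concentration [g/L] on the solute lattice."""

    per_strain: np.ndarray  # (n_strains, ny, nx)

    @property
    def total(self) -> np.ndarray:
        return self.per_strain.sum(axis=0)


# --------------------------------------------------------------------------
# rate laws (r terms), exposing a Picard linearization r(C) ~ a + b*C, b <= 0


class MichaelisMentenSink:
    """Saturable sink r(C) = -kmax * C / (K + C), kmax = mu-weighted X/Y."""

    def __init__(self, kmax: np.ndarray, K: float):
        if K <= 0:
            raise ValueError("half-saturation constant must be positive")
        if np.any(kmax < 0):
            raise ValueError("kmax must be non-negative")
        self.kmax = kmax
        self.K = K

    def __call__(self, C: np.ndarray) -> np.ndarray:
        return -self.kmax * C / (self.K + C)

    def linear_coefficients(self, C: np.ndarray):
        # Newton linearization about the current iterate: r ~ a + b*C with
        # b = r'(C0) <= 0; quadratic outer convergence once near the root.
        C0 = np.maximum(C, 0.0)
        denom = self.K + C0
        b = -self.kmax * self.K / denom**2
        a = -self.kmax * C0 / denom - b * C0
        return a, b


class ZerothOrderSink:
    """Constant sink r(C) = -k (valid while the solution stays positive)."""

    def __init__(self, k: np.ndarray):
        self.k = k

    def __call__(self, C: np.ndarray) -> np.ndarray:
        return -self.k * np.ones_like(C)

    def linear_coefficients(self, C: np.ndarray):
        return -self.k * np.ones_like(C), np.zeros_like(C)


class ConstantSource:
    """Constant source r(C) = +s (constitutive enzyme secretion)."""

    def __init__(self, s: np.ndarray):
        if np.any(s < 0):
            raise ValueError("source must be non-negative")
        self.s = s

    def __call__(self, C: np.ndarray) -> np.ndarray:
        return self.s * np.ones_like(C)

    def linear_coefficients(self, C: np.ndarray):
        return self.s * np.ones_like(C), np.zeros_like(C)


class _PlainRate:
    """Adapter putting an arbitrary callable through damped Picard cycles."""

    damping = 0.5

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self.fn = fn

    def __call__(self, C: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(C))

    def linear_coefficients(self, C: np.ndarray):
        return np.asarray(self.fn(C)), np.zeros_like(C)


# --------------------------------------------------------------------------


def rasterize_biomass(
    cells, grid: Grid2D, n_strains: int, slice_thickness: float
) -> BiomassField:
    """Deposit each cell's biomass onto the node containing its center.

    Nearest-node scheme, one channel per strain; exactly conservative:
    sum(field) * spacing² * slice_thickness == total agent biomass.
    """
    s = grid.spacing
    x = cells.x
    if grid.periodic_x:
        x = x % grid.width
    i = np.floor(x / s).astype(np.int64)
    j = np.floor(cells.y / s).astype(np.int64)
    if np.any(i < 0) or np.any(i >= grid.nx) or np.any(j < 0) or np.any(j >= grid.ny):
        raise ValueError("cell center outside the solute grid")
    node_volume = s * s * slice_thickness
    out = np.zeros((n_strains, grid.ny, grid.nx))
    np.add.at(out, (cells.strain, j, i), cells.biomass / node_volume)
    return BiomassField(out)


def compute_bulk_mask(
    biomass: BiomassField, h: float, condition: str, grid: Grid2D
) -> np.ndarray:
    """Boolean mask of nodes belonging to the bulk liquid.

    SURFACE: per lateral column, bulk nodes sit more than h above the
    column's front, where the front height is laterally smoothed by a
    windowed minimum over ±h so the boundary layer hugs the front contour
    (peaks of a rough front sit closer to the bulk than troughs, which is
    what feeds the fingering instability). RADIAL: bulk nodes are farther
    than h (center-to-center) from any biomass-bearing node.
    """
    if h < grid.spacing:
        raise ValueError("boundary-layer height must be at least one grid spacing")
    occ = biomass.total > 0.0
    if not occ.any():
        return np.ones(grid.shape, dtype=bool)
    s = grid.spacing
    if condition == "SURFACE":
        any_col = occ.any(axis=0)
        jtop = np.where(any_col, occ.shape[0] - 1 - occ[::-1].argmax(axis=0), -1)
        front = (jtop + 1.0) * s  # top edge of the highest occupied node
        front[~any_col] = 0.0
        win = 2 * int(np.ceil(h / s)) + 1
        mode = "wrap" if grid.periodic_x else "nearest"
        front = minimum_filter1d(front, size=win, mode=mode)
        _, yc = grid.node_centers()
        # biomass-bearing nodes are never bulk: a protrusion rising past
        # the smoothed boundary keeps consuming, it does not become source
        return (yc > front[None, :] + h) & ~occ
    if condition == "RADIAL":
        dist = distance_transform_edt(~occ, sampling=s)
        return dist > h
    raise ValueError("condition must be SURFACE or RADIAL")


def _neighbor_tables(grid: Grid2D) -> list[np.ndarray]:
    """Flat neighbor index per direction; -1 marks a no-flux boundary."""
    idx = np.arange(grid.ny * grid.nx).reshape(grid.shape)
    east = np.roll(idx, -1, axis=1)
    west = np.roll(idx, 1, axis=1)
    if not grid.periodic_x:
        east = east.copy()
        west = west.copy()
        east[:, -1] = -1
        west[:, 0] = -1
    north = np.full(grid.shape, -1, dtype=np.int64)
    south = np.full(grid.shape, -1, dtype=np.int64)
    north[:-1, :] = idx[1:, :]
    south[1:, :] = idx[:-1, :]
    return [a.ravel() for a in (east, west, north, south)]


def _assemble(grid: Grid2D, bulk_mask, D, a, b, bulk_value):
    """Sparse 5-point system: D*lap(C) + a + b*C = 0; Dirichlet on bulk."""
    N = grid.ny * grid.nx
    coef = D / grid.spacing**2
    interior = ~bulk_mask.ravel()
    nodes = np.arange(N)
    rows, cols, vals = [], [], []
    deg = np.zeros(N)
    for nb in _neighbor_tables(grid):
        valid = interior & (nb >= 0)
        rows.append(nodes[valid])
        cols.append(nb[valid])
        vals.append(np.full(valid.sum(), coef))
        deg[valid] += 1.0
    rows.append(nodes[interior])
    cols.append(nodes[interior])
    vals.append(-deg[interior] * coef + b.ravel()[interior])
    bulk = ~interior
    rows.append(nodes[bulk])
    cols.append(nodes[bulk])
    vals.append(np.ones(bulk.sum()))
    rhs = np.where(interior, -a.ravel(), bulk_value)
    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return A, rhs


def residual_field(field: SoluteField, rate, grid: Grid2D, D: float) -> np.ndarray:
    """Pointwise residual D*lap(C) + r(C) on interior nodes (0 on bulk)."""
    C = field.values
    flat = C.ravel()
    coef = D / grid.spacing**2
    lap = np.zeros(flat.size)
    deg = np.zeros(flat.size)
    for nb in _neighbor_tables(grid):
        valid = nb >= 0
        lap[valid] += flat[nb[valid]]
        deg[valid] += 1.0
    lap = (lap - deg * flat) * coef
    res = lap + np.asarray(rate(C)).ravel()
    res[field.bulk_mask.ravel()] = 0.0
    return res.reshape(grid.shape)


def _relative_residual(field, rate, grid, D) -> float:
    res = residual_field(field, rate, grid, D)
    cref = max(float(np.abs(field.values).max()), field.bulk_value, 1e-300)
    scale = max(D / grid.spacing**2 * cref, float(np.abs(rate(field.values)).max()), 1e-300)
    return float(np.abs(res).max() / scale)


def solve_reaction_diffusion(
    field: SoluteField,
    rate,
    grid: Grid2D,
    D: float,
    tol: float = 1e-8,
    max_cycles: int = 60,
) -> SoluteField:
    """Solve D*lap(C) + r(C) = 0 to steady state; returns the updated field.

    ``rate`` maps node concentrations to a source(+)/sink(−) density
    [g/L/h]; objects exposing ``linear_coefficients`` (the built-in rate
    laws) converge in a handful of outer cycles, arbitrary callables are
    damped. ``field.values`` serves as the warm start. Raises
    ``RuntimeError`` with the residual history on non-convergence and
    ``ValueError`` if a substrate solution leaves [0, bulk] by more than
    a tolerance-sized overshoot.
    """
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    law = rate if hasattr(rate, "linear_coefficients") else _PlainRate(rate)
    damping = getattr(law, "damping", 1.0)
    C = field.values.astype(float).copy()
    out = SoluteField(field.kind, C, field.bulk_value, field.bulk_mask)
    out.enforce_bulk()
    history = []
    for _ in range(max_cycles):
        a, b = law.linear_coefficients(out.values)
        A, rhs = _assemble(grid, out.bulk_mask, D, a, b, out.bulk_value)
        new = splu(A).solve(rhs).reshape(grid.shape)
        out.values = out.values + damping * (new - out.values)
        out.enforce_bulk()
        rel = _relative_residual(out, law, grid, D)
        history.append(rel)
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"reaction-diffusion solve did not reach tol={tol:g}; "
            f"residual history: {['%.3e' % r for r in history]}"
        )
    if field.kind == "SUBSTRATE":
        over = max(
            float(-out.values.min()),
            float(out.values.max() - out.bulk_value),
            0.0,
        )
        if over > max(tol * out.bulk_value, 1e-12 * out.bulk_value):
            raise ValueError(
                f"substrate solution violates [0, bulk] by {over:.3g} g/L "
                "(unstable rate law?)"
            )
        np.clip(out.values, 0.0, out.bulk_value, out=out.values)
    elif np.any(out.values < -max(tol, 1e-12) * max(out.values.max(), 1.0)):
        raise ValueError("negative enzyme concentration beyond tolerance")
    else:
        np.clip(out.values, 0.0, None, out=out.values)
    return out


def sample_concentration(field: SoluteField, grid: Grid2D, x, y):
    """Bilinear interpolation of node values at point(s) (x, y) [µm].

    Periodic in x when the grid is periodic; beyond the outermost node
    centers in y (or x on an open grid) the nearest-node value is used,
    which keeps the result inside the surrounding nodes' range. Points
    outside the domain raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    if np.any(y < 0) or np.any(y > grid.height):
        raise ValueError("sample point outside the domain (y)")
    if grid.periodic_x:
        x = x % grid.width
    elif np.any(x < 0) or np.any(x > grid.width):
        raise ValueError("sample point outside the domain (x)")
    s = grid.spacing
    u = x / s - 0.5
    v = y / s - 0.5
    i0 = np.floor(u).astype(np.int64)
    j0 = np.floor(v).astype(np.int64)
    fu = u - i0
    fv = v - j0
    if grid.periodic_x:
        i0 %= grid.nx
        i1 = (i0 + 1) % grid.nx
    else:
        i0c = np.clip(i0, 0, grid.nx - 1)
        fu = np.where(i0 < 0, 0.0, np.where(i0 >= grid.nx - 1, 0.0, fu))
        i0 = i0c
        i1 = np.clip(i0 + 1, 0, grid.nx - 1)
    j0c = np.clip(j0, 0, grid.ny - 1)
    fv = np.where(j0 < 0, 0.0, np.where(j0 >= grid.ny - 1, 0.0, fv))
    j0 = j0c
    j1 = np.clip(j0 + 1, 0, grid.ny - 1)
    V = field.values
    val = (
        V[j0, i0] * (1 - fu) * (1 - fv)
        + V[j0, i1] * fu * (1 - fv)
        + V[j1, i0] * (1 - fu) * fv
        + V[j1, i1] * fu * fv
    )
    return float(val[0]) if scalar else val
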