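"""Circular cell agents: growth, division and hard-disk overlap relaxation.

Cells are stored as a structure-of-arrays container (:class:`CellGroup`)
so that growth and shoving vectorize over thousands of agents. A cell's
radius is always derived from its biomass through the 2-D disk relation

    radius = sqrt(biomass / (rho_area * pi))

where ``rho_area`` [fg/µm²] is the areal biomass density (volumetric
density × nominal slice thickness). Biomass is the state variable; radius
is never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CellGroup",
    "init_monolayer",
    "init_cluster",
    "grow_cells",
    "divide_cells",
    "relax_overlaps",
    "front_height",
]


@dataclass
class CellGroup:
    """A set of circular agents sharing one areal biomass density.

    ``color`` and ``strain`` are integer codes into ``color_names`` /
    the run's strain roster; both are immutable per cell after creation
    (operations only append or drop rows, never relabel).
    """

    x: np.ndarray
    y: np.ndarray
    biomass: np.ndarray
    color: np.ndarray
    strain: np.ndarray
    ids: np.ndarray
    growth_rate: np.ndarray
    active: np.ndarray
    rho_area: float
    color_names: tuple[str, ...]
    next_id: int = 0

    def __post_init__(self) -> None:
        if np.any(self.biomass <= 0):
            raise ValueError("cell biomass must be strictly positive")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def radius(self) -> np.ndarray:
        """Disk radii [µm] derived from biomass."""
        return np.sqrt(self.biomass / (self.rho_area * math.pi))

    @property
    def total_biomass(self) -> float:
        return float(self.biomass.sum())

    def copy(self) -> "CellGroup":
        return CellGroup(
            self.x.copy(), self.y.copy(), self.biomass.copy(),
            self.color.copy(), self.strain.copy(), self.ids.copy(),
            self.growth_rate.copy(), self.active.copy(),
            self.rho_area, self.color_names, self.next_id,
        )


def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n cells to colors by exact-count (largest remainder) rounding."""
    names = list(fractions)
    quotas = np.array([fractions[c] * n for c in names])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # hand leftover cells to the largest fractional remainders
    order = np.argsort(-(quotas - counts), kind="stable")
    for k in range(short):
        counts[order[k]] += 1
    return dict(zip(names, counts))


def init_monolayer(
    n_cells: int,
    color_fractions: dict[str, float],
    strain_map: dict[str, int],
    width: float,
    seed,
    *,
    rho_area: float,
    r_div: float,
) -> CellGroup:
    """Seed a single layer of cells on the floor of a periodic domain.

    Cells are placed at uniform-random x positions and relaxed along x
    until non-overlapping (the lateral boundary is periodic). Colors are
    assigned by exact-count rounding of ``color_fractions`` and then
    randomly permuted. Initial biomass is drawn uniformly between 55% and
    95% of the division biomass so that the first division wave is
    desynchronized. Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    total = sum(color_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"color fractions sum to {total!r}, expected 1")
    rng = np.random.default_rng(seed)

    m_div = rho_area * math.pi * r_div**2
    biomass = rng.uniform(0.55, 0.95, n_cells) * m_div
    radius = np.sqrt(biomass / (rho_area * math.pi))
    if 2.0 * radius.sum() > width:
        raise ValueError(
            f"{n_cells} cells (summed diameter {2 * radius.sum():.1f} µm) "
            f"do not fit in width {width} µm"
        )

    counts = _largest_remainder_counts(color_fractions, n_cells)
    color_names = tuple(color_fractions)
    color = np.concatenate(
        [np.full(counts[c], k, dtype=np.int64) for k, c in enumerate(color_names)]
    )
    color = rng.permutation(color)
    strain = np.array([strain_map[color_names[c]] for c in color], dtype=np.int64)

    # Uniform-random non-overlapping arrangement on the periodic line:
    # exponential gaps normalized to the free slack give exactly the
    # uniform distribution conditioned on no overlap (no iteration needed).
    slack = width - 2.0 * radius.sum()
    gaps = rng.exponential(1.0, n_cells)
    gaps *= slack / gaps.sum()
    edges = np.cumsum(gaps + 2.0 * radius)
    x = (edges - radius + rng.uniform(0.0, width)) % width

    return CellGroup(
        x=x,
        y=radius.copy(),
        biomass=biomass,
        color=color,
        strain=strain,
        ids=np.arange(n_cells, dtype=np.int64),
        growth_rate=np.zeros(n_cells),
        active=np.ones(n_cells, dtype=bool),
        rho_area=rho_area,
        color_names=color_names,
        next_id=n_cells,
    )


def init_cluster(
    n_cells: int,
    color_fractions: dict[str, float],
    strain_map: dict[str, int],
    center: tuple[float, float],
    seed,
    *,
    rho_area: float,
    r_div: float,
) -> CellGroup:
    """Seed a round cluster of cells for the radial (immersed) condition.

    Cells are scattered uniformly over a disc just large enough to hold
    them, then relaxed apart on the open plane. Color assignment follows
    the same exact-count rounding as :func:`init_monolayer`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    total = sum(color_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"color fractions sum to {total!r}, expected 1")
    rng = np.random.default_rng(seed)
    m_div = rho_area * math.pi * r_div**2
    biomass = rng.uniform(0.55, 0.95, n_cells) * m_div
    counts = _largest_remainder_counts(color_fractions, n_cells)
    color_names = tuple(color_fractions)
    color = rng.permutation(np.concatenate(
        [np.full(counts[c], k, dtype=np.int64) for k, c in enumerate(color_names)]
    ))
    strain = np.array([strain_map[color_names[c]] for c in color], dtype=np.int64)
    R = 1.3 * r_div * math.sqrt(n_cells)  # ~60% packing before relaxation
    radii = R * np.sqrt(rng.uniform(0.0, 1.0, n_cells))
    theta = rng.uniform(0.0, 2.0 * math.pi, n_cells)
    cells = CellGroup(
        x=center[0] + radii * np.cos(theta),
        y=center[1] + radii * np.sin(theta),
        biomass=biomass,
        color=color,
        strain=strain,
        ids=np.arange(n_cells, dtype=np.int64),
        growth_rate=np.zeros(n_cells),
        active=np.ones(n_cells, dtype=bool),
        rho_area=rho_area,
        color_names=color_names,
        next_id=n_cells,
    )
    relax_overlaps(cells, tol=1e-3, max_iters=5000, rng=rng,
                   periodic_x=False, has_floor=False)
    return cells


def grow_cells(cells: CellGroup, mu: np.ndarray, dt: float) -> None:
    """Euler growth step, in place: biomass <- biomass·(1 + mu·dt)."""
    mu = np.asarray(mu, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.any(mu < 0):
        raise ValueError("negative growth rates must be clamped upstream")
    if mu.size and float(np.max(mu)) * dt > 1.0:
        raise ValueError(
            f"Euler step too large: max(mu)*dt = {float(np.max(mu)) * dt:.3g} > 1"
        )
    cells.biomass *= 1.0 + mu * dt
    cells.growth_rate = mu.copy() if mu.shape == cells.biomass.shape else np.broadcast_to(mu, cells.biomass.shape).copy()


def divide_cells(
    cells: CellGroup, r_div: float, rng: np.random.Generator,
    eps_overlap: float = 0.05,
) -> int:
    """Split every agent at or above the critical radius into two children.

    Children carry exactly half the parent biomass each (child radius =
    parent/√2 in 2-D), inherit color and strain, and are placed
    symmetrically about the parent center along a uniform-random axis at
    separation 2·r_child·(1 − eps_overlap). Parent ids are retired.
    Returns the number of divisions; 0 is a silent no-op.
    """
    r = cells.radius
    div = r >= r_div
    ndiv = int(div.sum())
    if ndiv == 0:
        return 0
    keep = ~div
    half = cells.biomass[div] / 2.0
    r_child = np.sqrt(half / (cells.rho_area * math.pi))
    theta = rng.uniform(0.0, 2.0 * math.pi, ndiv)
    off = r_child * (1.0 - eps_overlap)
    dx, dy = off * np.cos(theta), off * np.sin(theta)
    px, py = cells.x[div], cells.y[div]

    def _dup(a):
        return np.concatenate([a[keep], a[div], a[div]])

    cells.x = np.concatenate([cells.x[keep], px + dx, px - dx])
    cells.y = np.concatenate([cells.y[keep], py + dy, py - dy])
    cells.biomass = np.concatenate([cells.biomass[keep], half, half])
    cells.color = _dup(cells.color)
    cells.strain = _dup(cells.strain)
    cells.growth_rate = _dup(cells.growth_rate)
    cells.active = _dup(cells.active)
    new_ids = cells.next_id + np.arange(2 * ndiv, dtype=np.int64)
    cells.ids = np.concatenate([cells.ids[keep], new_ids])
    cells.next_id += 2 * ndiv
    return ndiv


@njit(cache=True)
def _bin_cells(x, y, r, width, periodic_x):
    n = x.size
    cell = 2.1 * r.max()
    if periodic_x:
        nbx = max(1, int(width / cell))
        cellx = width / nbx
        x0 = 0.0
    else:
        x0 = x.min()
        nbx = max(1, int((x.max() - x0) / cell) + 1)
        cellx = cell
    y0 = y.min()
    nby = max(1, int((y.max() - y0) / cell) + 1)
    nb = nbx * nby
    counts = np.zeros(nb + 1, np.int64)
    binof = np.empty(n, np.int64)
    for i in range(n):
        bx = int((x[i] - x0) / cellx)
        if periodic_x:
            bx = bx % nbx
        elif bx < 0:
            bx = 0
        elif bx >= nbx:
            bx = nbx - 1
        by = int((y[i] - y0) / cell)
        if by < 0:
            by = 0
        elif by >= nby:
            by = nby - 1
        b = by * nbx + bx
        binof[i] = b
        counts[b + 1] += 1
    starts = np.cumsum(counts)
    members = np.empty(n, np.int64)
    cursor = starts[:-1].copy()
    for i in range(n):
        b = binof[i]
        members[cursor[b]] = i
        cursor[b] += 1
    return nbx, nby, cellx, cell, x0, y0, starts, members


@njit(cache=True)
def _max_overlap(x, y, r, width, periodic_x):
    """Largest pairwise overlap [µm] (0 if none), via spatial binning."""
    nbx, nby, cellx, celly, x0, y0, starts, members = _bin_cells(
        x, y, r, width, periodic_x
    )
    worst = 0.0
    for i in range(x.size):
        bx = int((x[i] - x0) / cellx)
        if periodic_x:
            bx = bx % nbx
        elif bx < 0:
            bx = 0
        elif bx >= nbx:
            bx = nbx - 1
        by = int((y[i] - y0) / celly)
        if by < 0:
            by = 0
        elif by >= nby:
            by = nby - 1
        for oy in range(-1, 2):
            cy = by + oy
            if cy < 0 or cy >= nby:
                continue
            for ox in range(-1, 2):
                cx = bx + ox
                if periodic_x:
                    cx = cx % nbx
                elif cx < 0 or cx >= nbx:
                    continue
                b = cy * nbx + cx
                for k in range(starts[b], starts[b + 1]):
                    j = members[k]
                    if j <= i:
                        continue
                    dx = x[i] - x[j]
                    if periodic_x:
                        if dx > 0.5 * width:
                            dx -= width
                        elif dx < -0.5 * width:
                            dx += width
                    dy = y[i] - y[j]
                    sr = r[i] + r[j]
                    d2 = dx * dx + dy * dy
                    if d2 < sr * sr:
                        ov = sr - math.sqrt(d2)
                        if ov > worst:
                            worst = ov
    return worst


@njit(cache=True)
def _relax_sweep(x, y, r, order, width, periodic_x, has_floor, beta):
    """One randomized Gauss-Seidel shoving pass; positions move in place."""
    nbx, nby, cellx, celly, x0, y0, starts, members = _bin_cells(
        x, y, r, width, periodic_x
    )
    for oi in range(order.size):
        i = order[oi]
        bx = int((x[i] - x0) / cellx)
        if periodic_x:
            bx = bx % nbx
        elif bx < 0:
            bx = 0
        elif bx >= nbx:
            bx = nbx - 1
        by = int((y[i] - y0) / celly)
        if by < 0:
            by = 0
        elif by >= nby:
            by = nby - 1
        for oy in range(-1, 2):
            cy = by + oy
            if cy < 0 or cy >= nby:
                continue
            for ox in range(-1, 2):
                cx = bx + ox
                if periodic_x:
                    cx = cx % nbx
                elif cx < 0 or cx >= nbx:
                    continue
                b = cy * nbx + cx
                for k in range(starts[b], starts[b + 1]):
                    j = members[k]
                    if j == i:
                        continue
                    dx = x[i] - x[j]
                    if periodic_x:
                        if dx > 0.5 * width:
                            dx -= width
                        elif dx < -0.5 * width:
                            dx += width
                    dy = y[i] - y[j]
                    sr = r[i] + r[j]
                    d2 = dx * dx + dy * dy
                    if d2 >= sr * sr:
                        continue
                    d = math.sqrt(d2)
                    if d < 1e-9:
                        # coincident centers: deterministic lateral split
                        ux, uy = (1.0, 0.0) if i < j else (-1.0, 0.0)
                        d = 1e-9
                    else:
                        ux, uy = dx / d, dy / d
                    shift = 0.5 * beta * (sr - d)
                    # each cell takes half the overlap, mass-independent;
                    # beta > 1 over-relaxes to speed up dense-colony expansion
                    x[i] += ux * shift
                    y[i] += uy * shift
                    x[j] -= ux * shift
                    y[j] -= uy * shift
                    if has_floor:
                        if y[i] < r[i]:
                            y[i] = r[i]
                        if y[j] < r[j]:
                            y[j] = r[j]
                    if periodic_x:
                        x[i] = x[i] % width
                        x[j] = x[j] % width


def relax_overlaps(
    cells: CellGroup,
    tol: float = 1e-3,
    max_iters: int = 500,
    rng: np.random.Generator | None = None,
    *,
    width: float | None = None,
    periodic_x: bool = True,
    has_floor: bool = True,
    beta: float = 1.0,
) -> int:
    """Shove overlapping cells apart until the worst overlap is below tol.

    Iterative hard-disk relaxation: each sweep visits cells in a freshly
    randomized order and resolves every overlapping pair it encounters by
    displacing both cells along the center-to-center axis, half the
    overlap each. Cells pushed under the floor are lifted back to
    y = radius; a periodic lateral boundary uses minimum-image distances.
    Returns the number of sweeps performed.

    ``beta`` scales the per-pair displacement (over-relaxation). The
    default 1.0 is the physical half-overlap rule; values near 2 converge
    much faster on dense groups but act as an artificial surface
    smoother, visibly damping front instabilities — use them only when
    front morphology is irrelevant.

    Raises ``RuntimeError`` if the residual overlap still exceeds ``tol``
    after ``max_iters`` sweeps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if cells.n == 0:
        return 0
    if not (np.all(np.isfinite(cells.x)) and np.all(np.isfinite(cells.y))):
        raise ValueError("cell positions must be finite")
    if periodic_x and width is None:
        raise ValueError("width is required for a periodic domain")
    w = float(width) if width is not None else 0.0
    rng = rng or np.random.default_rng(0)
    r = cells.radius
    for sweep in range(1, max_iters + 1):
        if _max_overlap(cells.x, cells.y, r, w, periodic_x) < tol:
            return sweep - 1
        order = rng.permutation(cells.n)
        _relax_sweep(cells.x, cells.y, r, order, w, periodic_x, has_floor, beta)
    residual = _max_overlap(cells.x, cells.y, r, w, periodic_x)
    raise RuntimeError(
        f"overlap relaxation did not converge: residual {residual:.3g} µm "
        f"after {max_iters} sweeps (tol {tol:g})"
    )


def front_height(cells: CellGroup) -> float:
    """Height of the biomass front: max over cells of (y + radius) [µm]."""
    if cells.n == 0:
        raise ValueError("front_height of an empty cell group is undefined")
    return float(np.max(cells.y + cells.radius))
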