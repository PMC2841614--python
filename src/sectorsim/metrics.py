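"""Spatial-structure and fitness statistics for simulated cell groups.

The central statistic is the segregation index: for every metabolically
active focal cell, the activity-weighted frequency of same-color cells
within a fixed neighborhood (default 10 cell lengths), averaged over focal
cells. With fully active neighbors it reduces to the local same-lineage
frequency; it ranges over [0, 1] with 1 meaning complete segregation at
the neighborhood scale, and is a spatial analogue of the relatedness
coefficient r in Hamilton's rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.spatial import cKDTree

from .parameters import ParameterSet, delta_number  # noqa: F401  (re-exported)
from .agents import CellGroup

__all__ = [
    "SegregationParams",
    "metabolic_activity",
    "segregation_index",
    "delta_number",
    "strain_fitness",
    "relative_fitness",
    "active_layer_depth",
    "front_roughness",
    "FrontStats",
]


@dataclass(frozen=True)
class SegregationParams:
    """Neighborhood radius [µm] and the activity floor for focal cells.

    The default radius, 10 cell lengths, should be set to 10 × 2·r_div
    for the run's division radius.
    """

    radius: float = 20.0
    epsilon: float = 0.01
    normalized: bool = True  # activity-weighted frequency vs literal mean product

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("neighborhood radius must be positive")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("activity floor must lie in (0, 1)")


def metabolic_activity(G_local, K_G):
    """Monod activity m = G/(K_G + G) in [0, 1]."""
    G = np.asarray(G_local, dtype=float)
    if np.any(G < 0) or K_G < 0:
        raise ValueError("concentrations must be non-negative")
    out = G / (K_G + G)
    return out if out.ndim else float(out)


def segregation_index(
    cells: CellGroup,
    G_local: np.ndarray,
    K_G: float,
    params: SegregationParams,
    focal_color: Optional[str] = None,
    *,
    width: Optional[float] = None,
) -> float:
    """Activity-weighted same-lineage neighborhood frequency, in [0, 1].

    For every focal cell (activity m >= epsilon; restricted to
    ``focal_color`` if given, else all colors), neighbors are all *other*
    cells within the neighborhood radius (center-to-center; periodic in x
    when ``width`` is given). Each focal cell contributes

        s_i = sum_j g_j * m_j / sum_j m_j

    with g_j = 1 for same-color neighbors; the index is the mean of s_i.
    Focal cells with an empty or zero-activity neighborhood are excluded;
    if every focal cell is excluded a ``ValueError`` is raised. With
    ``params.normalized`` False the literal unnormalized mean product
    mean_j(g_j * m_j) is used instead (comparison variant; it cannot
    reach 1 unless all neighbors are fully active).
    """
    if cells.n == 0:
        raise ValueError("empty cell group")
    G_local = np.asarray(G_local, dtype=float)
    if G_local.shape != (cells.n,):
        raise ValueError("G_local must hold one substrate value per cell")
    m = metabolic_activity(G_local, K_G)

    focal = m >= params.epsilon
    if focal_color is not None:
        code = cells.color_names.index(focal_color)
        focal &= cells.color == code
    focal_idx = np.flatnonzero(focal)
    if focal_idx.size == 0:
        raise ValueError("no metabolically active focal cells")

    pts = np.column_stack([cells.x, cells.y])
    if width is not None:
        # periodic in x only: pad y's box far beyond any attainable distance
        box = [width, 2.0 * (cells.y.max() + params.radius) + width]
        pts = pts % box
        tree = cKDTree(pts, boxsize=box)
    else:
        tree = cKDTree(pts)

    neighborhoods = tree.query_ball_point(pts[focal_idx], params.radius)
    scores = []
    for i, nb in zip(focal_idx, neighborhoods):
        nb = np.asarray(nb)
        nb = nb[nb != i]
        if nb.size == 0:
            continue
        mw = m[nb]
        same = (cells.color[nb] == cells.color[i]).astype(float)
        if params.normalized:
            tot = mw.sum()
            if tot <= 0.0:
                continue
            scores.append(float(same @ mw / tot))
        else:
            scores.append(float(same @ mw / nb.size))
    if not scores:
        raise ValueError("every focal cell had an empty or inactive neighborhood")
    return float(np.mean(scores))


def strain_fitness(N_start: int, N_end: int, duration: float) -> float:
    """Mean rounds of division per hour: W = log2(N_end/N_start)/duration."""
    if N_start < 1:
        raise ValueError("N_start must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if N_end == 0:
        return -math.inf
    return math.log2(N_end / N_start) / duration


def relative_fitness(W1: float, W2: float) -> float:
    """Fitness of strain 1 relative to strain 2: W1/W2 (> 1 means S1 wins)."""
    if W2 <= 0:
        raise ValueError("relative fitness undefined for W2 <= 0")
    return W1 / W2


def active_layer_depth(
    cells: CellGroup,
    threshold_fraction: float,
    mu_max: float,
    bin_width: float = 2.0,
    *,
    width: Optional[float] = None,
) -> float:
    """Mean depth [µm] of the growing layer below the front, per column.

    A column's depth is its front height minus the lower edge (y − r) of
    the deepest cell growing at >= threshold_fraction·mu_max there;
    columns with cells but no growing cells contribute 0. Returns 0 if
    nothing grows.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    heights, lows = _column_stats(cells, bin_width, width,
                                  cells.growth_rate >= threshold_fraction * mu_max)
    if heights.size == 0:
        return 0.0
    return float(np.mean(np.where(np.isfinite(lows), heights - lows, 0.0)))


class FrontStats(NamedTuple):
    roughness: float  # SD of per-column front height [µm]
    gap_count: int  # columns whose front sits below gap_fraction * max


def front_roughness(
    cells: CellGroup,
    bin_width: float = 2.0,
    *,
    width: Optional[float] = None,
    gap_fraction: float = 0.3,
) -> FrontStats:
    """Front roughness and tower-gap count from per-column front heights.

    Roughness is the standard deviation of front height over lateral bins.
    A bin counts as a gap when its front height (0 for an empty bin) lies
    below ``gap_fraction`` of the tallest bin — the signature of inactive
    troughs between growing towers.
    """
    if cells.n == 0:
        raise ValueError("empty cell group")
    heights, _ = _column_stats(cells, bin_width, width, None, include_empty=True)
    hmax = heights.max()
    roughness = float(np.std(heights[heights > 0.0] if width is None else heights))
    gaps = int(np.sum(heights < gap_fraction * hmax))
    return FrontStats(roughness, gaps)


def _column_stats(cells, bin_width, width, grow_mask, include_empty=False):
    """Per lateral bin: front height, and lowest growing-cell y (inf if none)."""
    r = cells.radius
    x = cells.x % width if width is not None else cells.x
    if width is not None:
        lo = 0.0
        nbins = max(1, int(math.ceil(width / bin_width)))
    else:
        lo = x.min()
        nbins = int((x.max() - lo) / bin_width) + 1
    col = np.minimum((x - lo) / bin_width, nbins - 1).astype(np.int64)
    heights = np.zeros(nbins)
    np.maximum.at(heights, col, cells.y + r)
    lows = np.full(nbins, np.inf)
    if grow_mask is not None and grow_mask.any():
        np.minimum.at(lows, col[grow_mask], (cells.y - r)[grow_mask])
    if include_empty:
        return heights, lows
    occupied = np.zeros(nbins, dtype=bool)
    occupied[col] = True
    return heights[occupied], lows[occupied]
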