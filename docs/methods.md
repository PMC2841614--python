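# Model and methods

`sectorsim` simulates the growth of a two-dimensional cell group — a
biofilm cross-section, a colony edge, or a tumor-like cluster — as a set
of circular agents coupled to steady-state reaction-diffusion fields, and
measures how physical parameters shape the spatial mixing of lineages and
the fate of a cooperative secreted-enzyme phenotype.

## The individual-based model

**Agents.** Each cell is a disk with biomass `m` [fg] and radius
`r = sqrt(m / (rho_area * pi))`, where `rho_area = rho * slice_thickness`
converts the volumetric biomass density `rho` [g/L] into an areal density
using a nominal 1 µm slice. Cells carry an immutable neutral color label
(lineage marker) and a strain phenotype. Growth follows explicit Euler,
`m <- m (1 + mu dt)`, with a global adaptive step chosen so
`max(mu) * dt <= dt_frac` (default 0.05, i.e. at most 5% biomass change
per iteration). A cell at or above the critical radius `r_div` splits
into two children of equal biomass placed symmetrically about the parent
along a uniform-random axis; the 50/50 split and random axis are the
simplest neutral conventions (any division asymmetry would inject
unmodeled drift).

**Shoving.** Overlaps created by growth and division are removed by
iterative hard-disk relaxation: in randomized order, every overlapping
pair is displaced along its center-to-center axis, half the overlap
each, until the worst overlap is below a tolerance (0.05 µm in the main
loop, 2.5% of a cell diameter). This outward shoving is what advances
the group's front. Two numerical points matter:

- *Over-relaxation is a trap.* Scaling the pairwise displacement by a
  factor near 2 makes dense-colony relaxation converge an order of
  magnitude faster, but acts as an artificial surface tension: in
  controlled tests a 5 µm sinusoidal front perturbation decays under
  over-relaxation and grows under the physical half-overlap rule. The
  package therefore uses the physical rule (`beta = 1`) in simulations.
- *Continuity pre-advection.* The slow mode of pairwise relaxation is
  the laterally uniform expansion required by mass conservation. Before
  shoving, every cell is lifted by the laterally averaged displacement
  implied by the area produced below it this step (cumulative grown area
  divided by domain width). This is exact in the mean-field sense, is
  laterally uniform (it cannot bias front morphology), and leaves the
  relaxation only local work, keeping `beta = 1` affordable.

**Solute fields.** Substrate G and enzyme E live on a node-centered
lattice (spacing <= cell diameter; default 1 µm). Each iteration the
agents are rasterized to per-strain biomass concentrations (nearest-node,
exactly conservative), the diffusion boundary layer of height `h` is
rebuilt from the current front, and both fields are solved to steady
state — the standard quasi-steady-state assumption that diffusion is much
faster than growth. Above the boundary layer the bulk liquid is an
infinite source for substrate (Dirichlet `G = G_bulk`) and a perfect
sink for enzyme (`E = 0`). The floor is no-flux; lateral boundaries are
periodic for surface growth and no-flux/open for the radial condition.

The boundary layer follows the front contour: per lateral column the
front height is smoothed by a windowed *minimum* over ±h before adding h.
A protruding tip is therefore closer to the source than a trough — the
positive feedback behind front fingering. Biomass-bearing nodes are never
assigned to the bulk, so a tip that outruns the smoothed boundary keeps
consuming rather than becoming a source (this also closes the mass
balance; see below). The columnwise rule is a convention; the
distance-based rule used for the radial condition is geometrically
"parallel" to the front and provides weaker tip feedback.

**Solver.** The steady state of `D lap(C) + r(C) = 0` is found by outer
linearization cycles, each solving the 5-point sparse system directly
(LU). Monod sinks use a Newton linearization (`r ~ r(C0) + r'(C0)(C-C0)`,
with `r' <= 0`), which converges in a handful of cycles even when
`K_G << G`; enzyme sources are constant and need one solve. The contract
is the final residual (relative residual below `1e-6` by default against
the flux scale `D C_ref / s^2`); the algorithm behind it is
interchangeable. The substrate solution is checked against the maximum
principle (`0 <= G <= G_bulk`) and clipped only within round-off.

Dirichlet values sit on node centers, so the effective boundary lies half
a spacing beyond the interface; the analytic-slab tests account for this
O(s) offset when they verify the stencil's second-order interior error.

## Growth law and the social model

Strain phenotypes share physiology (`mu_max`, `K_G`, `Y`) and differ in
social traits. The growth rate is

    mu = mu_max * (1 - C * R_E) * benefit(E) * G / (K_G + G)

Cooperators secrete a diffusible enzyme at per-biomass rate `R_E` and pay
the fold cost `C * R_E` whenever they grow. Wherever local enzyme reaches
the threshold `tau`, *any* cell's growth is multiplied by `1 + B` — a
fold increase of B. The benefit is a hard step at `tau` (no smoothing),
and the cost/benefit asymmetry (producers always pay; everyone within
reach gains) is what makes exploitation possible. The `1 + B`
interpretation of "increases growth by a fold factor B" is the default
(a config switch selects the literal `x B` reading); with the default,
an enzyme-aided cooperator strictly outgrows an unaided exploiter exactly
when `(1 - C R_E)(1 + B) > 1`, i.e. `R_E < 2.5` at B = 3, C = 0.3.

**Metabolically coupled secretion.** Secretion is constitutive in the
genetic sense (never regulated), but the source term is
`R_E * m(G) * X`, scaled by the Monod activity `m(G) = G/(K_G+G)`:
substrate-starved biomass secretes nothing. This mirrors the cost side —
the `C R_E` penalty is likewise paid only through growth — and avoids a
thermodynamically free enzyme flux from dormant cells deep inside the
group. With a strictly per-biomass source, the enzyme background rises
without bound as inactive biomass accumulates, eventually handing the
benefit to every cell regardless of spatial structure; with metabolic
coupling the enzyme is produced where the action is, in the active layer,
and its spatial pattern tracks the lineage pattern there.

**Threshold calibration.** `tau` = 2e-3 g/L is set from the 1-D scaling
estimate of the enzyme level generated by a cooperator-rich patch of the
*initial monolayer* at the reference rate R_E = 1:
`E ~ R_E m X T h / D_E` with `X ~ 180 g/L`, film thickness `T ~ 2 µm`,
`h = 5 µm`, `D_E = 3.6e5 µm²/h` gives ~4e-3 for a pure patch and about
half that for the small (1-3 cell) cooperator clusters a 1:1 random
mixture actually produces. Anchoring `tau` at this earliest stage means
cooperation is *possible* from inoculation — a necessary condition in the
flux-limited regime, where lineages excluded from the front during the
first hours can never return. A fixed threshold far above this scale
would simply re-derive the trivial result that a costly trait with no
benefit loses. Note that enzyme concentrations scale linearly with `h`
at steady state, so `tau` is tied to the package's boundary-layer height;
re-scaling `h` re-scales the sensible `tau` proportionally. By the same
estimate, a pure cooperator film at R_E = 1 exceeds `tau` throughout its
active layer from a thickness of ~1-2 cell diameters onward.

## Statistics

**Segregation index.** For every metabolically active focal cell
(activity `m >= 0.01`), neighbors are all other cells within 10 cell
lengths (10 × the division diameter, 20 µm by default; center-to-center,
periodic across the lateral boundary). Each focal cell contributes the
activity-weighted same-color frequency `sum(g_j m_j) / sum(m_j)`; the
index is the mean over focal cells and lies in [0, 1], reaching 1 only
for complete segregation at the neighborhood scale. The normalization by
`sum(m_j)` is deliberate: the unnormalized mean product (available behind
a flag) cannot reach 1 unless every neighbor is fully active, which
contradicts the index's role as a spatial relatedness coefficient. With
fully active neighbors the index reduces to the local same-lineage
frequency.

**Active-layer number.** δ = `(1/h) sqrt(G_bulk D_G Y / (mu_max rho))`
is the inverse Thiele modulus of the non-dimensionalized substrate
equation (normalize G by `G_bulk`, biomass by `rho`, lengths by `h`; δ²
multiplies the dimensionless Laplacian). Small δ means a thin active
layer. `ParameterSet.with_delta(delta, vary)` rescales exactly one
constituent (`G_bulk`, `mu_max` or `D_G`) to reach a target δ — the
factorial design behind the collapse study.

**Fitness.** Strain fitness is the mean number of division rounds per
hour, `W = log2(N_end/N_start) / T`, and the relative fitness of strain 1
against strain 2 is `W1 / W2` (>1 means strain 1 wins). Fitness is
additive over consecutive intervals by construction.

**Front statistics.** Front height is `max(y + r)`. Roughness is the
standard deviation of per-column front height (2 µm columns). A column
is a *tower gap* when its front lies below 0.3 × the tallest column —
the signature of troughs that have fallen out of the active layer
between growing towers. (Counting literally empty columns cannot work
here: cells never die, so the inoculated floor keeps every column
nominally occupied.) Active-layer depth is the mean, per column, of
front height minus the lower edge of the deepest cell growing at a set
fraction of `mu_max`.

## Default parameters

| symbol | default | units | rationale |
|---|---|---|---|
| `mu_max` | 1.0 | 1/h | fast-growing heterotroph |
| `rho` | 200 | g/L | typical dense biofilm biomass density |
| `Y` | 0.5 | g/g | carbohydrate-to-biomass yield |
| `K_G` | 1e-4 | g/L | 0.1 mg/L Monod constant; `K_G << G_bulk` at every study δ |
| `D_G` | 8e6 | µm²/h | small-sugar diffusivity (≈2.2e-9 m²/s) |
| `D_E` | 3.6e5 | µm²/h | protein diffusivity (≈1e-10 m²/s) |
| `h` | 5 | µm | boundary layer; sets the length scale of δ |
| `G_bulk` | 0.03125 | g/L | baseline δ = 5; studies rescale it per condition |
| `r_div` | 1.0 | µm | division radius (cell length = 2 µm) |
| `B`, `C` | 3, 0.3 | — | enzyme benefit fold and cost scale |
| `tau` | 2e-3 | g/L | threshold calibration above |
| `R_E` | 0–2 | g/g/h | enzyme production rate range |

Domain defaults: 80 µm wide (periodic), 1 µm lattice, 40 cells seeded as
a near-confluent monolayer with biomass uniform in [0.55, 0.95] of the
division mass (desynchronizes the first division wave). The seeded
arrangement is drawn from the exact uniform-conditioned-on-no-overlap
distribution on the periodic line via normalized exponential gaps.

## Study designs and problem sizes

All headline studies run on the 80 µm domain with δ set via `G_bulk`
(unless a sweep varies `mu_max` or `D_G`), 10+ replicates per condition:

- **Regimes** (δ = 1, 2, 10): grown to 60 µm, so sectors coarsen well
  past the 20 µm neighborhood radius. Outputs: final segregation index,
  front roughness, tower-gap count.
- **Collapse** (δ = 2 via `G_bulk` / `mu_max` / `D_G` from the δ = 5
  baseline): grown to 60 µm; the three routes must agree within
  overlapping 95% t-intervals.
- **Competition** (B = 3, C = 0.3, R_E ∈ {0, 0.5, 1, 1.5, 2};
  δ = 10 vs 1): 1:1 mixtures grown to 50 µm; cooperator relative fitness
  per replicate.
- **Neutrality** (R_E = 0): identical strains; the relative-fitness CI
  must contain 1 and its between-replicate variance must grow as δ
  falls (founder effect).

These sizes are the package's own desk-scale choices; each battery runs
in minutes on one CPU.

## What this scale does and does not reproduce

The desk scale reproduces: the monotone δ-segregation relationship and
its collapse across parameter routes; rough, unstable fronts at δ = 1
(roughness grows exponentially with height under the physical shoving
rule); exploiter dominance in well-mixed groups; a peaked window of
enzyme production rates where cooperators beat exploiters under thin
active layers; and the founder-effect variance signature.

It does **not** reproduce fully developed towers separated by open gaps
within 60 µm of growth. The front instability at δ = 1 is real but slow
at these scales: with `h` only 2.5 cell diameters, discrete division
noise and shoving smooth perturbations at a rate comparable to their
growth, so while roughness rises steadily with height at δ = 1 (the
regime study measures it), amplitudes of order the film height — the
point where troughs starve and open gaps appear — require far taller
groups than the study battery simulates. Fully open inter-tower gaps,
and the additional boost they give cooperators by isolating enzyme
pockets between bulk sinks, therefore lie outside this scale: the
gap-count statistic reads 0 in the default regime study even at δ = 1,
where the fingering regime proper would require either much lower δ or
a much larger separation between `h`, the cell size and the domain.

## Degenerate inputs and numerical edges

Empty biomass makes the whole domain bulk; a stalled run (iteration cap
before the stop height) is flagged, not an error; extinction of a strain
yields a −∞ fitness sentinel; relative fitness is undefined (error) for
a non-growing reference strain; the segregation index excludes focal
cells with empty or fully inactive neighborhoods and errors only when no
focal cell remains. Solver non-convergence and relaxation
non-convergence raise with diagnostics rather than returning partial
fields. All randomness flows from a single `numpy` Generator per run;
identical (config, seed) reruns are bit-identical.
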