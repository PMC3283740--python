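# Methods

`pai1microenv` simulates how a growing tumor shapes its own microenvironment
through the cycle of a secreted matrix-binding protein — PAI-1 (Plasminogen
Activator Inhibitor type-1) — and how the resulting spatial pattern of
matrix-bound PAI-1 can switch individual cancer cells between mesenchymal and
amoeboid (blebbing) behavior. This note records the models, their
assumptions, the default parameters and why they were chosen, and the known
limitations.

## The lattice and the deposition cellular automaton

Space is a 2D square lattice with one site per cell diameter (10 µm nominal)
and one tick per minute. Concentrations are arbitrary units per site; the
experimental coat densities (µg/cm²) anchor only relative scale, so no
absolute concentration units are claimed.

Per tick, in fixed order:

1. **Growth** — Eden-type: every tumor cell with at least one empty Moore
   neighbor divides with probability `p_div` into a uniformly chosen empty
   Moore neighbor. Divisions resolve sequentially in RNG-shuffled order.
2. **Secretion** — every cell adds `sigma` units of soluble PAI-1 at its site.
3. **Diffusion** — explicit forward-Euler 5-point stencil with zero-flux
   boundaries, valid for `D·dt/h² ≤ 0.25`. Fluxes are exchanged pairwise, so
   total mass is conserved to rounding error, and the update is a convex
   combination, so extrema shrink monotonically.
4. **Deposition** — at every *cell-free* site, `min(k_on·c, c, capacity
   remaining)` moves from the soluble pool to matrix-bound *active* PAI-1.
   Matrix under a cell is unavailable: this is what localizes deposits to the
   periphery. Per-site binding capacity models vitronectin (VN), which
   stabilizes bound PAI-1 in its active conformation; the default capacity is
   effectively unlimited and a finite uniform or spatial profile is
   configurable.
5. **Latency decay** — a fraction `k_lat·dt` of bound active converts to
   bound latent per tick. The default `k_lat = ln 2 / 30 000` per tick gives a
   500-hour active half-life, the stability horizon of the engineered stable
   PAI-1 mutant used experimentally.

Defaults: `sigma = 1.0`, `D = 0.2`, `k_on = 0.2`, `p_div = 0.1`. `p_div` is
far above a biological division rate; it compresses the growth of a 500-cell
tumor into ~100–150 ticks so that whole-population studies over many seeds
remain cheap, while preserving the Eden growth universality class whose
boundary-history fluctuations drive the phenomenon of interest.

The mass ledger — cumulative secreted = soluble + bound active + bound
latent (+ consumed, in the agent-based model) — closes to ~1e-15 relative and
is checked after every study run.

**Deterministic disk control.** To show that peripheral heterogeneity comes
from stochastic growth history rather than from diffusion/deposition alone,
every stochastic run can be paired with a control that replays its exact
cell-count trajectory as deterministic quasi-disks (sites sorted by distance,
then angle, from the center). Under default rates the stochastic peripheral
coefficient of variation (~0.9) exceeds the disk control's (~0.36) in
essentially every seed pair.

## The mesenchymal–amoeboid switch

Single-cell state is a pair of dimensionless adhesion-engagement variables:
`I` (integrin-mediated, mesenchymal) and `P` (PAI-1-mediated, amoeboid),
driven by the local matrix-bound active PAI-1 concentration `C`:

    dI/dt = α_I · K^h/(K^h + C^h) · 1/(1 + P²) − µ·I
    dP/dt = α_P · C^h/(K^h + C^h) · 1/(1 + I²) − µ·P

Rising `C` gates integrin engagement off and PAI-1 engagement on (Hill
exponent `h`), and each variable represses the other's production — the
minimal mutual-antagonism motif that yields two stable states connected by
saddle-node bifurcations, i.e. a hysteretic cycle. A cell is labeled
amoeboid iff `P > I` (ties mesenchymal). The biochemical cascade behind the
amoeboid state (RhoA/ROCK1/MLC phosphorylation, PDK1 recruitment) is
deliberately abstracted into this two-variable system.

Defaults: `α_I = α_P = 6`, `h = 4`, `µ = 1`, `K = 6` concentration units.
Because the dynamics depend on `C` only through `C/K`, `K` is a pure scale:
it was set once so that the bistable window sits mid-range of the peripheral
concentrations the CA/ABM produce under their default rates (peripheral mean
≈ 4–5, peaks ≈ 12–30 at the 500-cell checkpoint). This is an explicit
calibration, not a biological measurement. With these defaults the static
bistable window is C ∈ [5.85, 6.15] and the quasi-static loop thresholds are
θ_up ≈ 6.2, θ_down ≈ 5.8.

Numerical notes:

- `steady_states` relaxes from a grid of initial conditions (explicit Euler,
  `dt·µ = 0.05·µ < 1`), polishes endpoints with a Newton solve, de-duplicates,
  and keeps points whose Jacobian passes the stability test (eigenvalues are
  `−µ ± sqrt(∂f/∂P·∂g/∂I)`, both real here). An independent closed-form
  oracle — the `dI/dt = 0` nullcline is explicit in `I(P)`, leaving a 1D
  bisection problem — agrees to ~1e-15.
- `sweep_hysteresis` integrates a triangular quasi-static schedule
  `0 → C_max → 0`. The quasi-static criterion is ≥ 50/µ time units per
  concentration unit; faster sweeps are allowed but flagged. Finite-rate
  sweeps overshoot the static saddle-nodes by the delayed-bifurcation lag
  (≈ rate^(−2/3)): ~0.13·K at the minimum rate, ~0.015·K at rate 2000/µ.
  The static window is always nested inside the dynamic loop; the
  reproducibility study checks nesting plus proximity ≤ 0.05·K at rate
  2000/µ.
- In this functional form the bistability is powered by the `1/(1+x²)`
  mutual antagonism, and *sharper* Hill gating narrows the window: the
  static width grows from 0.050·K at `h = 4` to 0.120·K at `h = 2`. The loop
  exists for every `h ≥ 2` at default gains.

**Threshold fitting.** `fit_thresholds` recovers the hysteresis thresholds
from an observed morphology time-course with known `C(t)` by scanning `K`
(the only scale parameter) on a log grid, minimizing the squared deviation
between the model-predicted and observed blebbing fraction, then sweeping
the fitted model. The objective is piecewise-constant in `K` between sampled
flip times, so the near-optimal plateau's log-centroid is reported, with the
plateau itself as the interval; a flat landscape (schedule never crossing a
threshold) is flagged non-identifiable. Recovery from multinomial-noise
time-courses of 500 cells is better than 1% in the reproducibility study —
the thresholds scale exactly with `K`, so threshold error equals `K` error.

## The agent-based model

Agents are tumor cells carrying the switch, coupled to the shared fields.
Per tick, fixed order: proliferation (mesenchymal only, Eden rule,
`p_div_mes = 0.1`) → secretion → diffusion → deposition → per-cell switch
update from the bound-active concentration at the cell's own site (5 Euler
substeps of 0.2/µ per tick) → movement → consumption → proteolysis → latency
decay. Agent iteration order is shuffled every tick; a single seeded RNG
makes event logs byte-identical across repeats.

- **Consumption** (`k_int = 0.5`/tick): an amoeboid cell with available uPAR
  internalizes up to `k_int` of the bound-active PAI-1 at its site via
  [uPAR:uPA:PAI-1] complexes; the mass leaves the system (lysosomal
  degradation; receptor recycling abstracted away). Mesenchymal cells never
  consume (contract-checked).
- **Proteolysis** (`k_prot = 0.005`/tick): mesenchymal cells degrade matrix
  integrity at their site; amoeboid migration needs no pericellular
  proteolysis, so amoeboid agents never proteolyse (contract-checked).
- **Movement**: amoeboid cells greedily ascend the bound-active field (step
  onto the empty Moore neighbor with the highest bound-active PAI-1, ties
  random) with probability 0.04 per tick — 0.4 µm/min over 10 µm sites at
  1-minute ticks, the one measured kinematic number. Mesenchymal cells step
  at most once per tick, and only onto matrix whose integrity has been
  proteolysed below 0.5.
- **Escape**: an amoeboid cell whose distance from the nearest mesenchymal
  cell exceeds 3 sites is logged as escaped (once per agent).

The default run grows a single cell for 250 ticks on a 72×72 grid
(~2 500–4 000 cells). Two emergent properties are the model's point:

- **Hiving cycles**: a cell meeting a high-PAI-1 spot flips (MAT), consumes
  the spot down through θ_down, and reverts (AMT). With consumption disabled
  the reversal never occurs — the cycle *requires* consumption.
- **Minority amoeboid population**: under default parameters the
  instantaneous amoeboid fraction peaks at ~0.1–0.3 early (the first
  deposition wave) and settles near ~0.1, self-regulated by consumption; it
  never approaches one half. The exact fraction is parameter-dependent and
  is reported by the reproducibility studies rather than asserted against
  any external number.

## Peripheral spatial statistics

The periphery is the set of cell-free sites 4-adjacent to the tumor, ordered
into a closed counterclockwise chain starting at the lexicographically
smallest site. Ordering assigns each site the arclength position of its
nearest point on the subpixel 0.5-contour of the 4-dilated mask — robust on
ragged stochastically-grown boundaries, where a purely graph-based
Moore-neighbor walk can cut corners at diagonal pinches. Interior holes are
excluded: the periphery is the outer rim.

- **Curvature**: the chain coordinates are smoothed with a circular Gaussian
  (σ = window/2, default window 5) and the turning angle is taken at each
  vertex of the smoothed polygon; convex bulges positive, invaginations
  negative. The closed-cycle identity (turning angles sum to 2π) is checked
  on the smoothed polygon. Smoothing the coordinates rather than the raw
  turning angles is essential on lattice chains: boxcar-smoothed raw angles
  mis-count the invaginations of synthetic lobed masks, while
  coordinate-smoothing recovers exactly `n_lobes` negative arcs across all
  tested radii, depths and windows.
- **Spots**: maximal wraparound runs of boundary sites with concentration at
  or above a threshold; the default threshold is θ_up of the active switch
  parameters, so "spot" operationally means "a stretch of periphery where a
  mesenchymal cell would undergo MAT".
- **Heterogeneity**: population CV, Gini coefficient, peak/mean, and the
  boundary fraction inside spots; all zero-safe.
- **Invagination association**: Spearman rank correlation between peripheral
  concentration and *negated* curvature, with a cyclic-shift permutation
  null (999 shifts drawn uniformly from 1..n−1) that preserves both
  sequences' autocorrelation — free shuffling would inflate significance on
  these strongly autocorrelated profiles. Type-I error at nominal 0.05 is
  0.045–0.055 on independent-noise profiles over realistic curvature
  sequences; profiles with massively tied curvature (perfect disks) make the
  test conservative.

The lobed-vs-disk study grows each seed mask (radius 16; lobed: 4 lobes,
depth 0.5) stochastically for 50 ticks at `p_div = 0.005` before measuring
the association. The short growth phase individualizes the geometry per
seed; longer or faster growth progressively fills the invaginations (Eden
growth smooths concavities) and erases the effect, which is itself the
expected physics.

## Image quantification

Intensities live on a 0–1000 working scale with significance threshold 100
and background 25; other bit depths are linearly rescaled onto this scale
before thresholding, and "positive" means intensity ≥ threshold (inclusive).
Colocalization percentages are per channel: colocalized pixels over that
channel's positives, ×100, optionally restricted to an ROI. Line profiles
sample the rasterized segment by nearest-pixel stepping, averaged across
`width` parallel offset lines. z-profiles count stained pixels per slice
from the substrate upward; the basal fraction uses the lower half of the
slices (first `n//2`; for odd counts the middle slice goes to the upper
half).

## Synthetic data

Every generator emits a `GenRecord` (name, parameters, seed, ground truth)
sufficient to regenerate the dataset bit-exactly.

- **Tumor masks**: discretized disks, or lobed shapes with radius modulated
  as `r(φ) = R·(1 − depth·(1 + cos(n·φ))/2)` giving `n` concave
  invaginations.
- **Colocalization pairs**: `⌊f·n_pos⌋` shared positive pixels plus disjoint
  per-channel remainders; positives uniform in [threshold, 1000], the rest
  uniform below background.
- **z-stacks**: positives assigned basal vs upper at `ratio : 1` per pixel,
  uniformly within halves, so the realized basal fraction is binomial around
  `ratio/(1+ratio)`.
- **Morphology time-courses**: `n_cells` switch trajectories along a
  concentration schedule, emitted into the three observable classes —
  amoeboid → blebbing with probability 0.9, mesenchymal → spindle with 0.9,
  remainder round (the ambiguous/transition class; three observed classes,
  two model states, reconciled by an explicit emission layer). Per-time-point
  counts are sampled per cell, or returned as expectations with
  `sample=False`.

What the generators do *not* emulate: optics (point-spread functions, noise
spectra of real microscopes), segmentation errors, 3D tumor geometry, or any
biochemical heterogeneity between cells beyond the state noise term. Passing
the ground-truth recovery tests therefore demonstrates the correctness of the
quantification arithmetic and the estimation procedure, not robustness to
real acquisition artifacts.

## Reproducibility studies and problem sizes

`pai1microenv.studies` packages the headline claims as self-contained
studies, each deterministic given a seed: 50 random-rate mass-ledger runs on
48² grids; 50 seed-pairs of 500-cell CA runs with matched disk controls on
64² grids; 30 lobed/disk pairs; the window/loop/nullcline comparison (2000
point bisection grid, 21 concentrations); 100 hiving seeds (400 ticks each,
21² grid); 20 default ABM runs (250 ticks, 72²); 100 random oracle instances
per operation; 20 threshold-recovery fits; 200 permutation-calibration
replicates. These sizes keep a full pass of all studies to roughly 1.5
minutes on one CPU while leaving comfortable statistical margins; all are
arguments, so larger replications are one call away.

## Known limitations

- 2D only; no nutrient limitation, death, or mechanical pushing; tumors are
  simply-connected in intent but stochastic growth can transiently enclose
  lakes, which the periphery statistics ignore by construction.
- The switch ODE is a minimal realization of a two-state cartoon, not a
  fitted biochemical model; its parameters (and hence θ_up, θ_down) are
  calibration constants on an arbitrary concentration scale.
- The coupling of each agent to the switch through its own-site bound-active
  concentration is this package's integration choice; alternative couplings
  (neighborhood averages, membrane-contact kernels) are untested.
- Soluble PAI-1 has no signaling role (deposition only), mirroring the
  experimental observation that soluble PAI-1 does not support blebbing.
- Division is restricted to mesenchymal cells and movement of mesenchymal
  cells to proteolysed paths; both are configurable simplifications that
  sharpen the migration/proliferation dichotomy rather than measured facts.
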