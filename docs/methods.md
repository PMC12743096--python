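# Methods

## Model overview and assumptions

`fibreguide` simulates collective cell invasion as a hybrid system: cells
are discrete overdamped point agents; the collagen bed is a continuum
field of symmetric positive-semi-definite 2×2 orientation tensors
discretised on a uniform periodic grid.  The core assumptions:

* **Overdamped motion.** Inertia is neglected; velocity equals the sum of
  a stochastic motility term and pairwise forces, reoriented by contact
  guidance.
* **Guidance changes direction only.** The guidance operator is applied
  as a length-preserving map: the product `M b` is rescaled back to
  `|b|`, so aligned collagen never changes cell speed, only heading.
* **Bidirectional fibres.** Fibres have orientation but no polarity.
  Orientation tensors are invariant under `v → −v`; all angular
  statistics live in `[0°, 180°)` and guidance response curves are
  symmetric about 90°.
* **Point cells with finite-size interactions.** Cell size enters only
  through the pairwise potential (volume exclusion below `2^{1/6}σ`,
  adhesion out to `r_max = 3σ`) and the remodelling kernel radius `σ/2`.
* **Local remodelling.** A cell only affects fibres within `σ/2` of its
  centre, weighted by a linear tent kernel; secretion is rank-1 along
  the cell's time-averaged direction of motion and throttled by the free
  area fraction `1 − λ1 − λ2`; degradation is first-order in `Ω`.
* **No cell death**, no fibre mechanics (stretch, stiffness), no
  chemotaxis, and a single collagen species.

## Parameters

Defaults (all tunable through `ModelParams` or TOML configs):

| symbol | meaning | default | units |
|---|---|---|---|
| `D` | cell diffusion coefficient | 0.3 | µm²/min |
| `epsilon` | pairwise interaction magnitude | 0.1 | µm²/min |
| `sigma` | cell diameter | 12 | µm |
| `F0` | repulsion cap | 2.4 | µm/min |
| `r_max` | interaction cutoff (`3σ`) | 36 | µm |
| `Delta0` | uncrowded cell-cycle length | 1440 | min |
| `lambda_bar` | half-maximal guidance fraction | 0.4 | – |
| `gamma` | guidance switch steepness | 10 | – |
| `m` | velocity-averaging (memory) window | 300 | min |
| `s`, `d` | secretion / degradation rate per cell | 0 | 1/min |
| `dt` | time step | 1 | min |
| `delta` | fibre-grid spacing | 2 | µm |
| `domain_length` | periodic square side | 360 (large preset: 540) | µm |

The two domain presets are 360 µm (60 h horizon) and 540 µm (96 h
horizon).  The degradation step requires `d·dt < 1`; `ModelParams`
rejects configurations violating it up front, and the remodelling update
additionally aborts if the *kernel-summed* per-node rate `d·dt·Σᵢωᵢ`
reaches 1 (many stacked cells).

## Numerical scheme

Forward Euler with `Δt = 1` min.  Per step, in this order:

1. draw motility kicks `ξ` and evaluate pairwise forces from the state
   at `t`;
2. sample the fibre tensor at each cell centre (periodic bilinear
   interpolation, each component independently) and build the guidance
   operator from the spectrally normalised tensor;
3. update all positions synchronously, `X ← X + Δt·M̂[ξ + ΣF]`;
4. remodel the fibre grid from the updated positions and the averaged
   velocity directions (window `m' = min(m, t − birth)`, evaluated on
   unwrapped positions so periodic crossings cannot flip directions —
   the time-average of the velocity collapses to the endpoint
   difference, so no further quadrature is involved);
5. run the proliferation sweep over the cells present at its start
   (daughters cannot divide in their birth step).

### Randomness

One `numpy` Generator per simulation, seeded from the configuration.
Draw order within a step is fixed: (1) the `2N` motility normals,
(2) one kick angle per coincident pair (ascending pair order),
(3) `N` division uniforms, (4) one placement angle per divider
(ascending cell id).  Identical configuration + seed therefore
reproduces output byte-for-byte, including the HDF5 field snapshots
(written with timestamp tracking disabled).

### Tie-breaks and degenerate inputs

* Isotropic tensors (`λ1 = λ2`): the major eigenvector reports as
  `(1, 0)`; immaterial, since the guidance operator reduces to the
  identity there.
* Empty tensor (`λ1 = 0`): anisotropy defined as 0, normalised tensor
  as the identity (no directional cue).  The alternative trace
  normalisation `Ω/(λ1+λ2)` is available via
  `guidance_normalisation = "trace"`; the spectral form is the default
  because it reduces exactly to the identity in the isotropic limit.
* Coincident cells (separation < 1e−9 µm, possible straight after
  division): the pair force direction is undefined, so the pair gets a
  shared random unit vector with magnitude `F0`, applied
  equal-and-opposite (momentum-free).
* `M·b = 0` with `b ≠ 0` (fully aligned rank-1 tensor, `b` exactly
  perpendicular): the cell does not move that step (measure-zero event).
* Cells with zero average displacement (or newborns) have no secretion
  direction and secrete nothing; they still degrade.
* Eigenvalues within 1e−9 below zero (floating-point drift) are clamped
  to 0; forward-Euler secretion can overshoot trace 1 because the free
  fraction is evaluated at the step start, so overshooting nodes are
  rescaled by `1/trace`, preserving orientation.
* Neighbour counting uses a closed boundary (`≤ 2^{1/6}σ`, with 1e−9 µm
  slack so exact lattice spacings count).

### Design choices that were genuinely open

* **Motility variance per component.** The stochastic kick applies
  variance `2D/Δt` to each component, giving the two-dimensional
  free-diffusion law MSD `= 4Dt` (verified to <5% in the tests).
* **Single guidance application.** Guidance acts once on the combined
  vector `ξ + ΣF`, not separately per term.
* **Repulsion-only cap.** `min{F, F0}` caps only the (positive)
  repulsive branch; adhesive magnitudes are negative and unaffected.
* **Kernel quadrature.** The tent kernel is evaluated at node centres
  (no sub-node quadrature); at the default spacing it spans 3 nodes.
  Reported dynamics are insensitive to the kernel's precise form.
* **Free-space factor timing.** `1 − λ1 − λ2` is evaluated at the step
  start for all cells jointly (the alternative — re-evaluating within a
  step as contributions accumulate — differs only at O(Δt²)).

## Initial conditions and presets

All initial conditions are generated programmatically.  Cells start as
a confluent hexagonally packed disc at the domain centre with the
zero-force spacing `2^{1/6}σ` (no initial force transient); the fibre
bed is either empty or spatially uniform with prescribed total fraction,
anisotropy and major angle (`λ1 = total/(2 − a)`, `λ2 = λ1(1 − a)`).
The named presets (`fig2` … `fig6`) bundle the experiment
parameterisations: de-novo secretion on an empty large domain
(`s = 0.025`, `d = 0.0025` /min); a non-remodelling phenotype on dense
aligned beds; degradation-only and secretion-only phenotypes; the
secretion/degradation sweep bed (total 0.5, anisotropy 0.9, vertical);
and a phenotype showcase on a near-empty isotropic bed.  Where a
published experiment's nonzero companion rate is not printed (the
degrading/secreting phenotype panels), the presets default to the
"large" rate of the sweep grid, `2^-4` /min, and accept overrides.

### What the generated data does and does not emulate

The synthetic initial states capture the study conditions — cell count,
packing, bed density/anisotropy/orientation — but idealise reality:
perfectly uniform beds, perfectly hexagonal confluence, a strictly
two-dimensional geometry, and point cells.  Passing tests therefore
validate the model's internal laws and its qualitative invasion
signatures, not agreement with any particular experimental microscopy
data.

## Analysis conventions

* Density profiles: histogram of x-coordinates (projection averages over
  y), default bin width `σ = 12` µm; bin widths not dividing the domain
  are snapped to the nearest divisor with a warning.
* Jensen–Shannon distance: base-2 logarithms, so values lie in [0, 1].
* Nodes with trace < 0.01 are treated as devoid of collagen:
  orientation and anisotropy are undefined and excluded from ring and
  region statistics.  Ring width defaults to `2δ = 4` µm.
* The L/R/T/B regions are quadrant sectors bounded by the domain
  diagonals through the centre (configurable via `region_masks`).
* The secretion/degradation sweep compares each `(s, d)` run with a
  `d = 0` reference sharing the same seed, averaging the JSD over
  repetitions (default 3); an independent-seed mode exists.  Two caveats
  discovered while characterising the sweep: (i) matched seeds do not
  suppress realisation noise at long horizons — trajectories decorrelate
  chaotically, leaving a JSD floor of ≈0.14 for ~400 cells in 30 bins;
  (ii) under a quasi-static colony the node trace relaxes to the balance
  `λ1+λ2 → s/(s+d)`, so when degradation exceeds secretion by much more
  than `λ̄/(1−λ̄)` the local bed falls below the guidance switch and
  invasion becomes isotropic regardless of the initial bed.  The
  reported critical secretion rate (smallest `s` whose JSD stays below
  threshold for all tested `d`) should be read with both effects in
  mind.

## Problem sizes used in the test suite

Unit and property tests run at desk scale (single cells to a few dozen,
hundreds of steps).  The behavioural checks use: 500 cells × 500 steps
for the free-diffusion law; 10⁵ Monte-Carlo sweeps for the proliferation
rate; one 42-hour large-domain run for the de-novo alignment profile;
10 repetitions × 2 bed densities for the horizontal-restriction check;
and the full 7 × 3 rate grid × 3 repetitions (with matched references)
for the sweep.  These sizes were chosen so the whole suite completes in
minutes while keeping each statistical assertion at ≥3 standard errors
of resolution.

## Known limitations

* Two-dimensional only; no fibre reorientation by cell-exerted force,
  no matrix mechanics, no collagen maturation or subtypes.
* Forward Euler is first-order: halving `Δt` changes individual
  trajectories (chaos) though not the statistical signatures.
* The proliferation rule is a coarse crowding model (hexagonal packing
  cap of six neighbours), not a cell-cycle model.
* The sweep's critical-rate readout depends on the JSD noise floor of
  the chosen binning and population size (see above).
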