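# Methods

## The model

A biofilm colony is represented as an expanding disc of fixed height with
radial symmetry: an active-fluid description in which local biomass
production sources a velocity field through a continuity constraint, and
that flow — not motility — drives collective expansion. At radius `r` and
time `t` the biomass is partitioned into a cell fraction `ρ1(r,t)` and a
spore fraction `ρ2(r,t) = 1 − ρ1`; a dimensionless nutrient field `n(r,t)`
(normalised so the initial uniform concentration is 1) diffuses over the
whole dish and is consumed under the biofilm. Cells grow at a Monod rate
and convert irreversibly to spores at a repressive-Hill rate:

    g(n) = g·n / (n + n_g)                 (growth, 1/hr)
    k(n) = k0·n_k^h / (n_k^h + n^h)        (sporulation, 1/hr)

With `n_g = 1` and `n_k = 0.03 ≪ 1`, growth and sporulation occupy
mutually exclusive nutrient regimes: where growth is half-maximal,
sporulation is off by a factor ~10⁻⁶; where sporulation is half-maximal,
growth is below 3% of maximum.

New cellular biomass contributes to radial expansion at rate `ϕ·g(n)`,
where `0 ≤ ϕ ≤ 1` converts biomass production into in-plane spreading
(the model's proxy for matrix effects such as poly-γ-glutamic acid, which
slows spreading). The transport system on the dish `[0, L]` with biofilm
boundary `R(t)`:

    ∂ρ1/∂t + (1/r)∂(r·v·ρ1)/∂r = ϕ·g(n)·ρ1 − k(n)·ρ1
    ∂ρ2/∂t + (1/r)∂(r·v·ρ2)/∂r = k(n)·ρ1
    ∂n/∂t  = D·(1/r)∂(r·∂n/∂r)/∂r − γ·g(n)·ρ1
    (1/r)∂(r·v)/∂r = ϕ·g(n)·ρ1,  v(0) = 0

The continuity closure for `v` is the unique choice under which
`ρ1 + ρ2 = 1` is preserved inside the biofilm given these sources. Biomass
is confined within `R`, which moves with the local flow,
`dR/dt = v(R)`; nutrients cross the biofilm boundary freely. Nutrient
consumption is yield-style (`γ` multiplies the realised growth activity
`g(n)·ρ1`): consumption should track what is actually being built.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| g | max growth rate | 1 | 1/hr |
| n_g | Monod half-saturation | 1 | – |
| k0 | max sporulation rate | 10 | 1/hr |
| n_k | Hill half-repression level | 0.03 | – |
| h | Hill exponent | 4 | – |
| γ | nutrient consumed per growth activity | 4 | 1/hr scale |
| ϕ | biomass-to-expansion efficiency | 0.3 | – |
| D | nutrient diffusivity | 300 (= 1.08×10⁶ µm²/hr) | µm²/s |
| R0 | inoculum radius | 1140 | µm |
| L | dish radius | 7800 | µm |

The defaults are the printed parameterization of the study system; `k0=10`
with `ϕ=0.3` is the calibration representing highly sporulating,
PGA-producing strains. `ϕ` and `k0` are the knobs swept in experiments.

## Numerical solution

Cell-centered grid on `[0, L]` (first node at `dr/2`; `dr = 5 µm`, 1560
nodes), fixed time step `dt = 2×10⁻³ hr`, operator splitting per step:

1. **Local reactions + continuity dilution** (explicit Euler, all terms
   evaluated on the pre-step fields). The transport equations are advanced
   in advective (non-conservative) form,
   `∂ρ/∂t + v·∂ρ/∂r = source − ρ·div(v)`, with
   `div(v) = ϕ·g(n)·ρ1` substituted *pointwise*. A uniform `ρ1 + ρ2` is
   then an exact fixed point of the discrete update: the partition holds to
   round-off (~10⁻¹⁴ over a 66-hr run) instead of accumulating splitting
   error, which is why this form was chosen over a conservative flux
   scheme (whose reaction/divergence mismatch relaxes the sum to a
   steady O(dt) offset).
2. **Advection**: first-order upwind differences of both fractions,
   restricted to nodes inside the biofilm (`v ≥ 0` always; CFL is checked
   each step and is ≈0.1–0.25 at the defaults).
3. **Nutrient diffusion**: backward-Euler finite-volume solve of the
   cylindrical Laplacian over the full dish with zero-flux walls at `r=0`
   and `r=L` (the axis face has zero area, so no special casing). The
   implicit solve makes `D = 1.08×10⁶ µm²/hr` impose no time-step limit,
   conserves cylindrical nutrient mass to round-off, and reproduces planar
   heat-kernel spreading (variance growth `2·D·τ`) to <0.1% on the test
   geometry.
4. **Boundary motion**: `R ← R + dt·v(R)` with `v(R)` linearly
   interpolated. A node newly engulfed by the boundary inherits the
   composition of its inward neighbour.

`v(r)` is the cumulative trapezoid of `r·ϕ·g(n)·ρ1` divided by `r`
(anchored analytically at `r = 0`); it is reported as 0 beyond `R`, where
no biomass exists. The solver refuses `dt·k0 > 0.5` (explicit reaction
stability) and aborts with a diagnostic on non-finite or negative fields.
The model is deterministic: identical parameters give bitwise identical
runs. Halving `dr` changes `R(t_end)` by <0.1% at the 20-hr test horizon;
the spore fraction at 18 hr moves by <0.01 points under simultaneous
`dr/2, dt/2` refinement.

Degenerate inputs: `ϕ=0` gives zero flow and a fixed boundary; `k0=0`
gives no spores and (at `ϕ=0.3`) a final radius within ~3% of the
sporulating run — sporulation is spatially offset from the growing edge
and so barely feeds back on expansion.

## Observables

* **Bulk spore percentage**: `100·∫ρ2·r·dr / ∫(ρ1+ρ2)·r·dr` over `r ≤ R`.
* **Leading edge**: `R(t)`; instantaneous velocities are centered finite
  differences smoothed with a 1-hr boxcar (the first sample is set to 0).
  The boxcar realises "change in radius within a 1-hour window" exactly
  and is trivially testable; the window is a parameter.
* **Sporulation front**: per snapshot, the most distal radius where the
  sporulation flux `k(n)·ρ1` reaches 75% of its maximum, with sub-grid
  linear interpolation on the descending limb. Snapshots with zero flux
  (e.g. `k0=0`) have no front and are skipped.
* **Cell region**: `{r ≤ R : ρ1 ≥ 0.5}`, summarised as `[min, max]`; its
  width narrows over time as sporulation consumes the trailing edge.
* **Velocity-ratio curve**: radial bins of 25 µm (≈5 grid cells, to
  suppress discretization noise); for each bin both fronts visited, the
  instantaneous velocity each front had at its *first* crossing of the bin
  (first crossing wins when numerical jitter recrosses); ratio =
  front / expansion, reported only where the expansion velocity is
  positive. Ratios pooled over the seven-value ϕ sweep
  {0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0} — chosen once to span slow to fast
  expansion — give the headline asymmetry: ratios up to ~6 at the slowest
  expansion velocities, ~0.9 in the top velocity decile. Pooling is
  per-position (each bin contributes the ratio measured where the fronts
  crossed it), not per-time.
* **Trajectory overlay**: the best time shift mapping the front trajectory
  onto the edge trajectory, found by grid search on the snapshot interval;
  only front samples at positions ≥ R0 are compared, i.e. biomass formed
  by outward spreading — the wave first ignites in interior biomass the
  edge never occupied, and that segment is not part of the overlay claim.

## Synthetic imaging phantom

`render_stack` turns a run into two-channel (T, Z, Y, X) uint16 stacks on
a strip oriented along the radius (biofilm center at the left edge of the
image): a constitutive channel `∝ ρ1 + 0.15·ρ2` (residual reporter left in
sporulated biomass), and a sporulation channel proportional to the flux
`k(n)·ρ1` normalised by its maximum over the run, attenuated to 10% in the
4 µm of biomass adjacent to the substrate. The biofilm is a hard disc of
radius `R(t)` and height 40 µm. Default geometry mirrors a 25x
acquisition: 1.43 µm pixels, 1.34 µm z-interval, 90-minute frames.
`add_background_and_noise` adds a bright substrate-air plane beyond the
edge (median 800/300 counts for the constitutive/sporulation channel,
Gaussian spread 30), Poisson shot noise and Gaussian read noise,
deterministically for a given seed; the realised background median and MAD
enter the ground-truth table.

The phantom deliberately omits optics (PSF, depth attenuation),
photobleaching, reporter maturation/dilution kinetics and cell-scale
texture. Passing recovery tests therefore demonstrates that the
quantification chain is unbiased against geometry, background and noise of
realistic magnitude — not that it would be unbiased against optical
artifacts absent from the phantom.

## Image quantification

Per timepoint, thresholds are `median + n·MAD` of a substrate ROI placed
20 µm beyond the leading edge on the maximum-intensity z-projection
(n = 4/4 at 40×40 µm for 25x-class data; n = 2/1 at 70×100 µm for
10x-class). The ROI is placed from a coarse half-maximum edge estimate of
the *same* frame: a simulated edge can advance more than the ROI offset
within one frame interval, so chaining the previous frame's measurement
would park the ROI on biomass. Projections aggregate only
threshold-passing voxels. Cross-sections average `ceil(40 µm/pixel)`
transverse pixels (28 px at 1.43 µm, 12 px at 3.58 µm). Ratio profiles
average sporulation/constitutive voxel ratios over dual-positive voxels in
1-pixel radial bins, clipped at the measured edge (isolated noise-passing
substrate voxels otherwise contaminate the profile tail), then smoothed
with a 10 µm Gaussian. The leading edge is the most distal radial-profile
position above threshold after a deliberately narrow 2 µm smoothing
(wider kernels blur the edge outward by ~0.5σ). The vegetative front uses
`scipy.signal.find_peaks` with a 10% prominence floor; its inner boundary
is the peak's left base. The measured sporulation front applies the same
75%-of-maximum rule to the smoothed ratio profile.

Two-phase fits of position-time curves exhaustively test every interior
sample as a continuous two-segment breakpoint and prefer a single line
unless BIC (2 vs 4 parameters) favours the split. Velocity comparison
refines both position series 4-fold by linear interpolation before taking
finite differences, and excludes positions beyond the distal boundary:
the two-phase inflection of the edge curve and, if the measured front
transiently regresses during its outward sweep, the last position before
retrograde movement. Regressions before the front's global minimum (the
initial interior ignition of the wave) are not treated as tracking
artifacts.

### What "recovery" means here

Ground truth for the leading edge is `R(t)`; the pipeline recovers it to
<1 px (median). For the sporulation front, the flux-based front and the
ratio-based measurand are *different observables*: the ratio's
denominator (`ρ1 + 0.15·ρ2`) rises steeply across the cell front, so the
ratio profile descends faster than the flux profile and its 75% point
sits systematically ~100–200 µm interior to the flux front. The recovery
test therefore compares the pipeline on the noisy stack against the same
measurement on the noiseless stack (same thresholds) — the well-posed
noise/background robustness question, recovered to <1 px median — while
the flux-based truth is kept in the ground-truth table and checked for
trajectory consistency with the observables module.

## Problem sizes

Tests and the acceptance script run the full printed geometry (1560-node
grid, 33,000 steps for a 66-hr run; ~5 s per run): seven 66-hr runs for
the ratio sweep, one extra 66-hr run at `k0=0`, a 20-hr pair for grid
refinement, and one 40-hr run rendered to a 25-frame, 30-plane stack for
the imaging pipeline. Synthetic-imaging unit tests use a scaled phantom
(R0 = 300 µm dish) purely to keep rendering fast; all acceptance-level
imaging checks use the default model geometry.

## Known limitations

* The milestones of the high-sporulation calibration land at 28.1% spores
  (18 hr) and 89.5% (66 hr) — within ~2 points of the ~30%/~90%
  experimental CFU levels, and converged in grid and time step; the model
  approaches but does not exactly hit the experimental percentages.
* First-order upwind advection smears the cell front over a few grid
  cells; front positions are still converged to <0.1% in `R` at `dr/2`.
* The coffee-stain initial condition allows `ρ1 + ρ2 < 1` (unoccupied
  volume) in the patchy interior; growth dilution relaxes the sum toward 1.
  The partition invariant applies to the standard uniform-disc start.
* No vertical structure, mechanics, osmotic spreading or explicit matrix
  species: `ϕ` is the sole morphogenesis knob.
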