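# sporefront

Active-fluid modeling and confocal-timelapse quantification of sporulation
waves in expanding *Bacillus subtilis* biofilm colonies.

In density-sensing strains, sporulation begins early in biofilm growth and
sweeps through the colony as a wave, while radial expansion is sustained
by a narrow front of vegetative cells at the edge. This package is for
quantitative microbiologists and biophysicists who want to (i) simulate
that feedback between collective expansion and single-cell differentiation
and (ii) run the matching image-quantification chain on two-channel
confocal stacks — real or synthetic.

## The model

A biofilm is an expanding disc of fixed height with cell fraction ρ₁,
spore fraction ρ₂ = 1 − ρ₁ and a freely diffusing nutrient n. Growth
follows a Monod law, sporulation a repressive Hill law, and new biomass
drives radial flow through a continuity constraint — the hallmark of an
active fluid:

    ∂ρ₁/∂t + (1/r)∂(r v ρ₁)/∂r = ϕ g(n) ρ₁ − k(n) ρ₁
    ∂ρ₂/∂t + (1/r)∂(r v ρ₂)/∂r = k(n) ρ₁
    ∂n/∂t  = D ∇²n − γ g(n) ρ₁
    (1/r)∂(r v)/∂r = ϕ g(n) ρ₁

with g(n) = g·n/(n+n_g), k(n) = k₀·n_k^h/(n_k^h+n^h), and ϕ ≤ 1 the
efficiency converting biomass production into spreading (a proxy for
matrix polymers such as PGA that slow expansion). Defaults: g = 1/hr,
n_g = 1, γ = 4, k₀ = 10/hr, n_k = 0.03, h = 4, D = 300 µm²/s,
R₀ = 1.14 mm, L = 7.8 mm. See `docs/methods.md` for the numerics.

The companion modules cover the rest of the workflow:

* `sporefront.observables` — bulk spore percentage, leading-edge and
  sporulation-flux-front trajectories, 1-hr-smoothed instantaneous
  velocities, per-position velocity-ratio curves.
* `sporefront.imaging` — synthetic two-channel confocal stacks (TIFF +
  JSON sidecar) rendered from runs, with background/noise and ground
  truth, so the pipeline is testable without microscopy data.
* `sporefront.quantify` — median+n×MAD thresholding, thresholded
  z-projections, cross-sections, YFP/mSc radial ratio profiles,
  vegetative-front and 75%-of-max sporulation-front extraction,
  parsimonious two-phase linear fits, velocity-ratio comparison.
* `sporefront.pipeline` / the `sporefront` CLI — end-to-end experiment
  drivers (`simulate`, `observe`, `make-synthetic`, `quantify`,
  `reproduce`).

## Worked example

```python
from sporefront import ModelParams, run_simulation
from sporefront.observables import (bulk_spore_percentage, leading_edge,
                                    sporulation_front, velocity_ratio_curve,
                                    trajectory_overlay_rms)

params = ModelParams()          # k0=10/hr, phi=0.3, printed defaults
run = run_simulation(params)    # ~5 s: 1560-node grid, 33,000 steps

print(f"final radius R(66 hr)      : {run.snapshots[-1].R:.0f} um")
print(f"bulk spores at 18 hr       : {bulk_spore_percentage(run.state_at(18)):.1f} %")
print(f"bulk spores at 66 hr       : {bulk_spore_percentage(run.state_at(66)):.1f} %")

edge = leading_edge(run)
front = sporulation_front(run)
mv, sv = edge.mean_velocity()
print(f"mean expansion velocity    : {mv:.1f} +/- {sv:.1f} um/hr")

lag, rms = trajectory_overlay_rms(edge, front)
print(f"wave-vs-edge overlay       : lag {lag:.1f} hr, RMS {rms:.0f} um")

curve = velocity_ratio_curve(edge, front)
print(f"velocity ratio range       : {curve.ratio.min():.2f} - {curve.ratio.max():.2f}")
```

prints

```
final radius R(66 hr)      : 2251 um
bulk spores at 18 hr       : 28.1 %
bulk spores at 66 hr       : 89.5 %
mean expansion velocity    : 16.8 +/- 12.2 um/hr
wave-vs-edge overlay       : lag 14.0 hr, RMS 104 um
velocity ratio range       : 0.61 - 2.59
```

Reading: the colony doubles its radius over 66 hr while its interior
converts almost entirely to spores (28% by 18 hr, 90% by 66 hr). The
sporulation wave retraces the leading edge's trajectory with a ~14 hr
delay and only ~100 µm RMS mismatch, and within this single run the wave
moves between 0.6× and 2.6× the speed the edge had at the same positions.
Sweeping ϕ from 0.05 to 1.0 and pooling those per-position ratios (the
`ratio_sweep` experiment) shows the asymmetry: slow-expanding colonies
experience sporulation waves several-fold faster than their edges, while
fast expanders keep the two nearly matched.

The same comparison from images instead of model fields:

```sh
sporefront make-synthetic --seed 7 --out stacks/
sporefront quantify --stacks stacks/ --out measurements/
```

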