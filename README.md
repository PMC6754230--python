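# kip2traffic

Model-based analysis of kinesin **Kip2** traffic on yeast astral
microtubules.  In budding yeast, Kip2 decorates cytoplasmic microtubules
*uniformly* along the shaft with a plus-end accumulation, independent of
microtubule length — unlike the length-dependent "antenna" pattern of
lattice-binding kinesins such as Kip3.  This package implements the
transport model that explains that pattern, the statistics used to
quantify the underlying microscopy tables, and the likelihood machinery
that estimates the motor's kinetic parameters from binned fluorescence
profiles.

It is written for quantitative cell biologists and modellers who want to
simulate, fit, or re-analyze SPB-aligned fluorescence profiles of
plus-end-directed motors.

## The model

A microtubule is a 1-D lattice of N sites (8 nm per tubulin dimer), its
minus end anchored at the spindle pole body (SPB).  Free motor at
concentration [Kip2]free enters in two ways and obeys exclusion (one
motor per site):

- minus-end loading onto site 1 at rate r_in = k_in·[Kip2]free (if free),
- lattice landing on any free site at rate r_on = k_on·[Kip2]free,
- detachment from the lattice at rate k_off (sites 1..N−1),
- stepping toward the plus end at rate k_step if the next site is free,
- detachment from the plus-end site at its own rate k_out,
- optionally a finite (closed) cytoplasmic pool, so that
  [Kip2]free ≤ [Kip2]total by conservation.

This is a totally asymmetric simple exclusion process with Langmuir
kinetics plus a dedicated minus-end entry channel.  Its key analytic
property: a *flat* shaft profile arises essentially only when all motor is
recruited at the minus end (k_on = 0) with no lattice unbinding
(k_off = 0), where the uniform interior density is r_in/k_step.  A
landing-dominated motor (k_in = 0, k_on > 0) instead accumulates linearly
with length — the antenna regime.

The package provides an exact master-equation oracle (N ≤ 12), a
mean-field steady-state solver for arbitrary N, an exact stochastic
(Gillespie) simulator including a growing-lattice control, a Gaussian-PSF
optical forward model onto camera pixels, and likelihood sampling of
(k_in, k_on, k_off, k_step, k_out, [Kip2]total, scale, background) from
binned mean±SEM profiles.

## Worked example

```python
import numpy as np
from kip2traffic import (MotorKinetics, LatticeSpec, ReservoirSpec,
                         solve_meanfield_steady_state, classify_flat_profile)

wt = MotorKinetics(k_in=0.01875, k_on=3.75e-5, k_off=0.0,
                   k_step=13.125, k_out=4.0, c_total=35.0)
prof = solve_meanfield_steady_state(wt, LatticeSpec(n_sites=250),
                                    ReservoirSpec(volume=40.0))
print(classify_flat_profile(wt.replace(k_on=0.0)).regime_label)
print(f"shaft {prof.occupancy[125]:.3f}  tip {prof.occupancy[-1]:.3f}  "
      f"flux {prof.flux:.3f}/s")
```

prints

```
minus-end-only
shaft 0.062  tip 0.229  flux 0.914/s
```

meaning: with pure minus-end loading the profile is classified flat; with
the small landing rate included, a 2 µm microtubule carries ~0.06 motors
per site along the shaft, accumulates to 0.23 at the plus-end site, and
delivers ~0.9 motors per second into the plus end.

Fitting synthetic wild-type profiles end to end:

```python
from kip2traffic.reproduction import wt_loading_to_landing_ratio
out = wt_loading_to_landing_ratio(seed=1)
print(round(out["ratio"]))
```

prints a loading-to-landing ratio near `500` — the median k_in is
hundreds of times the median per-site k_on, the signature of SPB-gated
run initiation.

A thin CLI covers the same pipeline (`kip2traffic generate | quantify |
fit | sample | compare | reproduce`); see `kip2traffic --help`.

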