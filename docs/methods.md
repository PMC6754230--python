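# Methods

## Transport model

The microtubule is a single-file lattice of N sites, one 8 nm tubulin
dimer (= one kinesin footprint) per site, minus end first.  The
13-protofilament structure is not resolved; the fluorescence scale
parameter absorbs protofilament multiplicity.  The kinetic scheme is a
totally asymmetric exclusion process with Langmuir attachment plus a
minus-end loading channel:

| rate | meaning | units | wild-type default |
|------|---------|-------|-------------------|
| k_in  | minus-end loading rate constant (site 1 only, if free) | /nM/s | 0.01875 |
| k_on  | landing rate constant per free site (including site 1 and site N) | /nM/s | 3.75e-5 |
| k_off | lattice detachment, sites 1..N−1 | /s | 0 |
| k_step| forward step if the next site is free | /s | 13.125 |
| k_out | plus-end (site N) detachment; k_off does not act there | /s | 4.0 |
| c_total | total motor concentration | nM | 35 |

Conventions encoded here: the minus-end site receives *both* r_in and
r_on (the schematic does not exclude it from lattice binding); the
plus-end site detaches exclusively at k_out; a one-site lattice uses
entry r_in + r_on and exit k_out.  The free concentration is reduced by
bound motors when the reservoir is closed
(c_free = c_total − n_filaments·Σρ / (V·N_A); default volume 40 fL — the
order of magnitude of a haploid yeast cell — one filament).  At the
defaults the depletion is ~2%, so closed and clamped reservoirs give
nearly identical profiles; both are available.

### Where the defaults come from

The underlying measurements pin *ratios and scales*, not absolute rates:
the stepping rate is the measured speckle speed divided by the step size
(6.3 µm/min ÷ 8 nm = 13.125 /s); the wild-type loading-to-landing ratio
k_in/k_on is 500; the loading mutant (bfa1Δ bub2Δ) has k_in 12-fold
lower; the phosphorylation-site mutant (S63A) has k_on 6-fold higher;
lattice unbinding is zero in the flat-profile regime.  The remaining
absolute choices are this package's own and are labelled as such:

- shaft density r_in/k_step = 0.05 (k_in·c_total = 0.656 /s): a visibly
  occupied but far-from-crowded shaft;
- k_out = 4.0 /s.  The plus-end residence (1/k_out = 0.25 s) is chosen so
  that *every* strain stays below the tip-jamming threshold over the
  measured length range: the landing-derepressed strain collects a total
  landing flux of up to ~4.4·r_in on its longest microtubules, and any
  k_out below that drives the mean-field solution into a shock (a dense
  tip domain invading the shaft).  An exit rate of the same magnitude as
  the loading rate — attractive on symmetry grounds for the wild type —
  is therefore not usable as a study-wide default; the trade-off is a
  more modest plus-end peak (tip occupancy ~4× shaft in the wild type).

### Solvers

*Mean-field.*  The stationary site-balance equations are solved by damped
Newton iteration with an analytic tridiagonal Jacobian (LAPACK `dgtsv`),
initialized at the uniform low-density guess; residual tolerance 1e−10 on
every balance equation.  When Newton stalls — shock/jamming regimes where
the fixed point has a sharp density front — the iterate is relaxed with
short damped fixed-point bursts, and finally the rate equations are
integrated in pseudo-time with a stiff BDF method (the fixed point is the
attractor of the dynamics, so this converges regardless of regime) and
polished with Newton.  Inside likelihood loops the expensive integration
budget is capped (`deep_fallback=False`): a jammed parameter point fits
unjammed data catastrophically, so returning +inf there changes nothing.
With a closed reservoir, c_free is iterated to self-consistency (the map
is strongly contracting at realistic volumes).

*Exact oracle.*  For N ≤ 12 the full 2^N continuous-time Markov chain is
assembled sparsely and its stationary distribution solved directly; this
is the reference the mean-field solver and simulator are tested against
(mean-field factorization error ≤ 0.05 sup-norm at the tested points;
simulation within 3 Monte-Carlo SE).

*Stochastic simulation.*  An exact event-driven (Gillespie) sampler over
the channels load/land/detach/step/exit(/grow), with integer copy-number
book-keeping when the reservoir is closed (bound + free = total exactly,
checked per event).  The growing-lattice control appends empty plus-end
sites as a Poisson process; growth 0 reduces event-for-event to the fixed
lattice.

## Optical forward model

Bound motors are point emitters at site centers.  Pixel intensity is
background + scale · Σ_i ρ_i · [Φ((x+Δ/2−s_i)/σ) − Φ((x−Δ/2−s_i)/σ)] with
pixel size Δ = 133.35 nm (the camera's 2-pixel length bin is 266.7 nm)
and PSF σ = 135 nm (≈ diffraction-limited sigma for GFP at NA 1.46; the
imaging system's PSF is not otherwise specified).  The kernel has unit
mass per site, so the background-subtracted sum over an all-covering
window equals scale·Σρ for any σ.  scale and background are per-strain
nuisance parameters because the data are in arbitrary units.

## Quantification conventions

- Peak detection: global maximum after a 3-pixel moving average; ties
  break toward the SPB-proximal scan start; the noise floor is estimated
  from first differences (robust to plateau-shaped profiles), and a
  channel whose prominence is below 3 floors is rejected with a reason
  code.
- Profile length = SPB(mCherry)-peak to GFP-peak distance; bins are
  half-open multiples of 266.7 nm; per-position mean ± SEM over the bin's
  members, each truncated at its plus end + 3 pixels; single-member bins
  carry SEM 0 and a degenerate flag.
- Q-Q normalization: quantiles 0.5%..99.5% in 0.5% steps (linear
  interpolation between order statistics), OLS of reference on source
  quantiles.
- Plus-end regressions: peak = maximum of the bin mean within ±2 pixels
  of the aligned plus end; weights 1/SEM²; zero SEM falls back to an
  unweighted fit with a warning.
- Speckle speed = |Δpixel|·133.35 nm / (Δframe·1.07 s), reported in
  µm/min.
- 3-D length = Euclidean plus-end–SPB distance; spindles > 2 µm excluded;
  lengths ≤ 666.7 nm (5 pixels) flagged undetectable; absent microtubules
  recorded as 0 µm.  The recording window is 85.6 s (80 × 1.07 s).
- Draw summaries use midpoint interpolation for quantiles, so the median
  of an even-length sample is the mean of the central order statistics.

## Likelihood and sampling

negLL = ½ Σ ((mean − prediction)/SEM)² per bin and pixel, with each bin
predicted at its midpoint length rounded to whole sites (the same
convention the generator uses, so fitting is unbiased with respect to the
within-bin length distribution, which is unknown for real data).  A
per-pixel Gaussian with SEM weighting is the default likelihood form;
mean-field forward predictions are the default (a config switch enables
ensemble-averaged stochastic predictions, validated against mean-field in
tests).

Sampling is in log10 space with uniform truncation ranges (≥ 4 decades
per rate; the binding ranges span 7 decades so the full arbitrary-unit
degeneracy k·c_total·scale = const fits inside them).  k_step is fixed by
default at the speckle-derived 13.125 /s because profile shape in a.u.
constrains only the ratios r_in/k_step, k_out/k_step, and N·r_on/r_in;
sampling it remains available.  The affine-invariant ensemble sampler
(emcee, 32 walkers) is initialized at a multi-start L-BFGS-B
maximum-likelihood point and *overdispersed along the concentration
degeneracy*: each walker redraws c_total log-uniformly over its range
with k_in, k_on rescaled to keep the identified products fixed.  Without
this, short chains cannot populate the flat direction that the
c_total ≥ 35 nM conditioning filters on.  Burn-in 150 steps; the retained
tail provides the requested draws (default 2,000 in the scaled-down
reproductions; 20,000 at full scale).  A split-chain R̂ per parameter is
reported and the result flagged non-converged above 1.05 — expected for
the deliberately flat degenerate directions at scaled-down chain lengths;
the identified ratios are stable regardless.

Cross-strain fits share k_step, k_off, k_out, the optics, *and the total
motor concentration* between strains; k_in and k_on are per-strain.
Sharing the concentration encodes that the strains are the same cell type
expressing the same motor (the preset truths differ only in binding rate
constants, and the conditioning statement refers to a single
concentration); it also makes the per-draw cross-strain rate ratio equal
the identified intensity-product ratio, because every shared nuisance
cancels within a draw.  With per-strain concentrations, the conditioned
fold estimate at scaled-down chain lengths inherits an artifact of the
two concentration margins' imperfect ridge mixing; sharing removes it.
For samples from *one joint chain* the comparison pairs draws by index
(`compare_strains_paired`); conditioning (c_total ≥ 35 nM) is applied
within the draw, and the fold difference is the median per-draw ratio.
Samples from *separate* fits are treated as independent and paired after
a seeded permutation.  One-sided p-values are violation fractions with a
floor of 1/n_draws.

## Synthetic data

Generators are pure functions of (configuration, seed) and emit
ground-truth sidecars.  The profile generator renders the forward model
at each bin's midpoint length and adds i.i.d. Gaussian pixel noise per
simulated cell (σ = 25 a.u. against a shaft signal of ~50 a.u. above
background; SEM at 100 cells/bin ≈ 5% of the shaft signal).  Raw per-cell
scans carry an mCherry SPB peak so alignment and binning run end to end.
The SPB-pair generator draws per-cell b:m ratios lognormally (median 17/3
for correctly oriented cells, 2/3 for inverted ones, log-sd 0.5) with 20%
multiplicative measurement noise per side; speckle speeds are truncated
normal 6.3 ± 2.1 µm/min quantized to integer pixels and frames; dynamics
series alternate growth (1.4 ± 1.1 µm/min, truncated positive) and
shrinkage phases over 80 frames.  The shrinkage speed (2.8 ± 1.4 µm/min)
is not a measured value; it is a realistic scale for yeast astral
microtubules, chosen once.

What the generator does *not* emulate: photophysics (bleaching,
blinking), pixel-correlated noise, microtubule pivoting and tracking
error, within-bin length dispersion, and a multi-motor tip compartment —
the model's plus-end accumulation is capped at one motor on the terminal
site, so rendered synthetic peaks are weaker than the pronounced tip
peaks of real images.  Tests passing on these data therefore demonstrate
the correctness and calibration of the estimation machinery under the
stated noise model, not robustness to those real-data features.

## Scaled-down reproductions

`kip2traffic.reproduction` regenerates each headline quantity at desk
scale: 6 length bins × 100 cells per bin per strain, ≥ 2,000 retained
draws per fit (the full-scale analyses use 20,000).  These sizes keep a
complete run within minutes on one CPU while leaving the Monte-Carlo
error of the reported medians well inside the quantities' tolerances.

## Known limitations

- Mean-field factorization neglects nearest-neighbour correlations; the
  error is small at the study's densities (checked against the exact
  oracle at N ≤ 6) but grows near jamming.
- Absolute rates are not identifiable from arbitrary-unit profiles; only
  ratio conclusions should be read from single-strain fits, and
  cross-strain folds require the joint fit's shared-nuisance pairing.
- The sampler's R̂ on purposely-flat directions stays above 1.05 at
  scaled-down chain lengths; results are flagged, and only functions of
  the identified combinations are reported.
- The S63A-like regime approaches the tip-jamming threshold on long
  microtubules; conclusions there depend on the k_out default discussed
  above.
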