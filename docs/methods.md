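# Methods

## The physical model

Saturation transfer encodes dilute labile-proton pools into the water
signal: a frequency-selective RF field saturates protons resonating at a
chemical shift `delta` (ppm from water), and chemical exchange carries that
saturation into the (detectable) water pool.  `cestmrf` simulates this with
the Bloch-McConnell equations for a star-shaped exchange topology: a water
pool (transverse + longitudinal components), any number of mobile solute
pools (amide at +3.5 ppm, glutamate amine at +3 ppm, aliphatic rNOE
protons at -3.5 ppm; each with full Bloch dynamics), and one
motion-restricted semisolid pool carrying only longitudinal magnetization,
saturated at the rate `pi * w1^2 * g(dw)`.

* `g` is the semisolid absorption lineshape, super-Lorentzian by default
  (Lorentzian by configuration).  The super-Lorentzian diverges on
  resonance; inside +-1 ppm of the pool's resonance it is bridged by a
  quadratic in `dw^2` interpolated exactly through the samples at 1, 1.5
  and 2 ppm, so the bridged segment joins the analytic branch continuously.
* Exchange rates obey detailed balance: the solute-to-water rate is the
  declared `k_sw`; the reverse rate is `f_s * k_sw` with water pool size 1.
* A per-pixel static-field offset `b0_shift` (ppm) adds to every resonance.

For a continuous-wave block the system is linear, `dM/dt = A M + b`, and is
advanced exactly through the eigendecomposition of `A` (the matrix
exponential), `M(t) = M_ss + e^{At}(M_0 - M_ss)` with `M_ss = -A^{-1} b`.
Agreement with an independently assembled two-pool system is at machine
precision (tested against a direct linear solve for the steady state and a
1e-6-s-step Runge-Kutta integration for transients).

Readout is idealized: signal = water longitudinal magnetization at the end
of saturation times `exp(-TE/T2_water)`; the 90-degree excitation consumes
all free-pool magnetization (set to zero, transverse spoiled) while the
unexcited semisolid pool carries over, and the longitudinal subsystem then
relaxes for the remainder of TR.  Because the echo train itself contributes
no pool-specific contrast, this keeps the trajectory physics (saturation,
exchange, incomplete recovery, semisolid carry-over) while avoiding EPI
simulation.

## Acquisition protocols

Each fingerprinting protocol acquires 31 images: an unsaturated M0
reference (TR 15 s, TE 20 ms) and 30 pseudo-random CW saturation blocks.
All four protocols fit the 120-135 s-per-protocol envelope.  Exact
published per-entry tables for this family of protocols are not available,
so the defaults are seeded generators over declared ranges:

| target | offsets (ppm)        | B1 (uT)  | sat / TR (s) | total (s) |
|--------|----------------------|----------|--------------|-----------|
| mt     | {6, 8, 10, 12, 14}   | 1 - 6    | 2.5 / 3.7    | 126       |
| rnoe   | -3.5                 | 0.2 - 2  | 2.5 / 3.7    | 126       |
| amide  | +3.5                 | 0.5 - 4  | 2.5 / 3.7    | 126       |
| glu    | +3 / -3 alternating  | 3 - 8    | 3.0 / 4.0    | 135       |

The glutamate protocol alternates the saturation side.  Rationale: the
amine pool exchanges at ~7000 1/s, so its saturation efficiency is low and
its imprint on the trajectory is nearly common-mode across high-power
entries; L2 normalization (below) removes common-mode structure.
Interleaving -3 ppm entries — which carry the identical direct-water and
(nearly identical) semisolid load but no glutamate effect — makes the
glutamate contribution differential, roughly doubling its surviving
contrast.  This is the fingerprinting analogue of the GluCEST asymmetry
reference.

Z-spectrum sweeps (0.7 uT/3 s, 5.9 uT/0.5 s, 1.5 uT/4 s; 7 to -7 ppm) and
the WASSR sweep (0.3 uT/3 s, +-1 ppm, 0.1 ppm steps) insert one dummy
saturation entry after M0: every recorded entry then starts from the same
post-readout recovery state, which keeps water-only spectra symmetric to
numerical precision.  Without it the first entry carries the long-TR M0
transient.

## Dictionaries and normalization

A dictionary is the Cartesian product of per-parameter value lists
simulated through one protocol; row order is lexicographic over the
declared parameter order and is bitwise independent of the worker count
(fixed 4096-row chunks).  Trajectories are encoded by dividing the 30
saturated entries by the M0 entry and scaling to unit Euclidean norm.

Shipped desk-scale grids (all user-overridable YAML):

* `mt`: f_ss 0.02-0.30 (29), k_ssw 5-100 1/s (20), T1 1.2-2.4 s (13),
  T2 30-120 ms (10) — 75,400 rows.
* `rnoe`: f_rnoe 0.001-0.019 (10), k_rnoe 5-50 1/s (7), f_ss (8),
  k_ssw (6), T1 (5), T2 (5) — 84,000 rows.
* `amideglu`: f_amide 0.0005-0.01 (7), k_amide 50-500 1/s (4), glutamate
  2-30 mM (7), k_glu 4000-10000 1/s (4), f_ss (5), k_ssw (3), T1 (3),
  T2 (3) — 105,840 rows, simulated through both the amide and the
  glutamate protocol.

The T2 range deliberately covers white/grey matter but not CSF; estimates
in CSF-like pixels will rail against the grid bounds.  Glutamate is
declared in mM and converted internally to a proton volume fraction as
`f = 3c / 111000` (three amine protons per molecule against the 111 M
water-proton pool); `k_glu` brackets reported in-vitro amine exchange
rates (~7000-8300 1/s at pH 7, 37 C).

Each network's dictionary template also carries the *non-target* pools at
fixed nominal values where their spectral bleed is non-negligible: the MT
dictionary includes a nominal glutamate pool because the several-ppm-wide
amine line reaches under the >= 6 ppm MT offsets and would otherwise bias
f_ss by ~0.002-0.003 absolute.  The other cross-pool bleeds measure an
order of magnitude below the phantom noise floor and are omitted to keep
the simulation matrices small.

## The digital phantom

A 5x5 array of circular vials (64x64 image, radius 4 px, 49 px per vial):
amide volume fraction 0.09-0.81% along one axis, glutamate 5-25 mM along
the other, replicated over four semisolid backgrounds f_ss = 6, 10, 14,
18% — 100 unique (amide, glutamate, MT) combinations.  Non-varied
parameters sit at the base tissue (T1 1.8 s, T2 75 ms, k_ssw 40 1/s,
k_amide 300 1/s, k_glu 7000 1/s, plus a fixed rNOE pool f = 0.5%,
k = 20 1/s).  Every pixel's four trajectories are simulated from its
vial's full multi-pool tissue model — including the pools each
single-network dictionary deliberately omits, so the phantom genuinely
tests the divide-and-conquer premise.  White Gaussian noise with
std = sigma * M0 (default sigma = 1% of M0, a declared stand-in for
scanner-calibrated noise levels) is added independently per pixel and
entry, seeded.

What the phantom does *not* emulate: B0/B1 inhomogeneity fields (flat
field; the WASSR/correction path is exercised separately), partial-volume
edges, Rician noise statistics at low SNR, and T1/T2 map estimation error
(truth maps are supplied, mirroring the separately-measured-relaxometry
workflow).  Passing recovery tests therefore demonstrate the decoding
pipeline under idealized geometry, not robustness to field or registration
artifacts.

## The quantification pipeline

Three fully connected networks applied pixelwise and sequentially:

1. **MT network** — input: 30 normalized MT-trajectory entries + water T1
   + T2 (32); outputs f_ss, k_ssw.
2. **rNOE network** — input: 30 rNOE entries + T1 + T2 + the MT outputs
   (34); outputs f_rnoe, k_rnoe.
3. **amide/glutamate network** — input: 30 amide + 30 glutamate entries +
   T1 + T2 + the MT outputs (64); outputs f_amide, k_amide, glutamate
   concentration (mM), k_glu.  One joint network resolves the spectral
   overlap of the +3.5 and +3 ppm pools.

Hidden layers: 300 ReLU neurons, two layers (four for the combined
network).  Sigmoid outputs with per-parameter min-max scaling over the
training grid guarantee estimates stay inside the grid range.  Scalar
inputs are min-max scaled: T1/T2 by the global tissue envelope
(1.2-2.4 s / 30-120 ms), upstream f_ss/k_ssw by the downstream grid's own
bounds — during training the true values are used, at inference the MT
network's estimates (so error propagates down the chain exactly as it
would in use).

Training: Adam, learning rate 2e-4, minibatch 1024, MSE on scaled targets,
float32 (bit-reproducible for a fixed seed and BLAS).  Gaussian noise
(sigma = 1% of M0, matching the phantom) is injected into the raw
trajectories afresh every epoch, before M0 normalization.  A fixed 20%
validation split drives early stopping (patience 10 generally; the
experiment default runs up to 120 epochs with patience 15).  Training logs
(loss histories, configuration) are archived with the weights, along with
the protocol hashes; inference refuses stacks whose schedule hash differs
from the training protocol.

## Conventional Z-spectrum analysis

WASSR B0 mapping (cubic-spline interpolation to 0.001 ppm, minimum
position; boundary minima flagged), spline resampling onto nominal offsets
(out-of-sweep ends NaN), optional smoothing spline, then the metric suite:
MTR, MTR_asym, dST, GluCEST (5.9 uT), AACID (1.5 uT) as closed forms on
the interpolated spectrum, and MTR_Rex / AREX from a bounded multi-pool
Lorentzian decomposition (default five pools at 0, -2.3 (semisolid), +3.5,
-3.5, +3 ppm with declared start values and bounds; deterministic trust
region fit with tolerances 1e-14).  The default pipeline order is WASSR ->
correct -> smooth -> metrics; ROI statistics average Z before metric
evaluation.

## Recovery statistics

Vial means are compared with ground truth by Pearson's r and the
intraclass correlation coefficient, fixed package-wide to ICC(2,1)
(two-way random effects, absolute agreement, single measure) — the variant
that penalizes systematic offset and scale error, which correlation alone
cannot see.  Group comparisons use paired two-tailed t-tests and one-way
ANOVA with two-sided Tukey HSD.  Statistics are computed on vial means
(n = number of vials), pooled over all 100 vials and per MT background
(n = 25).

## Desk-scale choices and their consequences

The default experiment (`run_phantom_study`, also behind
`scripts/acceptance.py` and `cestmrf study`) uses the shipped grids
(~0.8-1.1e5 rows per network, against hundreds of millions in a
production-scale dictionary) and at most 120 training epochs; the full
chain runs in roughly 12-15 minutes on one CPU core.  At this scale the
limiting factor is the fixed small learning rate, not the row count:
validation error is still creeping downward when training stops, and the
MT/amide estimates carry a fraction-of-a-percent residual bias visible in
the ICC.

**Glutamate is information-limited, not training-limited.**  At 7 T in
semisolid-laden tissue (f_ss * k_ssw = 4 1/s here) the water loss at +3 ppm
is dominated by direct and semisolid saturation at every feasible power;
sweeping B1 from 1 to 10 uT changes the 5->25 mM glutamate contrast per
entry only between 0.30 and 0.38% of M0.  Against 1%-of-M0 noise the
per-pixel posterior spread is >= ~19 mM — comparable to the full 2-30 mM
grid — so any MSE-optimal estimator shrinks strongly toward the prior
mean.  Consequences, visible in every recovery report: glutamate vial
means correlate with truth (the ordering survives vial averaging) but with
a slope far below one, a negative bias at high concentrations, and an ICC
far below the MT and amide values; the spread of glutamate errors across
noise realizations exceeds amide, which exceeds MT.  Reproducing
absolute-agreement glutamate recovery at this vial size would need either
several-fold lower noise or larger vials; both are fixed study conditions
here.

## Known limitations

* Continuous-wave saturation blocks only; shaped or adiabatic pulses and
  the echo train are not simulated.
* T1/T2 enter as given maps; their own estimation error (and the influence
  of solute pools on apparent water relaxation) is outside the model.
* The sequential design propagates upstream (MT) estimation error into the
  rNOE and amide/glutamate networks by construction.
* Single-compartment tissue per pixel; no partial volume, no CSF-range T2.
* The rNOE protocol's trajectory is weakly contaminated by vial-to-vial
  amide variation (measured ~30% of the rNOE signal step between adjacent
  grid values); rNOE estimates wobble accordingly.
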