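# Methods

## Scientific setting

Trastuzumab binding to HER2 on SKBR3 breast-cancer cells triggers removal
of the receptor from the plasma membrane. The measurable quantity is the
mean quantum-dot fluorescence per cell of membrane-bound, Affibody-labeled
HER2, recorded at a single fixation time per experimental condition.
Conditions differ in drug exposure (0–60 min), optional drug-free chase
periods (2 h or 5 h) and the timing of the Affibody label (before the
experiment or in the last ten minutes before fixation). The package
implements the two dynamic compartment models used to interpret such
data, the preprocessing that turns per-cell records into one signal per
condition, maximum-likelihood calibration with profile-likelihood
uncertainty, and a synthetic single-cell data generator that stands in
for the unpublished microscopy tables.

## Trafficking models

Both models are mass-action reaction networks over dimensionless receptor
amounts; the freedom of scale in the observation function is used to fix
the initial total membrane amount to one, so every state is a fraction of
the initial membrane pool. Time is in minutes, rates in 1/min.

**Model A (single population).** Membrane receptors `N_m` and internal
receptors `N_i` exchange through constitutive internalization (`k_int`),
recycling (`k_rec`), production (`k_prod`) and degradation (`k_deg`).
Drug binding (activation `k_act·N_m·T`, dissociation `k_diss`) moves
receptors into activated states with their own internalization,
recycling and degradation rates (`k_int_T`, `k_rec_T`, `k_deg_T`). An
Affibody label binds membrane receptors (`k_on·A·N_m`, off-rate `k_off`)
and makes them observable; internal receptors cannot bind or release the
free label pool. "Degradation" means removal from the recycling-competent
pool, not proteolysis. The pre-treatment equilibrium pins down two rates:
`k_deg = k_prod/N_i(0)` and `k_int = (k_prod + k_rec·N_i(0))/N_m(0)`;
`complete_steady_state` applies these before every simulation or fit.

**Model B (two membrane regions).** The membrane pool is split into
ruffled (`N_R`) and flat (`N_F`) regions with region-specific activation
and drug-induced internalization (`k_int_RT`, `k_int_FT`); label and
drug-dissociation kinetics are shared. The constitutive processes removed
in the Model A reduction are absent, and by default there is no recycling
or degradation at all, so internalized receptors are absorbing apart from
ligand dissociation. The 16 receptor states are built by product
construction {region} × {plain, T, A, TA} × {membrane, internal} from a
single reaction list; the test suite checks the generated equations
against independently hand-written ones.

Because the two regions are exchangeable in the likelihood when both
regions' rates are free, fitted optima are canonicalized to the
convention that the ruffled region is the faster-internalizing one.

**Observation.** `N_obs = s_c · Σ(label-bound membrane states)` — two
states in Model A, four in Model B. `s_c` (signal units per receptor
unit) absorbs the units of the fluorescence readout. The exact scaling
symmetry (`s_c → λ·s_c`, initial amounts `→ /λ`) is verified numerically
rather than symbolically (`check_scaling_symmetry`).

**Dosing.** Treatment schedules are ordered on/off events per compound
plus a fixation time. The free compound amounts follow switch semantics:
at an "on" event the amount jumps to its excess-ratio value
(`T(0) = 2.5e4 · N_m(0)`, `A(0) = 50 · N_m(0)`, both configurable), at a
washing "off" event it drops to zero while bound complexes persist and
continue to dissociate (released label/drug is not re-tracked in the
drug-free medium). Only the products `k_act·T0` and `k_on·A0` are
identifiable and reported; the elementary bimolecular constants are
derived internally from the ratios, so results do not depend on the ratio
choice.

**Integration.** With the free-compound amounts at their
switch-determined values the receptor subsystem is linear within each
inter-event interval, and the default back end propagates it with matrix
exponentials — exact to machine precision and fast enough for the
multistart/profile studies. A second back end (`method="ivp"`) integrates
the free compounds as states with their consumption and release terms
(LSODA, rtol 1e-8, atol 1e-10, hard restart at every event). At the
physiological excess ratios the two agree to a few parts in 1e4; the
difference is pure ligand depletion, negligible at 2.5e4-fold excess.
Solver noise below zero is clamped to zero before observation; negative
values beyond 1e-6 raise an error.

**Timeline conventions.** The protocol's incubation durations are encoded
with t = 0 at the first incubation step of each condition: a 10-min
Affibody window precedes drug addition in the standard conditions, and
occupies the last 10 min before fixation in the "label before
measurement" variants (appended after the drug pulse when there is no
chase). The label is washed out at drug addition by default (configurable
via `affibody_during_drug`), since the protocol does not state whether
label remains in the medium during the pulse.

## Preprocessing

Each picture has an additive background `b_p`; a cell of condition `c` on
picture `p` has expected luminosity `s_c + b_p`, and dedicated background
regions measure `b_p` directly. Both record types enter one joint
least-squares system (equal weights — no weighting information is
available), solved by dense `lstsq`; rank deficiency and pictures without
background records are rejected. The condition uncertainty is the SEM of
the background-corrected cell values. Cells below 600 µm² or flagged
(spherical / partially captured) are screened out first. A per-cell
`background_local` column, corresponding to the later measurement
protocol, bypasses the additive model by direct subtraction. For
presentation, signals are divided by `s_c(fitted) × (predicted control
observable at t = 0)` so the control condition maps to one.

## Inference

The goodness function is `-2 log L(θ) = Σ_c ((y(t_c,θ) − y_c)/σ_c)²`
with per-condition Gaussian noise of known σ (estimated upstream, not
refit). Choices that matter:

- **Scale and bounds.** Parameters are optimized on log10 scale, default
  bounds [−8, 4] (the published rates span six decades); fraction-valued
  parameters (`N_F0`, `N_i0`) use [−4, 0], with `N_R0 = 1 − N_F0` under
  the freedom-of-scale convention.
- **Multistart.** 64 Latin-hypercube starts by default (seeded,
  recorded), each followed by a trust-region least-squares descent; the
  full cost-sorted ensemble (waterfall) is retained.
- **Solution filters.** Converged optima are accepted only if the initial
  internal fraction is ≤ 5% and `k_on·A0` lies in [0.5, 4] 1/min —
  post-hoc acceptance constraints, not penalties, matching how the
  published analysis discarded solutions.
- **Profiles.** 95% intervals from the Δ(−2 log L) = 3.84 crossing
  (pointwise, 1 df — whether the published intervals were pointwise is
  not stated; this choice is recorded in the output). The walk
  re-optimizes all other parameters at each grid point, warm-started,
  with a step policy targeting fixed cost increments (default 0.1,
  coarser in the large simulation studies) capped at 0.5 log10 units. A
  profile that stays below threshold to the bound yields an unbounded
  interval end, which is how the practical non-identifiability of the
  fast drug-induced rates (`k_int_T`, `k_rec_T`, `k_int_RT`) manifests.
- **Reduction.** Candidate processes are removed by fixing their rates to
  zero, refitting, and accepting the least harmful removal when the
  likelihood-ratio test is non-significant at 0.05 — ties between
  equally good solutions therefore resolve in favor of the smaller
  model. Boundary caveat: fixing a rate at zero sits on the edge of the
  parameter space, where the χ² reference distribution is conservative.
- **Tied parameters.** The alias `k_act_T0` drives both regions'
  activation rates jointly (the published fit estimated their difference
  to zero); it is also the interior-point nested pair used to check LRT
  calibration.

## Synthetic data generator

The generator emulates the measurement structure of the study designs:
the 12-condition main design (cell counts 218, 223, 185, 302, 168, 188,
218, 189, 209, 202, 198, 176) and the 4-condition flat/ruffled validation
design (38, 69, 66, 74 cells). Per condition it simulates the model,
reads the observable at fixation, draws per-picture backgrounds
(normal, default mean 50, sd 10 luminosity units, 6 pictures per
condition with round-robin cell allocation) and per-cell signals
(lognormal around the condition mean, CV 0.5 by default — single-cell
intensity histograms of this type of data are right-skewed, but no
parametric family is published, so the family is configurable and
recorded in the truth file). Phenotype-sorted conditions use flat share
1.0 for flat cells and the 60/40 flat/ruffled region mixture for ruffled
cells (ruffled cells still contain flat membrane regions). Cell areas are
drawn above the 600 µm² screening threshold.

What the generator does **not** emulate: inter-batch variability between
cell passages (the published error bars are within-sample SEMs and the
authors note batch effects are not covered), segmentation errors,
spatially correlated backgrounds, and any dependence of per-cell variance
on condition. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the stated noise model, not robustness to
real-data artifacts.

## Study sizes used in the validation suite

The acceptance-level checks run at the study's own conditions: 20
generator/fit replicates with 64 multistarts for parameter recovery, 200
replicates for the type-I error of the likelihood-ratio test, and 100+
random draws for the equation-level oracle comparisons. The headline
membrane-clearance predictions are single deterministic simulations.

## Known discrepancy in the published flat-cell prediction

The published validation table reports model-predicted membrane ratios
after 60 min of drug of 0.66 (pure flat regions) and 0.29 (60/40
flat/ruffled mixture). From the printed point estimates
(`k_act_F·T0 = 0.41`, `k_diss = 5.0e-2`, `k_int_FT = 0.0126`) the flat
subsystem's slow eigenvalue is ≈ −0.0112/min, giving a 60-min ratio of
≈ 0.52; this package's simulation reproduces that value (0.523).
Moreover the two printed predictions are mutually inconsistent: a 60/40
mixture of 0.66 and ≈ 0 would give 0.40, not 0.29, whereas 0.6 × 0.52 ≈
0.31 is close to the printed mixture value. The package therefore
reports the simulated values and flags the flat-population discrepancy
in the validation report rather than adjusting any input to match the
printed 0.66. Whether the published prediction used unrounded internal
estimates or a different ratio definition cannot be determined from the
printed material.

## Limitations

- No spatial or sub-endosomal structure; ruffles enter only as a second
  well-mixed receptor pool, and heterodimers with other HER-family
  receptors are not modeled.
- The measurement model assumes independent Gaussian condition-level
  noise with known σ; misspecified σ rescales the goodness function but
  not the estimates.
- Profile intervals are pointwise; no simultaneous bands or Bayesian
  posteriors are provided.
- LRT-based reduction of rates fixed at zero uses the standard χ²
  reference despite the boundary, as in the published analysis.
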