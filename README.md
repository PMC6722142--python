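# her2traffic

Dynamic compartment modeling of trastuzumab-induced HER2 internalization
in SKBR3 breast-cancer cells: trafficking ODE models, fluorescence
preprocessing, maximum-likelihood inference with profile-likelihood
confidence intervals, nested-model reduction, and a synthetic single-cell
data generator.

## Who this is for

Quantitative cell biologists and systems-biology modelers who measure
drug-induced membrane-receptor clearance with single-cell fluorescence
(pulse-chase designs, one fixation time per condition) and want to infer
the underlying trafficking rates — internalization, recycling,
degradation, ligand binding — together with honest identifiability
statements.

## The models

Receptor amounts are dimensionless multiples of the initial membrane
pool (fixed to one by the freedom of scale); time is in minutes.

**Model A** (single population): membrane receptors N_m and internal
receptors N_i with constitutive production/internalization/recycling/
degradation (k_prod, k_int, k_rec, k_deg), drug-activated states N^T
with their own rates (k_act·T, k_diss, k_int,T, k_rec,T, k_deg,T), and an
Affibody label (k_on·A, k_off) that makes membrane receptors observable:

    N_obs = s_c · (N_m^A + N_m^{T,A})

The pre-treatment steady state fixes k_deg = k_prod/N_i(0) and
k_int = (k_prod + k_rec·N_i(0))/N_m(0).

**Model B** (two membrane regions): the membrane pool splits into
ruffled (N_R) and flat (N_F) regions with region-specific drug-induced
internalization (k_int,RT, k_int,FT) and, in the reduced form, no
recycling or degradation; the observable sums the label-bound membrane
states of both regions.

Parameters are estimated by minimizing

    -2 log L(θ) = Σ_c ((y(t_c, θ) − y_c) / σ_c)²

over 64 seeded multistarts on log10 scale, with 95% confidence intervals
from the profile likelihood (Δ = 3.84 crossing) and model reduction by
likelihood-ratio tests. See `docs/methods.md` for the full account.

## Worked example

Predict the drug-induced membrane clearance of the reduced two-region
model at the published point estimates — 10 min Affibody labeling, then
60 min of trastuzumab:

```python
from her2traffic import (membrane_ratio, pulse_chase_schedule,
                         reference_parameters, simulate)

params = reference_parameters("B")          # published Model B estimates
sched = pulse_chase_schedule("before_experiment", drug_min=60)
for share in (1.0, 0.6):                    # pure flat / 60:40 mixture
    traj = simulate("B", params.with_flat_share(share), sched,
                    output_times=[0.0, 10.0, 70.0])
    print(share, round(membrane_ratio(traj, 10.0, 70.0), 3))
```

prints

```
1.0 0.524
0.6 0.314
```

i.e. a receptor population in flat membrane regions keeps ~52% of its
membrane receptors after one hour of drug, while a 60/40 flat/ruffled
mixture keeps ~31% — ruffled-region receptors internalize about three
orders of magnitude faster and are essentially cleared. The same numbers
come from the CLI:

```sh
her2traffic validate --outdir out
#  cell_population  flat_region_share  predicted_ratio_total_membrane  predicted_ratio_observed
#             flat                1.0                        0.523504                  0.502575
#          ruffled                0.6                        0.314102                  0.301545
```

The full pipeline runs as `her2traffic generate | preprocess | fit |
profile | validate | report`, each stage writing a seeded, digest-stamped
manifest. For example:

```sh
her2traffic generate --seed 5 --design both --outdir out
her2traffic preprocess --cells out/cells.csv --backgrounds out/backgrounds.csv --outdir out
her2traffic fit --signals out/signals.csv --model B --seed 5 --outdir out
```

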