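# hublong

Longitudinal hub/no-hub functional-connectome profiles and mixed-model
analysis for glioma cohorts.

## The problem

After surgical resection of a glioma, the brain's functional network
architecture reorganizes over months. A compact way to track this is the
*spatial connectomic profile*: resting-state fMRI is parcellated into N
cortical regions (333 in the reference atlas), a per-session functional
connectivity (FC) matrix is built from the absolute Pearson correlations
|r| between region time series, and each subject-session matrix is
divided by its own whole-brain mean FC so that global FC shifts — common
in glioma — do not masquerade as network-specific change. Regions are
partitioned a priori into *hubs* (default-mode network, DMN, plus the
fronto-parietal network, FTPN) and *no-hubs* (primary sensory, salience,
cingulo-opercular and attention networks), and five block means summarize
each visit:

- FC within DMN, within FTPN, within hubs (DMN ∪ FTPN as one extended
  network), within no-hubs, and between hubs and no-hubs.

Longitudinal change in these metrics, and their link to cognition, is
tested with linear mixed models: for metric *y* of subject *i* at visit
*t* (months post-surgery),

```
y_it = β0 + β1·t + β2·(t × grade_i) + β3·(t × lateralization_i)
     + γ'·covariates_i + b_i + ε_it,      b_i ~ N(0, σ²)
```

with a random intercept per subject, REML estimation, Wald t tests, and
Benjamini–Hochberg FDR across the models of one family (the five FC
metrics, or the tests of one cognitive domain). Grade is coded LGG = 1 /
HGG = 0 and lateralization LEFT = 1 / RIGHT = 0. A third family regresses
each cognitive score on time and four time × FC-metric interactions.

Because patient-level imaging from such cohorts is rarely shareable, the
package includes a synthetic-cohort generator that reproduces the study
structure — 28 subjects (11 low-grade / 17 high-grade gliomas, 15 left /
13 right), baseline plus follow-up visits thinned to ≈73 total
observations, 275-volume sessions at TR 2.6 s — with block-structured
time series whose hub/no-hub correlations drift with time × group, so
every stage of the pipeline can be exercised and validated end to end.

## Worked example

```python
import hublong

cfg = hublong.default_config()                       # the emulated study conditions
profiles, cohort, truth = hublong.simulate_profiles_fast(cfg, seed=1)
fits = hublong.fc_outcome_models(profiles, cohort)
print(hublong.fits_to_frame(fits)[
    ["response", "term", "estimate", "p", "q_fdr", "sigma2_random"]
].round(4).head(9).to_string(index=False))
```

```
           response                term  estimate      p  q_fdr  sigma2_random
         within_dmn                time    0.0071 0.0000 0.0000         0.0121
         within_dmn          time:grade    0.0036 0.0631 0.3157         0.0121
         within_dmn time:lateralization   -0.0090 0.0000 0.0000         0.0121
        within_ftpn                time    0.0004 0.7402 0.7402         0.0095
        within_ftpn          time:grade    0.0001 0.9725 0.9725         0.0095
        within_ftpn time:lateralization   -0.0013 0.4734 0.4734         0.0095
        within_hubs                time    0.0046 0.0000 0.0000         0.0136
        within_hubs          time:grade   -0.0009 0.5085 0.7751         0.0136
        within_hubs time:lateralization   -0.0046 0.0008 0.0014         0.0136
```

Reading the output: the generator gives right-lateralized patients a
+0.005/month gain in normalized within-hub FC (and a loss in no-hub FC);
with LEFT = 1 coding the fitted `time` term is the right-group slope
(+0.0046 here) and `time:lateralization` is the left-minus-right contrast
(−0.0046), both recovered close to truth with σ² matching the configured
between-subject variance. The `q_fdr` column corrects each term across
the five FC models.

The full time-series route (simulate sessions → FC matrices → profiles →
all model tables) runs from the shell:

```sh
hublong run --seed 3 --out runs/demo
```

which writes `fc_matrices/`, `profiles.tsv` and Table-1..4-shaped TSVs
(`table1_baseline.tsv` … `table4_fc_cognition_models.tsv`) plus a
deterministic `run.log`.

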