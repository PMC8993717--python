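# rnvgphase

Phase analysis of gated radionuclide ventriculography (RNVG / MUGA)
studies for cardiotoxicity risk stratification.

The package:

* extracts **first-harmonic phase and amplitude images** from gated
  blood-pool frame stacks (per-pixel Fourier fit; counts are minimal at
  the phase angle, so a larger angle means later contraction) and a
  count-based LVEF;
* computes **approximate entropy (ApEn)** over the LV region using a
  serpentine (boustrophedon) pixel ordering, plus the companion
  dyssynchrony parameters **synchrony**, **phase-histogram entropy**, and
  **phase SD**;
* reproduces the **(m, r) input-parameter optimization**: ApEn sweeps
  over template length `m` in 1..5 and tolerance `r` in 0.25..21 on
  simulated phase images, with **flip-point** detection (the tolerance at
  which normal and abnormal ApEn cross) and an advisory operating-point
  recommendation (defaults: `m=2`, `r=7`);
* generates **synthetic data**: radial-segment phase images with
  normal / MI / LBBB / aneurysm presets, gated frame stacks with Poisson
  counting noise (the exact inverse of phase extraction), and two-group
  patient cohorts with serial LVEF trajectories;
* runs the **two-group statistics**: Shapiro-Wilk-gated Welch-t /
  rank-sum comparisons, Henze-Zirkler multivariate normality,
  Hotelling's T², logistic models with an ApEn x baseline-LVEF
  interaction, Mann-Whitney AUC, and repeated stratified-CV Random
  Forest / Naive-Bayes classifiers. Patients are labeled CTRCD when the
  LVEF drops more than 10 percentage points to below 50%.

## CLI

Five composable subcommands (each accepts `--seed`, `--config`, `--out`):

```sh
# synthetic cohort + one gated study per patient
rnvgphase simulate --mode cohort-studies --out sim --seed 7

# frame stack -> phase/amplitude images (CSV + optional PNG preview)
rnvgphase extract-phase sim/studies/P000 --out maps --png

# studies -> per-patient feature table (merging serial LVEFs for labels)
rnvgphase features sim/studies --visits sim/cohort.csv --out features.csv

# (m, r) sweep with flip-point report on simulated normal/MI pairs
rnvgphase sweep --out sweep --pairs 5 --seed 7

# two-group statistical stage
rnvgphase cohort-stats features.csv --out stats --seed 7
```

`--config` takes a YAML file overriding the defaults
(`m`, `r`, `bins`, `amplitude_threshold`, `frames`, `total_counts`,
`seed`); explicit CLI flags win over the config file.

## Conventions

* Images are 0-based, row-major, origin top-left; phase is stored in
  degrees in [0, 360).
* ApEn uses Chebyshev template distance, includes self matches, and
  counts both template lengths over the same start range, so the result
  is a true conditional-probability sum and is always >= 0. Tolerance
  `r` is in degrees of phase.
* Phase values are treated as linear (non-circular) in ApEn, phase SD,
  and the histogram; synchrony is circular by construction. The exact
  synchrony / histogram-entropy normalizations are this package's
  documented choices (amplitude-weighted resultant length; Shannon
  entropy over 64 equal bins divided by `ln(bins)`).
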