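# crtuning

Visual-tuning analysis of a marked (calretinin-expressing, CR+) versus
unmarked (CR−) neuronal population in mouse primary visual cortex, built as
a reusable, tested pipeline with a ground-truth simulator standing in for
in-vivo recordings.

The package is aimed at systems-neuroscience analysts who want the complete
chain from raw observables to population statistics: two-photon calcium
traces (7 frames/s) and laminar-probe spike trains are reduced to per-trial
responses, per-cell tuning metrics, group comparisons, a cluster scan, and
an optogenetic gain analysis — and every step can be exercised against
synthetic data whose ground truth is known.

## What it computes

For each cell, from drifting-grating responses R(φ):

- **ΔF/F** — (F − F₀)/F₀ with F₀ the mean fluorescence just before stimulus
  onset; the response is the mean ΔF/F from 0.5 s after onset to offset.
- **OSI** = |Σ R(φ)e^{2iφ}| / Σ R(φ) (equal to 1 − circular variance) and
  **DSI**, the undoubled-angle analogue.
- **Suppression index** SI = (R_pref − R_largest)/R_pref, with R_pref the
  response at the smallest diameter reaching 95% of the maximum.
- **Frequency tuning** by difference-of-Gaussians fits
  R(f) = a_e·e^{−f²/2σ_e²} − a_i·e^{−f²/2σ_i²}, with interpolated half-max
  frequencies and a low-pass classification at the lowest tested frequency.
- **Contrast tuning** by Naka-Rushton fits R(c) = b + R_max·cⁿ/(cⁿ + C₅₀ⁿ).
- **Group statistics** gated by Shapiro-Wilk normality (Student t /
  Mann-Whitney U; Wilcoxon signed-rank for paired data; plain χ² for
  proportions), and a **cluster scan**: Hartigan's dip test (an exact
  implementation) on the first principal component of every pair and
  triplet of tuning metrics, Bonferroni corrected.
- **Laser (optogenetic) analysis** on 16-channel laminar sessions: 3×SD
  spike thresholding, rate − spontaneous responses, 2 Hz inclusion,
  deep/middle/top layer split, per-unit Friedman and population Wilcoxon
  tests of the laser effect, and per-state C₅₀/SI to separate gain changes
  from tuning changes.

## Worked example

```bash
crtuning simulate --seed 5 --out run/
crtuning analyze run/session.h5 --seed 5 --out run/results
crtuning report run/results
```

prints (seed 5, a reduced 36-cell configuration):

```
tuning analysis report
========================================
cells: 36 (12 marked), responsive: 34
osi                marked 0.24+-0.051 (n=12)  unmarked 0.298+-0.036 (n=22)  mann_whitney p=0.188
dsi                marked 0.261+-0.036 (n=12)  unmarked 0.316+-0.039 (n=22)  t p=0.359
...
calcium-vs-spiking: r=0.832 (n=212), slope p=1.3e-55
cluster scan: 35 subsets, min corrected p=1, significant: 0
ephys_contrast: 8/16 units, laser +4.72%+-11.20  wilcoxon p=0.74
```

Reading it: the marked subpopulation is generated less orientation
selective than the unmarked one, and the analysis recovers that ordering
(at this small n the difference is not yet significant — at the default
study-scale configuration of 65 + 173 cells it is); direction selectivity
does not differ by construction; per-stimulus calcium responses track the
same cells' spiking; no clustering is found within the marked group; and a
small simulated laser effect is invisible at 16 units but highly
significant at the default 64-unit session.

The same steps are available as library calls (`generate_population`,
`build_protocol`, `simulate_spikes`, `compute_dff`, `trial_responses`,
`orientation_selectivity`, `size_tuning`, `fit_naka_rushton`,
`cluster_scan`, `laser_modulation`, …); see the module docstrings.

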