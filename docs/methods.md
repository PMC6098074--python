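# Methods

## The forward model

Each simulated neuron is a `GroundTruthCell` whose expected firing rate for
a drifting-grating stimulus factorises as

    rate = [ baseline + rate_max · f_dir(φ) · f_size(d) · f_sf(f_s) · f_tf(f_t) · f_con(c) ] · g_laser

with every factor normalised to 1 at the cell's preferred stimulus, so that
the preferred full-contrast stimulus drives the cell at baseline + rate_max
(up to the contrast factor, which is c/(c+C₅₀)-saturating and below 1 even
at 100% contrast).

- **Direction**: a doubled-angle von Mises, exp(κ(cos 2Δ − 1)), multiplied
  by a smooth opposite-lobe weight w(Δ) = b + (1−b)(1+cos Δ)/2, b ∈ [0,1].
  In the continuum the circular moments give OSI = I₁(κ)/I₀(κ) independent
  of b, and DSI = (1−b)(1+I₁/I₀)/(2(1+b)); both relations are inverted in
  closed form / by Brent's method so that per-cell OSI/DSI targets can be
  drawn directly.  Sampling at the 12 battery directions leaves only six
  distinct doubled angles, which aliases higher circular harmonics into the
  discrete OSI: the discrete value equals (I₁+I₅+I₇+…)/(I₀+2I₆+…), about
  +0.024 above the continuum value at κ = 4 and +0.003 at κ = 2.  Discretely
  sampled OSI is therefore a slightly biased estimator of the model's
  continuum OSI for sharply tuned cells — an inherent property of the
  12-direction battery, not of the implementation.
- **Size**: integrated excitatory minus inhibitory Gaussians,
  f(d) = [erf(d/2√2σ_e) − w·erf(d/2√2σ_i)]₊ with σ_i > σ_e, normalised to
  its maximum; off-centre stimuli are attenuated by a Gaussian of the
  centre offset.  The inhibitory weight w is solved per cell (Brent) so
  that the 95%-rule suppression index measured on the 20–100° battery hits
  a drawn target; σ_e is clipped to ≤16° so the battery reaches the curve's
  asymptote and targets stay reachable, and the *achieved* SI is stored as
  ground truth.
- **Spatial/temporal frequency**: a difference of Gaussians in linear
  frequency with a narrower surround (σ_i = s·σ_e, s < 1) that cuts low
  frequencies; amplitude ratio a ∈ [0.25, 0.95).  This is the same family
  the analysis fits, which makes generate-and-fit recovery of the half-max
  frequency well posed; the cell's realised peak frequency, high half-max
  frequency and low-pass flag are computed from a dense grid and stored as
  ground truth.  Defaults (σ_sf median 0.10 cpd, σ_tf median 5 Hz,
  lognormal spread 0.4) give population mean high half-max ≈ 0.15 cpd and
  ≈ 7.5 Hz with roughly half the cells low-pass.
- **Contrast**: Naka-Rushton cⁿ/(cⁿ + C₅₀ⁿ); the factor is exactly 0.5 at
  the cell's true C₅₀.
- **Laser**: a multiplicative gain applied to the whole rate (baseline
  included) on laser-on trials *and* on the grey period preceding them,
  because the light is on through the pre-stimulus interval; the measured
  response (rate − spontaneous) then scales exactly by the gain in
  expectation.

Spiking is homogeneous Poisson with the trial's rate inside each stimulus
epoch and the spontaneous rate between trials; within-trial dynamics
(e.g. temporal-frequency locking) are not modelled.  Fluorescence is a
linear indicator model: each spike adds amplitude·e^{−Δt/τ} to subsequent
frames (defaults τ = 1.8 s, amplitude 0.2·F₀ per spike, GCaMP6s-like
order of magnitude), plus white Gaussian noise per frame (default
3% of F₀; the paired calcium/spiking validation uses 1%).

## Population structure and study conditions

Default populations hold 65 marked and 173 unmarked cells.  True OSI is
drawn from Beta distributions with means 0.18 (marked) vs 0.25 (unmarked)
and SDs 0.16 / 0.13 (printed SEMs × √n); true SI targets have means
0.27 vs 0.41.  DSI, spatial/temporal frequency, C₅₀, rates and depths
(uniform 120–350 µm, layer-2/3-like) are drawn identically for both
groups, so any group difference the analysis reports in those metrics is a
false positive by construction.  Spontaneous and evoked rate scales are
free parameters (lognormal, medians 1.5 and 8 Hz for imaged cells); ephys
unit populations use multiunit-scale rates (medians 4 and 25 Hz) because
pooled single/multi-unit recordings carry several cells per channel and
the percent-change-of-response estimator has the response in its
denominator, which is only well conditioned for robustly driven units.

All randomness derives from one seed via numpy `SeedSequence.spawn` in a
fixed, documented stage order (population, protocol, spikes, fluorescence,
movie, ephys), so a session is a pure function of (config, seed).

## Analysis conventions

- ΔF/F baselines use the mean raw fluorescence over the 1 s window before
  onset (configurable); frames belong to a window when their start time
  falls in the half-open interval.  The responsiveness gate pools all
  trials against pooled pre-onset baseline samples in ΔF/F units with a
  one-sided Welch t-test at α = 0.1 plus the 5% maximum-response rule
  (the maximum is over per-stimulus mean responses).
- Negative mean responses are clamped to zero before OSI/DSI, the RF
  centre of mass and the size-tuning rule (the index formulas presuppose
  nonnegative mass); clamps are logged.
- Preference is the argmax of the mean response with ties broken toward
  the lowest angle; preferred orientation is the direction mod 180°.
- Selection rules are inclusive at their boundaries: size analyses require
  the preferred orientation within 30° of the presented one and an RF
  centre within 10° of the stimulus centre (the fixed 100 px ≈ 10°
  conversion); SF — and, by the same logic, TF — analyses require 60°.
- Frequency fits use bounded trust-region least squares with five
  data-driven starts (one near-constant), tolerance 1e-10; half-max points
  are interpolated on a 4000-point log grid over [min(f)/4, 4·max(f)].
  Contrast fits include a baseline term and constrain n ∈ (0.5, 6],
  C₅₀ ∈ (0, 100].
- The ephys percent change averages responses per laser state first and
  forms the ratio per unit; units with nonpositive laser-off responses are
  excluded from the percentage but kept in the paired Wilcoxon.  The
  per-unit Friedman test blocks condition levels (e.g. the five contrasts)
  against the two laser states.
- Spike detection thresholds negative crossings at 3× a robust SD
  (median |x| / 0.6745) with a 1 ms refractory merge.

## The dip statistic

`dip_statistic` is an exact implementation of Hartigan's dip: the minimal
sup-norm distance between the empirical CDF and any unimodal CDF (convex
below the mode, concave above, an atom allowed at the mode).  For each
candidate mode the cost is the larger of two one-sided band-threading
costs — computed from incremental convex hulls of the ECDF corner points —
plus a coupling constraint that the convex branch can end no higher than
the concave branch begins; the minimum over modes is found by bisection on
the band radius (tolerance 1e-11·n).  The implementation is validated in
the test suite against an independent linear-programming oracle that
solves the defining optimisation directly on small samples.  The statistic
is exactly invariant under affine maps of the data but *not* under
nonlinear monotone transforms (those genuinely change how clustered the
spacings are; a statistic invariant to all monotone transforms would be
distribution-free under every continuous null and hence powerless).
p-values are Monte-Carlo, from uniform null samples of the same size
(default 10,000 draws); the null table depends only on n and uses a fixed
internal seed so one table serves all subsets and repeated scans.

## Cluster scan sensitivity

The scan z-scores each feature per subset (units are incommensurate — µm
vs cpd vs unitless — so unscaled PCA would be dominated by depth), adds
seeded ±10 µm jitter to depth (cells imaged together share a depth, which
would otherwise fake clustering), takes the first principal component's
scores, and dip-tests them with Bonferroni correction over all 21 pairs +
35 triplets.  A consequence of z-scoring worth knowing: for any two-feature
subset the standardised covariance matrix has unit diagonal, so PC1 is
exactly the ±45° projection.  A cluster split that lives on a *single*
feature is therefore diluted by 1/√2 and its within-cluster spread inflated
by the other features' noise; a 6-within-SD separation on one feature
arrives on PC1 at only ≈1.8 within-SD — below the 2σ threshold at which a
two-Gaussian mixture is even bimodal — so the scan has essentially no
power against single-feature splits.  It is sensitive to cluster structure
shared across features (a joint two-feature split of the same size is
detected reliably; see the test suite).  This is a genuine property of the
z-scored-PCA + dip design, inherited by the pipeline.

## Problem sizes

Default study-scale runs use 65+173 cells, five-minute calcium batteries,
and 64-unit ephys sessions with eight repetitions per unique stimulus;
the acceptance script runs exactly this configuration.  Tests exercise the
same code paths on reduced populations and durations, and the Monte-Carlo
calibrations state their replicate counts inline (e.g. 10,000 null cells
for the responsiveness gate, 100 seeded runs for scan calibration and
laser recovery).

## Known limitations

- No biophysical calcium dynamics, motion artifacts, eye movements,
  neuropil contamination or anesthesia-state covariates are simulated, so
  passing tests certify the analysis logic, not robustness to those
  real-data nuisances.
- Measured OSI/DSI from finite noisy trials are upward-biased relative to
  ground truth (resultant-length bias); group *differences* are preserved.
- The 95%-rule preferred diameter is noise-sensitive and biased toward
  larger sizes at realistic trial counts.
- Spike sorting is out of scope; units are threshold crossings pooled per
  channel.
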