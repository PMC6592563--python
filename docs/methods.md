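# Methods

`tissuecorr` asks whether the space–time correlation seen in single-cell
reporter signals across a tissue is carried by cell contacts (juxtacrine
signalling, e.g. gap junctions) or by diffusing molecules (paracrine
signalling), and provides a parameterised stochastic model that reproduces
the contact-mediated case.  This note records the models, the numerical
choices, and what the synthetic data can and cannot show.

## Distances and the discrimination logic

Each unordered cell pair is characterised by three numbers: a similarity
score *r* of the two cells' transcriptional histories, the Euclidean distance
*d_E* between their median centroids (normalised by a reference cell diameter
so it is dimensionless), and the geodesic distance *d_G* — the minimal number
of cell–cell contacts on a path between them, infinite when the contact graph
disconnects them.

Contact-mediated coupling propagates along chains of touching cells, so among
pairs at similar *d_E* the score should fall with *d_G*.  Diffusion-mediated
coupling depends on physical separation, so among pairs with equal *d_G* the
score should fall with *d_E*.  The two conditionings are the juxtacrine and
paracrine tests; a third test regresses *r* on *d_E* among touching pairs
(*d_G* = 1), where a shorter centroid distance proxies a larger contact area.

Trends are fitted by median (quantile τ = 0.5) regression, which is robust to
the non-normal, bounded distribution of correlation coefficients.  The slope
is tested one-sided (H1: slope < 0) with a bootstrap standard error
(pair-level resampling, 999 resamples by default) and a Student-t reference
with n − 2 degrees of freedom.  Pair resampling ignores the dependence
between pairs sharing a cell, so a cell-level block bootstrap is available
(`resample="cells"`); the default follows the simpler scheme because the
type-I calibration test shows it is not anticonservative at the sample sizes
used.  Pairs with infinite *d_G* are excluded from every regression and their
count is reported.  No multiple-testing correction is applied across windows;
all p-values are reported together so users can correct as they see fit.

Default conditioning windows: *d_E* ∈ (0, 1.5], (1.5, 2.5], (2.5, 3.5] cell
diameters for the juxtacrine tests, and the overlapping sets *d_G* ∈ {2, 3}
and {3, 4} for the paracrine tests — overlapping because a 2-D projection can
only overestimate *d_G*, and agreement across the two windows hedges against
that bias.  For validating the discrimination logic on the simulator, the
juxtacrine window is *d_E* ∈ (0, 2.5]: in the dense synthetic tissue nearly
all pairs with *d_E* < 1.5 are already touching, leaving no variation in
*d_G* to regress on, while (0, 2.5] spans *d_G* = 1–3.

## Contact-network sampling

Only centroids are observed.  Cells are modelled as circles with diameters
drawn i.i.d. from a Gamma distribution parameterised by the tissue's mean and
sd of cell diameter (default 12.0 ± 2.2 µm; shape = (µ/σ)², scale = σ²/µ);
two cells are in contact when the centroid distance is at most the sum of
radii (tangency counts).  Each cell gets one diameter per sample — a cell has
one size — and the per-pair geodesic distance is the elementwise median over
999 sampled networks.  An odd sample count makes the median itself a sample
value, so entries are integers or infinity, never interpolated.  Geodesic
distances are scale-invariant: rescaling coordinates and the size
distribution together leaves them unchanged.

The reference diameter for normalising *d_E* defaults to the mean of the size
distribution (12.0 µm); for Gamma(12.0, 2.2) the mean and median differ by
under 2%, so the choice is immaterial at the precision of the analysis.

Centroid clouds also bound the mean cell size without any size measurement:
with N cells, N_ch of them vertices of the convex hull of area A_ch, the
average cell area lies between A_ch/N and A_ch/(N − N_ch), giving diameter
bounds √(A_ch/N) and √(A_ch/(N − N_ch)) under the model of a circle inscribed
in the square of average area.  That model implies cells cover π/4 ≈ 79% of
the tissue area, which is only sensible for densely packed tissue — the
regime the method targets.

## Signal reconstruction

Imaging records each cell simultaneously in a sensitive channel I¹ that clips
above a saturation level and a coarse linear channel I².  Where I¹ is
unsaturated the channels are linearly related, I² = α + β I¹; fitting (α, β)
by OLS on the unsaturated range allows the clipped stretch to be replaced by
(I² − α)/β, restoring one signal linear in the fluorophore population.  The
saturation onset I¹_min is not printed anywhere in the imaging metadata, so
it defaults to 95% of the observed channel-1 maximum — deliberately
conservative — and can be overridden when the detector's clip level is known.
Calibration is pooled per dataset (a single (α, β)), matching the physical
picture of one detector pair.  No background subtraction, detrending or
photobleach correction is applied.

## Similarity scores

- **Pearson r** at zero lag between reconstructed signal series (an
  `optimal_lag` diagnostic exists for QC; zero lag dominates in this system).
- **Sc1** (levels): candidate step-function transcription profiles from
  upstream Bayesian switch inference come with occurrence probabilities.
  Sc1 is the *expected pairwise Pearson correlation* under the product of the
  two cells' candidate distributions: Σ_p Σ_q w_p w_q · r(profile_p,
  profile_q), profiles sampled right-continuously on a shared 15-min grid.
  The alternative reading — Pearson of the probability-weighted mean
  profiles — is deliberately not the default: averaging profiles first
  destroys per-candidate correlation structure, and the double sum reduces
  exactly to plain Pearson when each cell has a single candidate.  Candidate
  pairs with a degenerate (constant) profile are skipped with weight
  renormalisation.
- **Sc2** (timing): each switch becomes a Gaussian density bump of sd 3 h at
  the switch time, signed +1 for an up-switch and −1 for a down-switch;
  candidates are combined with the same double weighting.  Unit amplitudes
  throughout — Pearson is scale-invariant, so whether the kernel is
  peak-normalised is immaterial.  Identical trains score exactly 1 at any sd.

## The stochastic tissue model

Each cell carries 4 copies of the gene, each cycling on → off → primed → on
with exponential holding times.  Estimated means: on 11.605 h, refractory
3.5 h, off 15.1 h; the per-copy rates are the printed per-cell rates divided
by 4.  mRNA is born at 4.25/4 per on copy and 0.275/4 per off/primed copy per
hour and dies at µ = 0.14095 per molecule per hour.

Coupling: a cell senses n(t), the number of on copies summed over its contact
neighbours (itself excluded), which multiplies its off→primed and primed→on
rates by (1 + δ n(t)) and optionally its on-copy transcription rate by
(1 + δ_b n(t)); δ ∈ {0.3, 0.5} with δ_b = δ/10 are the study settings.

Recordings start from quiescent tissue and show a bell-shaped ensemble mean,
so both transcription rates are modulated by α e^(−t/12 h), with α = 4/(1 −
e⁻⁴) ≈ 4.0747 chosen so the modulation integrates to the 48 h horizon, and
all cells start with every copy off and zero mRNA.

The modulation makes the process nonhomogeneous.  Simulation stays exact:
between events the total propensity has the closed form c₁ + c₂ e^(−s/12),
so the waiting time solves log U + ∫ r(s) ds = 0 analytically where a
component vanishes and by safeguarded Newton iteration otherwise (the
integral is concave and increasing, so Newton from the homogeneous guess
converges monotonically; tolerance 1e−13 relative).  The reaction fired at
t + τ is drawn from the instantaneous rates at t + τ.  Coupling factors are
re-evaluated after every event — exact, since n(t) is piecewise constant
between events.  This integration approach was chosen over per-reaction
thinning: both are exact, but integration has no rejection-rate tuning.

The transcription-rate read-out β(t) = β_H N(t) + β_L (F(t) + P(t)) uses the
base per-copy rates — neither the coupling factor nor the decay modulation —
because that is the quantity switch inference would reconstruct from data.

With coupling and decay disabled the model is a renewal-modulated birth–death
process whose stationary mean mRNA per cell is (β_H p_on + β_L (1 − p_on))/µ
with p_on = T0/(T0+T1+T2) ≈ 0.384, i.e. ≈ 12.8 molecules — the closed form
the stationarity test checks.

The `slope_experiment` battery repeats (fresh tissue → simulate → pairwise
correlations → median-regression slope against d_E) across replicates, at
both the mRNA and the β(t) level, over all pairs and restricted to short
range (d_E < 2 diameters, where gradients are steeper).

## Parameter estimation

Step profiles are first reduced to alternating switch trains: runs of
same-direction switches collapse to their first switch (continuous switch
inference often emits several same-direction switches that the discrete
three-state model regards as one episode).  Up→down gaps are on-durations,
down→up gaps are down-durations (refractory + off); the final open-ended gap
of each train is right-censored at the horizon.  The segment before the first
switch is discarded: its starting state is unobserved, and treating it as a
duration of either kind would require a left-truncation model the data cannot
identify.

On-durations are exponential; the censored MLE is the closed form
(Σ all durations)/(# complete).  Down-durations are hypoexponential (sum of
two exponentials); the censored log-likelihood Σ log f_d + Σ log(1 − F_d) is
maximised in log-parameters by Nelder–Mead from five starts (method-of-
moments plus a coarse grid, tolerance 1e−8), with the constraint T1 < T2
imposed by ordering afterwards — the likelihood is exchange-symmetric, so the
constraint merely selects one of two equal maxima.  Density and survival are
evaluated in log space, continued through the Erlang-2 limit as the two rates
approach; a fit landing on the diagonal is flagged.  The printed forms of
these likelihoods are sums of densities; they are implemented as
log-likelihoods, since the argmax of a sum of densities is not an MLE.
Candidate-profile weights propagate into the likelihood as observation
weights.  Transcription rates β_L and β_H are probability-weighted medians of
post-down-switch and post-up-switch levels.

## Synthetic data: what it does and does not emulate

The generator provides every input the pipeline consumes.  Defaults are the
study conditions: 100 cells in a 90 × 90 µm field (drawn count optional),
Gamma(12.0, 2.2) µm diameters, 48 h at 15-min cadence, channel-1 saturation,
linear channel 2, additive Gaussian intensity noise (the imaging noise model
is not characterised further, so Gaussian with configurable sd is the
package's choice), and frame-to-frame centroid jitter of 0.5 µm.  The stated
field intensity of the source tissue is internally inconsistent with its
stated cell count (it implies ~10 cells where ~100 are reported, and ~100
cells are required for the dense packing every other part of the analysis
assumes); the generator therefore treats the 90 µm field and the ~100-cell
count as the binding constraints.

Duration fixtures use *non-informative* right-censoring: each duration
competes with an independent exponential censoring time whose rate is
calibrated so the expected censored share equals `censor_fraction`.  A scheme
that truncates a chosen subset at a uniform fraction of their own value was
considered and rejected: there the censoring time depends on the value it
censors, the standard censored likelihood is mis-specified, and the
exponential MLE acquires a +p/(2(1−p)) relative bias (≈ +5.6% at 10%
censoring) — an inconsistency between generator and estimator, not a property
of either.

Not emulated: microscope optics, z-stacks, photobleaching, cell movement
beyond stationary jitter, the reporter-protein (translation/maturation) step
between mRNA and fluorescence — synthetic tracks are driven directly by an
mRNA-like signal — and 3-D geometry.  Passing tests therefore demonstrate
the statistical machinery under the assumed data-generating structure, not
robustness to real-data artefacts such as segmentation errors or spectral
bleed-through.

## Problem sizes and determinism

Monte-Carlo checks use sizes at which their tolerances are meaningful:
10⁴ draws for duration-recovery (3 s.e. acceptance), 50 cells × 200 h for
the stationarity oracle, 50 tissue replicates × ~100 cells for the coupling
and discrimination batteries, 999 network samples per tissue, and 999
bootstrap resamples per slope test (reduced in the quick examples).  All
randomness flows through explicit integer seeds (replicate k derives seed +
k); identical seeds give bit-identical outputs, and the pipeline stamps every
output file with the config hash and seed.

## Known limitations

- 2-D contact inference can only overestimate geodesic distance; the
  overlapping paracrine windows mitigate but do not remove this.
- The bootstrap p-value treats pairs as exchangeable; pairs sharing a cell
  are not independent (the cell-level option exists but is approximate).
- Sc1's double-sum definition is one of two defensible readings of
  probability-weighted profile correlation; the other (correlation of
  expected profiles) is available via the same building blocks but is not
  the default.
- The hypoexponential MLE becomes ill-conditioned when the two means are
  close (near-Erlang data); the boundary flag marks such fits.
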