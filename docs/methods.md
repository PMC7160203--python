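# Methods

## The variability statistic

For a preprocessed run with repetition time TR = 2.3 s and *t* = 125
volumes, every in-brain voxel's time series is decomposed with a
zero-phase DFT brick-wall filter: rfft coefficients with
`f_lo ≤ f ≤ min(f_hi, Nyquist)` are retained (the DC bin only when
`f_lo = 0`), everything else is zeroed. Band SDs are evaluated directly
from the retained spectral power (Parseval), which is numerically
identical to filtering and taking the time-domain SD but roughly twice as
fast; the equivalence is asserted in the tests to 1e-16.

* **SD** uses the sample convention (denominator *t* − 1) throughout, so
  fSD is a ratio of like estimators.
* **Whole band.** The nominal whole band (0–0.25 Hz) exceeds the Nyquist
  frequency at TR 2.3 s (≈ 0.2174 Hz); it is implemented as the full
  spectrum of the mean-centred series, i.e. 0–Nyquist. This is stated
  loudly because 0.25 Hz is simply unrepresentable at this sampling rate.
* **fSD** = SD(sub-band)/SD(whole band). Voxels whose whole-band SD falls
  below 1e-8 × the in-mask grand SD are removed from the usable mask
  rather than given a fabricated value; all bands share the resulting
  intersection mask.
* **z-fSD** standardises each subject's own fSD map across in-mask voxels
  (denominator *n* − 1). A spatially constant fSD map (e.g. a pure
  sinusoid phantom) has no defined z-map and raises instead of returning
  zeros. fSD and z-fSD are invariant to any positive rescaling of the
  input, which is why grand-mean scaling cannot affect them — verified
  bitwise in tests.

At *t* = 125 the slow5 band spans 5 rfft bins and slow4 spans 13, so
single-voxel fSD estimates are intrinsically noisy (relative SD ≈ 20%
for slow5); spatial smoothing and cluster-level inference, not per-voxel
precision, carry the analysis.

## Preprocessing arms

**GSR arm order:** drop initial volumes → despike → grand-mean scale →
smooth → detrend → nuisance regression. Despiking winsorises samples
beyond 4 robust z-scores of each voxel's median/MAD (a deliberate,
simple stand-in for dedicated despiking tools). The nuisance design is
[intercept, 6 motion parameters, CSF, WM, global signal], no derivative
or squared terms; the global signal is the mean in-mask series,
recomputed from the data at the regression step. The despike → grand-mean
order and the decision not to band-limit the nuisance regressors are
fixed here as package conventions; with band-limited regressors,
regression and band-pass filtering commute (tested).

**ICA arm order:** drop → smooth → grand-mean scale → spatial ICA →
component scoring → threshold rejection → non-aggressive removal →
detrend. Dimensionality is the smallest k explaining ≥ 90% of the
high-passed (0.01 Hz) variance, capped at t/4 — a deterministic
replacement for Laplace-approximation model selection. FastICA runs with
the deflation update (converges on low-rank phantoms where the symmetric
update stalls), retried up to 3 times with fresh seeds before raising an
error that carries the attempt log. Removal regresses all component time
courses jointly and subtracts only the noise components' unique
contribution, so it is idempotent and preserves variance shared with
signal components. A final linear detrend replaces the drift handling
that the high-pass performs inside the decomposition (removal operates on
the unfiltered data).

**Component noise score** (0–100) is a clipped weighted sum of five
bounded features, monotone in each: time-series spikiness (weight 40),
brain-edge energy fraction (25), non-grey-matter energy fraction (25),
spectral power fraction above 0.1 Hz (60), and spatial roughness — one
minus the correlation of the map with a lightly smoothed copy of itself,
which fires for sparse alternating-sign patterns but not for coherent
blobs (30). Rejection applies to components scoring **above** the
threshold chosen on a labelled training set by maximising the balance
ratio (3·TPR + TNR)/4 over the grid of observed scores, ties resolved
toward the larger threshold (conservative rejection). With no noise
components in the training set TNR is defined as 1 and the selector
degenerates gracefully to "keep everything".

## Group statistics

Voxelwise one-way ANCOVA by OLS: group dummy-coded against HC (results
are invariant to the reference choice — tested), covariates age, sex,
education, total grey-matter volume, optionally motion and CeVD status.
Omnibus group effect is the 2-df F test; pairwise comparisons are
one-sided t contrasts per direction. Voxels whose residual sum of squares
falls below a numerical floor are reported as statistic 0 rather than as
0/0 noise.

Cluster inference: supra-threshold voxels at voxel-defining p < 0.001
(parametric t or F tail) are grouped by 18-connectivity (configurable),
and family-wise error is controlled by Freedman–Lane permutation: the
data are residualised on the covariate-only model, residual rows are
permuted (the statistic of the permuted fit depends only on these
residuals, which makes the permutation loop a handful of matrix
products), and the null distribution of the maximum cluster is recorded.
The null is ordered lexicographically by (cluster size, excess mass =
Σ(stat − threshold)): with spatially coherent data whole parcels cross
the threshold together, cluster sizes tie heavily, and a pure size
ranking makes the achievable p-values so coarse that the empirical FWER
collapses toward zero; ranking ties by the continuous mass restores
near-uniform p-values while keeping size as the primary criterion.
p = (1 + b)/(1 + n_perm), so p is never zero. The lenient reporting rule
(uncorrected cluster p with extent k ≥ 40, inclusive) is available as a
separate, clearly flagged output.

Measured calibration on 150 null phantoms (12/12/12, n_perm = 500):
FWER 0.02 with the mass tie-break, ~0.03 on plain smoothed Gaussian
fields — mildly conservative, as expected from residual-permutation
schemes at n = 36 and the residual discreteness of cluster statistics.

## Associations

Cluster ROI means are partially correlated (double residualisation on
[intercept, age, sex, education, GMV]; two-tailed t with
df = n − n_cov − 2) with baseline cognition, hippocampal volume, and
cognitive decline = year-2 minus baseline (negative = worsening), in the
combined aMCI + AD sample. Missing year-2 scores propagate by listwise
deletion and `n_used` is reported; an outcome with too few complete cases
yields an NA row rather than an error. Bonferroni multiplies raw p by the
number of clusters in the band, capped at 1.

## Cohort statistics

Categorical rows use Pearson chi-square without continuity correction;
continuous rows use the one-way ANOVA reconstructed from per-group
(mean, SD, n) — a lossless reconstruction, verified against raw-data
ANOVA to 1e-10. Post-hoc pairwise tests are Fisher-LSD t tests on the
pooled within-group variance. Inclusion arithmetic subtracts the stated
quality-control exclusions from enrolment counts per group.

## The synthetic phantom

Each grey-matter voxel carries a sum of spectrally disjoint band-limited
processes (slow5, slow4, and a "high" remainder band above slow4) built
in the frequency domain with flat amplitude and uniform random phases, so
the injected population SD per band is exact and fSD has an analytic
value. Per-(group, network, band) multiplicative factors inject disease
effects; defaults encode the qualitative pattern of interest (posterior
DMN and visual network up, salience network down in aMCI at slow5;
posterior-DMN slow4 reduced in AD) and are deliberately band-specific —
fSD is invariant to broadband scaling, so only relative band changes are
observable.

Key defaults and why:

* grid 24 × 24 × 18, six disjoint rectangular parcels of ≥ 30 voxels
  (posterior/anterior DMN, SN, VN, hippocampus, generic background grey)
  inside a brain mask that also contains a non-grey rind;
* 125 volumes at TR 2.3 s (the scan duration after discarding the
  initial volumes), baseline intensity 100 (so grand-mean scaling is
  well-posed);
* `network_coherence` 0.5: each parcel shares a common band process
  carrying half its variance. Temporal coherence is the defining feature
  of a resting-state network and the spatial structure that
  cluster-extent inference exploits; fully independent voxels make
  cluster recovery unrealistically patchy;
* white noise SD 0.5, linear drift amplitude 1.0, Poisson(1) motion
  spikes of amplitude 6 with matching jumps in the recorded motion
  traces; head-motion geometry itself is not simulated — the phantom is
  "pre-aligned" and motion enters only as artifacts plus recorded traces;
* a shared global nuisance signal (band-limited to slow4) can be coupled
  brain-wide via the `(group, "brain")` key with additional
  network-specific weights — a global signal must pervade the brain for
  the brain-mean regressor to estimate it;
* each subject draws a log-normal jitter (σ = 0.2) on the posterior-DMN
  slow4 factor; baseline cognition (group means anchored to the published
  cohort's values), two-year decline, and hippocampal volume are linear
  in this latent factor plus Gaussian noise (slopes 5 z-units, 3 z-units,
  800 mm³; noise SDs 0.5, 0.4, 150), so lower slow4 DMN variability goes
  with worse cognition, faster decline and smaller hippocampus by
  construction. Year-2 cognition is missing completely at random for 30%
  of subjects;
* cohort covariates: age ~ N(73, 6), education ~ N(7, 5) truncated at 0,
  GMV ~ N(600, 60), motion and CeVD rates per group matching the
  published cohort's descriptives. Default cohort 12/12/12; a
  published-cohort-sized preset (48/98/96) exists.

The labelled ICA training fixtures pair smooth, band-limited,
network-localised signal components with the five noise archetypes
(spiking time series, brain-edge rings, non-grey localisation,
high-frequency/high-power spectra, sparse alternating-sign maps) and —
mirroring conservative manual classification practice — include
brain-wide smooth low-frequency components labelled *signal*, so the
trained threshold retains global/physiological components.

**What the phantom does not emulate:** anatomy and registration,
physiological (cardiac/respiratory) noise spectra, spatial noise
correlations beyond parcel coherence, multi-site effects, realistic
lesion topography. Passing tests therefore demonstrate the correctness
and calibration of the statistical machinery under the stated generative
model, not performance on acquired data.

## Problem sizes used in tests and the acceptance script

Analysis experiments run at desk scale: a 16 × 16 × 12 grid (30-voxel
parcels) for calibration, association and mechanism experiments, the full
24 × 24 × 18 grid for effect recovery, 12/12/12 cohorts for group
comparisons and 30 + 30 patients for associations, with 300–500
permutations. The mechanism experiment (GSR-vs-ICA sign flip) disables
spikes and drift to isolate the global-signal pathway, and uses
brain-wide coupling 0.8 with an extra 0.7 into SN for aMCI against an
intrinsic aMCI SN slow4 factor of 0.67: the GSR arm then sees the
intrinsic decrease (global variance removed), the ICA arm the coupled
increase. `scripts/acceptance.py` repeats the same experiments at
reduced replication (8–60 repetitions per quantity) and reports each
value with its problem size.

## Known limitations

* Permutation p-values are mildly conservative at n = 36 (Freedman–Lane
  with 7 design columns); the calibration band in the tests reflects
  this.
* The five-feature component score is a compact stand-in for a full
  classifier ensemble; its threshold is data-set specific and the
  published threshold/ratio values are not reproduction targets.
* Brick-wall filtering leaks for frequencies off the DFT grid (worst
  case half-bin offset); the tests quantify this rather than hide it.
* The lenient k ≥ 40 rule is tied to the published voxel size; on the
  phantom grid it is a reporting convention, not a calibrated error rate.
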