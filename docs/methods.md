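# Methods

This note documents the models, conventions and numerical choices behind
`cognet`, and what the synthetic-data tests do and do not establish about
behaviour on real data.

## Data model

A subject's BOLD series is a voxels × time matrix **X** under a fixed 3D
mask. Voxels are linearised in canonical order: mask coordinates sorted
ascending by x, then y, then z (exactly `numpy.argwhere` on the boolean
mask). Written maps fill out-of-mask voxels with 0 (not NaN) for viewer
compatibility, and are stored as 32-bit floats, so round-trips are exact to
float32 precision only. Affines must agree to 1e-4 per element between an
image and its mask; no registration, smoothing or slice-time correction is
performed — inputs are assumed pre-registered to a common grid.

## Reduction and model order

Each subject's series is voxel-wise demeaned and projected on its top
temporal principal directions (default retention 1.5·K, capped at the
numerical rank; note that per-voxel demeaning costs one temporal dimension).
The reduced matrices are concatenated along the reduced-time axis,
column-demeaned over voxels, and the top-K subspace whitened. The whitened
matrix handed to ICA is **K × voxels** with zero-mean unit-variance rows:
spatial ICA treats voxels as the i.i.d. sample dimension. The whitening and
de-whitening transforms are exact inverses on the retained subspace
(verified to 1e-8).

The model order is either fixed by the caller (typical for replication runs;
the reference study fixed K = 72) or selected by minimum description length
in the classical signal-array form

    MDL(k) = −(p−k)·N·log( gm(λ_{k+1..p}) / am(λ_{k+1..p}) )
             + ½·k·(2p−k+1)·log N ,

minimised over k = 0..p−1. The spectrum is that of the pooled temporal
covariance estimated across mask voxels, so N is the voxel count. The
estimate is invariant to global rescaling of the spectrum. Degenerate cases:
a flat spectrum returns 0 with a warning ("no detectable sources"); a
numerically zero noise floor (noise-free synthetic data) returns the exact
rank, since k sources then describe the data perfectly.

## InfoMax and ICASSO

InfoMax maximises output entropy through a logistic nonlinearity by natural
gradient, which matches super-Gaussian (spatially sparse) sources. The
implementation follows the classical recipe: data visited in shuffled blocks
(block ≈ √(N/3), clipped to [8, 512]), update
W ← W + η((block·I + (1−2g(WX))(WX)ᵀ)/block)W, initial learning rate
η = 0.015 annealed by 0.9 whenever the weight-change direction swings by
more than 60°, random Gaussian initial weights (rejected if near-singular),
convergence when the maximum absolute weight change over a pass falls below
1e-6, at most 500 passes. Weight blow-ups trigger a restart at half the
learning rate. Non-convergence is flagged, not raised. Every source map's
sign is fixed so its skewness is nonnegative; this makes runs reproducible
and gives scores a consistent orientation downstream.

ICASSO reruns InfoMax under *bootstrap* (resampling the ICA sample
dimension, i.e. voxels, with replacement), *randinit* (fresh initial
weights), or *both*; bootstrap-only is the default. Estimates are always
evaluated on the full data so they are comparable, pooled, and clustered by
average linkage on distance 1 − |corr|, cut at exactly K clusters. Each
cluster reports

    Iq = mean intra-cluster similarity (self-pairs excluded)
         − mean member-to-non-member similarity ,

with a singleton's intra term defined as 1 and the extra term as 0 when the
cluster holds every estimate. The centrotype is the member with maximal
total intra-cluster similarity. Components are ordered by descending Iq.
Note that even bit-identical duplicate runs give Iq slightly below 1
whenever distinct components are weakly correlated — the extra-cluster term
is then small but nonzero.

## Component QC

Group maps are z-scored over the mask (population sd). The extent rule
excludes a component when fewer than 50 voxels reach |z| ≥ 1.0 — the count
of exactly 50 passes. The retention threshold on stability is Iq ≥ 0.8.
Exclusion order is fixed: stability, then the artifact label, then extent;
the report partitions the input and re-screening the retained set is a
no-op. Artifact identification and canonical-network classification
(AUD/CCN/DMN/SMN/VIS/CBL/SCN) are expert judgements consumed from a
two-column label file; they are not inferred. Low-frequency dominance — the
periodogram power fraction in (0, 0.1 Hz], zero-frequency excluded — is
computed and reported but not enforced by default (pass `enforce_lowfreq`
to make it an exclusion); for white noise the expected ratio is
band-edge/Nyquist (0.4 at TR = 2 s).

## Dual regression

Stage 1 regresses each time point's volume on the voxel-demeaned group maps,
giving subject time courses; stage 2 regresses each voxel's series on the
variance-normalised time courses, giving subject maps whose betas carry
amplitude. With this normalisation, rescaling a group map by c scales its
stage-1 time course by 1/c and leaves stage-2 maps unchanged. Group maps
must be full row rank (condition number ≤ 1e8); collinear components are
named in the error. A `normalize_timecourses=False` variant exposes the raw
convention.

## Network expression scores

For each subject and component: (a) take the back-reconstructed subject map;
(b) subtract the subject's own voxel mean; (c) subtract the across-subjects
mean profile (double centering, computed over all subjects); (d) project on
the group z-map and divide by the topography's squared norm; (e) z-transform
each column against the control group, so control columns have mean 0 and
sd 1 and patient scores read as standard deviations from controls.
Classical SSM log-transforms strictly positive images before centering; ICA
maps are signed, so the log step is omitted and the subtractive double
centering retained (`ssm_log` is documented but refused if enabled).
Scores are invariant to adding a subject-wise constant and to positively
rescaling a topography.

## Domain models

Stepwise regression is bidirectional with the conventional entry/removal
thresholds 0.05/0.10 (the defaults of the statistics package such studies
typically use). Forward entry picks the candidate with the smallest
coefficient p-value; backward removal drops included predictors whose
p-value reaches the removal threshold; iteration stops at a fixed point,
with a cycle guard (at most 2·p sweeps; a revisited state terminates at the
best-R² state seen). Candidates whose entry would push the design's
condition number beyond 1e8 are refused with a note. Fits are ordinary least
squares (statsmodels); confidence intervals are t-based with df = n − k − 1,
two-sided. An empty selection marks the domain "not generated" — the
expected outcome for a score that carries no network signal, though with
6 candidates at entry α = 0.05 a null domain still acquires a spurious
model in roughly a quarter of replicates; that false-generation rate is a
property of stepwise selection itself, not of this implementation.

Models are fitted on the patient group only (controls have no MoCA domain
scores) and without covariate adjustment by default. Composite
domain-related networks are voxelwise sums of the *group* z-maps weighted by
the fitted coefficients, preserving sign. Hubs are components selected in at
least two generated models, sorted by membership count then component
number. Group comparisons are two-tailed pooled-variance t-tests per
component at α = 0.05 with no multiplicity correction (a Welch variant is
available), plus a summary-statistics form for published means/sds.

## Synthetic cohorts

The generator reproduces the *statistical* structure the pipeline assumes,
not anatomy:

- **Sources** — Gaussian blobs (default σ = 1.5 voxels) inside an
  ellipsoidal mask, centres placed by farthest-point sampling with local
  refinement so pairwise map |cosine| ≈ 0.05 (< 0.2 guaranteed). The width
  serves ICA identifiability: sparser sources shrink the finite-sample ICA
  error, and every map is checked at generation to have ≥ 50 voxels at
  |z| ≥ 1 so true sources survive the extent filter by construction.
- **Time courses** — built in the frequency domain on bins inside
  0.01–0.08 Hz (TR = 2 s), so spectral power is in-band by construction;
  requesting a band at or above Nyquist is an error.
- **Mixing** — subject loadings ~ N(1, 0.3²) per component; the patient
  group's mean loading is reduced by 0.15 on the last two components by
  default (mild expression loss); additive white Gaussian noise
  (σ = 0.1; an AR(1) option exists because real BOLD noise is
  autocorrelated).
- **Cohort** — 40 patients, 15 controls, 150 time points by default;
  ages/sex/handedness/MMSE/LED drawn to resemble a typical PD-vs-control
  sample; maximum displacement drawn in [0.2, 2.0] mm so the motion screen
  excludes nobody by default.
- **Domain scores** — each MoCA domain uses its standard integer range
  (visuospatial/executive 0–5, naming 0–3, attention 0–6, language 0–3,
  abstraction 0–2, delayed recall 0–5, orientation 0–6). Patient scores are
  planted sparse linear models on the loadings, rounded and clipped;
  delayed recall is planted null by default so the "no model generated"
  outcome class is exercised. Residual sds are calibrated from a target R²
  (default 0.6; abstraction 0.3), treating the rounding variance 1/12 as
  part of the non-signal variance, and planted signal sds are scaled to
  (range width)/6 so clipping is negligible; realized generating-model R²
  then averages on target (the small remaining gap at n = 40 is the usual
  downward bias of the sample R² statistic).

What passing tests show: each stage recovers what this generator planted,
at the stated problem sizes. What they do not show: robustness to real
BOLD structure — hemodynamic variability, motion and scanner artifacts,
spatially correlated noise, non-Gaussian source shapes — none of which the
generator emulates.

## Problem sizes and runtime choices

The test-suite and acceptance-script experiments run on a 20×20×10 grid
(≈ 1450 mask voxels), 6 sources, 150 time points, with 10-subject noise-free
cohorts for ICA recovery (ICASSO 20 runs) and 55-subject default cohorts
for end-to-end replication (ICASSO 10 runs, 20 replicates); stepwise
selection is benchmarked against exhaustive best-subset search (BIC, subsets
up to size 4, 10 candidates, n = 200, 100 replicates) and the group t-test's
type-I error against 2000 null replicates. These sizes keep a full run in
the minutes range on one CPU while leaving each check statistically
meaningful.

## Known limitations

- Back-reconstruction implements dual regression only (no PCA-based GICA
  back-projection).
- Order selection offers MDL only (no AIC or Laplace evidence).
- Stepwise selection at entry α = 0.05 admits spurious predictors at the
  binomially expected rate; agreement with best-subset BIC is therefore
  structurally below ~85–90% whenever null candidates exist. Users wanting
  sparser models should tighten `alpha_enter`.
- Canonical-network labels come from the analyst; no template matching is
  provided, and no anatomical (Brodmann/cerebellar-lobule) naming.
- No cross-validation or held-out validation of domain models.
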