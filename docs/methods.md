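# Methods

## Gradient estimation

Per subject, the P×P functional-connectivity matrix is the Pearson
correlation of the parcellated time-series, Fisher z-transformed with the
diagonal set to 0 (atanh(1) is undefined, and the zeroed diagonal guarantees
sparsification never keeps self-connections). Negative correlations are
retained through the z-transform; no thresholding happens before
sparsification.

Sparsification keeps, per row, the k = round(density·(P−1)) largest
off-diagonal values by signed value (density 0.10, so k = 20 at P = 200),
with ties broken toward lower parcel index via a stable sort. The affinity
is the cosine similarity between sparsified rows with negative values
clipped to 0 — the standard kernel for connectivity-profile similarity. A
disconnected affinity graph is a hard error (component sizes reported), not
something silently repaired: it means the connectivity structure cannot
support a single embedding.

The diffusion-map embedding uses anisotropy α = 0.5 and multiscale scaling
λ/(1−λ) (diffusion time 0); both are exposed in `RunConfig`. Numerically
the Markov operator is diagonalized through its symmetric conjugate
D^{1/2} M D^{-1/2} (scipy `eigh` on the top n+1 eigenpairs), eigenvectors
are back-transformed and normalized against the trivial constant
eigenvector, which is then discarded. Explained variance is reported as
each retained non-trivial eigenvalue over their sum — a declared
convention, since no canonical normalization exists for this quantity.

Ten components are computed; the first two are analyzed. The template comes
from the element-wise mean of all subjects' z-matrices (mean of z, not of
r), with a deterministic sign convention (each column's largest-magnitude
entry positive). Subjects are aligned to the template by orthogonal
Procrustes — rotation plus reflection, no scaling or translation — jointly
on all ten components, which stabilizes the rotation before columns 1–2 are
extracted. Whether to align 2 or 10 components is a genuine free choice;
aligning all retained components is the default here because the rotation
estimate is then better conditioned.

## Network metrics

Within-network score: unweighted mean gradient value per network (networks
have unequal sizes; no size weighting). Within-network dispersion: sum of
squared Euclidean distances to the network centroid in the (G1, G2) plane.
Between-network dispersion: Euclidean distance between centroids in the
same plane. Global variation: sample standard deviation (denominator P−1)
of each of the first two gradients across all parcels. These satisfy the
ANOVA decomposition (pooled within-dispersion + size-weighted
between-centroid scatter = total scatter), which the tests verify.

## Group statistics

The group effect on (G1, G2) is tested with Hotelling's T² formulated as
the Hotelling–Lawley trace of a rank-1 hypothesis in a multivariate linear
model with intercept, group, age, sex (0/1 by first appearance), and mean
framewise displacement: T² = ν·tr(H E⁻¹) with ν = n − p, and the exact
transform F = T²(ν−q+1)/(qν) on (q, ν−q+1) degrees of freedom. With one
response this reduces to the square of the covariate-adjusted t statistic;
with intercept+group only it equals the classical two-sample T² — both are
asserted in the tests. Regional tests run vectorized across parcels with a
closed-form 2×2 error inverse.

Scalar metrics (dispersions, global variation) use OLS with the same
covariates and a two-sided t-test on the group coefficient (statsmodels).
Bonferroni families: parcels m = P, network scores m = K, within-dispersion
m = K, between-dispersion m = K(K−1)/2, global variation m = 2. The
correlation screen (patients only, pairwise deletion of missing values)
defaults to m = features × variables but is configurable, because no single
convention is canonical for that family. Spearman CIs use the Fisher
transform tanh(atanh(ρ) ± 1.96/√(n−3)); the 1.03/√(n−3) variance-inflation
variant is available behind a flag — both round to the same interval at two
decimals for ρ = 0.30, n = 116.

## Prediction

Features are the 14 within-network gradient scores; the target is the raw
SDMT score. The cohort splits once into 80% training/validation and a 20%
hold-out (size = ceil(0.2·n); 24 of 116), fixed across all repetitions —
repetitions re-draw only the CV fold splits. Each repetition runs fivefold
nested CV: the inner fivefold loop grid-searches depth {2,3,4} × learning
rate {0.05,0.1,0.3} × rounds {50,100,200} (a small grid spanning the
bias–variance range; subsampling fixed at 1 for determinism) by mean inner
MAE; per outer fold, an all-feature model's total-gain importances are
extracted, features are ranked by mean gain across outer folds, and models
restricted to the top-n features (n = 1..14) are scored on the outer
validation folds. The selected subset minimizes mean validation MAE,
smallest n on ties. Hold-out evaluation refits the selected model on all
training rows with the modal hyperparameters across outer folds.

Permutation significance shuffles the target and re-runs the identical
selection + validation procedure. To keep many permutations tractable the
permutation runs collapse the grid to the single configuration the observed
runs selected (logged); for exchangeability the observed MAE entering
p = (1 + #{null ≤ observed})/(n_perm + 1) is recomputed by that same
reduced procedure. Direction of influence is the Spearman correlation
between a feature's values and the selected model's out-of-fold
predictions, recorded for every feature.

With fixed seeds the entire stage is bit-reproducible (single-threaded
histogram tree method), and hold-out targets provably never touch training
(asserted by a mutation test).

## Synthetic cohorts

Subjects are temporally white, zero-mean Gaussian draws (an optional AR(1)
flag adds temporal smoothness; the pipeline consumes only correlations) from
a unit-diagonal covariance Σ = ΛΛᵀ + band + ψI, rescaled to correlation
form. Λ stacks:

- a global factor (between-network baseline correlation 0.05);
- one indicator factor per network (within-network correlation 0.35), with
  4 bridge parcels on each side of every network boundary splitting their
  loading between the two adjacent networks — parcellation boundaries are
  fuzzy in real data, and these bridges are also what keeps the sparsified
  affinity graph connected, since pure block structure makes top-10% row
  supports network-exclusive;
- two smooth axis columns (scales 1.0 and 0.6) interpolated along a
  canonical cortical ordering that places visual and sensorimotor cortex at
  opposite ends with transmodal cortex between them. Axis 1 (visual ↔
  sensorimotor) is therefore the slowest embedding mode and becomes G1;
  axis 2 (sensory → transmodal, DMN at the extreme) becomes G2, matching
  the gradient order reported for this preprocessing style. The DMN carries
  the largest |axis-2| anchor so the template sign convention puts the DMN
  at the positive end of G2.

The band is a squared-exponential spatial kernel (amplitude 0.3, length 2
parcels) emulating local spatial autocorrelation. ψ = 0.5 is idiosyncratic
parcel noise.

Planted effects (patients): the sensorimotor network-factor loading is
attenuated by 45% — a within-network coherence loss chosen as the planted
"connectivity shift" because additive shifts on the axis columns
redistribute globally through the embedding and alignment, moving every
network at once, whereas factor attenuation concentrates the detectable
effect in the planted network; and the whole axis-2 column is multiplied by
0.7 (gradient compression). Per subject, a latent coupling δ ~ N(1, 0.3)
(truncated at ±2.5 sd) scales the DMN entries of axis 2 and generates the
cognition score sdmt = 39.8 + 25·(δ−1) + N(0, 2) for patients — tied to the
generative parameter, never to downstream gradient values, so recovery is a
genuine end-to-end test. The small score noise makes the cognition score an
almost noiseless readout of the coupling: the binding constraint on
score–feature correlation is then the gradient pipeline itself (finite-T
estimation noise caps it near 0.5), which is the strong-signal regime the
prediction validation is designed around. The price is a synthetic SDMT
spread (sd ≈ 7 points) below the ~13 points typical of real patient
cohorts. Covariates mirror the target cohort: age N(37.6, 9.9²)/N(38.1,
12²), sex Bernoulli(0.69/0.58 female), mean FD lognormal with median 0.1 mm
and σ = 0.4 (generated independent of signal). Default group sizes are 122
patients and 97 controls.

What the generator does not emulate: hemodynamics, motion artifacts and
their spatial signatures, scanner noise spectra, lesions, realistic
long-range hub topology, or the full breadth of inter-subject FC
variability (optional per-network and global-coherence variability knobs
exist but default to 0). Passing recovery tests therefore demonstrates that
the pipeline detects effects of this planted form at these magnitudes — not
performance on real data.

## Known limitations

- The per-subject multiscale scaling λ/(1−λ) is extremely sensitive when
  λ₁ ≈ 1 (typical for clustered FC affinities). Any latent that alters
  connectivity cohesion anywhere therefore loads, through this global scale
  and the Procrustes seesaw, on the gradient scores of *several* networks
  at once: in the synthetic world the DMN coupling δ is carried not only by
  the DMN-G2 score (the strongest single carrier) but at comparable
  strength by several other network scores. Feature selection identifies
  the DMN feature reliably at the default, study-sized cohort, where the
  importance-gain ranking can resolve the carrier hierarchy; at half that
  size selection becomes unstable even though the underlying correlation
  structure is still recovered.
- The band-pass stage is a second-order zero-phase Butterworth; the filter
  family is a package choice (the common fMRI default), validated by
  sinusoid probes rather than prescribed. A finite-order filter is only
  approximately idempotent (exactly flat nowhere), so re-filtering changes
  broadband signals slightly while leaving in-band content intact.
- Simulation sizes in the validation suite (replicate counts, permutation
  counts) are chosen to give stable rates at interactive runtimes and are
  stated next to each reported rate.
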