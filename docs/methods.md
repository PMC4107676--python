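# Methods

This note documents the models implemented in `hyperconn`, their
assumptions, the defaults and why they were chosen, and what the synthetic
validation data does and does not establish about behavior on acquired
data.

## Coordinate and unit conventions

Voxel coordinates are 0-based in array order `(x, y, z)`; world coordinates
are `voxel * voxel_size` (diagonal affine, no rotation, for all synthetic
volumes).  Diffusivities are in mm²/s, b-values in s/mm², streamline
lengths in voxel units.  All randomness flows from explicit integer seeds;
pipeline stages derive their seeds from the global seed and the stage name
(CRC-32), so identical configurations produce byte-identical JSON reports.

## DWI phantom

Each voxel's noise-free signal is a multi-compartment Gaussian mixture

    S(g) = S0 · [ Σ_f frac_f · exp(−b gᵀ D_f g) + (1 − Σ_f frac_f) · exp(−b d_iso) ],

where each bundle contributes an axially symmetric tensor whose principal
axis follows the local bundle tangent (straight cylinders or circular-arc
tubes), with default eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s typical of
coherent white matter and an isotropic background of 0.7·10⁻³ mm²/s.
Overlapping fractions above 1 are rejected.  Noise is Rician — the
magnitude of a complex Gaussian perturbation with σ = S0/snr — the standard
MR magnitude model.  The acquisition geometry defaults mirror the emulated
protocol: b = 1000 s/mm², 126 diffusion directions, five b0 volumes,
0.309 mm isotropic voxels.

Gradient directions come from a Fibonacci spiral on the upper hemisphere.
The scheme is deterministic and identical for every seed (the seed drives
only the noise); a spiral is quasi-uniform without requiring an
electrostatic-repulsion optimizer, which matters only at the percent level
for condition numbers here.

Not emulated: eddy currents, susceptibility distortion, motion, T2 decay,
partial-volume anatomy, or spatially varying SNR.  Phantom-based tests
therefore validate the numerics of each stage, not robustness to scanner
artifacts.

## Tensor fit and scalar maps

The tensor is fit per masked voxel by log-linear least squares on
`ln(S/S0) = −b gᵀDg`, with S0 the mean of the five b0 volumes.  The default
is the unweighted fit; signal-squared weighting (`method="wls"`) is
available but interacts with the Rician noise floor at low SNR — in
simulation at SNR 20 it biases λ₁ low by ≈5% while the unweighted fit is
unbiased to <0.5% — so it is not the default.  No positivity constraint is
imposed; voxels with non-positive-definite tensors are flagged.
Eigenvalues are sorted descending; FA, MD, AD, RD follow the usual closed
forms, with FA defined as 0 for the all-zero tensor.

A caveat the tests respect: for tensors with a (near-)degenerate eigenvalue
pair, *sorted* eigenvalue estimates show repulsion under noise (~6% at
SNR 20 for λ₂=λ₃) that is an artifact of ordering, not of the estimator;
bias checks use distinct eigenvalues.

## Q-Ball reconstruction

The normalized shell signal E = S/S0 is expanded in a real, even-order,
antipodally symmetric spherical-harmonic basis (default order 8 → 45
coefficients, well-determined by 126 directions) with Laplace–Beltrami
regularization (λ = 0.006); the Funk–Radon transform is applied
analytically by scaling order-ℓ coefficients with 2π·P_ℓ(0).  The ODF is
sampled on a 3-times-subdivided icosahedron (642 vertices, ≈4° angular
resolution, exactly antipodally symmetric), clamped at zero and
sum-normalized per voxel.  SH order and regularization are conventional
settings for this direction count, not values taken from any particular
acquisition; both are exposed.

GFA = std(ψ)/rms(ψ) over the sphere samples (population std), 0 for an
all-zero ODF.  Peaks are strict local maxima over the tessellation
neighborhood on one canonical hemisphere, pruned below 0.5 × the voxel
maximum and within 25° of a stronger peak (antipodal directions count as
identical); a numerically uniform ODF yields no peaks.  Each peak carries a
GFA-like magnitude — voxel GFA scaled by the peak's ODF value relative to
the voxel maximum — so the strongest peak carries the voxel GFA itself and
the white-matter threshold acts per orientation.  In simulation the
single-fiber GFA at these settings is ≈0.17 while the isotropic-background
GFA at SNR 20 is ≈0.014 (95th percentile 0.018), so the 0.026–0.029
threshold band separates tissue classes cleanly.

## Tractography

At any continuous point the direction field is evaluated by choosing, in
each of the 8 surrounding voxels, the peak best aligned with the current
heading (antipodally sign-corrected), blending with trilinear weights, and
normalizing.  Steps follow a 4th-order Runge–Kutta scheme; when the
proposed turn exceeds the angular limit (default 60°) the step is halved,
down to a quarter of the nominal step (0.5 voxels), after which the track
terminates — this is the "adaptive" element.  Tracks run bidirectionally
from each seed (first step along the strongest peak) and stop on leaving
the white-matter mask (nearest-neighbor lookup), exhausting `max_steps`, or
violating the curvature limit at minimum step.

Seeding cycles all white-matter voxels per batch in a fresh random order
with uniform within-voxel jitter.  Stagnation is declared when the relative
gain in *distinct* accepted fibers (keyed on endpoint voxels and rounded
length) over a 3-batch window falls below 1%.  Distinct fibers are used
because the raw accepted count grows linearly with seeding effort by
construction and can never stagnate; the distinct count is the quantity
that actually saturates as the bundle becomes fully explored.

Fibers shorter than 3 voxels are discarded.  The statistical outlier filter
removes, within each connected region-pair bundle, tracks whose length
falls outside median ± 3·MAD (zero-MAD bundles keep all members).  This is
a stand-in for unpublished "unlikely-fiber" heuristics in the tradition of
connection-confidence filtering; it is deliberately simple and fully
specified so its effect is testable.

## Connectome construction

Each accepted streamline contributes exactly once to one unordered parcel
pair, mapped from its two endpoints (a background endpoint falls back to
the nearest labeled voxel within a 1-voxel neighborhood, ties to the lowest
label; endpoint assignment rather than traversal counting keeps each fiber
a single connection).  Self-loops and unassigned tracks are counted but
excluded.  Weights are fiber counts divided by the white-matter volume (the
number of voxels that permitted seed placement), making `w_ij` a fiber
density; doubling the white-matter volume exactly halves every weight.

Regional DTI summaries average FA/MD/AD/RD over each parcel's valid voxels
and discard parcels in which no single axial plane contains at least 5
voxels — small volumes whose anatomical placement cannot be trusted after
registration.  The slice axis is configurable (axial by default, matching
the acquisition's slice direction).

## Graph metrics

Efficiency uses the Latora–Marchiori construction with edge lengths
ℓ = 1/w (shortest paths via Dijkstra); disconnected pairs contribute zero.
Consequently global efficiency scales linearly under uniform weight
scaling — the tests assert this rather than (false) scale invariance.

Regional efficiency is the triangle-intensity generalization of the
clustering coefficient: weights are renormalized by the global matrix
maximum, the sum runs over unordered neighbor pairs, and nodes with fewer
than two neighbors score 0.  This makes the unit triangle score exactly 1
and the measure invariant under uniform weight scaling.  Local efficiency
is the mean over nodes.

Modularity is maximized with an in-package Louvain (multi-level)
implementation: local moves to convergence with gains evaluated against
the standard null model, ties broken toward the lowest community id;
community aggregation; repeat until no gain.  The best of `n_restarts`
shuffled node orders (default 20) is kept, deterministic given the seed.
The full hierarchy is retained (each finer level refines the coarser); the
scalar reported per subject is the top-level Q, with the nested levels
available for inspection.  The returned Q always equals a from-scratch
evaluation of its partition, and on exhaustive-search oracles (all
partitions of ≤8-node graphs) Louvain never exceeds and almost always
attains the true maximum.

One caution encoded in the tests: "adding an intra-community edge never
decreases Q of a fixed partition" is not a theorem — for fully separated
communities Q is already maximal and extra internal weight dilutes it — so
the monotonicity test uses a connected fixture where the property holds.

Partition similarity defaults to the adjusted Rand index clipped at 0
(normalized mutual information available), cross-checked against
scikit-learn.

## Group statistics

Mann–Whitney U uses midranks; the p-value is exact (full enumeration of
rank assignments) for n₁+n₂ ≤ 12 without ties, otherwise a normal
approximation with tie and continuity corrections.  At n = 8 vs 8 and
α = 0.05 the attained two-sided level of this test is ≈0.038 (discreteness
of U), which is what the null-calibration checks expect.  AUROC is the
pair-counting probability that a positive outranks a negative, ties ½.

## The iterated cross-validated prediction model

Per iteration, subjects are split into k near-equal random folds (weekly
scheme: one week's 16 subjects, k = 4, i.e. 12 train / 4 test; integral
scheme: all 48 subjects, k = 3, i.e. 32/16).  Per fold, using training rows
only: (1) PCA (SVD of the centered matrix) keeping 10 components, truncated
at the numerical rank; (2) a two-class Fisher axis a ∝ S_W⁻¹(μ₁−μ₀) with a
small ridge (1e-8 × mean scatter) against singular scatter, unit-normalized,
sign fixed so the second class projects positive; (3) back-projection to
region space and selection of the 16 regions with most energy (squared
coefficient; ties to the lower index); (4) OLS with intercept on the
selected regions (constant columns dropped, minimum-norm solution if
underdetermined); (5) prediction of the held-out fold.  Out-of-bag
predictions are pooled over all iterations before a single Pearson r —
the primary score — with per-iteration r and per-subject means also
available.  Selection frequency is counted per fold-model (primary) and
per iteration.  Folds whose training rows contain one group are skipped
and counted, not imputed.  Iterations redraw folds; a bootstrap variant
(resample subjects, predict out-of-bag) is available behind a flag.

No training-fold statistic sees test rows; an adversarial test corrupts a
held-out subject and verifies its fold's other predictions are unchanged.

## Synthetic cohorts

All animals of a cohort individualize a single template connectome — a
planted-partition graph (84 nodes, 4 modules of 21, p_in = 0.9,
p_out = 0.05, Uniform(0.5, 1.5) weights) — by multiplicative per-node
factors (lognormal, σ = 0.05) with weekly node jitter (σ = 0.02) and a
developmental weight growth of 2%/week.  Sharing a template mirrors the
fact that real cohorts share anatomy; fully independent graphs per subject
would make between-subject feature noise dominate any regional signal.

The disease transform, applied once per animal, has three components with
distinct, deliberate effects:

- degree-preserving rewiring of 30% of edges — destroys triangles and
  module structure, lowering modularity Q and local efficiency;
- a global weight scale of 0.8 — lowers global efficiency (regional
  efficiency is scale-invariant by construction);
- scaling of the edges *among* the 16 informative regions by 0.5 —
  concentrates the group signature on the regions that drive behavior.

Informative regions default to 4 per module, evenly spaced (16 total);
balancing across modules keeps their expected effect sizes homogeneous.
Behavior scores are `intercept + β · Σ_r features[r] + N(0, noise_sd)`
clipped at zero, with β = −40 per informative region on the recorded
features (regional efficiencies plus iid measurement noise, σ = 0.008,
standing in for tractography estimation error), intercept 350 and score
noise σ = 10 — numbers on the scale of trials-to-criteria counts, with the
disease group scoring stochastically higher (worse).  Effect sizes are
calibrated to the qualitative direction of the emulated study (disease
lower on all three network metrics); no published effect magnitudes exist
to match.

### The recovery benchmark

`CohortSpec.recovery_benchmark()` is the configuration under which the
prediction model should recover the planted structure exactly: fully
connected modules with unit weights, no connectome jitter, disease effect
confined to the informative subnetwork, score noise zero (the behavior
score is then an exact linear function of the recorded informative
features), and subject variability reduced to the iid feature noise.

This configuration is deliberately austere, for a reason worth recording.
The selection step ranks regions by energy on a *whitened* (Fisher)
discriminant axis.  With connectome-mediated subject variability the
within-class feature covariance is far from isotropic — edge and node
jitter correlate neighboring regions' efficiencies, and the max-weight
renormalization injects a strong common mode — and whitening such noise
reorders region energies away from the mean-difference profile: with a
frozen 48-subject dataset, one or two unrelated regions can persistently
displace the weakest planted region regardless of noise amplitude (the
distortion is scale-free).  With iid feature noise the within-class
covariance is isotropic, whitening is neutral, and the planted regions'
selection margins are wide and stable across cohort seeds.  Passing the
recovery benchmark therefore shows the selection machinery is correct and
leak-free; it does not show that planted-region recovery would survive
strongly correlated anatomical variability — on the default (richer)
cohort the model still predicts well (pooled r ≈ 0.97 in the README
example) but exact 16-of-16 selection is not guaranteed, which is a
property of whitened discriminants, not an implementation defect.

### Null behavior

`CohortSpec.exchangeable_null()` removes every disease component, making
the groups exchangeable; Mann–Whitney on local efficiency then rejects at
the attained ≈3.8% level.  For the prediction model's permuted-label null,
note that a *single* permutation's pooled out-of-bag r at n = 48 is itself
a random variable with sd ≈ 0.09–0.13 (measured over 40 permutations), so
the null check averages pooled r over 10 independent label permutations,
which concentrates the estimator (sd ≈ 0.03) enough to test that the model
finds no signal where none exists.

## Problem sizes and numerical choices

Tests and the acceptance script use: 100 random ≤6-node graphs against the
exhaustive shortest-path oracle (tolerance 1e-10); 50 random ≤8-node graphs
against exhaustive partition search (20 Louvain restarts); 500 single-fiber
voxels at SNR 20 for peak-direction recovery; 200 iterations for the CV
recovery and 10 × 200 for the permuted null; 200 cohorts for power and 500
for null calibration at one time point; and a reduced end-to-end pipeline
(16×12×8 phantom, one seeding batch, 4+4 animals × 2 weeks, 20 CV
iterations) run twice for byte-identical-report determinism.  These sizes
were chosen so the full validation runs in minutes on one CPU while keeping
every Monte-Carlo margin wide (observed: power 100%, null 2–5%, recovery
16/16 with selection-frequency margins ≥ 0.7).

Other numerics: SH fit solved by a single regularized normal-equation
factorization shared across voxels; eigen-decomposition via `eigh` on
stacked symmetric matrices; Louvain gain tolerance 1e-12 with
lowest-community-id tie-breaks; PCA rank tolerance `max(n,p)·eps·s₁`;
TSV matrices written at 17 significant digits and parsed with round-trip
float precision so matrix round-trips are bit-exact.

## Known limitations

- Single-shell, single-tensor-per-bundle phantoms; no multi-shell models,
  spherical deconvolution, or DKI.
- Deterministic tractography only; no probabilistic or global variants,
  no anatomical constraints.
- The fiber outlier filter is a specified stand-in, not a published
  algorithm.
- "Hierarchical modularity" is summarized by the top-level Louvain Q; a
  nested-quality index over the hierarchy is not computed (the hierarchy
  itself is returned).
- The cohort generator reproduces the statistical design of a two-group
  longitudinal study, not rat neuroanatomy: parcels are abstract nodes and
  connectome differences are planted, so cohort-level results validate the
  statistical machinery, not biological effect sizes.
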