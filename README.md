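# hyperconn

Structural brain-network analysis from diffusion-weighted MRI, with a
synthetic-data backbone so every stage is testable without acquired data.

The package reimplements, as a reusable and tested pipeline, the
computational chain of a longitudinal rodent connectomics study of vascular
cognitive impairment (hypertensive vs normotensive rats): diffusion-tensor
scalar maps and Q-Ball fiber reconstruction, deterministic streamline
tractography, connectome construction over an anatomical parcellation,
weighted graph metrics, group discrimination, and an iterated
cross-validated model that predicts behavioral scores from regional network
parameters.  It is aimed at researchers who want to prototype or audit this
kind of analysis with fully controlled ground truth.

## What it computes

**Diffusion modelling.** Per voxel, the tensor model `ln(S/S0) = -b gᵀDg`
is fit by log-linear least squares, giving FA, MD, AD = λ₁ and
RD = (λ₂+λ₃)/2.  Crossing fibers are resolved by analytic Q-Ball imaging: a
real symmetric spherical-harmonic fit of the shell signal (order 8,
Laplace–Beltrami regularization) with the Funk–Radon transform applied via
the Legendre scaling `2π P_ℓ(0)`, yielding an orientation distribution
function, its generalized fractional anisotropy GFA = std(ψ)/rms(ψ), and
per-voxel fiber peaks.

**Tractography and connectome.** White matter is masked by thresholding the
per-orientation GFA (working range ≈ 0.026–0.029); streamlines are
integrated bidirectionally with an adaptive 4th-order Runge–Kutta scheme on
the peak field, seeded over white-matter voxels until the yield of distinct
fibers stagnates, then length- and outlier-filtered (minimum 3 voxels).
Edge weights are `w_ij = fibers(i,j) / white-matter volume` over an 84-node
(2 × 42 structures) parcellation.

**Graph metrics.** Global efficiency (mean inverse weighted shortest-path
length, edge length 1/w), regional efficiency

    E_reg(i) = 2/(k_i(k_i−1)) · Σ_{j<l} (ŵ_ij ŵ_jl ŵ_li)^{1/3},   ŵ = w/max(w),

local efficiency (its mean), and multi-level (Louvain) modularity Q with
the full community hierarchy and partition-similarity (ARI/NMI) between
subjects.

**Prediction.** Over many random k-fold splits (weekly scheme: 16 subjects,
4 folds; integral scheme: 48 subjects, 3 folds): PCA to 10 components →
two-class Fisher discriminant → the 16 regions with most energy on the
back-projected axis → ordinary least squares on those regions → prediction
of the held-out fold.  Pooled out-of-bag predictions are scored by Pearson
correlation and each region's selection frequency is reported, alongside
Mann–Whitney U tests and AUROC for group contrasts.

**Synthetic data.** A phantom generator reproduces the acquisition geometry
(b = 1000 s/mm², 126 spiral directions, five b0 volumes, 0.309 mm isotropic
voxels) over straight and arc fiber bundles with Rician noise, and a cohort
generator builds two-group longitudinal cohorts whose disease connectomes
have lower modularity and efficiency and whose behavior scores depend
linearly on a sparse set of regional efficiencies.

## Worked example

```python
import numpy as np
from hyperconn.synthetic import CohortSpec, make_cohort
from hyperconn.graphs import network_metrics
from hyperconn.predict import CVConfig, FeatureMatrix, mann_whitney_u, run_cv_prediction

records = make_cohort(CohortSpec(seed=7))          # 8+8 animals, weeks 10/22/40
week10 = [r for r in records if r.week == 10]
q = {g: [network_metrics(r.connectome, n_restarts=10, seed=0).Q
         for r in week10 if r.group == g] for g in ("control", "disease")}
u, p = mann_whitney_u(q["control"], q["disease"])
print(f"modularity Q at week 10:  control {np.mean(q['control']):.3f}  "
      f"disease {np.mean(q['disease']):.3f}  (U={u:.0f}, p={p:.4f})")

data = FeatureMatrix.from_records(records)
result = run_cv_prediction(data, CVConfig(scheme="integral", n_iterations=200, seed=1))
print(f"pooled out-of-bag Pearson r = {result.pooled_r:.3f}")
```

prints

```
modularity Q at week 10:  control 0.612  disease 0.403  (U=64, p=0.0009)
pooled out-of-bag Pearson r = 0.970
```

The disease group's connectomes are measurably less modular (U = 64 is the
maximal separation at n = 8 vs 8), and the cross-validated model recovers
the planted link between regional efficiencies and the behavior score on
held-out animals.

A command-line umbrella covers the same stages on files
(`hyperconn simulate-phantom | fit-dti | qball | track | connectome |
metrics | simulate-cohort | predict | groupstats | pipeline`); see
`hyperconn --help`.

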