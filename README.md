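# cognet

Group-ICA network analysis of resting-state fMRI cohorts, built for studies
that relate whole-brain network expression to cognitive domain scores — the
typical design being a patient group (e.g. Parkinson's disease) and healthy
controls, with the Montreal Cognitive Assessment (MoCA) administered to the
patients.

The package implements the full analysis chain as a tested library:

1. **Subject table handling** — validation, levodopa-equivalent dose
   (LED = levodopa/carbidopa ×1 + entacapone ×0.35 + pramipexole ×100 +
   ropinirole ×20 + rotigotine ×10 + selegiline ×10 + amantadine ×1) and the
   head-motion screen (exclude at ≥ 3 mm maximum displacement).
2. **Masked BOLD I/O** — 4D NIfTI series under a 3D mask as voxels × time
   matrices, with a documented canonical voxel ordering.
3. **Dimension reduction** — subject-level PCA, temporally concatenated
   group PCA with whitening, and minimum-description-length (MDL) selection
   of the model order K from the group eigenspectrum,
   MDL(k) = −(p−k)·N·log(gm(λ_{k+1..p})/am(λ_{k+1..p})) + ½k(2p−k+1)·log N.
4. **InfoMax ICA + ICASSO** — natural-gradient InfoMax with a logistic
   nonlinearity on the whitened K × voxels matrix; repeated runs under
   bootstrap resampling and/or random re-initialisation, average-linkage
   clustering of all estimates by |spatial correlation|, per-cluster
   stability index I_q (mean intra-cluster minus mean extra-cluster
   similarity) and centrotype maps.
5. **Component QC** — z-scored group maps, the voxel-extent rule (exclude
   components with < 50 voxels at |z| ≥ 1), I_q ≥ 0.8 retention,
   low-frequency dominance of time courses, and user-supplied
   artifact/network labels (AUD/CCN/DMN/SMN/VIS/CBL/SCN).
6. **Dual regression** — subject time courses (stage 1) and subject spatial
   maps (stage 2) from the group maps.
7. **Network expression scoring** — scaled-subprofile-model projection:
   double-centred subject maps projected on each group topography, then
   z-scored against the control group.
8. **Domain modelling** — bidirectional stepwise regression (entry p ≤ 0.05,
   removal p ≥ 0.10) of each MoCA domain on the network scores of the
   patient group; composite "domain-related network" maps
   Σᵢ Bᵢ·z-mapᵢ; hub components shared by ≥ 2 domain models; two-sample
   t-tests of network scores between groups.

Because suitable clinical rs-fMRI data are rarely shareable, the package
ships a first-class **synthetic cohort generator** with known ground truth —
compact near-orthogonal spatial sources, band-limited (0.01–0.08 Hz,
TR = 2 s) time courses, subject-level expression loadings and MoCA-like
domain scores planted as sparse linear models on those loadings — so every
stage has a quantitative recovery test.

## Worked example

```python
import numpy as np
from cognet import CohortConfig, analyze_cohort, simulate_cohort

bundle = simulate_cohort(CohortConfig(), seed=7)   # 40 PD + 15 Ctr subjects
res = analyze_cohort(bundle.bolds, bundle.metadata, k=6, n_runs=10, seed=7)

print(res.components.ids, np.round(res.icasso.iq, 3))
m = res.models["attention"]
print(f"attention: R2={m.r2:.3f}  p={m.model_p:.1e}")
print(m.table.round(3))
print("delayed_recall generated:", res.models["delayed_recall"].generated)
```

prints

```
['IC1', 'IC2', 'IC3', 'IC4', 'IC5', 'IC6'] [0.974 0.974 0.974 0.973 0.973 0.972]
attention: R2=0.650  p=2.5e-08
         B  ci_low  ci_high      p
IC3 -0.515  -0.778   -0.253  0.000
IC5  0.564   0.328    0.799  0.000
IC4  0.540   0.225    0.855  0.001
delayed_recall generated: False
```

All six simulated sources pass QC with I_q ≈ 0.97. The attention domain was
planted on three components; the stepwise model recovers exactly those three
(as the matched ICs 3/4/5), with a fitted R² of 0.65 against a generating
R² calibrated to 0.6. The delayed-recall domain is generated as pure noise,
and correspondingly no model is produced for it. `res.hubs` lists components
selected by several domain models, and `res.group_tests` holds the
per-component PD-vs-Ctr t-tests.

The same pipeline is available from the shell:

```bash
cognet simulate --out cohort/ --seed 7
cognet pipeline --cohort cohort/ --k 6 --runs 10 --seed 7 --out results/
cognet led --doses "levodopa/carbidopa=200,entacapone=200,pramipexole=1.5"
```

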