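# drgqmri

Quantitative MRI of the dorsal root ganglion (DRG): a tested, reproducible
pipeline for B1-aware T2/M0 mapping from multi-echo spin-echo data,
CSF-normalised proton density (PD), 3D ROI volumetry, inter-rater
reliability, and the statistical battery used to discriminate painful from
non-painful neurofibromatosis type 1 (NF1) — together with a synthetic
phantom-cohort generator so every stage is testable end to end without any
patient data.

## The problem

The DRG houses the cell bodies of sensory neurons and is central to
neuropathic pain. In NF1, ganglia enlarge and their tissue composition
changes; three imaging features capture this on a multi-echo spin-echo
acquisition (echo train length 10, ΔTE = 15 ms, TR = 4800 ms, voxels
1.5 × 1.5 × 1.8 mm):

* **volume** — voxel count × voxel volume of the segmented ganglion (mm³);
* **T2** — the transverse relaxation time from the echo-train decay (ms);
* **PD** — the fitted equilibrium magnetisation M0 of the ganglion,
  normalised to a cerebrospinal-fluid reference on the same axial slices
  (arbitrary units).

Estimating T2 and M0 per voxel is confounded by transmit-field (B1)
inhomogeneity: when the refocusing flip angle deviates from 180°,
stimulated-echo pathways inflate late echoes and a naive exponential fit
overestimates T2. The fitter here models the full echo train with the
extended phase graph (EPG) formalism for a CPMG sequence — the signal at
echo *k* is a function *S_k(T2, T1, M0, B1·180°)* — and estimates
(T2, M0, B1) per voxel by dictionary matching over a (T2 × B1) lattice
followed by bounded nonlinear refinement with M0 profiled out in closed
form. At B1 = 1 the model reduces exactly to *M0·exp(−k·ΔTE/T2)*.

Downstream, per-DRG features are aggregated per subject (sides averaged
within level, levels L5/S1 averaged, then readers averaged), reliability is
quantified with the two-way absolute-agreement intraclass correlation
ICC(A,1) built from the ANOVA mean squares, and group structure is analysed
with Mann–Whitney U, Wilcoxon signed-rank, χ²/Fisher, Spearman ρ, ROC
curves with DeLong confidence intervals and Youden-optimal cutoffs
(J = sensitivity + specificity − 1), and univariate logistic regression
(IRLS) with McFadden's R², AIC and likelihood-ratio tests.

The phantom module generates ellipsoidal ganglia with exact requested
volumes, a CSF reference tube, smooth polynomial B1 fields, EPG-simulated
echo trains with Rician magnitude noise, perturbed two-reader masks, and
whole cohorts (28 healthy controls, 12 NF1 without pain, 8 NF1 with pain)
whose per-group feature distributions are log-normal with medians and
interquartile ranges calibrated to the published cohort tables.

## Worked example

Simulate one healthy-control subject, fit the maps, extract the three
features of the left L5 ganglion:

```python
import numpy as np
from drgqmri import (AcquisitionProtocol, FitOptions, T2RelaxometryModel,
                     compute_volume, extract_roi_mean, make_scene,
                     normalize_pd, sample_cohort, simulate_multiecho,
                     default_cohort_config)

protocol = AcquisitionProtocol()          # 10 echoes, dTE 15 ms, 1.5x1.5x1.8 mm
spec = sample_cohort(default_cohort_config(seed=7))[0]   # first healthy control
scene = make_scene(spec, protocol)
series = simulate_multiecho(scene, protocol, noise_sigma=0.01, seed=spec.seed)

model = T2RelaxometryModel(series, t1_assumed=1000.0,
                           options=FitOptions(min_r2=0.80))
result = model.fit(mask=scene.mask,
                   labels=scene.mask.drg_labels() + [scene.mask.csf_label()])
print(result.summary())

mask = scene.mask
lab = mask.label_for("L5", "L")
vol = compute_volume(mask, lab)
t2, _ = extract_roi_mean(result.t2, mask, lab, result.maps.qc_flags)
pd = normalize_pd(result.m0, mask, lab, mask.csf_label(), result.maps.qc_flags)
```

Output:

```
T2 relaxometry fit (EPG-CPMG dictionary + refinement)
  voxels fitted:   1909
  voxels flagged:  129 (6.8%)
  T2  median [ms]: 111.3
  M0  median     : 0.9043
  B1  median     : 0.926
  R^2 median     : 0.9966

L5-left DRG:  volume   862.6 mm^3   (truth   862.3)
              T2       110.7 ms     (truth   110.3)
              PD       0.863 a.u.   (truth   0.866)
```

The fit recovers this subject's ground truth to a fraction of a percent:
volume is exact to within one voxel by construction, and the B1-aware fit
removes the T2 bias that a plain exponential fit would incur at the
simulated B1 ≈ 0.93.

## Pipeline CLI

The same stages run as a pipeline with a YAML configuration
(`examples/demo.yaml` is a small complete example):

```bash
drgqmri run --config examples/demo.yaml --out out/ --seed 0
# or stage by stage
drgqmri simulate --config examples/demo.yaml
drgqmri fit --config examples/demo.yaml
drgqmri extract --config examples/demo.yaml
drgqmri reliability --config examples/demo.yaml
drgqmri analyze --config examples/demo.yaml
```

Each stage reads only the previous stage's outputs (4D NIfTI series with
JSON echo-time sidecars, labelled 3D NIfTI masks with label-table sidecars,
float32 NIfTI maps, CSV feature tables, JSON reports); a manifest with
per-stage seeds and SHA-256 checksums makes runs with the same seed
byte-comparable.

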