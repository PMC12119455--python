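# Methods

This note documents the models, numerical choices and known limitations of
`drgqmri`. Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs show.

## Forward model: EPG-CPMG

The signal model for a multi-echo spin-echo (CPMG) train is the extended
phase graph: configuration states `(F+(k), F-(k), Z(k))` indexed by
dephasing order `k`, evolved through 90° excitation (about x) and a train
of refocusing pulses (about y) with effective flip angle `B1 · 180°`. Each
echo period applies half-interval relaxation (T2 on transverse states, T1
recovery on `Z(0)`), a gradient shift of the dephasing orders, the RF
mixing matrix, a second shift and half-interval relaxation; the k-th echo
is `|F(0)|` at the echo centre. States above order `n_echoes + 1` cannot
refocus within the train and are truncated exactly.

Properties used as test anchors:

* at `B1 = 1` the model reduces to `M0 · exp(-k ΔTE / T2)` (no stimulated
  pathways) — verified to 1e-10 across the whole dictionary T2 grid;
* the signal is linear in M0 (initial state and T1 recovery both scale);
* the implementation matches an independent isochromat simulator (explicit
  3×3 Bloch rotations over discrete dephasing partitions; exact when the
  partition count exceeds the number of distinct dephasing orders) to
  better than 1e-8 — in practice to rounding error.

T1 is not fitted. With TR = 4800 ms and ten echoes spanning 150 ms, the
echo train constrains T1 poorly; a per-tissue constant is passed in
(1000 ms tissue, 4000 ms CSF in the phantom) and the same constant is
assumed by the fitter. The residual sensitivity of the echoes to T1 is
small because stimulated-echo storage intervals are short.

## Voxel-wise estimation

Two stages, deterministic throughout:

1. **Dictionary matching.** Unit-M0 EPG signals are precomputed on a
   T2 × B1 lattice (defaults: 120 log-spaced T2 points over 20–2500 ms,
   36 B1 points over 0.6–1.3). The atom maximising the normalised
   dot-product with the measured train is selected; M0 is the closed-form
   least-squares scale. Atoms are ordered with T2 fastest-ascending so an
   exact argmax tie resolves to the smaller T2.
2. **Refinement** (default on). Alternating golden-section line searches on
   log-T2 and B1 with M0 profiled out, brackets re-centred and shrunk over
   three rounds (log-T2 half-widths 0.40/0.06/0.012; B1 half-widths
   0.10/0.02/0.006). This is equivalent at the optimum to bounded nonlinear
   least squares in (T2, M0, B1) but is derivative-free and fully
   vectorised over voxels. The derivative-free form matters: around
   `B1 = 1` the signal's B1-sensitivity vanishes to first order (the echo
   amplitudes are symmetric in the flip-angle error), so gradient-based
   steps stall in that flat valley; the line search does not. Noiseless
   round trips over 200 random draws recover T2 and M0 to better than
   0.5% (worst observed 0.35%).

If refinement fails to improve on the grid solution the grid solution is
returned with a non-convergence QC flag. An all-zero voxel yields NaNs and
a zero-signal flag rather than an exception.

A log-linear mono-exponential fitter (`method="loglin"`, weights `s²`) is
included as a baseline. It ignores B1; at `B1 = 0.75` it overestimates a
100 ms T2 by more than 10% on the same data the EPG fit recovers to 1%,
which is the pipeline's own demonstration of why the B1-aware model is the
default.

**QC.** Per voxel: coefficient of determination `r²` of the fit, residual
RMS, and a flag bitmask (zero signal, `r² < min_r2`, T2 outside bounds,
non-convergence). Defaults: `min_r2` 0.95 for noiseless work, 0.80 in the
noisy pipeline; T2 plausibility bounds (10, 3000) ms. The ROI-level QC
report lists any ROI with more than 20% flagged voxels for visual review.
Flagged voxels are excluded from T2/PD means; volume uses the raw mask
count (it is a geometry feature, not an intensity feature).

**Rician bias is not corrected.** Magnitude noise adds a floor of
`σ·sqrt(π/2)` where the signal is small. Simulations keep SNR high enough
(default `noise_sigma` 0.01 against CSF M0 = 1, i.e. SNR ≈ 70–100 in
tissue at the first echo) that the induced T2/M0 bias is below 1%; the
tests confirm cohort-median recovery errors well under that. Low-SNR data
would need a noise-floor term this package does not implement.

## Features

* **Volume** = voxel count × voxel volume, spacing read from the mask
  geometry (not a protocol constant), so anisotropic or gap-inclusive data
  stay correct.
* **T2/PD ROI means** are arithmetic means over QC-clean in-mask voxels.
* **PD** = mean M0 over the ganglion divided by mean M0 over CSF voxels
  restricted to the axial slices the ganglion occupies. The slice
  restriction approximates "reference at the same distance from the
  receiving coil"; an exact coil-distance criterion is not operationalisable
  without coil sensitivity maps. PD is computed per ganglion against its
  own slice-matched reference (not one global CSF value per subject), and
  is invariant under any global rescaling of the M0 map.
* **Aggregation**: per rater, left/right are averaged within level; the L5
  and S1 values are averaged into "mean of L5 and S1"; rater values are
  averaged last. The long per-DRG table preserves per-side, per-rater
  values for the paired left-right contrasts and the reliability analysis.
  Subjects missing any of their four ganglia are dropped from the
  aggregated table and listed in a completeness report.

## Reliability

ICC(A,1) — two-way random-effects, single-measure, absolute agreement —
from the ANOVA mean squares:

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with the exact F-based 95% interval (McGraw–Wong). Absolute agreement is
the right form here because a systematic offset between readers is a real
disagreement about the measured quantity; the consistency form would hide
it. Single-measure is reported as the headline (reliability of one
reading); the average-measure ICC(A,k) is also returned, since downstream
analysis uses the two-reader mean. A zero-variance matrix returns ICC = 1
with a degenerate interval and a warning.

## Statistics

Small-cohort conventions: two-sided tests, significance at p ≤ 0.05, no
multiple-comparison correction (each subject contributes one aggregated
value per feature and the analysis is exploratory). Exact paths where the
sample sizes allow: Mann–Whitney U by enumeration when `n·m ≤ 400` with no
ties, Wilcoxon signed-rank exactly for `n ≤ 15` without ties, Fisher's
exact test when any expected 2×2 cell is below 5. The 2×2 χ² uses Yates
continuity correction — the convention of R's `chisq.test`, which analyses
of this kind conventionally use, and the form under which the balanced
sex-split example recomputes to its reported p-value.

ROC analysis builds the empirical curve over all thresholds; AUC by
trapezoid equals the mid-rank U statistic scaled by `n₁·n₂` (asserted to
1e-12 against an independent U computation). The 95% CI is DeLong's
(clipped to [0, 1]). The Youden-optimal cutoff maximises
sensitivity + specificity − 1 over midpoints between adjacent distinct
scores, ties broken toward higher specificity. Higher feature values score
toward the pain class for all three features, matching the direction of
the group effects.

Logistic regression is fitted by IRLS (convergence when the score norm
falls below 1e-8, at most 100 iterations), standard errors from the
inverse observed information, McFadden R² = 1 − lnL/lnL₀,
AIC = 4 − 2 lnL, and a χ²₁ likelihood-ratio test against the
intercept-only model. Perfect or quasi-separation (linear predictor
saturating) is detected and flagged on the result rather than raised; at
n = 20 with a strong predictor this is a live possibility and the flag
propagates into the analysis report.

## The phantom: what it emulates and what it does not

Each subject's scene is a 64×64×16 grid at 1.5×1.5×1.8 mm: four
ellipsoidal ganglia (levels along y, sides along x, random axis ratio in
[1, 2.5]) around the central slices, a 3 mm-radius CSF tube along y
through the grid centre (so it intersects every ganglion's slices),
background tissue (T2 70 ms, M0 0.7), CSF (T2 2000 ms, M0 1), and a smooth
random quadratic B1 field rescaled exactly into a configured range
(default [0.8, 1.1]). DRG M0 is set to `PD × M0_CSF`, making the
ground-truth PD exact by construction. Masks are voxelised by taking
exactly `round(V/voxel-volume)` voxels nearest the centre in the
ellipsoidal norm, so the voxelised volume is within half a voxel volume of
any requested volume and the blob is connected.

Slice geometry: the acquisition this emulates interleaves 1.8 mm slices
with 1.8 mm gaps; the phantom models contiguous 1.8 mm slices, and
volumetry always reads spacing from the mask geometry, so a gap-inclusive
dataset (effective 3.6 mm spacing) would be handled correctly by the same
code.

Cohort calibration: each subject's feature on the mean-of-levels scale is
log-normal with `exp(μ)` equal to the target group median and σ solved
from the target interquartile range (`σ = asinh(IQR/(2·median))/z₇₅`,
exact for log-normal quartiles). The subject value splits into L5/S1 by
fixed factors derived from the published per-level medians and into
left/right by symmetric arithmetic jitter (SD 3%) that preserves the level
mean. In the degenerate σ → 0 limit every aggregated feature equals its
configured median exactly, which anchors the end-to-end tests. Volume
draws are truncated symmetrically in log-space to what the grid can hold
(default subject-level bounds 120–4800 mm³); symmetric truncation leaves
the median — the calibrated quantity — untouched, at the cost of a
narrower simulated IQR for the most dispersed group. Demographics are
drawn normal from the published medians/IQRs with fixed per-group sex
counts.

Simulated readers toggle boundary voxels of each ganglion independently
with a configured probability (default 0.1) and keep the largest connected
component, so masks remain connected and non-empty; at perturbation 0 the
reader masks equal the truth and downstream ICC is exactly 1.

Rician noise is applied per echo independently (`|s + n₁ + i n₂|`,
Gaussian channels of SD `noise_sigma`); no inter-echo noise correlation is
modelled. With `noise_sigma = 0` no RNG is consumed and the series is
bit-reproducible; with a seed it is bit-reproducible per seed.

What the phantom does **not** emulate — and therefore what passing tests
do not demonstrate about patient data: anatomical shape variation and
partial-volume mixtures at ganglion boundaries, segmentation ambiguity
beyond random boundary toggles, coil sensitivity profiles beyond a smooth
B1 field, B0/off-resonance and slice-profile effects, k-space artefacts,
multi-compartment T2 decay within a voxel, and inter-echo noise
correlation. End-to-end recovery on the phantom validates the estimation
chain, not the acquisition physics of a scanner.

## Problem sizes and determinism

Default problem sizes were chosen so a full 48-subject cohort (simulate,
fit, extract, analyse) completes in a few minutes on one CPU: fitting is
restricted to a one-voxel dilation of the union of ganglion and CSF masks
(the only voxels any downstream feature reads), the dictionary is
120 × 36, and the refinement is vectorised across all masked voxels of a
subject. Every stochastic component (cohort draws, scene jitter, noise,
reader perturbation) derives from a single master seed through
`numpy.random.SeedSequence` spawning; per-stage seeds are recorded in the
pipeline manifest together with SHA-256 checksums of every output file.
Cohort medians of 8–20 subjects retain intrinsic sampling spread (the SD
of the median of 20 log-normal draws at the calibrated T2 IQR is ≈ 5%),
which bounds how closely any single simulated cohort can be expected to
match the calibration targets.

## Known limitations

* No Rician noise-floor correction; low-SNR regimes are out of scope.
* T1 is assumed, not estimated; a wrong T1 assumption biases B1 slightly
  and T2 weakly.
* The ICC confidence interval assumes the two-way normal ANOVA model;
  feature distributions are right-skewed, so the interval is approximate.
* The DeLong CI at n = 8 vs 12 is a large-sample approximation; the
  bootstrap alternative is not implemented.
* The B1 estimate at `B1 ≈ 1` is weakly identified from CPMG data alone
  (first-order insensitivity); T2/M0 remain accurate there because the
  same flatness makes them insensitive to the residual B1 error.
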