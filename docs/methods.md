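# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mrhabitats`, and what the synthetic phantom does and does not
emulate.

## Signal model and relaxometry

All conversions rest on the spoiled gradient-recalled echo (SPGR)
steady-state equation

    S = S0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1).

Units: T1 in seconds, TR in milliseconds (converted internally), flip angle
α in degrees, ΔR1 = R1 − 1/T10 in s⁻¹.

**VFA T1 fitting.** Native (T10, S0) are fitted per voxel by nonlinear least
squares over the flip-angle samples, seeded by the linearized DESPOT1
regression (S/sin α against S/tan α) and bounded to T10 ∈ [0.05, 10] s.
Voxels with all-zero or non-finite signals are flagged failed and excluded
downstream. The fit is exact on noiseless data and scale-equivariant in S0.

**OE baseline drift.** Scanner drift in the OE series is modelled as an
exponentially time-varying *effective flip angle*

    α(t) = α0 · (1 + A_drift · (1 − e^(−t/τ_drift))),

fitted by least squares to the pre-gas-switch ROI-mean signal only and
extrapolated across the series. The functional form (monotone, bounded,
two parameters) and the ROI-mean-then-apply-voxel-wise strategy are package
choices; per-voxel drift fits are unstable at realistic SNR, and for ROIs
with heterogeneous T10 the ROI-mean fit is an approximation. A fit with τ
pinned at its bounds falls back to no drift with a warning. DCE data are
converted with the constant nominal angle.

**Signal → ΔR1.** The SPGR equation is inverted per frame for E1, giving
T1(t) = −TR/ln E1. Frames with E1 outside (0, 1) (noise pushing the signal
outside the model's range) are set to NaN; voxels with more than half their
frames invalid are flagged erratic and always removed by preprocessing.
On noiseless data the inversion recovers injected ΔR1 curves to < 1e−8 s⁻¹.

## Preprocessing

Erratically enhancing voxels (ROI-boundary motion, large vessels) are
removed before feature extraction: the trapezoidal area under |ΔR1(t)| over
the full series is ranked per modality and the top ⌈fraction·N⌉ voxels
(default fraction 0.01) from *each* modality are removed as a union.
Ceiling rounding, union removal and a stable (z, y, x) tie-break are
interpretation choices, as is per-tumor (not cohort-level) ranking.
Non-finite frames are linearly interpolated for the ranking integral. The
operation is deliberately not idempotent — rerunning removes further voxels.

## Feature sets

* **AUC (d = 2).** Signed trapezoidal areas: DCE over frames with
  0 ≤ t − t_inj ≤ 90 s (integration stops at the last frame inside the
  window — no partial-frame interpolation; on the 5.78 s grid this truncates
  at most one frame), OE over all post-switch frames. Signed areas keep
  negative/absent OE responses representable; the modulus AUC is used only
  for exclusion.
* **PCA (d = 4).** Each voxel's DCE and OE curves are concatenated after
  scaling the OE block by s = mean(SD_dce)/mean(SD_oe) (means over voxels of
  per-voxel temporal sample SDs), and mean-centered PCA is computed once
  over the pooled cohort of voxels. Component signs are fixed (largest
  loading positive) for deterministic output. Weightings on the first four
  components form the feature set.

Features are not standardized before clustering: cluster ordering relies on
raw DCE AUC scale, and the AUC pair is kept in its native units.

## Habitat clustering

`HabitatMixture.fit(n_clusters)` runs full-covariance EM (scikit-learn)
from 10 random initializations (means drawn from random data points,
covariances from the data), keeping the restart with the highest
log-likelihood; the clustering pools all tumors' voxels into one feature
space. Covariances are regularized by 1e−6 × the mean feature variance on
the diagonal. EM stops when the mean per-sample log-likelihood changes by
less than 1e−4 or after 500 iterations — past that point the likelihood
only creeps along near-degenerate directions without moving any
assignments, at 10–50× the iteration cost. Hard labels are the
responsibility argmax; responsibilities are kept in the results for
soft-assignment extensions. Clusters are relabelled 1..N_C by increasing
within-cluster mean DCE AUC so labels are comparable across fits (ties keep
their pre-permutation order).

## Model selection

* **AIC** = 2k − 2 lnL with k = N_C·d + N_C·d(d+1)/2 + (N_C − 1)
  (means, full covariances, weights).
* **Contiguity z-score.** Observed metric: the number of 26-connected
  components summed over labels in a tumor's region map. Null: 100
  redraws of the in-mask labels with replacement from the observed label
  multiset at fixed positions — this preserves label marginals while
  destroying spatial structure, which is the property under test.
  z = (mean_null − observed)/SD_null, so contiguous maps score positive.
  Note that with a 26-connected kernel the null itself percolates when only
  two balanced labels are present (few components even for random maps), so
  two-label maps yield modest z even when perfectly contiguous; z grows
  with N_C, and three-label structured maps score z ≈ 5.
* **Stability.** For each N_C, the feature set is bootstrap-resampled over
  voxels (default 100 realizations; the scaled-down phantom cohort uses 50),
  the mixture refitted with the same restart policy and fresh seeds, and
  each realization's centers matched to the reference centers by the
  Hungarian algorithm (minimum total Euclidean distance; optimal
  assignment). All matched centers, grouped by reference index, are scored
  with silhouettes (singleton groups score 0). Median near +1 means refits
  reproduce the same centers.
* **Selection rule.** Among (feature set, N_C) with median stability
  ≥ s_min (default 0.8) and per-tumor median contiguity z ≥ z_min (default
  3), take the largest N_C; break feature-set ties toward lower AIC. If
  nothing passes both thresholds, fall back to the stability criterion
  alone with a warning. Both thresholds are configuration, codifying a
  judgement originally made by inspection.

## Comparison with the threshold-based method

The TBM three-class scheme is: class 1 = DCE-non-enhancing (OE ignored),
class 2 = DCE-enhancing/OE-refractory (putatively hypoxic "perfused
Oxy-R"), class 3 = enhancing in both. The underlying per-voxel enhancement
call is not fully specified in the literature it comes from; this package
uses a documented stand-in — a one-sided Welch t-test of mean post-event
ΔR1 against the pre-event frames at a configurable α (default 0.05), whose
null call rate is verified by simulation. Habitat maps are collapsed to
three classes before comparison (six clusters map 1 | {2,3} | {4,5,6};
other N_C use the analogous DCE-AUC-ordered split; the grouping is
configurable). Agreement is quantified per tumor and pooled: proportional
agreement φ, Cohen's κ = (p_o − p_e)/(1 − p_e) (degenerate constant maps
are reported as 1 if identical else 0, with a warning), and Bland–Altman
bias ± 1.96 SD limits on per-tumor class voxel counts, with the bias also
expressed as a percentage of the mean tumor size.

## The digital phantom

The phantom exists so every downstream stage is testable with known ground
truth. An ellipsoidal tumor is partitioned into habitats by radial shells
(optionally azimuthal wedges); each habitat has DCE kinetics
A·(1 − e^(−k_in t'))·e^(−k_out t') (t' in minutes), OE kinetics
sign·A_oe·(1 − e^(−t'/τ)) (t' in seconds), and a native T10. Raw signals go
through the same SPGR forward model the analysis inverts, the OE series
through the time-varying-flip-angle drift model, plus additive Gaussian
noise. Acquisition timing defaults to the protocol above.

Default three-habitat configuration (chosen once as a plausible preclinical
regime; the literature gives no quantitative noise or drift magnitudes):

| habitat | extent (ρ) | A_dce (s⁻¹) | OE response | T10 (s) |
|---|---|---|---|---|
| necrotic core | 0–0.45 | 0 | none | 1.8 |
| hypoxic shell | 0.45–0.75 | 0.8 | −0.01 s⁻¹, τ 90 s | 1.5 |
| perfused rim | 0.75–1 | 1.8 | +0.04 s⁻¹, τ 60 s | 1.2 |

S0 = 1000, noise SD = 2 signal units (baseline SNR ≈ 18 for the DCE readout
and ≈ 43 for the OE readout), drift A = 0.05 with τ = 300 s. Within-habitat
amplitudes carry a spatially unstructured 10% per-voxel jitter: real tumor
habitats are smooth continua in feature space, not point masses, and without
this the mixture's overfit splits of a zero-width cluster can be spuriously
reproducible across bootstrap refits, inflating stability above the true
N_C. The jitter broadens each habitat without adding clusterable
substructure (a deterministic radial gradient is available as an option but
deliberately not the default, since a structured gradient is itself a
fourth habitat-like feature). Kinetic template shapes are the simplest
forms reproducing the three canonical enhancement classes; all parameters
are configuration, not constants.

What the phantom does **not** emulate: Rician noise (additive Gaussian
only — adequate at these SNRs, noted as an extension), arterial input
functions or pharmacokinetic (Tofts-type) exchange, B1 inhomogeneity,
motion, partial-volume mixing at habitat boundaries, and inter-tumor
biological variability beyond the seeded noise. Passing tests therefore
demonstrate correctness of the estimation and selection machinery under a
faithful forward model, not performance on in-vivo data.

## Problem sizes and determinism

The standard evaluation cohort is four tumors of ~530 voxels each (20×20×10
grids), a sweep of N_C = 2..5 over both feature sets, 50 stability
bootstraps and 100 contiguity redraws — chosen so a full run completes in a
couple of minutes on one CPU while leaving the metric behaviour clearly
resolved. A single global seed is expanded deterministically into per-stage
child seeds (phantom rendering, reference fits, bootstrap refits, contiguity
nulls); reruns with the same configuration and seed are bit-reproducible.

## Known limitations

* The optimum selection is threshold-based; on data whose stability at
  N_C just above the truth hovers near s_min, the selected N_C can vary
  with the bootstrap seed. The rule trace in the evaluation report makes
  the margin visible.
* The TBM enhancement call is a stand-in; agreement statistics against it
  quantify consistency with *this* implementation, not with the original.
* Drift correction assumes a shared α(t) across the ROI.
* κ is unstable when one method assigns nearly all voxels to one class
  (chance agreement → 1); the degenerate-case convention is documented
  above.
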