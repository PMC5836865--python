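# mrhabitats

Data-driven mapping of tumor oxygenation and perfusion heterogeneity from
combined dynamic contrast-enhanced (DCE) and oxygen-enhanced (OE) MRI.

Tumor hypoxia drives treatment resistance, and voxels that enhance after a
gadolinium injection (perfused) but not after a switch to 100% oxygen
breathing (oxygen-refractory) are putatively hypoxic. `mrhabitats`
implements an optimized, data-driven alternative to fixed enhancement
thresholds: voxel-wise ΔR1(t) curves from both modalities are reduced to
feature vectors, clustered with Gaussian mixtures, and the feature set and
number of clusters N_C are chosen by a three-metric evaluation framework.
The package is aimed at quantitative-MRI researchers working with
multi-spectral dynamic tumor data.

## What it computes

For each tumor voxel the dynamic signal S(t) is converted to the change in
longitudinal relaxation rate via the spoiled gradient-recalled echo (SPGR)
signal equation

    S = S0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1)

using T10 and S0 maps fitted to variable flip angle (VFA) data, with the OE
baseline drift modelled as an exponentially time-varying effective flip
angle α(t) = α0·(1 + A·(1 − e^(−t/τ))); then ΔR1(t) = 1/T1(t) − 1/T10.

Two feature sets are extracted: **AUC** (signed trapezoidal area under the
first 90 s post-injection of the DCE curve, and under all post-gas-switch
OE frames) and **PCA** (weightings on the first four principal components of
scaled, concatenated DCE+OE curves). Each is clustered with full-covariance
Gaussian mixtures (best of 10 random restarts) for a sweep of N_C, and three
metrics decide the optimum:

* **AIC** = 2k − 2 lnL, with k the free-parameter count of the mixture;
* **contiguity z-score** — connected-region count (26-connectivity) of each
  tumor's habitat map versus a label-shuffle bootstrap null;
* **stability score** — silhouettes of bootstrap-refit cluster centers after
  Hungarian matching to the reference centers (+1 = perfectly reproducible).

The selected habitat map is finally compared against the prior
threshold-based three-class method (TBM) with proportional agreement φ,
Cohen's κ, and Bland–Altman statistics on per-class voxel counts.

Because no in-vivo data ship with the package, a digital-phantom module
generates synthetic DCE/OE/VFA acquisitions (default timing: 96 DCE frames
at 5.78 s with injection at frame 25; 42 OE frames at 28.80 s with the gas
switch at frame 19) for ellipsoidal tumors with known habitat ground truth.

## Worked example

```python
from mrhabitats import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=21))
print(result.selection)
print(result.report.table[["feature_set", "n_clusters", "aic",
                           "median_stability", "median_contiguity_z"]].to_string())
print(f"phi={result.pooled_agreement.phi:.3f}, "
      f"kappa={result.pooled_agreement.kappa:.3f}")
```

This simulates a four-tumor, three-habitat phantom cohort (~530 voxels per
tumor), runs relaxometry, feature extraction and the full evaluation sweep
(N_C = 2..5, 50 bootstrap refits), and prints:

```
('pca', 3)
  feature_set  n_clusters           aic  median_stability  median_contiguity_z
0         auc           2  38082.927559          0.985660            -0.846947
1         auc           3  37163.800859          0.982180             4.605783
2         auc           4  37134.431525          0.656371             4.910723
3         auc           5  37124.119669          0.640321             2.695543
4         pca           2  21023.680266          0.980623             0.421423
5         pca           3  19998.185378          0.977528             5.273539
6         pca           4  19973.305541          0.706405             4.124091
7         pca           5  19974.938102          0.335540             3.141802
phi=0.993, kappa=0.987
```

Stability stays near +1 up to the true habitat number (3) and degrades
beyond it, true habitat maps are far more contiguous than chance (z ≈ 5),
and the selection rule recovers N_C = 3, breaking the feature-set tie toward
the PCA set's lower AIC. The near-perfect φ/κ against TBM reflects the
phantom's three cleanly separated enhancement classes. When the N_C = 4
stability median lands close to the 0.8 selection threshold the chosen N_C
can vary with the bootstrap seed — see the "Known limitations" section of
`docs/methods.md`. A command-line entry point covers the same workflow:
`mrhabitats phantom --out dir/` and `mrhabitats run --out dir/ --seed 21`.

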