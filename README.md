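# robustprofiler

Outlier-resistant patient-specific (varying-coefficient) regularized
regression for anti-cancer drug-sensitivity prediction.

## The problem

Elastic-net-type regression on gene expression is a standard way to predict
a drug response such as log IC50 and to select biomarkers, but it yields one
averaged model for all samples. Varying-coefficient approaches fix this by
fitting, for every target patient, a local model weighted toward samples
with similar values of a scalar *modulator* m (e.g., a sensitivity index),
so the regression coefficients become functions β(m) and biomarkers can be
sensitivity-specific. Both ingredients, however, rest on least squares, and
expression/response datasets routinely contain gross errors. A few
contaminated samples can dominate every local fit.

`robustprofiler` implements a robust version of this pipeline for
biostatisticians and computational biologists working with
sample × gene expression matrices and per-sample drug responses:

1. **Outlier weights.** Robust principal components of `[X | y]` are found by
   projection pursuit (loadings maximize a MAD scale, so outliers cannot
   attract them). In the score space, a Minimum Volume Ellipsoid estimate
   gives a robust location/scatter, and each sample receives
   `w_i = min(1, q / RD_i²)`, where `RD_i²` is its squared robust Mahalanobis
   distance and `q` the χ²(k) 0.95 quantile: samples inside the ellipsoid
   keep full weight, gross outliers are capped in proportion to how far out
   they sit.
2. **Kernel localization.** A Gaussian kernel
   `K_h(m_t, m_i) = exp(−(m_t−m_i)²/2h²)` localizes each target fit to its
   modulator neighborhood.
3. **Weighted adaptive elastic net.** Each target model solves, by
   coordinate descent,

   ```
   min  ½ Σ_i w_i K_h(m_t, m_i) (y_i − β₀ − x_iᵀβ)²
        + λ Σ_j v_j ( δ|β_j| + ((1−δ)/2) β_j² )
   ```

   with adaptive penalty weights `v_j = 1/(|β̂_init,j| + ε)` from an initial
   non-adaptive fit; δ=1 is the (adaptive) lasso, δ=0 the ridge.
4. **Model selection and screening.** (λ, δ, h) are chosen by 3-fold CV in
   which every validation sample is predicted by a local model fit at its
   own modulator value. A per-dataset contamination score C (mean exceedance
   of robust distances on the first principal component of `[X | y]`) is
   zero for clean datasets and flags contaminated ones, so the robust
   pipeline can be targeted at the drugs that need it.

A Monte Carlo harness (`robustprofiler.simulate`) generates
varying-coefficient datasets with serially correlated designs and rowwise
cellwise contamination, and scores methods by per-target support recovery
(T.P/T.N) and median squared test error.

## Worked example

Planting three gross outliers in a clean 50 × 10 dataset and asking for the
weight chain (`examples/02_outlier_weights.py`):

```
chi-square cutoff (df=5): 11.07
outlier sample  3: RD^2 =    116.5  weight = 0.095
outlier sample 11: RD^2 =     83.9  weight = 0.132
outlier sample 29: RD^2 =     82.2  weight = 0.135
clean samples at full weight: 36 / 47
```

The planted samples sit 7–10× beyond the χ² cutoff and their influence on
any downstream fit is capped at roughly a tenth; most clean samples keep
weight exactly 1.

A miniature paired study with 20% grossly corrupted samples
(`examples/04_simulation_study.py`) ends with:

```
   method  tp_mean  tp_sem  tn_mean   tn_sem  pe_mean   pe_sem
nonrobust 0.391358 0.11680 0.713580 0.051660 1.722825 0.301830
   robust 0.474074 0.14126 0.810974 0.059803 1.107576 0.183841

robust pe <= non-robust pe in 5 of 6 paired replicates
```

i.e. downweighting the corrupted rows recovers more of the true support
(tp, tn) and predicts held-out samples with ~36% lower median squared error
on average.

The other examples show patient-specific biomarker frequency tables
(`examples/01_patient_specific_fit.py`) and dataset-level contamination
screening and ranking (`examples/03_contamination_screen.py`). A thin CLI
mirrors the library (`robustprofiler fit / predict / cv / screen /
biomarkers / simulate`); every output carries a sidecar JSON with the seed
and parameters that produced it.

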