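# petmr-habitats

Quantitative analysis of co-registered antibody-PET and diffusion-weighted
MRI for metastatic breast cancer lesions: ADC map computation, SUV/TBR
quantification, intratumoral habitat mapping, brain physiologic regions, and
lesion-level response statistics. Because no patient images ship with the
package, every stage runs on synthetic co-registered phantoms and lesion
cohorts with planted ground truth, so the whole pipeline is testable on any
machine.

It is aimed at imaging scientists who combine a HER2-targeted PET tracer
(voxel values in SUV) with diffusion MRI (voxel values summarized by the
apparent diffusion coefficient, ADC) and want a reproducible, tested
implementation of the standard per-lesion and voxelwise analyses.

## What it computes

**ADC mapping.** From a diffusion series with b-values b (s/mm²) and signals
S(b), the mono-exponential model S(b) = S₀·exp(−b·ADC) gives the two-point
estimator

    ADC = −ln(S/S₀) / (b − b₀)

and, with three or more b-values, the log-linear mode: ADC = −slope of the
ordinary least-squares fit of ln S on b (the default; it reduces to the
two-point formula on two points). ADC is reported in 10⁻³ mm²/s. Nonpositive
signals make a voxel *invalid* — excluded downstream, never clamped.

**ROI metrics.** SUV_mean/median/max and ADC_mean per region of interest,
with tumor-to-background ratios TBR_mean = SUV_mean(lesion)/SUV_mean(background)
and TBR_max analogously. Volumes on different grids are composed in world
coordinates (trilinear for intensities, nearest-neighbor for masks). Lesion
tables are filtered to diameters ≥ 1 cm (analysis set) and volumes > 5 mL
(habitat-eligible set).

**Habitat maps.** Two voxelwise partitions of a lesion on its joint
(SUV, ADC) profile: the *2-step* method thresholds each metric at its
per-lesion median and combines the High/Low calls into four Boolean classes
(HH, HL, LH, LL); the *1-step* method z-scores both features per lesion and
applies Ward-linkage hierarchical agglomerative clustering cut at k clusters
(default k = 3), with cluster ids renumbered by descending mean SUV. Brain
lesions additionally get a physiologic partition — enhancing core
(T1post − T1pre), vasogenic edema (T2/FLAIR hyperintensity), edema with
restricted diffusion (low ADC inside the edema) — via Otsu thresholds by
default.

**Response statistics.** Diameter-based lesion categories (≥ 30% shrinkage →
responding, ≥ 20% growth → progressing, else stable; responding ∪ stable =
favorable), Mann–Whitney U comparisons (exact for small untied samples),
unregularized logistic regression, and ROC/AUC with a seeded class-stratified
percentile-bootstrap CI.

## Worked example

```python
from petmr_habitats import (PhantomSpec, generate_phantom, compute_adc_loglinear,
                            resample_adc, one_step_clusters)

phantom = generate_phantom(PhantomSpec(seed=42))       # 3 nested habitats
adc = resample_adc(compute_adc_loglinear(phantom.dwi), phantom.suv.grid)
res = one_step_clusters(phantom.suv, adc, phantom.lesion_mask, k=3)
print(res.habitat_map.summary)
```

prints

```
   label      class  voxel_count  volume_fraction  mean_suv  mean_adc
0      1  cluster_1           35         0.161290  6.004572  0.797238
1      2  cluster_2           79         0.364055  4.002588  1.262228
2      3  cluster_3          103         0.474654  2.005083  1.597788
```

— the three recovered clusters sit at the planted (SUV, ADC) means of
(6, 0.7), (4, 1.2) and (2, 1.7): cluster 1 is the high-uptake, low-ADC
(cellularly dense) core, cluster 3 the low-uptake, high-ADC rim, and the
adjusted Rand index against the planted labels is 1.0.

The numbered drivers under `analysis/` run each stage in order
(`01_simulate_phantom.py` … `06_full_pipeline.py`) and write their tables
under `results/`. A thin CLI mirrors the stages:
`petmr-habitats simulate|adc|metrics|habitats|stats|run`.

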