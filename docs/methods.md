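# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic phantoms do and do not establish
about real PET/MRI data.

## Signal model and ADC estimation

Diffusion-weighted signal is modeled per voxel as mono-exponential decay,
S(b) = S₀·exp(−b·ADC), with b in s/mm² and ADC reported in 10⁻³ mm²/s
(soft-tissue values ≈ 0.5–3.0 on that scale; the factor 1000 is applied once,
at output). Two estimators are provided:

* **two-point**: ADC = −ln(S/S₀)/(b − b₀) between the reference acquisition
  and one high-b acquisition;
* **log-linear** (default): minus the OLS slope of ln S on b over all
  b-values with positive signal at that voxel. On exactly two usable points
  it equals the two-point formula; on noiseless mono-exponential input it is
  exact to floating tolerance.

The reference b₀ is the lowest *acquired* b-value, not 0 — typical
whole-body protocols (e.g. b = 50/500/800) omit b = 0, and using b = 50 as
reference also suppresses perfusion contributions. It is configurable.
Voxels with nonpositive signal are flagged invalid and excluded from every
downstream mean; clamping them to an epsilon would bias ADC upward exactly
where the signal floor is hit. IVIM, kurtosis and Rician-noise modeling are
out of scope.

## Grids, resampling and ROI statistics

Volumes live on axis-aligned grids (shape, spacing, origin in mm); all
cross-grid operations work in world coordinates so the finer MRI grid and
coarser PET grid compose without shifting origins. Intensities resample
trilinearly, masks by nearest neighbor (kept binary); both via
`scipy.ndimage.map_coordinates` with edge extension. ROI statistics use the
conventional definitions (even-count median = midpoint of the central pair);
TBRs divide lesion SUV_mean/SUV_max by the matched background ROI's values
and refuse nonpositive backgrounds rather than emitting infinities. The
background region must be named explicitly per lesion — for organs without a
contralateral partner there is no defensible automatic choice.

Lesion filters: the analysis set keeps baseline diameter ≥ 1 cm (boundary
inclusive), the habitat-eligible set keeps volume strictly > 5 mL. The
strict volume gate reflects partial-volume limits of voxelwise analysis at
PET resolution; both bounds are parameters.

## Habitat mapping

**2-step.** Medians of SUV and ADC are computed per lesion over valid voxels
(per-lesion rather than pooled: pooled medians would mix tissue contexts
across sites). A voxel is High on a metric if *strictly greater* than the
median (deterministic tie rule; a flag switches to ≥). The Boolean
combination yields HH/HL/LH/LL with complete, disjoint coverage of valid
lesion voxels. Lesions with < 8 valid voxels are rejected (medians
unstable); the bound is a parameter. A constant metric classes every voxel
Low for that metric, with a warning. Because the split depends only on
ranks, any strictly increasing transform of a metric leaves the map
unchanged — asserted as a property test.

**1-step.** Features (SUV, ADC) are z-scored per lesion (population SD) so
both metrics contribute comparably, then clustered by Ward-linkage
agglomerative clustering on Euclidean distance, cut at k clusters. Default
k = 3, configurable 2–6; no automatic model selection is attempted. Ward is
the variance-minimizing linkage and the standard choice for intensity
features. Cluster ids are renumbered by descending native-unit mean SUV so
labels are deterministic and cluster 1 is always the highest-uptake habitat.
A zero-variance feature is dropped (z-score 0) with a warning. Invalid-ADC
voxels are excluded from both methods and reported as an invalid fraction.

**Brain physiologic regions.** Enhancing core = (T1post − T1pre) above an
enhancement threshold; edema territory = T2/FLAIR above a hyperintensity
threshold; restricted diffusion = non-core edema with ADC below a
restriction threshold; vasogenic edema and residual complete the partition
of the context mask. Thresholds default to Otsu on the respective histogram
within the context (restriction: within the non-core edema), overridable by
absolute values; a near-constant histogram yields an empty region instead of
an arbitrary split. Otsu is appropriate for the bimodal histograms these
contrasts produce in practice; on diffuse low-contrast lesions absolute
thresholds should be supplied.

## Response statistics

Lesion categories follow diameter change c = (follow-up − baseline)/baseline:
c ≤ −0.30 or disappearance → responding; c ≥ +0.20 → progressing; else
stable. Responding ∪ stable = favorable. Mann–Whitney U (U = pairs with
a > b plus half the ties) uses exact enumeration when the combined sample is
≤ 12 and untied — enumeration is cheap there — and the tie-corrected normal
approximation with continuity correction otherwise. Logistic regression is
unregularized maximum likelihood (Newton, log-likelihood tolerance 1e-8);
zero-variance features are dropped with coefficient 0 so the fit stays
identified, and complete/quasi-separation (diverging coefficients) is
flagged rather than raised since the fitted ranking remains usable for ROC.
AUC uses the rank formula with tied pairs at 0.5; CIs are percentile
bootstrap, default 2,000 replicates, resampled within each outcome class and
fully seeded. P values are unadjusted by default (Holm optional). Lesions
are treated as independent units; within-patient correlation is a known
limitation, not modeled.

## Synthetic phantoms and cohorts

Phantoms plant spherical habitats (nested or disjoint; innermost wins) with
true SUV and ADC means; spheres admit analytic volume oracles (4πr³/3) that
the tests check voxel counts against, and an MRI grid (default 2 mm
isotropic, 48³) with a 2× coarser PET grid exercises the resampling stage.
No acquisition voxel size is assumed — all geometry is configuration. Noise
is additive Gaussian, independent across modalities: the simplest model that
makes signal-to-noise statements testable. It omits Rician DWI noise floors,
partial-volume blur, attenuation and scanner artifacts, so passing tests
demonstrate correctness of the *computations*, not robustness to every
real-acquisition effect.

Cohorts draw per-lesion SUV_mean and ADC_mean from class-conditional normals
whose defaults match published per-lesion magnitudes in metastatic breast
cancer (favorable: SUV 2.6 ± 1.4, nonresponding: 2.9 ± 2.7; ADC 1.3 ± 0.5
with the favorable class shifted by a configurable effect size, default
0.4 SD ≈ 1.5 vs 1.3). Site frequencies follow a 42-lesion metastatic
distribution (bone-dominant). Diameters are engineered so the diameter rule
reproduces the intended category, keeping labels and diameters mutually
consistent. For equal-variance normal classes separated by δ SDs the true
AUC of the metric is Φ(δ/√2) — the closed form the parameter-recovery checks
compare against.

## Pipeline determinism and problem sizes

One global seed is split via `numpy.random.SeedSequence.spawn` into
per-stage substreams, so stages cannot perturb each other's randomness;
reruns with one config are byte-identical on all CSV/JSON outputs, and every
output carries the config hash (computed over everything except the output
path). The test suite and the acceptance script use desk-scale problem
sizes chosen to keep the full run in seconds while leaving the statistical
checks well-powered: 48³ MRI grids, ~200–1,500-voxel lesions, 100-lesion
cohorts, 200 Monte-Carlo replicates, 20 clustering seeds.

## Known limitations

Axis-aligned (diagonal-affine) NIfTI only; inputs are assumed co-registered
(simultaneous acquisition) — no registration is performed; no DICOM
ingestion; no PET partial-volume correction; no automatic lesion
segmentation; no patient-level mixed models; no claim of reproducing any
patient-derived AUC or habitat fraction, which depend on non-public clinical
images.
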