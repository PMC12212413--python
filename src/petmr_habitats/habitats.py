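"""Intratumoral habitat maps from co-registered SUV and ADC volumes.

Two voxelwise methods partition a lesion into subregions ("habitats") by
joint tracer uptake (SUV, a HER2-expression surrogate) and water diffusivity
(ADC, a cellularity surrogate):

* the 2-step method thresholds each metric at its per-lesion median and
  combines the High/Low calls into four Boolean classes (HH, HL, LH, LL);
* the 1-step method clusters voxels on their standardized (SUV, ADC) profile
  with Ward-linkage hierarchical agglomerative clustering cut at k clusters.

A separate routine derives physiologic regions of a brain lesion (enhancing
core, vasogenic edema, edema with restricted diffusion, residual) from
T1 pre/post-contrast, T2/FLAIR and ADC volumes by automatic thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.cluster import AgglomerativeClustering

from .adc import AdcVolume
from .core import Grid, ImageVolume, RoiMask

__all__ = [
    "HabitatMap",
    "ClusterResult",
    "BrainRegions",
    "two_step_habitats",
    "one_step_clusters",
    "habitat_summary",
    "brain_physiologic_regions",
]

TWO_STEP_LEGEND = {1: "HH", 2: "HL", 3: "LH", 4: "LL"}

MIN_VOXELS_FOR_MEDIAN_SPLIT = 8


@dataclass
class HabitatMap:
    """Integer label volume over a lesion (0 = outside / excluded).

    ``legend`` maps each nonzero label to a habitat class name;
    ``invalid_fraction`` is the share of lesion voxels excluded because their
    ADC was not computable.
    """

    labels: np.ndarray
    grid: Grid
    legend: dict[int, str]
    invalid_fraction: float = 0.0
    summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = set(np.unique(self.labels[self.labels > 0]).tolist())
        if not present <= set(self.legend):
            raise ValueError(f"legend missing labels: {sorted(present - set(self.legend))}")

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ClusterResult:
    """Output of the 1-step clustering: a HabitatMap plus cluster metadata.

    Cluster ids are contiguous from 1 and renumbered by descending mean SUV so
    that cluster 1 is always the highest-uptake habitat. Centroids are given
    both in standardized (z-score) and native units (SUV unitless,
    ADC 1e-3 mm^2/s).
    """

    habitat_map: HabitatMap
    k: int
    linkage: str
    centroids_native: np.ndarray
    centroids_standardized: np.ndarray


@dataclass
class BrainRegions:
    """Physiologic partition of a brain-lesion context mask.

    The four masks are pairwise disjoint and their union equals the context
    mask. ``thresholds`` records the enhancement, hyperintensity and
    diffusion-restriction cutoffs actually applied.
    """

    core: np.ndarray
    vasogenic_edema: np.ndarray
    restricted_diffusion: np.ndarray
    residual: np.ndarray
    grid: Grid
    thresholds: dict[str, float | None]


def _valid_lesion_voxels(adc: AdcVolume, lesion: RoiMask) -> np.ndarray:
    return lesion.data & adc.valid


def two_step_habitats(
    suv: ImageVolume,
    adc: AdcVolume,
    lesion: RoiMask,
    strict_high: bool = True,
    min_voxels: int = MIN_VOXELS_FOR_MEDIAN_SPLIT,
) -> HabitatMap:
    """Median-threshold ("2-step") habitat map with four Boolean classes.

    Each metric's median is computed per lesion over valid voxels; a voxel is
    High for a metric if strictly greater than that median (``strict_high``
    False uses >=). The High/Low calls combine into HH(1)/HL(2)/LH(3)/LL(4),
    with the ADC call second (HL = high SUV, low ADC). Lesions with fewer
    than ``min_voxels`` valid voxels are rejected (medians too unstable).
    """
    if suv.grid != adc.grid or suv.grid != lesion.grid:
        raise ValueError("SUV, ADC and lesion mask must share one grid")
    valid = _valid_lesion_voxels(adc, lesion)
    n_valid = int(valid.sum())
    if n_valid < min_voxels:
        raise ValueError(
            f"lesion {lesion.name!r}: only {n_valid} valid voxels; "
            f"median split needs at least {min_voxels}"
        )

    labels = np.zeros(suv.data.shape, dtype=np.int32)
    calls = []
    for name, values in (("SUV", suv.data[valid]), ("ADC", adc.data[valid])):
        if np.ptp(values) == 0:
            warnings.warn(
                f"lesion {lesion.name!r}: constant {name}; all voxels classed Low for {name}"
            )
            calls.append(np.zeros(values.shape, dtype=bool))
            continue
        med = np.median(values)
        calls.append(values > med if strict_high else values >= med)
    high_suv, high_adc = calls
    cls = np.where(
        high_suv,
        np.where(high_adc, 1, 2),
        np.where(high_adc, 3, 4),
    )
    labels[valid] = cls

    invalid_fraction = 1.0 - n_valid / lesion.n_voxels
    hmap = HabitatMap(labels, suv.grid, dict(TWO_STEP_LEGEND), invalid_fraction)
    hmap.summary = habitat_summary(hmap, suv, adc)
    return hmap


def one_step_clusters(
    suv: ImageVolume,
    adc: AdcVolume,
    lesion: RoiMask,
    k: int = 3,
) -> ClusterResult:
    """Ward-linkage agglomerative clustering ("1-step") of (SUV, ADC) profiles.

    Features are z-scored per lesion so the two metrics contribute on equal
    footing; a zero-variance feature is set to 0 with a warning and clustering
    proceeds on the other. The tree is cut at ``k`` clusters.
    """
    if suv.grid != adc.grid or suv.grid != lesion.grid:
        raise ValueError("SUV, ADC and lesion mask must share one grid")
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = _valid_lesion_voxels(adc, lesion)
    n_valid = int(valid.sum())
    if k > n_valid:
        raise ValueError(f"k={k} exceeds the {n_valid} valid voxels of lesion {lesion.name!r}")

    feats = np.column_stack([suv.data[valid], adc.data[valid]]).astype(float)
    z = np.zeros_like(feats)
    for j, name in enumerate(("SUV", "ADC")):
        sd = feats[:, j].std()
        if sd == 0:
            warnings.warn(f"lesion {lesion.name!r}: zero-variance {name}; feature dropped")
        else:
            z[:, j] = (feats[:, j] - feats[:, j].mean()) / sd

    if k == 1:
        raw = np.zeros(n_valid, dtype=int)
    else:
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)

    # renumber clusters 1..k by descending mean SUV for stable reporting
    order = np.argsort([-feats[raw == c, 0].mean() for c in range(k)])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    ids = remap[raw]

    labels = np.zeros(suv.data.shape, dtype=np.int32)
    labels[valid] = ids
    centroids_native = np.vstack([feats[ids == c].mean(axis=0) for c in range(1, k + 1)])
    centroids_std = np.vstack([z[ids == c].mean(axis=0) for c in range(1, k + 1)])

    legend = {c: f"cluster_{c}" for c in range(1, k + 1)}
    hmap = HabitatMap(labels, suv.grid, legend, 1.0 - n_valid / lesion.n_voxels)
    hmap.summary = habitat_summary(hmap, suv, adc)
    return ClusterResult(hmap, k, "ward", centroids_native, centroids_std)


def habitat_summary(hmap: HabitatMap, suv: ImageVolume, adc: AdcVolume | ImageVolume) -> pd.DataFrame:
    """Per-habitat voxel count, volume fraction and mean SUV / mean ADC.

    Fractions are over labeled voxels and sum to 1; the weighted combination
    of habitat means reproduces the whole-lesion mean (law of total
    expectation).
    """
    adc_data = adc.data if isinstance(adc, (AdcVolume, ImageVolume)) else np.asarray(adc)
    labeled = hmap.labeled_mask
    total = int(labeled.sum())
    rows = []
    for label in sorted(np.unique(hmap.labels[labeled]).tolist()):
        sel = hmap.labels == label
        n = int(sel.sum())
        rows.append(
            {
                "label": label,
                "class": hmap.legend[label],
                "voxel_count": n,
                "volume_fraction": n / total,
                "mean_suv": float(suv.data[sel].mean()),
                "mean_adc": float(adc_data[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def _otsu_or_none(values: np.ndarray) -> float | None:
    """Otsu threshold, or None when the sample is (near-)constant."""
    if values.size == 0 or np.ptp(values) < 1e-12:
        return None
    return float(threshold_otsu(values))


def brain_physiologic_regions(
    t1pre: ImageVolume,
    t1post: ImageVolume,
    t2flair: ImageVolume,
    adc: ImageVolume | AdcVolume,
    context: RoiMask,
    enhancement_threshold: float | None = None,
    hyperintensity_threshold: float | None = None,
    restriction_threshold: float | None = None,
) -> BrainRegions:
    """Partition a brain-lesion context into physiologic habitats.

    * enhancing core: (T1post - T1pre) above the enhancement threshold;
    * edema territory: T2/FLAIR above the hyperintensity threshold;
    * restricted diffusion: edema-territory voxels outside the core with ADC
      below the restriction threshold;
    * vasogenic edema: remaining edema territory; residual: everything else
      in the context mask.

    Thresholds default to Otsu on the respective histogram within the context
    (restriction: within the non-core edema territory); pass absolute values
    to override. A (near-)constant histogram yields an empty region rather
    than an arbitrary split.
    """
    for name, vol in (("t1pre", t1pre), ("t1post", t1post), ("t2flair", t2flair), ("adc", adc)):
        if vol is None:
            raise ValueError(f"missing required sequence: {name}")
    adc_data = adc.data
    grid = t1pre.grid
    for name, vol in (("t1post", t1post), ("t2flair", t2flair), ("adc", adc), ("context", context)):
        if vol.grid != grid:
            raise ValueError(f"{name} is not on the same grid as t1pre")

    ctx = context.data
    diff = np.asarray(t1post.data, dtype=float) - np.asarray(t1pre.data, dtype=float)

    thr_enh = enhancement_threshold
    if thr_enh is None:
        thr_enh = _otsu_or_none(diff[ctx])
    core = ctx & (diff > thr_enh) if thr_enh is not None else np.zeros_like(ctx)

    thr_hyper = hyperintensity_threshold
    if thr_hyper is None:
        thr_hyper = _otsu_or_none(np.asarray(t2flair.data)[ctx])
    territory = ctx & (t2flair.data > thr_hyper) if thr_hyper is not None else np.zeros_like(ctx)

    edema_noncore = territory & ~core
    thr_adc = restriction_threshold
    if thr_adc is None:
        thr_adc = _otsu_or_none(adc_data[edema_noncore])
    restricted = (
        edema_noncore & (adc_data < thr_adc) if thr_adc is not None else np.zeros_like(ctx)
    )

    vasogenic = edema_noncore & ~restricted
    residual = ctx & ~(core | vasogenic | restricted)
    return BrainRegions(
        core=core,
        vasogenic_edema=vasogenic,
        restricted_diffusion=restricted,
        residual=residual,
        grid=grid,
        thresholds={
            "enhancement": thr_enh,
            "hyperintensity": thr_hyper,
            "restriction": thr_adc,
        },
    )
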