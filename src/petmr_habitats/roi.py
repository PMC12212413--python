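"""Cross-grid resampling, per-ROI summary statistics and tumor-to-background ratios.

All grid arithmetic happens in world coordinates (mm), so an ADC map on the
finer MRI grid resamples onto the coarser PET grid without shifting the
origin. Intensities interpolate trilinearly; masks use nearest-neighbor so
they stay binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .adc import AdcVolume
from .core import Grid, ImageVolume, RoiMask

__all__ = [
    "RoiStats",
    "TbrResult",
    "resample_to_grid",
    "resample_mask",
    "resample_adc",
    "extract_roi_stats",
    "compute_tbr",
    "filter_lesions",
]


@dataclass(frozen=True)
class RoiStats:
    """Summary statistics of one ROI: SUV mean/median/max, optional ADC mean.

    ``volume_ml`` = voxel count x voxel volume. The even-count median is the
    midpoint of the two central values. Invalid-ADC voxels are excluded from
    ``adc_mean`` (None when no valid voxel remains is an error upstream).
    """

    roi: str
    tissue_class: str
    suv_mean: float
    suv_median: float
    suv_max: float
    adc_mean: float | None
    n_voxels: int
    volume_ml: float


@dataclass(frozen=True)
class TbrResult:
    """Tumor-to-background ratios of SUV_mean and SUV_max."""

    tbr_mean: float
    tbr_max: float
    background_roi: str


def _world_to_source_indices(target: Grid, source: Grid) -> np.ndarray:
    world = target.index_grid_world()  # (3, *shape)
    spacing = np.asarray(source.spacing).reshape(3, 1, 1, 1)
    origin = np.asarray(source.origin).reshape(3, 1, 1, 1)
    return (world - origin) / spacing


def resample_to_grid(vol: ImageVolume, target: Grid, kind: str = "intensity") -> ImageVolume:
    """Resample a volume onto a target grid in world space.

    ``kind='intensity'`` interpolates trilinearly; ``kind='mask'`` uses
    nearest-neighbor. Values outside the source extent take the nearest edge
    value. Disjoint world extents are rejected.
    """
    if kind not in ("intensity", "mask"):
        raise ValueError(f"kind must be 'intensity' or 'mask', got {kind!r}")
    if vol.grid == target:
        return ImageVolume(vol.data.copy(), target, vol.modality)
    lo_s, hi_s = vol.grid.world_extent()
    lo_t, hi_t = target.world_extent()
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise ValueError("source and target grids do not overlap in world space")
    coords = _world_to_source_indices(target, vol.grid)
    order = 1 if kind == "intensity" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=order, mode="nearest"
    )
    return ImageVolume(out, target, vol.modality)


def resample_mask(mask: RoiMask, target: Grid) -> RoiMask:
    """Nearest-neighbor mask transfer preserving name/class metadata."""
    vol = resample_to_grid(ImageVolume(mask.data.astype(float), mask.grid), target, kind="mask")
    return RoiMask(vol.data > 0.5, target, mask.name, mask.tissue_class, mask.laterality)


def resample_adc(adc: AdcVolume, target: Grid) -> AdcVolume:
    """Resample an ADC map with its validity mask (trilinear / nearest)."""
    vol = resample_to_grid(adc.volume, target, kind="intensity")
    valid = resample_to_grid(
        ImageVolume(adc.valid.astype(float), adc.grid), target, kind="mask"
    )
    return AdcVolume(vol, valid.data > 0.5)


def extract_roi_stats(
    suv: ImageVolume, mask: RoiMask, adc: AdcVolume | None = None
) -> RoiStats:
    """Mean/median/max SUV (and mean ADC over valid voxels) within one ROI."""
    if suv.grid != mask.grid:
        raise ValueError(f"ROI {mask.name!r} is not on the same grid as the SUV volume")
    vals = suv.data[mask.data]
    if vals.size == 0:
        raise ValueError(f"ROI {mask.name!r} contains no voxels")
    adc_mean: float | None = None
    if adc is not None:
        if adc.grid != mask.grid:
            raise ValueError(f"ROI {mask.name!r} is not on the same grid as the ADC volume")
        sel = mask.data & adc.valid
        if not sel.any():
            raise ValueError(f"ROI {mask.name!r}: no valid ADC voxels remain")
        adc_mean = float(adc.data[sel].mean())
    return RoiStats(
        roi=mask.name,
        tissue_class=mask.tissue_class,
        suv_mean=float(vals.mean()),
        suv_median=float(np.median(vals)),
        suv_max=float(vals.max()),
        adc_mean=adc_mean,
        n_voxels=mask.n_voxels,
        volume_ml=mask.volume_ml,
    )


def compute_tbr(lesion: RoiStats, background: RoiStats) -> TbrResult:
    """TBR_mean = lesion SUV_mean / background SUV_mean; likewise for SUV_max."""
    if background.suv_mean <= 0 or background.suv_max <= 0:
        raise ValueError(
            f"background ROI {background.roi!r} has nonpositive SUV; TBR undefined"
        )
    return TbrResult(
        tbr_mean=lesion.suv_mean / background.suv_mean,
        tbr_max=lesion.suv_max / background.suv_max,
        background_roi=background.roi,
    )


def filter_lesions(
    records: pd.DataFrame,
    min_diameter_cm: float = 1.0,
    min_habitat_volume_ml: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis-set and habitat-eligibility filters.

    The analysis set keeps lesions with baseline diameter >= ``min_diameter_cm``
    (boundary inclusive: a lesion of exactly 1 cm is retained). The
    habitat-eligible set keeps analysis-set lesions with volume strictly
    greater than ``min_habitat_volume_ml``. Lesions with a missing diameter
    are excluded with a warning, never silently.
    """
    diam = pd.to_numeric(records["baseline_diameter_mm"], errors="coerce")
    missing = diam.isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} lesion(s) with missing diameter: "
            f"{records.loc[missing, 'lesion_id'].tolist() if 'lesion_id' in records else missing.sum()}"
        )
    analysis = records[~missing & (diam >= min_diameter_cm * 10.0)].copy()
    if "volume_ml" in analysis.columns:
        eligible = analysis[analysis["volume_ml"] > min_habitat_volume_ml].copy()
    else:
        warnings.warn("no 'volume_ml' column; habitat-eligible set is empty")
        eligible = analysis.iloc[0:0].copy()
    return analysis, eligible
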