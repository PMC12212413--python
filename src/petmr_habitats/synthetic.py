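"""Synthetic co-registered PET/ADC phantoms and lesion cohorts with ground truth.

No patient images are distributed with this package, so every downstream
stage is exercised on phantoms that plant known habitat geometry and signal
levels:

* lesions are spheres containing nested/disjoint spherical habitats, each
  with a true SUV mean (unitless) and a true ADC mean (1e-3 mm^2/s);
* the diffusion series follows the mono-exponential decay
  S(b) = S0 * exp(-b * ADC_true) with optional additive Gaussian noise;
* the PET grid is coarser than the MRI grid by an integer factor (default
  2x) so the resampling stage is genuinely exercised;
* lesion cohorts draw per-class SUV/ADC summary metrics from normal
  distributions whose defaults match published per-lesion magnitudes
  (SUV_mean ~2.6-2.9, ADC_mean ~1.3-1.5 in 1e-3 mm^2/s), with a tunable
  ADC-response effect size in SD units.

Spheres are deliberate: they admit analytic volume oracles (4*pi*r^3/3) that
the tests check voxel counts against. Gaussian noise, additive and
independent across modalities, is the simplest testable choice; Rician DWI
noise, partial-volume effects and scanner artifacts are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adc import ADC_SCALE, DwiSeries
from .core import Grid, ImageVolume, RoiMask
from .habitats import HabitatMap
from .stats import classify_response

__all__ = [
    "HabitatSphere",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "BrainSpec",
    "BrainPhantom",
    "generate_phantom",
    "generate_lesion_cohort",
    "generate_brain_sequences",
    "cohort_from_counts",
    "paint_labels",
    "SITE_FREQUENCIES",
]

# per-lesion site frequencies of the metastatic cohort the defaults emulate
SITE_FREQUENCIES = {
    "brain": 3 / 42,
    "breast": 5 / 42,
    "bone": 26 / 42,
    "soft tissue": 6 / 42,
    "liver": 2 / 42,
}


@dataclass(frozen=True)
class HabitatSphere:
    """One planted habitat: a sphere with true SUV/ADC means and noise SDs.

    ADC is in 1e-3 mm^2/s; noise SDs are additive Gaussian, ``dwi_noise_sd``
    in raw signal units on every diffusion-weighted volume and
    ``suv_noise_sd`` in SUV units on the PET volume.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv_mean: float
    adc_mean: float
    suv_noise_sd: float = 0.0
    dwi_noise_sd: float = 0.0


def _default_habitats() -> tuple[HabitatSphere, ...]:
    # three nested habitats inside a 15 mm lesion; distinct (SUV, ADC) pairs
    c = (48.0, 48.0, 48.0)
    return (
        HabitatSphere("rim", c, 15.0, suv_mean=2.0, adc_mean=1.8, suv_noise_sd=0.1, dwi_noise_sd=5.0),
        HabitatSphere("mid", c, 12.0, suv_mean=4.0, adc_mean=1.2, suv_noise_sd=0.1, dwi_noise_sd=5.0),
        HabitatSphere("core", c, 8.0, suv_mean=6.0, adc_mean=0.7, suv_noise_sd=0.1, dwi_noise_sd=5.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, signal levels and noise of one synthetic lesion phantom.

    The MRI grid carries the DWI series; the PET grid is coarser by
    ``pet_downsample`` (integer factor) with voxel centers at the centers of
    the corresponding MRI blocks. Habitats are painted largest-first so the
    innermost sphere wins where they nest. Voxel sizes are configuration, not
    constants: no acquisition resolution is assumed.
    """

    mri_shape: tuple[int, int, int] = (48, 48, 48)
    mri_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    pet_downsample: int = 2
    habitats: tuple[HabitatSphere, ...] = field(default_factory=_default_habitats)
    background_suv: float = 0.5
    background_adc: float = 1.0
    bvalues: tuple[float, ...] = (50.0, 500.0, 800.0)
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.mri_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.pet_downsample < 1:
            raise ValueError("pet_downsample must be a positive integer")
        b = np.asarray(self.bvalues, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0) or np.any(b < 0):
            raise ValueError("b-values must be >= 0 and strictly increasing")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        lo, hi = self.mri_grid.world_extent()
        for h in self.habitats:
            if h.radius_mm <= 0:
                raise ValueError(f"habitat {h.name!r}: radius must be positive")
            if h.suv_noise_sd < 0 or h.dwi_noise_sd < 0:
                raise ValueError(f"habitat {h.name!r}: noise SDs must be nonnegative")
            c = np.asarray(h.center_mm, dtype=float)
            if np.any(c - h.radius_mm < lo) or np.any(c + h.radius_mm > hi):
                raise ValueError(
                    f"habitat {h.name!r} (radius {h.radius_mm} mm) exceeds the grid extent"
                )

    @property
    def mri_grid(self) -> Grid:
        return Grid(self.mri_shape, self.mri_spacing_mm)

    @property
    def pet_grid(self) -> Grid:
        f = self.pet_downsample
        shape = tuple(int(s // f) for s in self.mri_shape)
        spacing = tuple(sp * f for sp in self.mri_spacing_mm)
        # PET voxel centers sit at the centers of f^3 MRI-voxel blocks
        origin = tuple((f - 1) / 2.0 * sp for sp in self.mri_spacing_mm)
        return Grid(shape, spacing, origin)


@dataclass
class Phantom:
    """One generated phantom: DWI on the MRI grid, SUV and truth on the PET grid."""

    dwi: DwiSeries
    suv: ImageVolume
    lesion_mask: RoiMask
    truth: HabitatMap
    adc_true: ImageVolume
    lesion_mask_mri: RoiMask
    truth_mri: HabitatMap


def _sorted_outermost_first(habitats: tuple[HabitatSphere, ...]) -> list[HabitatSphere]:
    return sorted(habitats, key=lambda h: -h.radius_mm)


def paint_labels(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    """Integer habitat labels (1-based, in spec order; 0 = background) on a grid.

    Habitats paint largest-first, so the innermost of nested spheres wins.
    """
    world = grid.index_grid_world()
    labels = np.zeros(grid.shape, dtype=np.int32)
    index_of = {h.name: i + 1 for i, h in enumerate(spec.habitats)}
    for h in _sorted_outermost_first(spec.habitats):
        d2 = sum((world[a] - h.center_mm[a]) ** 2 for a in range(3))
        labels[d2 <= h.radius_mm**2] = index_of[h.name]
    return labels


def _paint_field(
    spec: PhantomSpec, grid: Grid, attr: str, background: float
) -> tuple[np.ndarray, np.ndarray]:
    """(values, labels) of a per-habitat scalar painted on a grid."""
    labels = paint_labels(spec, grid)
    values = np.full(grid.shape, background, dtype=float)
    for i, h in enumerate(spec.habitats, start=1):
        values[labels == i] = getattr(h, attr)
    return values, labels


def _truth_map(spec: PhantomSpec, labels: np.ndarray, grid: Grid) -> HabitatMap:
    legend = {i: h.name for i, h in enumerate(spec.habitats, start=1)}
    return HabitatMap(labels, grid, legend)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one seeded phantom from a :class:`PhantomSpec`.

    The DWI series lives on the MRI grid and follows
    S(b) = S0 exp(-b * ADC_true) + Gaussian noise; the SUV volume lives on the
    (coarser) PET grid with the habitat geometry painted directly in world
    coordinates, plus Gaussian noise. With all noise SDs zero, voxel values
    equal the planted means exactly. Identical specs (same seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    mri, pet = spec.mri_grid, spec.pet_grid

    adc_true, labels_mri = _paint_field(spec, mri, "adc_mean", spec.background_adc)
    dwi_sd_mri = np.zeros(mri.shape)
    for i, h in enumerate(spec.habitats, start=1):
        dwi_sd_mri[labels_mri == i] = h.dwi_noise_sd

    volumes = []
    for b in spec.bvalues:
        signal = spec.s0 * np.exp(-b * adc_true / ADC_SCALE)
        noise = rng.normal(0.0, 1.0, mri.shape) * dwi_sd_mri
        volumes.append(ImageVolume(signal + noise, mri, modality=f"DWI_b{b:g}"))
    dwi = DwiSeries(np.asarray(spec.bvalues, dtype=float), volumes)

    suv_true, labels_pet = _paint_field(spec, pet, "suv_mean", spec.background_suv)
    suv_sd_pet = np.zeros(pet.shape)
    for i, h in enumerate(spec.habitats, start=1):
        suv_sd_pet[labels_pet == i] = h.suv_noise_sd
    suv = ImageVolume(suv_true + rng.normal(0.0, 1.0, pet.shape) * suv_sd_pet, pet, "SUV")

    lesion_pet = RoiMask(labels_pet > 0, pet, "lesion", "lesion")
    lesion_mri = RoiMask(labels_mri > 0, mri, "lesion", "lesion")
    return Phantom(
        dwi=dwi,
        suv=suv,
        lesion_mask=lesion_pet,
        truth=_truth_map(spec, labels_pet, pet),
        adc_true=ImageVolume(adc_true, mri, "ADC"),
        lesion_mask_mri=lesion_mri,
        truth_mri=_truth_map(spec, labels_mri, mri),
    )


# ---------------------------------------------------------------------------
# lesion cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Class-conditional distributions of per-lesion metrics.

    ``adc_effect_sd`` shifts the favorable-class ADC mean upward by that many
    pooled SDs relative to ``adc_mean_nonresponding`` (responding lesions show
    higher diffusivity). Defaults reproduce the magnitudes of a published
    42-lesion metastatic cohort: favorable fraction 29/42, SUV_mean 2.6 +/- 1.4
    vs 2.9 +/- 2.7, ADC 1.3 +/- 0.5 with a 0.4-SD shift (1.5 vs 1.3).
    """

    n_lesions: int = 42
    fraction_favorable: float = 29 / 42
    suv_mean_favorable: float = 2.6
    suv_sd_favorable: float = 1.4
    suv_mean_nonresponding: float = 2.9
    suv_sd_nonresponding: float = 2.7
    adc_mean_nonresponding: float = 1.3
    adc_sd: float = 0.5
    adc_effect_sd: float = 0.4
    responding_within_favorable: float = 11 / 29
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 2:
            raise ValueError("a cohort needs at least 2 lesions")
        if not 0.0 <= self.fraction_favorable <= 1.0:
            raise ValueError("fraction_favorable must be in [0, 1]")
        for name in ("suv_sd_favorable", "suv_sd_nonresponding", "adc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        params = (
            self.suv_mean_favorable,
            self.suv_mean_nonresponding,
            self.adc_mean_nonresponding,
            self.adc_effect_sd,
        )
        if not np.all(np.isfinite(params)):
            raise ValueError("distribution parameters must be finite")

    @property
    def adc_mean_favorable(self) -> float:
        return self.adc_mean_nonresponding + self.adc_effect_sd * self.adc_sd


def generate_lesion_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-lesion cohort table from class-conditional distributions.

    Exactly ``round(n * fraction_favorable)`` lesions are favorable. Diameters
    are engineered so that the diameter-based response rule reproduces the
    intended category (favorable lesions split responding/stable; progressing
    lesions grow >= 20%). Ancillary metrics (SUV_median/max, TBRs, normal-
    breast ratio, ADC-split SUV means) are derived with realistic ratios so
    the full comparison table runs. Reproducible under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lesions
    n_fav = int(round(n * spec.fraction_favorable))
    favorable = np.zeros(n, dtype=bool)
    favorable[:n_fav] = True
    rng.shuffle(favorable)

    suv_mean = np.where(
        favorable,
        rng.normal(spec.suv_mean_favorable, spec.suv_sd_favorable, n),
        rng.normal(spec.suv_mean_nonresponding, spec.suv_sd_nonresponding, n),
    )
    suv_mean = np.clip(suv_mean, 0.05, None)
    adc_mean = np.where(
        favorable,
        rng.normal(spec.adc_mean_favorable, spec.adc_sd, n),
        rng.normal(spec.adc_mean_nonresponding, spec.adc_sd, n),
    )
    adc_mean = np.clip(adc_mean, 1e-3, None)

    sites = rng.choice(
        list(SITE_FREQUENCIES), size=n, p=np.asarray(list(SITE_FREQUENCIES.values()))
    )
    baseline = np.exp(rng.normal(np.log(22.0), 0.35, n))  # mm, lognormal around 22

    responding = favorable & (rng.random(n) < spec.responding_within_favorable)
    change = np.where(
        responding,
        rng.uniform(-0.80, -0.31, n),
        np.where(favorable, rng.uniform(-0.25, 0.15, n), rng.uniform(0.21, 0.60, n)),
    )
    followup = baseline * (1.0 + change)

    suv_median = suv_mean * rng.uniform(0.85, 1.0, n)
    suv_max = suv_mean * rng.uniform(2.0, 3.0, n)
    bg = np.clip(rng.normal(0.9, 0.2, n), 0.3, None)
    tbr_mean = suv_mean / bg
    tbr_max = suv_max / (bg * rng.uniform(1.2, 1.5, n))
    breast_bg = np.clip(rng.normal(0.35, 0.08, n), 0.1, None)

    df = pd.DataFrame(
        {
            "lesion_id": [f"L{i:03d}" for i in range(n)],
            "patient_id": [f"P{i // 3:02d}" for i in range(n)],
            "site": sites,
            "baseline_diameter_mm": baseline,
            "followup_diameter_mm": followup,
            "volume_ml": 4.0 / 3.0 * np.pi * (baseline / 2.0) ** 3 / 1000.0,
            "suv_mean": suv_mean,
            "suv_median": suv_median,
            "suv_max": suv_max,
            "adc_mean": adc_mean,
            "tbr_mean": tbr_mean,
            "tbr_max": tbr_max,
            "suv_max_normal_breast": suv_max / breast_bg,
            "suv_mean_adc_low": suv_mean * rng.uniform(0.9, 1.2, n),
            "suv_mean_adc_high": suv_mean * rng.uniform(0.8, 1.1, n),
        }
    )
    df["response_category"] = [
        classify_response(b, f) for b, f in zip(df.baseline_diameter_mm, df.followup_diameter_mm)
    ]
    df["outcome"] = np.where(df.response_category == "progressing", "nonresponding", "favorable")
    if not (df.outcome.eq("favorable").to_numpy() == favorable).all():
        raise AssertionError("engineered diameters inconsistent with response rule")
    return df


def cohort_from_counts(
    site_counts: dict[str, int],
    response_counts: dict[str, int],
    n_subcentimeter: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic cohort with prescribed site/response counts.

    Builds one lesion row per counted unit with diameters engineered to land
    in the requested response category, plus ``n_subcentimeter`` extra lesions
    below 1 cm (which the diameter filter removes). Site and response counts
    are interleaved deterministically; metric columns are drawn with the seed.
    """
    if sum(site_counts.values()) != sum(response_counts.values()):
        raise ValueError("site and response counts must total the same number of lesions")
    n = sum(site_counts.values())
    sites = [s for s, c in site_counts.items() for _ in range(c)]
    categories = [r for r, c in response_counts.items() for _ in range(c)]

    change_by_cat = {"responding": -0.40, "stable": 0.00, "progressing": 0.30}
    baseline = np.full(n, 20.0)
    followup = np.array([20.0 * (1.0 + change_by_cat[c]) for c in categories])

    small = pd.DataFrame(
        {
            "site": ["bone"] * n_subcentimeter,
            "baseline_diameter_mm": 6.0,
            "followup_diameter_mm": 6.0,
        }
    )
    df = pd.DataFrame(
        {"site": sites, "baseline_diameter_mm": baseline, "followup_diameter_mm": followup}
    )
    df = pd.concat([df, small], ignore_index=True)
    df["lesion_id"] = [f"L{i:03d}" for i in range(len(df))]
    df["volume_ml"] = 4.0 / 3.0 * np.pi * (df.baseline_diameter_mm / 2.0) ** 3 / 1000.0

    rng = np.random.default_rng(seed)
    df["suv_mean"] = np.clip(rng.normal(2.7, 1.5, len(df)), 0.05, None)
    df["adc_mean"] = np.clip(rng.normal(1.4, 0.5, len(df)), 1e-3, None)
    df["response_category"] = [
        classify_response(b, f) for b, f in zip(df.baseline_diameter_mm, df.followup_diameter_mm)
    ]
    return df


# ---------------------------------------------------------------------------
# brain phantoms


@dataclass(frozen=True)
class BrainSpec:
    """Nested-sphere brain-lesion phantom: enhancing core inside an edema shell.

    The optional restricted-diffusion sub-shell occupies radii
    (core_radius_mm, restricted_radius_mm] inside the edema shell. Intensities
    are arbitrary MR units; ADC levels are 1e-3 mm^2/s (edema high, core and
    restricted tissue low).
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    center_mm: tuple[float, float, float] = (47.0, 47.0, 47.0)
    core_radius_mm: float = 10.0
    edema_radius_mm: float = 20.0
    restricted_radius_mm: float | None = 14.0
    context_margin_mm: float = 6.0
    t1_base: float = 100.0
    enhancement_contrast: float = 80.0
    flair_base: float = 100.0
    flair_hyper_contrast: float = 80.0
    adc_background: float = 0.8
    adc_core: float = 0.7
    adc_edema: float = 1.8
    adc_restricted: float = 0.5
    noise_sd: float = 0.0  # MR intensity units (T1/FLAIR)
    adc_noise_sd: float = 0.0  # 1e-3 mm^2/s; ADC lives on a ~1 scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius_mm <= 0 or self.edema_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if self.core_radius_mm >= self.edema_radius_mm:
            raise ValueError("enhancing core must be strictly contained in the edema shell")
        if self.restricted_radius_mm is not None and not (
            self.core_radius_mm < self.restricted_radius_mm <= self.edema_radius_mm
        ):
            raise ValueError("restricted sub-shell must lie within the edema shell")
        if self.noise_sd < 0 or self.adc_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing_mm)


@dataclass
class BrainPhantom:
    """Generated brain sequences plus truth masks for each physiologic region."""

    t1pre: ImageVolume
    t1post: ImageVolume
    t2flair: ImageVolume
    adc: ImageVolume
    context: RoiMask
    truth_core: RoiMask
    truth_vasogenic: RoiMask
    truth_restricted: RoiMask | None


def generate_brain_sequences(spec: BrainSpec) -> BrainPhantom:
    """Generate T1 pre/post, T2/FLAIR and ADC volumes with nested truth regions.

    T1post exceeds T1pre by the enhancement contrast only inside the core;
    FLAIR hyperintensity covers core + edema shell; the restricted sub-shell
    carries ADC below the edema level. Truth masks are exported per region.
    """
    grid = spec.grid
    world = grid.index_grid_world()
    d2 = sum((world[a] - spec.center_mm[a]) ** 2 for a in range(3))

    core = d2 <= spec.core_radius_mm**2
    edema_full = d2 <= spec.edema_radius_mm**2
    if spec.restricted_radius_mm is not None:
        restricted = (d2 <= spec.restricted_radius_mm**2) & ~core
    else:
        restricted = np.zeros(grid.shape, dtype=bool)
    vasogenic = edema_full & ~core & ~restricted
    context = d2 <= (spec.edema_radius_mm + spec.context_margin_mm) ** 2

    rng = np.random.default_rng(spec.seed)

    def noisy(base: np.ndarray, sd: float) -> np.ndarray:
        return base + (rng.normal(0.0, sd, grid.shape) if sd > 0 else 0.0)

    t1pre = np.full(grid.shape, spec.t1_base, dtype=float)
    t1post = t1pre + np.where(core, spec.enhancement_contrast, 0.0)
    flair = np.full(grid.shape, spec.flair_base, dtype=float)
    flair[edema_full] += spec.flair_hyper_contrast
    adc = np.full(grid.shape, spec.adc_background, dtype=float)
    adc[vasogenic] = spec.adc_edema
    adc[restricted] = spec.adc_restricted
    adc[core] = spec.adc_core

    return BrainPhantom(
        t1pre=ImageVolume(noisy(t1pre, spec.noise_sd), grid, "T1pre"),
        t1post=ImageVolume(noisy(t1post, spec.noise_sd), grid, "T1post"),
        t2flair=ImageVolume(noisy(flair, spec.noise_sd), grid, "T2FLAIR"),
        adc=ImageVolume(noisy(adc, spec.adc_noise_sd), grid, "ADC"),
        context=RoiMask(context, grid, "context", "lesion"),
        truth_core=RoiMask(core, grid, "truth_core", "lesion"),
        truth_vasogenic=RoiMask(vasogenic, grid, "truth_vasogenic", "lesion"),
        truth_restricted=(
            RoiMask(restricted, grid, "truth_restricted", "lesion") if restricted.any() else None
        ),
    )
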