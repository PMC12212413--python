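"""End-to-end orchestration: phantom -> ADC -> resample -> metrics -> habitats -> stats.

A single global seed is fanned out through ``numpy.random.SeedSequence`` into
independent per-stage substreams, so adding a stage never perturbs another
stage's randomness and a rerun with the same config is byte-identical on all
CSV/JSON outputs. Every output file carries the config hash (a header comment
in CSVs, a key in JSONs, plus a manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import adc as adcmod
from . import habitats as hab
from . import roi as roimod
from . import stats as statsmod
from . import synthetic as synth
from .core import ImageVolume, RoiMask, save_volume

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("petmr_habitats.pipeline")


class ConfigError(ValueError):
    """Raised with every configuration problem aggregated into one message."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n" + "\n".join(f"  - {e}" for e in errors))


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are errors, not typos."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    adc_mode: str = Field(default="loglinear", pattern="^(loglinear|twopoint)$")
    b_reference_index: int = 0
    habitat_method: str = Field(default="both", pattern="^(twostep|onestep|both)$")
    k: int = Field(default=3, ge=2, le=6)
    min_diameter_cm: float = Field(default=1.0, gt=0)
    min_habitat_volume_ml: float = Field(default=5.0, ge=0)
    n_boot: int = Field(default=2000, ge=1)
    n_lesions: int = Field(default=42, ge=2)
    adc_effect_sd: float = 0.4
    save_volumes: bool = True


def validate_config(raw) -> PipelineConfig:
    """Schema-check a raw config (dict or JSON text), reporting all errors at once."""
    if isinstance(raw, (str, bytes)):
        try:
            raw = json.loads(raw)
        except json.JSONDecodeError as e:
            raise ConfigError([f"config is not valid JSON: {e}"]) from e
    try:
        return PipelineConfig(**raw)
    except ValidationError as e:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigError(msgs) from e


def _config_hash(config: PipelineConfig) -> str:
    # the hash covers everything that can change results, not where they land
    payload = json.dumps(config.model_dump(exclude={"out_dir"}), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages on a synthetic phantom + cohort; returns the run directory.

    Stage order: simulate -> ADC -> resample -> ROI metrics -> filters ->
    habitats (gated on lesion volume) -> summaries -> statistics. Any stage
    error aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))  # no timestamps
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info("config hash %s, seed %d", cfg_hash, config.seed)
        streams = np.random.SeedSequence(config.seed).spawn(3)
        phantom_seed, cohort_seed, boot_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in streams
        )

        stage = "simulate"
        spec = synth.PhantomSpec(seed=phantom_seed)
        phantom = synth.generate_phantom(spec)
        cohort = synth.generate_lesion_cohort(
            synth.CohortSpec(
                n_lesions=config.n_lesions,
                adc_effect_sd=config.adc_effect_sd,
                seed=cohort_seed,
            )
        )
        if config.save_volumes:
            for i, v in enumerate(phantom.dwi.volumes):
                save_volume(v, str(out / f"dwi_b{spec.bvalues[i]:g}.nii"))
            save_volume(phantom.suv, str(out / "suv.nii"))
            save_volume(phantom.lesion_mask, str(out / "lesion_mask.nii"))

        stage = "adc"
        if config.adc_mode == "loglinear":
            adc_map = adcmod.compute_adc_loglinear(phantom.dwi)
        else:
            adc_map = adcmod.compute_adc_two_point(phantom.dwi)
        if config.save_volumes:
            save_volume(adc_map.volume, str(out / "adc.nii"))

        stage = "resample"
        adc_pet = roimod.resample_adc(adc_map, phantom.suv.grid)

        stage = "roi_metrics"
        lesion_stats = roimod.extract_roi_stats(phantom.suv, phantom.lesion_mask, adc_pet)
        background = _background_mask(phantom)
        bg_stats = roimod.extract_roi_stats(phantom.suv, background, adc_pet)
        tbr = roimod.compute_tbr(lesion_stats, bg_stats)
        roi_rows = pd.DataFrame(
            [
                {**asdict(lesion_stats), "tbr_mean": tbr.tbr_mean, "tbr_max": tbr.tbr_max},
                {**asdict(bg_stats), "tbr_mean": np.nan, "tbr_max": np.nan},
            ]
        )
        _write_csv(roi_rows, out / "roi_metrics.csv", cfg_hash)

        stage = "filters"
        analysis_set, eligible_set = roimod.filter_lesions(
            cohort, config.min_diameter_cm, config.min_habitat_volume_ml
        )
        _write_csv(analysis_set, out / "lesions.csv", cfg_hash)
        log.info(
            "filters: %d/%d lesions in analysis set, %d habitat-eligible",
            len(analysis_set), len(cohort), len(eligible_set),
        )

        stage = "habitats"
        phantom_eligible = lesion_stats.volume_ml > config.min_habitat_volume_ml
        if phantom_eligible:
            summaries = []
            if config.habitat_method in ("twostep", "both"):
                hmap = hab.two_step_habitats(phantom.suv, adc_pet, phantom.lesion_mask)
                summaries.append(hmap.summary.assign(method="twostep"))
                if config.save_volumes:
                    save_volume(
                        ImageVolume(hmap.labels, hmap.grid), str(out / "habitats_twostep.nii")
                    )
            if config.habitat_method in ("onestep", "both"):
                cres = hab.one_step_clusters(phantom.suv, adc_pet, phantom.lesion_mask, config.k)
                summaries.append(cres.habitat_map.summary.assign(method="onestep"))
                if config.save_volumes:
                    save_volume(
                        ImageVolume(cres.habitat_map.labels, cres.habitat_map.grid),
                        str(out / "habitats_onestep.nii"),
                    )
            _write_csv(pd.concat(summaries, ignore_index=True), out / "habitat_summary.csv", cfg_hash)
        else:
            log.info(
                "habitat stage skipped: phantom lesion volume %.1f mL not > %.1f mL",
                lesion_stats.volume_ml, config.min_habitat_volume_ml,
            )

        stage = "stats"
        table = statsmod.metric_comparison_table(analysis_set)
        _write_csv(table, out / "metric_comparison.csv", cfg_hash)
        y = (analysis_set.outcome == "favorable").to_numpy().astype(int)
        fit = statsmod.logistic_fit(analysis_set["adc_mean"].to_numpy(), y, ["adc_mean"])
        roc = statsmod.roc_auc(fit.fitted_probabilities, y, config.n_boot, boot_seed)
        _write_json(
            {
                "adc_logistic": {
                    "intercept": fit.intercept,
                    "coef_adc_mean": float(fit.coefficients[0]),
                    "separation_flag": fit.separation_flag,
                },
                "adc_roc": {
                    "auc": roc.auc,
                    "ci_level": roc.ci_level,
                    "ci_lower": roc.ci_lower,
                    "ci_upper": roc.ci_upper,
                    "n_boot": roc.n_boot,
                    "seed": roc.seed,
                },
                "n_lesions_analysis_set": int(len(analysis_set)),
            },
            out / "response_stats.json",
            cfg_hash,
        )

        stage = "manifest"
        _write_json(
            {
                "seed": config.seed,
                "config": config.model_dump(),
                "stages": ["simulate", "adc", "resample", "roi_metrics", "filters",
                           "habitats" if phantom_eligible else "habitats(skipped)", "stats"],
                "files": sorted(
                    p.name for p in out.iterdir() if p.name not in ("run.log", "manifest.json")
                ),
            },
            out / "manifest.json",
            cfg_hash,
        )
        log.info("pipeline complete: %s", out)
        return out
    except Exception as e:
        log.error("stage %r failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(handler)
        handler.close()


def _background_mask(phantom: synth.Phantom) -> RoiMask:
    """A contralateral-style background box in the lesion-free corner of the PET grid."""
    shape = phantom.suv.grid.shape
    m = np.zeros(shape, dtype=bool)
    n = tuple(max(2, s // 6) for s in shape)
    m[: n[0], : n[1], : n[2]] = True
    m &= ~phantom.lesion_mask.data
    return RoiMask(m, phantom.suv.grid, "background_box", "contralateral")
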