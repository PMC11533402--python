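"""End-to-end orchestration: simulate -> segment -> phenotype -> pet-quant -> stats.

One YAML config drives the whole run; it is schema-validated (unknown keys
rejected) before any stage executes.  Each stage writes its outputs under the
run directory and the run closes with a manifest recording the config hash,
seed, package versions, per-stage row counts, and a SHA-256 checksum of every
output file — enough to audit bit-identical re-runs.  A stage failure is
recorded in the manifest with the stage name and downstream stages are
skipped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort_stats import TransformSpec, run_contrast_grid
from .io import (
    dump_yaml,
    sha256_file,
    sha256_obj,
    write_channel_tiff,
    write_csv,
    write_mask_tiff,
    write_pet_nifti,
    write_voi_niftis,
)
from .phenotyping import PhenotypeRules, quantify_field
from .petquant import suvr_table
from .plots import forest_plot
from .segmentation import ThresholdParams, detect_nuclei, marker_mask
from .simulate import (
    REGIONS,
    TIMEPOINTS,
    CohortSimParams,
    FieldSimParams,
    generate_cohort,
    generate_field,
    generate_pet_phantom,
)

logger = logging.getLogger(__name__)

_STRICT = ConfigDict(extra="forbid")


class FieldStageConfig(BaseModel):
    model_config = _STRICT
    enabled: bool = True
    n_fields_per_region: int = 1
    regions: list[str] = Field(default_factory=lambda: list(REGIONS))
    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.325
    n_nuclei: int = 40
    glial_fraction: float = 0.4
    phenotype_fraction: float = 0.5
    nucleus_radius_px: float = 8.0
    marker_overlap_target: float = 1.0
    noise_sd: float = 0.18
    glial_marker: str = "IBA1"
    phenotype_marker: str = "iNOS"
    write_images: bool = True


class SegmentationConfig(BaseModel):
    model_config = _STRICT
    radius_fraction: float = 0.05
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    nucleus_method: str = "otsu"
    min_area_um2: float = 2.0
    max_area_um2: float = 500.0
    smooth_sigma: float = 1.0
    split_touching: bool = False

    def threshold_params(self) -> ThresholdParams:
        return ThresholdParams(self.radius_fraction, self.k, self.r, self.p, self.q)


class PhenotypingConfig(BaseModel):
    model_config = _STRICT
    phenotype_overlap_threshold: float = 0.25


class PetStageConfig(BaseModel):
    model_config = _STRICT
    enabled: bool = True
    shape: list[int] = Field(default_factory=lambda: [64, 64, 48])
    noise_sd: float = 5.0
    injected_dose_kBq: float = 37000.0
    body_weight_g: float = 250.0
    write_volumes: bool = True


class CohortStageConfig(BaseModel):
    model_config = _STRICT
    enabled: bool = True
    sexes: list[str] = Field(default_factory=lambda: ["M", "F"])
    outcomes: list[str] = Field(
        default_factory=lambda: ["iba1_density", "inos_iba1_density", "gfap_density", "c3_gfap_intensity"]
    )
    n_animals_per_group: int = 6
    n_replicates: int = 3
    true_gmr: float = 2.0
    baseline_geomean: float = 1000.0
    sd_log_animal: float = 0.3
    sd_log_replicate: float = 0.15
    regions: list[str] = Field(default_factory=lambda: list(REGIONS))
    timepoints: list[int] = Field(default_factory=lambda: list(TIMEPOINTS))


class StatsConfig(BaseModel):
    model_config = _STRICT
    alpha: float = 0.05
    use_t: bool = True
    collapse: str = "by_cell"
    make_plots: bool = True


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run."""

    model_config = _STRICT
    seed: int = 0
    out_dir: str = "runs/demo"
    fields: FieldStageConfig = Field(default_factory=FieldStageConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    phenotyping: PhenotypingConfig = Field(default_factory=PhenotypingConfig)
    pet: PetStageConfig = Field(default_factory=PetStageConfig)
    cohort: CohortStageConfig = Field(default_factory=CohortStageConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .io import load_yaml

        return cls.model_validate(load_yaml(path))


def _stage_fields(config: RunConfig, out: Path, seeds: np.random.SeedSequence) -> dict:
    fc, sc, pc = config.fields, config.segmentation, config.phenotyping
    tparams = sc.threshold_params()
    rules = PhenotypeRules.for_marker(fc.glial_marker, pc.phenotype_overlap_threshold)
    img_dir = out / "fields"
    truth_rows, quant_rows, record_frames = [], [], []
    child_seeds = seeds.generate_state(len(fc.regions) * fc.n_fields_per_region)
    idx = 0
    for region in fc.regions:
        for rep in range(1, fc.n_fields_per_region + 1):
            params = FieldSimParams(
                width_px=fc.width_px,
                height_px=fc.height_px,
                pixel_size_um=fc.pixel_size_um,
                n_nuclei=fc.n_nuclei,
                glial_fraction=fc.glial_fraction,
                phenotype_fraction=fc.phenotype_fraction,
                nucleus_radius_px=fc.nucleus_radius_px,
                marker_overlap_target=fc.marker_overlap_target,
                noise_sd=fc.noise_sd,
                glial_marker=fc.glial_marker,
                phenotype_marker=fc.phenotype_marker,
                seed=int(child_seeds[idx]),
            )
            idx += 1
            dapi, glia, phen, truth = generate_field(params)
            stem = f"{region.replace(' ', '_')}_rep{rep}"
            if fc.write_images:
                img_dir.mkdir(parents=True, exist_ok=True)
                write_channel_tiff(img_dir / f"{stem}_dapi.tif", dapi)
                write_channel_tiff(img_dir / f"{stem}_{fc.glial_marker}.tif", glia)
                write_channel_tiff(img_dir / f"{stem}_{fc.phenotype_marker}.tif", phen)
            nuclei = detect_nuclei(
                dapi,
                min_area_um2=sc.min_area_um2,
                max_area_um2=sc.max_area_um2,
                method=sc.nucleus_method,
                threshold_params=tparams,
                smooth_sigma=sc.smooth_sigma,
                split_touching=sc.split_touching,
            )
            g_mask = marker_mask(glia, tparams, smooth_sigma=sc.smooth_sigma)
            p_mask = marker_mask(phen, tparams, smooth_sigma=sc.smooth_sigma)
            if fc.write_images:
                write_mask_tiff(img_dir / f"{stem}_nuclei.tif", nuclei)
            records, quant = quantify_field(
                nuclei, g_mask, p_mask, rules, fc.pixel_size_um,
                intensity_channel=phen, region=region, replicate_id=rep,
            )
            records.insert(0, "field", stem)
            record_frames.append(records)
            quant_rows.append(quant.to_dict())
            t = truth.nuclei.copy()
            t.insert(0, "field", stem)
            truth_rows.append(t)
    write_csv(out / "field_truth.csv", pd.concat(truth_rows, ignore_index=True))
    write_csv(out / "nucleus_records.csv", pd.concat(record_frames, ignore_index=True))
    quants = pd.DataFrame(quant_rows)
    write_csv(out / "field_quant.csv", quants)
    return {"n_fields": idx, "n_nuclei_detected": int(quants["n_nuclei"].sum())}


def _stage_pet(config: RunConfig, out: Path, seeds: np.random.SeedSequence) -> dict:
    pc = config.pet
    volume, vois, truth = generate_pet_phantom(
        shape=tuple(pc.shape),
        noise_sd=pc.noise_sd,
        seed=int(seeds.generate_state(1)[0]),
        injected_dose_kBq=pc.injected_dose_kBq,
        body_weight_g=pc.body_weight_g,
    )
    if pc.write_volumes:
        pet_dir = out / "pet"
        pet_dir.mkdir(parents=True, exist_ok=True)
        write_pet_nifti(pet_dir / "phantom.nii.gz", volume)
        write_voi_niftis(pet_dir / "vois", vois, volume.voxel_size_mm)
    table, ref = suvr_table(volume, vois)
    table["planted_uptake"] = table["voi"].map(truth)
    table["reference_suv_q1"] = ref
    write_csv(out / "suvr.csv", table)
    return {"n_vois": len(table), "reference_suv_q1": ref}


def _stage_cohort(config: RunConfig, out: Path, seeds: np.random.SeedSequence) -> dict:
    cc = config.cohort
    child = seeds.generate_state(len(cc.sexes) * len(cc.outcomes))
    tables = []
    i = 0
    for sex in cc.sexes:
        for outcome in cc.outcomes:
            tables.append(
                generate_cohort(
                    CohortSimParams(
                        n_animals_per_group=cc.n_animals_per_group,
                        n_replicates=cc.n_replicates,
                        true_gmr=cc.true_gmr,
                        baseline_geomean=cc.baseline_geomean,
                        sd_log_animal=cc.sd_log_animal,
                        sd_log_replicate=cc.sd_log_replicate,
                        regions=tuple(cc.regions),
                        timepoints=tuple(cc.timepoints),
                        sex=sex,
                        outcome_name=outcome,
                        seed=int(child[i]),
                    )
                )
            )
            i += 1
    table = pd.concat(tables, ignore_index=True)
    write_csv(out / "cohort.csv", table)
    return {"n_rows": len(table)}


def _stage_stats(config: RunConfig, out: Path) -> dict:
    table = pd.read_csv(out / "cohort.csv")
    st = config.stats
    results = run_contrast_grid(
        table, alpha=st.alpha, use_t=st.use_t, collapse=st.collapse
    )
    write_csv(out / "contrasts.csv", results)
    if st.make_plots:
        fig_dir = out / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        for (sex, outcome), fam in results.groupby(["sex", "outcome_name"]):
            ax = forest_plot(fam, title=f"{outcome} — {sex}")
            ax.figure.savefig(fig_dir / f"forest_{outcome}_{sex}.png", dpi=100)
            import matplotlib.pyplot as plt

            plt.close(ax.figure)
    n_sig = int(results["significant_fdr"].sum())
    return {"n_cells": len(results), "n_significant_fdr": n_sig}


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every enabled stage and write the run manifest.

    Returns the run directory.  The manifest lists the config hash, the seed,
    package versions, each stage's status and row counts, and per-file
    checksums; identical config + seed reproduce identical outputs.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.model_dump(mode="json")
    dump_yaml(out / "config.yaml", cfg_dict)
    root_seq = np.random.SeedSequence(config.seed)
    stage_seqs = dict(zip(("fields", "pet", "cohort"), root_seq.spawn(3)))

    manifest: dict = {
        "config_sha256": sha256_obj(cfg_dict),
        "seed": config.seed,
        "versions": {
            "gliaphen": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    stages = [
        ("fields", config.fields.enabled, lambda: _stage_fields(config, out, stage_seqs["fields"])),
        ("pet", config.pet.enabled, lambda: _stage_pet(config, out, stage_seqs["pet"])),
        ("cohort", config.cohort.enabled, lambda: _stage_cohort(config, out, stage_seqs["cohort"])),
        ("stats", config.cohort.enabled, lambda: _stage_stats(config, out)),
    ]
    failed = False
    for name, enabled, fn in stages:
        if not enabled:
            manifest["stages"][name] = {"status": "disabled"}
            continue
        if failed:
            manifest["stages"][name] = {"status": "skipped (upstream failure)"}
            continue
        try:
            info = fn()
            manifest["stages"][name] = {"status": "ok", **info}
            logger.info("stage %s: %s", name, info)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            logger.exception("stage %s failed", name)
            failed = True

    manifest["files"] = {
        str(p.relative_to(out)): sha256_file(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
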