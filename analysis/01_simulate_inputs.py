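#!/usr/bin/env python
"""Generate the synthetic study inputs: fluorescence fields, a PET phantom,
and cohort outcome tables with planted ground truth.

Writes image/volume data under scratch/ (binary) and the planted-truth
tables under results/.
"""

from pathlib import Path

import pandas as pd

import gliaphen as gp
from gliaphen.io import write_channel_tiff, write_csv, write_pet_nifti, write_voi_niftis

SCRATCH = Path("scratch")
RESULTS = Path("results")
SEED = 1


def main() -> None:
    truth_rows = []
    for i, region in enumerate(gp.REGIONS):
        params = gp.FieldSimParams(seed=SEED + i, noise_sd=0.18)  # SNR (fg-bg)/sd = 5
        dapi, glia, phen, truth = gp.generate_field(params)
        stem = region.replace(" ", "_")
        field_dir = SCRATCH / "fields"
        field_dir.mkdir(parents=True, exist_ok=True)
        write_channel_tiff(field_dir / f"{stem}_dapi.tif", dapi)
        write_channel_tiff(field_dir / f"{stem}_IBA1.tif", glia)
        write_channel_tiff(field_dir / f"{stem}_iNOS.tif", phen)
        t = truth.nuclei.copy()
        t.insert(0, "region", region)
        truth_rows.append(t)
        print(f"{region}: planted {truth.n_nuclei} nuclei "
              f"({truth.n_glial} glial, {truth.n_phenotype} iNOS+)")
    write_csv(RESULTS / "field_truth.csv", pd.concat(truth_rows, ignore_index=True))

    volume, vois, uptakes = gp.generate_pet_phantom(noise_sd=5.0, seed=SEED + 100)
    pet_dir = SCRATCH / "pet"
    pet_dir.mkdir(parents=True, exist_ok=True)
    write_pet_nifti(pet_dir / "phantom.nii.gz", volume)
    write_voi_niftis(pet_dir / "vois", vois, volume.voxel_size_mm)
    write_csv(RESULTS / "pet_truth.csv",
              pd.DataFrame(sorted(uptakes.items()), columns=["voi", "uptake_kBq_ml"]))
    print(f"PET phantom: {len(vois)} VOIs, cerebellar reference {uptakes['cerebellum']} kBq/ml")

    tables = []
    outcome_gmrs = [("iba1_density", 2.0), ("inos_iba1_density", 3.0),
                    ("gfap_density", 1.5), ("c3_gfap_intensity", 1.8)]
    for s, sex in enumerate(("M", "F")):
        for o, (outcome, gmr) in enumerate(outcome_gmrs):
            tables.append(gp.generate_cohort(gp.CohortSimParams(
                sex=sex, outcome_name=outcome, true_gmr=gmr,
                seed=SEED + 200 + 10 * s + o,
            )))
    cohort = pd.concat(tables, ignore_index=True)
    write_csv(SCRATCH / "cohort.csv", cohort)  # large intermediate; summaries go to results/
    print(f"cohort: {len(cohort)} rows "
          f"({cohort['animal_id'].nunique()} animals, planted GMRs 1.5-3.0)")


if __name__ == "__main__":
    main()
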