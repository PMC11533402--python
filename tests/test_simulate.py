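"""Synthetic-data generators: determinism, planted truth, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from gliaphen import (
    CohortSimParams,
    FieldSimParams,
    PlacementError,
    generate_cohort,
    generate_field,
    generate_pet_phantom,
    generate_racine_series,
)
from gliaphen.petquant import CEREBELLUM


def test_empty_field_is_pure_background():
    params = FieldSimParams(n_nuclei=0, noise_sd=0.0, seed=1)
    dapi, glia, phen, truth = generate_field(params)
    for img in (dapi, glia, phen):
        assert (img.pixels == params.background_level).all()
    assert truth.n_nuclei == truth.n_glial == truth.n_phenotype == 0


def test_planted_counts_follow_rounding_rule():
    params = FieldSimParams(n_nuclei=50, glial_fraction=0.4, phenotype_fraction=0.5, seed=2)
    assert (params.n_glial, params.n_phenotype) == (20, 10)
    _, _, _, truth = generate_field(params)
    assert (truth.n_nuclei, truth.n_glial, truth.n_phenotype) == (50, 20, 10)


def test_truth_invariants(clean_field):
    params, _, _, _, truth = clean_field
    assert truth.n_phenotype <= truth.n_glial <= truth.n_nuclei
    expected_area = params.width_px * params.height_px * params.pixel_size_um**2 * 1e-6
    assert truth.region_area_mm2 == pytest.approx(expected_area)
    # per-nucleus records consistent with counts
    assert truth.nuclei["is_glial"].sum() == truth.n_glial
    assert (truth.nuclei.loc[truth.nuclei["is_phenotype"], "is_glial"]).all()


def test_planted_marker_fully_covers_glial_nuclei(clean_field):
    """At overlap target 1.0, the glia mask covers every glial nucleus pixel."""
    _, _, _, _, truth = clean_field
    for row in truth.nuclei[truth.nuclei["is_glial"]].itertuples():
        rr, cc = np.ogrid[: truth.dapi_mask.shape[0], : truth.dapi_mask.shape[1]]
        disc = (rr - row.row) ** 2 + (cc - row.col) ** 2 <= row.radius_px**2
        assert truth.glia_mask[disc & truth.dapi_mask].all()


def test_partial_overlap_target_is_respected():
    params = FieldSimParams(seed=9, marker_overlap_target=0.6, noise_sd=0.0)
    _, _, _, truth = generate_field(params)
    from gliaphen import overlap_fraction
    from skimage.measure import label

    nuclei = label(truth.dapi_mask, connectivity=2)
    for lab in range(1, nuclei.max() + 1):
        frac = overlap_fraction(nuclei, lab, truth.glia_mask)
        assert frac == 0.0 or frac >= 0.6


def test_field_determinism():
    a = generate_field(FieldSimParams(seed=42, noise_sd=0.2))
    b = generate_field(FieldSimParams(seed=42, noise_sd=0.2))
    for x, y in zip(a[:3], b[:3]):
        np.testing.assert_array_equal(x.pixels, y.pixels)
    pd.testing.assert_frame_equal(a[3].nuclei, b[3].nuclei)


def test_placement_failure_on_overcrowded_field():
    with pytest.raises(PlacementError):
        generate_field(FieldSimParams(width_px=64, height_px=64, n_nuclei=200, seed=0))


def test_pet_phantom_planted_truth_and_validation():
    volume, vois, truth = generate_pet_phantom(noise_sd=0.0, seed=0)
    assert CEREBELLUM in vois
    # disjoint VOIs, each filled at its planted concentration
    total = np.zeros(volume.voxels.shape, int)
    for name, mask in vois.items():
        total += mask
        assert (volume.voxels[mask] == truth[name]).all()
    assert total.max() == 1
    with pytest.raises(ValueError):
        generate_pet_phantom(voi_uptake_map={"thalamus": -1.0})


def test_cohort_noise_free_ratio_exact():
    params = CohortSimParams(sd_log_animal=0.0, sd_log_replicate=0.0, true_gmr=2.0, seed=0)
    table = generate_cohort(params)
    veh = table.loc[table["exposure"] == "Veh", "value"].unique()
    dfp = table.loc[table["exposure"] == "DFP", "value"].unique()
    assert len(veh) == 1 and len(dfp) == 1
    assert dfp[0] == pytest.approx(2.0 * veh[0])


def test_cohort_determinism_and_schema():
    a = generate_cohort(CohortSimParams(seed=5))
    b = generate_cohort(CohortSimParams(seed=5))
    pd.testing.assert_frame_equal(a, b)
    assert set(a.columns) == {
        "animal_id", "sex", "exposure", "region", "dpe", "outcome_name", "value", "replicate_id",
    }
    # each animal in exactly one exposure group
    assert (a.groupby("animal_id")["exposure"].nunique() == 1).all()


def test_cohort_gmr_estimate_converges_to_one_under_null():
    """Large-n sanity: the estimated GMR concentrates near the planted 1.0."""
    from gliaphen import estimate_gmr

    params = CohortSimParams(
        n_animals_per_group=200, true_gmr=1.0, sd_log_animal=0.3,
        regions=("amygdala",), timepoints=(3,), seed=11,
    )
    res = estimate_gmr(generate_cohort(params), "M", "amygdala", 3, "glial_density")
    assert abs(np.log(res.gmr)) < 3 * res.se_log


def test_racine_series_patterns():
    const = generate_racine_series(3, duration_min=40)
    assert (const.scores == 3).all()
    zeros = generate_racine_series(0, duration_min=60)
    assert (zeros.scores == 0).all()
    alt = generate_racine_series([2, 3], duration_min=40, interval_min=5)
    assert alt.scores.mean() == pytest.approx(2.5)
    with pytest.raises(ValueError):
        generate_racine_series(3, duration_min=30)
    with pytest.raises(ValueError):
        generate_racine_series([6])


def test_param_validation():
    with pytest.raises(ValueError):
        FieldSimParams(glial_fraction=1.5)
    with pytest.raises(ValueError):
        FieldSimParams(noise_sd=-1.0)
    with pytest.raises(ValueError):
        CohortSimParams(n_replicates=5)
    with pytest.raises(ValueError):
        CohortSimParams(true_gmr=0.0)
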