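"""Log-scale GMR contrasts, Wald duality, BH-FDR, and the Racine filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gliaphen import (
    CohortSimParams,
    RacineSeries,
    TransformSpec,
    bh_fdr,
    estimate_gmr,
    generate_cohort,
    generate_racine_series,
    log_transform,
    racine_include,
    run_contrast_grid,
)
from _oracles import bh_naive


# ---------------------------------------------------------------------- log


def test_log_transform_c3_shift():
    """A zero C3 intensity with the +10 shift maps to ln 10."""
    out = log_transform([0.0], TransformSpec(shift=10.0))
    assert out[0] == pytest.approx(np.log(10.0))
    assert log_transform([1.0], TransformSpec())[0] == 0.0


def test_log_transform_round_trip():
    spec = TransformSpec(shift=10.0)
    v = np.array([0.0, 3.5, 120.0])
    np.testing.assert_allclose(np.exp(log_transform(v, spec)) - spec.shift, v, atol=1e-12)


def test_log_transform_zero_policies():
    with pytest.raises(ValueError, match=r"positions \[1\]"):
        log_transform([1.0, 0.0], TransformSpec(zero_policy="error"))
    out = log_transform([4.0, 0.0], TransformSpec(zero_policy="half_min"))
    assert out[1] == pytest.approx(np.log(2.0))  # half the minimum positive
    with pytest.raises(ValueError):
        log_transform([-1.0, 2.0], TransformSpec())


# ---------------------------------------------------------------------- GMR


def _one_cell(true_gmr, seed, sd_a=0.3, sd_r=0.15, n=8):
    params = CohortSimParams(
        n_animals_per_group=n, true_gmr=true_gmr, sd_log_animal=sd_a,
        sd_log_replicate=sd_r, regions=("amygdala",), timepoints=(3,), seed=seed,
    )
    return generate_cohort(params)


def test_identical_groups_give_unit_gmr():
    table = _one_cell(1.0, seed=0, sd_a=0.0, sd_r=0.0)
    res = estimate_gmr(table, "M", "amygdala", 3, "glial_density")
    assert res.gmr == pytest.approx(1.0)
    assert res.log_gmr == pytest.approx(0.0)


def test_noise_free_cohort_recovers_planted_gmr_exactly():
    table = _one_cell(2.0, seed=1, sd_a=0.0, sd_r=0.0)
    res = estimate_gmr(table, "M", "amygdala", 3, "glial_density")
    assert res.gmr == pytest.approx(2.0, abs=1e-12)


def test_small_group_yields_missing_result_with_reason():
    table = _one_cell(2.0, seed=2, n=2)
    table = table[~table["animal_id"].eq("M-Veh-01")]
    res = estimate_gmr(table, "M", "amygdala", 3, "glial_density")
    assert not res.ok and "fewer than 2 animals" in res.reason


def test_wald_duality_holds_cell_by_cell(rng):
    """CI excludes 1 exactly when p < alpha, for t and for normal criticals."""
    for use_t in (True, False):
        for seed in range(40):
            res = estimate_gmr(_one_cell(1.3, seed=seed), "M", "amygdala", 3,
                               "glial_density", use_t=use_t)
            excludes = res.ci_low > 1.0 or res.ci_high < 1.0
            assert excludes == (res.p_raw < 0.05) == res.significant_raw


# ---------------------------------------------------------------------- BH


def test_bh_worked_example():
    np.testing.assert_allclose(bh_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04])


def test_bh_degenerate_cases():
    assert bh_fdr([0.37])[0] == 0.37
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)  # step-up at j=m
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        q = bh_fdr(p)
        np.testing.assert_array_equal(q, bh_naive(p))  # bit-exact vs definition
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20))
def test_bh_q_monotone_in_p(p):
    q = bh_fdr(p)
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------- Racine


def test_racine_filter_boundaries():
    assert racine_include(generate_racine_series(3, duration_min=40))
    assert not racine_include(generate_racine_series(2, duration_min=40))
    # alternating 2/3 -> mean exactly 2.5 -> included (closed bound)
    assert racine_include(generate_racine_series([2, 3], duration_min=40))


def test_racine_window_not_covered_errors():
    series = RacineSeries(np.array([10.0, 20.0, 30.0]), np.array([3, 3, 3]))
    with pytest.raises(ValueError):
        racine_include(series, window_min=40)


# ---------------------------------------------------------------------- grid


def _grid_table(seed, true_gmr=1.5, regions=("CA1", "thalamus"), timepoints=(3, 7)):
    return generate_cohort(CohortSimParams(
        true_gmr=true_gmr, regions=regions, timepoints=timepoints, seed=seed,
    ))


def test_grid_shape_and_fdr_families():
    table = _grid_table(seed=3)
    res = run_contrast_grid(table)
    assert len(res) == 4  # 2 regions x 2 timepoints, one sex, one outcome
    valid = res[np.isfinite(res["gmr"])]
    assert valid["q_fdr"].notna().all()
    assert (valid["q_fdr"] >= valid["p_raw"] - 1e-15).all()


def test_grid_permutation_invariance():
    table = _grid_table(seed=4)
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = run_contrast_grid(table).reset_index(drop=True)
    b = run_contrast_grid(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_missing_cell_leaves_others_unaffected():
    table = _grid_table(seed=5)
    broken = table[~((table["region"] == "CA1") & (table["dpe"] == 3) & (table["exposure"] == "Veh"))]
    res = run_contrast_grid(broken)
    bad = res[(res["region"] == "CA1") & (res["dpe"] == 3)]
    assert not bad["gmr"].notna().any() and bad["reason"].str.len().gt(0).all()
    good = res[(res["region"] == "thalamus")]
    assert np.isfinite(good["gmr"]).all()


def test_grid_collapse_by_region_pools_timepoints():
    table = _grid_table(seed=6)
    res = run_contrast_grid(table, collapse="by_region")
    assert len(res) == 2 and (res["dpe"] == "all").all()


def test_c3_intensity_outcome_gets_shift_ten():
    from gliaphen.cohort_stats import default_transform

    assert default_transform("c3_gfap_intensity").shift == 10.0
    assert default_transform("iba1_density").shift == 0.0
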