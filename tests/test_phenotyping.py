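"""Colocalization classification, densities, and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gliaphen import (
    FieldImage,
    FieldSimParams,
    PhenotypeRules,
    aggregate_replicates,
    classify_glia,
    classify_phenotype,
    compute_density,
    detect_nuclei,
    generate_field,
    marker_mask,
    mean_intensity_on_nuclei,
    overlap_fraction,
    quantify_field,
)


def _square_nucleus(n_fg: int):
    """A 10x10 (100 px) nucleus with exactly n_fg marker-covered pixels."""
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:15, 5:15] = 1
    mask = np.zeros((20, 20), dtype=bool)
    flat = np.argwhere(labels == 1)
    mask[tuple(flat[:n_fg].T)] = True
    return labels, mask


def test_overlap_fraction_pixel_count_oracle():
    labels, mask = _square_nucleus(70)
    assert overlap_fraction(labels, 1, mask) == pytest.approx(0.70)


def test_overlap_fraction_extremes():
    labels, _ = _square_nucleus(0)
    assert overlap_fraction(labels, 1, np.ones((20, 20), bool)) == 1.0
    assert overlap_fraction(labels, 1, np.zeros((20, 20), bool)) == 0.0


def test_overlap_fraction_missing_label_errors():
    labels, mask = _square_nucleus(10)
    with pytest.raises(KeyError):
        overlap_fraction(labels, 7, mask)


@pytest.mark.parametrize(
    "marker,n_fg,expected",
    [
        ("IBA1", 70, True),   # closed bound: exactly 70% is glial
        ("IBA1", 69, False),
        ("GFAP", 40, True),   # closed bound: exactly 40% is glial
        ("GFAP", 39, False),
    ],
)
def test_glial_boundary_semantics(marker, n_fg, expected):
    labels, mask = _square_nucleus(n_fg)
    rec = classify_glia(labels, mask, PhenotypeRules.for_marker(marker))
    assert bool(rec["is_glial"].iloc[0]) is expected


def test_phenotype_mask_identical_to_glia_mask_marks_all_glia():
    labels, mask = _square_nucleus(80)
    rules = PhenotypeRules(glia_overlap_threshold=0.7, phenotype_overlap_threshold=0.7)
    rec = classify_glia(labels, mask, rules)
    rec = classify_phenotype(rec, labels, mask, rules)
    assert rec["is_phenotype_positive"].equals(rec["is_glial"])


def test_empty_phenotype_mask_gives_zero_positives():
    labels, mask = _square_nucleus(100)
    rules = PhenotypeRules.for_marker("IBA1")
    rec = classify_phenotype(classify_glia(labels, mask, rules), labels, np.zeros_like(mask), rules)
    assert rec["is_phenotype_positive"].sum() == 0


def test_exact_recovery_on_clean_field(clean_field):
    """Full planted-count recovery at zero noise and full marker coverage."""
    params, dapi, glia, phen, truth = clean_field
    nuclei = detect_nuclei(dapi)
    rules = PhenotypeRules.for_marker(params.glial_marker)
    rec = classify_glia(nuclei, marker_mask(glia), rules)
    rec = classify_phenotype(rec, nuclei, marker_mask(phen), rules)
    assert len(rec) == truth.n_nuclei
    assert rec["is_glial"].sum() == truth.n_glial
    assert rec["is_phenotype_positive"].sum() == truth.n_phenotype
    assert (rec.loc[rec["is_glial"], "glia_overlap"] == 1.0).all()


@given(thr=st.floats(min_value=0.0, max_value=1.0))
def test_raising_threshold_never_increases_counts(thr):
    params = FieldSimParams(seed=5, noise_sd=0.0, marker_overlap_target=0.8)
    dapi, glia, _, _ = generate_field(params)
    nuclei = detect_nuclei(dapi)
    mask = marker_mask(glia)
    low = classify_glia(nuclei, mask, PhenotypeRules(glia_overlap_threshold=thr))
    high = classify_glia(nuclei, mask, PhenotypeRules(glia_overlap_threshold=min(1.0, thr + 0.1)))
    assert high["is_glial"].sum() <= low["is_glial"].sum()


def test_counts_conserved_for_every_field(clean_field):
    params, dapi, glia, phen, _ = clean_field
    nuclei = detect_nuclei(dapi)
    rules = PhenotypeRules.for_marker(params.glial_marker)
    _, quant = quantify_field(nuclei, marker_mask(glia), marker_mask(phen), rules, params.pixel_size_um)
    assert quant.n_phenotype <= quant.n_glial <= quant.n_nuclei


def test_mean_intensity_arithmetic_and_missing():
    labels, mask = _square_nucleus(100)
    rules = PhenotypeRules.for_marker("IBA1")
    rec = classify_glia(labels, mask, rules)
    channel = np.zeros((20, 20))
    channel[5:15, 5:15] = 5.0  # mean over nucleus = 5
    rec, field_mean = mean_intensity_on_nuclei(rec, labels, FieldImage(channel, 1.0, "C3"))
    assert rec["mean_marker_intensity"].iloc[0] == pytest.approx(5.0)
    assert field_mean == pytest.approx(5.0)
    # no glial nuclei -> missing, not zero
    rec_none = classify_glia(labels, np.zeros_like(mask), rules)
    _, fm = mean_intensity_on_nuclei(rec_none, labels, FieldImage(channel, 1.0, "C3"))
    assert np.isnan(fm)


def test_mean_intensity_four_pixel_oracle():
    labels = np.zeros((2, 2), dtype=np.int32)
    labels[:] = 1
    channel = FieldImage(np.array([[0.0, 0.0], [10.0, 10.0]]), 1.0, "C3")
    rec = classify_glia(labels, np.ones((2, 2), bool), PhenotypeRules())
    rec, _ = mean_intensity_on_nuclei(rec, labels, channel)
    assert rec["mean_marker_intensity"].iloc[0] == pytest.approx(5.0)


def test_density_arithmetic():
    assert compute_density(50, 2.0) == 25.0
    assert compute_density(0, 2.0) == 0.0
    assert compute_density(10, 1.0) == 2 * compute_density(10, 2.0)
    with pytest.raises(ValueError):
        compute_density(1, 0.0)


def test_density_scales_with_pixel_size(clean_field):
    """Halving the pixel size quarters the area, quadrupling the density."""
    params, dapi, glia, phen, _ = clean_field
    nuclei = detect_nuclei(dapi)
    rules = PhenotypeRules.for_marker(params.glial_marker)
    gm, pm = marker_mask(glia), marker_mask(phen)
    _, q1 = quantify_field(nuclei, gm, pm, rules, 0.325)
    _, q2 = quantify_field(nuclei, gm, pm, rules, 0.650)
    assert q1.glial_density == pytest.approx(4.0 * q2.glial_density)


def test_aggregate_replicates_mean_and_symmetry():
    df = pd.DataFrame(
        {"animal_id": ["a1"] * 2, "region": ["CA1"] * 2, "glial_density": [10.0, 20.0]}
    )
    out = aggregate_replicates(df)
    assert out["value"] == 15.0 and out["n_replicates"] == 2
    shuffled = aggregate_replicates(df.iloc[::-1])
    assert shuffled["value"] == out["value"]
    single = aggregate_replicates(df.iloc[:1])
    assert single["value"] == 10.0
    with pytest.raises(ValueError):
        aggregate_replicates(pd.DataFrame({"animal_id": ["a1", "a2"], "region": ["CA1"] * 2, "glial_density": [1.0, 2.0]}))
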