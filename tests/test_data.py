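import numpy as np
import pandas as pd
import pytest

from poolfish import data as pfd
from poolfish.data import (SurveyDataError, binarize_catch, detection_events,
                           filter_rare_species, load_survey, scale_covariates,
                           write_survey)


def toy_tables(tmp_path, catch_rows):
    """Write a minimal two-species / two-pool survey to disk."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    (tmp_path / "species.csv").write_text(
        "species_id,mean_length\nA,50\nB,300\n")
    (tmp_path / "pools.csv").write_text(
        "pool_id,mesohabitat,max_depth,turbidity,complexity,river_km,conductivity\n"
        "P1,0,1.2,5,20,10,300\nP2,1,4.8,50,60,200,800\n")
    (tmp_path / "visits.csv").write_text(
        "visit_id,pool_id,year\nV1,P1,2018\nV2,P2,2019\n")
    (tmp_path / "samples.csv").write_text(
        "sample_id,visit_id,gear,effort_raw,sample_depth,sample_complexity,seine_variant\n"
        "S1,V1,backpack_EF,120,0.8,15,none\n"
        "S2,V1,seine_LM,20,1.0,25,seine5m\n"
        "S3,V2,boat_EF,600,2.5,55,none\n"
        "S4,V2,seine_SM,35,1.5,,none\n")
    (tmp_path / "catch.csv").write_text(
        "species_id,sample_id,count\n" + "\n".join(catch_rows) + "\n")
    return tmp_path


def test_load_validate_roundtrip(tmp_path):
    path = toy_tables(tmp_path / "in", ["A,S1,3", "A,S3,1", "B,S3,37"])
    (tmp_path / "in").mkdir(exist_ok=True)
    ds = load_survey(str(path))
    assert (ds.n_species, ds.n_pools, ds.n_visits, ds.n_samples) == (2, 2, 2, 4)
    # counts >= 1 become detections, elementwise
    y, vis = ds.detections.flat()
    assert y.sum() == 3
    # missing sample complexity imputed from the pool, flagged
    s4 = ds.samples.set_index("sample_id").loc["S4"]
    assert s4["complexity_imputed"] and s4["sample_complexity"] == 60
    out = tmp_path / "out"
    write_survey(ds, str(out))
    ds2 = load_survey(str(out))
    for tab in ("species", "pools", "visits"):
        pd.testing.assert_frame_equal(
            getattr(ds, tab).reset_index(drop=True),
            getattr(ds2, tab).reset_index(drop=True), check_dtype=False)
    assert np.array_equal(ds.detections.y, ds2.detections.y)


@pytest.mark.parametrize("mutation, message", [
    (lambda p: (p / "samples.csv").write_text(
        "sample_id,visit_id,gear,effort_raw,sample_depth,sample_complexity,seine_variant\n"
        "S1,V9,backpack_EF,120,0.8,15,none\n"), "orphan"),
    (lambda p: (p / "catch.csv").write_text(
        "species_id,sample_id,count\nA,S1,-2\n"), "negative"),
    (lambda p: (p / "samples.csv").write_text(
        "sample_id,visit_id,gear,effort_raw,sample_depth,sample_complexity,seine_variant\n"
        "S1,V1,backpack_EF,0,0.8,15,none\nS3,V2,boat_EF,600,2.5,55,none\n"),
     "effort"),
    (lambda p: (p / "species.csv").write_text("species_id\nA\nB\n"),
     "missing column"),
])
def test_load_rejects_malformed(tmp_path, mutation, message):
    path = toy_tables(tmp_path, ["A,S1,1"])
    mutation(path)
    with pytest.raises(SurveyDataError, match=message):
        load_survey(str(path))


def test_binarize_catch_elementwise():
    counts = np.array([[[0, 3], [1, 0]], [[37, 0], [0, 2]]])
    da = binarize_catch(counts)
    assert np.array_equal(da.y, (counts >= 1).astype(int))
    with pytest.raises(SurveyDataError, match="negative"):
        binarize_catch(np.array([[-1]]))


def test_rare_species_filter_rule(tiny_dataset):
    # build detections by hand: species 0 at 3 visits, species 1 at 2 visits
    ds = tiny_dataset
    y = np.zeros_like(ds.detections.y)
    mask = ds.detections.mask
    y[0, 0, 0] = y[0, 1, 0] = y[0, 2, 0] = 1
    y[1, 0, 0] = y[1, 1, 1] = 1
    ds2 = pfd.SurveyDataset(
        species=ds.species, pools=ds.pools, visits=ds.visits,
        samples=ds.samples, detections=pfd.DetectionArray(y=y, mask=mask),
        scaling=ds.scaling)
    assert list(detection_events(ds2)) == [3, 2]
    kept, removed = filter_rare_species(ds2, min_events=3)
    assert kept.n_species == 1 and removed == [ds.species["species_id"][1]]
    # idempotent
    again, removed2 = filter_rare_species(kept, min_events=3)
    assert removed2 == [] and again.n_species == 1
    with pytest.raises(ValueError):
        filter_rare_species(ds2, min_events=0)


def test_filter_empty_dataset_is_noop(tiny_dataset):
    ds = tiny_dataset
    empty = pfd.SurveyDataset(
        species=ds.species.iloc[:0], pools=ds.pools, visits=ds.visits,
        samples=ds.samples,
        detections=pfd.DetectionArray(
            y=ds.detections.y[:0], mask=ds.detections.mask))
    out, removed = filter_rare_species(empty)
    assert out.n_species == 0 and removed == []


def test_scaling_conventions(tmp_path):
    path = toy_tables(tmp_path, ["A,S1,1"])
    ds = scale_covariates(load_survey(str(path)))
    # pool depths {1.2, 4.8} -> {0.25, 1.0}
    assert np.allclose(ds.pools["depth_scaled"], [0.25, 1.0])
    # standardized covariates: mean 0, population SD 1
    for col in ("turbidity_std", "complexity_std", "river_km_std",
                "conductivity_std"):
        v = ds.pools[col].to_numpy()
        assert abs(v.mean()) < 1e-9 and abs(v.std() - 1) < 1e-9
    v = ds.species["length_std"].to_numpy()
    assert abs(v.mean()) < 1e-9 and abs(v.std() - 1) < 1e-9
    # effort scaled per gear to (0, 1]
    for g, grp in ds.samples.groupby("gear"):
        assert np.isclose(grp["effort_scaled"].max(), 1.0)
    assert ((ds.samples["effort_scaled"] > 0)
            & (ds.samples["effort_scaled"] <= 1)).all()
    # inverse transform recovers raw values
    info = ds.scaling
    raw = info.unstandardize("turbidity", ds.pools["turbidity_std"])
    assert np.allclose(raw, ds.pools["turbidity"], atol=1e-12)
    assert np.allclose(info.scale_depth(ds.pools["max_depth"]) * info.depth_divisor,
                       ds.pools["max_depth"], atol=1e-12)


def test_effort_scaling_example():
    efforts = np.array([60.0, 120.0, 240.0])
    assert np.allclose(efforts / efforts.max(), [0.25, 0.5, 1.0])


def test_zero_variance_covariate_rejected(tmp_path):
    path = toy_tables(tmp_path, ["A,S1,1"])
    (path / "pools.csv").write_text(
        "pool_id,mesohabitat,max_depth,turbidity,complexity,river_km,conductivity\n"
        "P1,0,1.2,5,20,10,300\nP2,1,4.8,5,60,200,800\n")
    with pytest.raises(SurveyDataError, match="zero-variance"):
        scale_covariates(load_survey(str(path)))


def test_generated_surveys_pass_validation(small_dataset):
    # simulate() output re-validates unchanged and is fully scaled
    small_dataset.validate()
    assert small_dataset.is_scaled
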