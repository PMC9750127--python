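"""Experiment container: union assembly, subsetting, aggregation, round-trip."""

import numpy as np
import pandas as pd
import pytest

from lipidomics.containers import (
    ExperimentError,
    SampleRecord,
    aggregate_technical_replicates,
    build_experiment,
    load_experiment,
    log2_transform,
    save_experiment,
    subset,
)

from conftest import make_experiment, make_table


def test_build_union_semantics():
    exp = make_experiment(
        {
            "A": [("PC(34:1)", "PC", 34, 1, 12.0, 10.0), ("PC(36:2)", "PC", 36, 2, 12.5, 20.0)],
            "B": [("PC(36:2)", "PC", 36, 2, 12.5, 30.0), ("PE(36:2)", "PE", 36, 2, 10.0, 40.0)],
        }
    )
    assert exp.assay.shape == (3, 2)
    assert np.isnan(exp.assay.at["PC(34:1)", "B"])
    assert np.isnan(exp.assay.at["PE(36:2)", "A"])
    assert exp.assay.at["PC(36:2)", "B"] == 30.0


def test_build_identical_lipid_sets_no_missing():
    exp = make_experiment(
        {
            "A": [("PC(34:1)", "PC", 34, 1, 12.0, 1.0)],
            "B": [("PC(34:1)", "PC", 34, 1, 12.0, 2.0)],
        }
    )
    assert not exp.assay.isna().any().any()


def test_build_errors():
    table = {"A.tsv": make_table([("PC(34:1)", "PC", 34, 1, 12.0, 1.0)])}
    with pytest.raises(ExperimentError, match="empty target"):
        build_experiment(table, [])
    with pytest.raises(ExperimentError, match="no matching"):
        build_experiment(table, [SampleRecord("X", "missing.tsv")])
    dup = [SampleRecord("X", "A.tsv"), SampleRecord("X", "A.tsv")]
    with pytest.raises(ExperimentError, match="duplicate sample_id"):
        build_experiment(table, dup)


def test_median_rt_stored_as_consensus():
    exp = make_experiment(
        {
            "A": [("PC(34:1)", "PC", 34, 1, 12.0, 1.0)],
            "B": [("PC(34:1)", "PC", 34, 1, 13.0, 2.0)],
            "C": [("PC(34:1)", "PC", 34, 1, 12.2, 3.0)],
        }
    )
    assert exp.lipids.at["PC(34:1)", "retention_time_min"] == pytest.approx(12.2)
    assert exp.lipids.at["PC(34:1)", "retention_time_spread_min"] == pytest.approx(1.0)


def test_subset_by_class_and_identity(mixed_experiment):
    sub = subset(mixed_experiment, lipid_predicate=lambda r: r["lipid_class"] == "PC")
    assert set(sub.lipids["lipid_class"]) == {"PC"}
    assert sub.n_samples == mixed_experiment.n_samples

    same = subset(mixed_experiment, lambda r: True, lambda r: True)
    pd.testing.assert_frame_equal(same.assay, mixed_experiment.assay)
    assert len(same.provenance) == len(mixed_experiment.provenance) + 1

    with pytest.raises(ExperimentError, match="every lipid"):
        subset(mixed_experiment, lipid_predicate=lambda r: False)


def test_operations_do_not_mutate_input(mixed_experiment):
    before = mixed_experiment.assay.copy()
    n_prov = len(mixed_experiment.provenance)
    subset(mixed_experiment, lipid_predicate=lambda r: r["lipid_class"] == "PC")
    log2_transform(mixed_experiment)
    pd.testing.assert_frame_equal(mixed_experiment.assay, before)
    assert len(mixed_experiment.provenance) == n_prov


def test_every_transform_appends_one_provenance_record(mixed_experiment):
    n = len(mixed_experiment.provenance)
    e1 = subset(mixed_experiment, lambda r: True)
    assert len(e1.provenance) == n + 1
    e2 = log2_transform(e1)
    assert len(e2.provenance) == n + 2


def test_aggregate_technical_replicates():
    per_sample = {
        "T1": [("PC(34:1)", "PC", 34, 1, 12.0, 2.0)],
        "T2": [("PC(34:1)", "PC", 34, 1, 12.0, 4.0)],
        "B1": [("PC(34:1)", "PC", 34, 1, 12.0, 9.0)],
    }
    factors = {"T1": {"condition": "A"}, "T2": {"condition": "A"}, "B1": {"condition": "B"}}
    roles = {"T1": "technical", "T2": "technical"}
    exp = make_experiment(per_sample, factors=factors, roles=roles)
    agg = aggregate_technical_replicates(exp, method="mean")
    assert agg.n_samples == 2
    assert agg.assay.at["PC(34:1)", "T1"] == pytest.approx(3.0)
    assert agg.assay.at["PC(34:1)", "B1"] == pytest.approx(9.0)


def test_aggregate_ignores_missing_unless_all_missing():
    per_sample = {
        "T1": [("PC(34:1)", "PC", 34, 1, 12.0, 2.0)],
        "T2": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
    }
    roles = {"T1": "technical", "T2": "technical"}
    factors = {"T1": {"condition": "A"}, "T2": {"condition": "A"}}
    exp = make_experiment(per_sample, factors=factors, roles=roles)
    agg = aggregate_technical_replicates(exp)
    # (2.0, missing) -> 2.0 ; PE present only in T2 -> 5.0
    assert agg.assay.at["PC(34:1)", "T1"] == pytest.approx(2.0)
    assert agg.assay.at["PE(36:2)", "T1"] == pytest.approx(5.0)


def test_log2_requires_positive_values():
    exp = make_experiment({"A": [("PC(34:1)", "PC", 34, 1, 12.0, 0.0)]})
    with pytest.raises(ExperimentError, match="strictly positive"):
        log2_transform(exp)


def test_assay_kind_transitions_guarded(mixed_experiment):
    exp = log2_transform(mixed_experiment)
    assert exp.assay_kind == "log2"
    with pytest.raises(ExperimentError, match="illegal assay kind"):
        exp.set_kind("raw_area")


def test_save_load_roundtrip(tmp_path, mixed_experiment):
    exp = mixed_experiment
    exp.assay.iat[0, 1] = np.nan  # missingness must survive
    save_experiment(exp, tmp_path / "exp")
    back = load_experiment(tmp_path / "exp")
    pd.testing.assert_frame_equal(back.assay, exp.assay)
    assert back.assay_kind == exp.assay_kind
    assert back.provenance == exp.provenance
    assert list(back.samples["condition"]) == list(exp.samples["condition"])
    assert np.isnan(back.assay.iat[0, 1])


def test_load_missing_or_corrupt(tmp_path):
    with pytest.raises(ExperimentError, match="not found"):
        load_experiment(tmp_path / "nope")
    d = tmp_path / "broken"
    d.mkdir()
    (d / "assay.tsv").write_text("lipid\tS1\nPC(34:1)\t1.0\n")
    with pytest.raises(ExperimentError, match="missing"):
        load_experiment(d)
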