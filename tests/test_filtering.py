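"""Reference-bound filtering, duplicate resolution, missingness filtering."""

import numpy as np
import pytest

from lipidomics.containers import ExperimentError
from lipidomics.filtering import (
    RULE_ORDER,
    FilterPolicy,
    deduplicate_lipids,
    filter_by_reference,
    filter_missingness,
)
from lipidomics.io_formats import InternalReferenceEntry

from conftest import make_experiment, make_table
from lipidomics.containers import SampleRecord, build_experiment

PC_REF = InternalReferenceEntry(
    lipid_class="PC", rt_min=10, rt_max=14, carbons_min=28, carbons_max=44,
    double_bonds_min=0, double_bonds_max=8, allow_odd_chains=False,
)
PE_REF = InternalReferenceEntry(
    lipid_class="PE", rt_min=9, rt_max=13, carbons_min=28, carbons_max=44,
    double_bonds_min=0, double_bonds_max=8, allow_odd_chains=False,
)


def five_lipid_experiment():
    rows = [
        ("PC(34:1)", "PC", 34, 1, 12.0, 10.0),   # in bounds
        ("PC(36:2)", "PC", 36, 2, 20.0, 10.0),   # rt out
        ("PC(50:2)", "PC", 50, 2, 12.0, 10.0),   # carbons out
        ("PC(34:9)", "PC", 34, 9, 12.0, 10.0),   # double bonds out
        ("PC(35:1)", "PC", 35, 1, 12.0, 10.0),   # odd chain
    ]
    return make_experiment({"A": rows, "B": rows})


def test_each_rule_removes_its_lipid_and_conserves_counts():
    exp = five_lipid_experiment()
    out, report = filter_by_reference(exp, [PC_REF])
    assert out.n_lipids == 1
    assert report.counts == {
        "rt_window": 1, "carbon_bounds": 1, "double_bond_bounds": 1, "odd_chain": 1
    }
    assert report.n_removed + report.n_retained == report.n_input


def test_first_violated_rule_wins_attribution():
    # rt out AND odd chain: must be attributed to rt_window (first in order)
    rows = [
        ("PC(35:1)", "PC", 35, 1, 20.0, 10.0),
        ("PC(34:1)", "PC", 34, 1, 12.0, 10.0),
    ]
    exp = make_experiment({"A": rows})
    _, report = filter_by_reference(exp, [PC_REF])
    assert report.counts == {"rt_window": 1}
    assert report.records[0]["rule"] == RULE_ORDER[0]


def test_all_in_bounds_is_identity_with_empty_report():
    rows = [("PC(34:1)", "PC", 34, 1, 12.0, 10.0)]
    exp = make_experiment({"A": rows})
    out, report = filter_by_reference(exp, [PC_REF])
    assert out.n_lipids == exp.n_lipids
    assert report.n_removed == 0


def test_odd_chain_removed_when_disallowed():
    rows = [("PC(17:0/18:1)", "PC", 35, 1, 12.0, 10.0),
            ("PC(16:0/18:1)", "PC", 34, 1, 12.0, 10.0)]
    exp = make_experiment({"A": rows})
    out, report = filter_by_reference(exp, [PC_REF])
    assert report.counts == {"odd_chain": 1}
    assert "PC(17:0/18:1)" not in out.assay.index


def test_unlisted_class_policies():
    rows = [("PE(36:2)", "PE", 36, 2, 10.5, 10.0),
            ("PC(34:1)", "PC", 34, 1, 12.0, 10.0)]
    exp = make_experiment({"A": rows})
    with pytest.warns(UserWarning, match="without reference entry"):
        out, _ = filter_by_reference(exp, [PC_REF])
    assert out.n_lipids == 2
    out2, rep2 = filter_by_reference(exp, [PC_REF], FilterPolicy(unlisted_class="drop"))
    assert out2.n_lipids == 1
    assert rep2.counts == {"unlisted_class": 1}


def test_internal_standards_exempt_from_reference_bounds():
    tables = {"A.tsv": make_table([
        ("PC(14:0/14:0)", "PC", 28, 0, 5.0, 10.0),  # rt far outside window
        ("PC(34:1)", "PC", 34, 1, 12.0, 10.0),
    ])}
    targets = [SampleRecord("A", "A.tsv")]
    exp = build_experiment(tables, targets, internal_standard_names=["PC(14:0/14:0)"])
    out, report = filter_by_reference(exp, [PC_REF])
    assert "PC(14:0/14:0)" in out.assay.index
    assert report.n_removed == 0


def test_filtering_idempotent():
    exp = five_lipid_experiment()
    once, _ = filter_by_reference(exp, [PC_REF])
    twice, rep = filter_by_reference(once, [PC_REF])
    assert list(twice.assay.index) == list(once.assay.index)
    assert rep.n_removed == 0


def test_deduplicate_keep_max_area():
    tables = {"A.tsv": make_table([
        ("PC(34:1)", "PC", 34, 1, 12.0, 100.0),
        ("PC(34:1)", "PC", 34, 1, 12.4, 60.0),
    ])}
    exp = build_experiment(tables, [SampleRecord("A", "A.tsv")])
    assert exp.n_lipids == 2
    out, report = deduplicate_lipids(exp, "keep_max_area")
    assert out.n_lipids == 1
    assert out.assay.iloc[0, 0] == 100.0
    assert report.counts == {"duplicate": 1}
    assert report.n_removed + report.n_retained == report.n_input


def test_deduplicate_merge_sum():
    tables = {"A.tsv": make_table([
        ("PC(34:1)", "PC", 34, 1, 12.0, 100.0),
        ("PC(34:1)", "PC", 34, 1, 12.4, 60.0),
    ])}
    exp = build_experiment(tables, [SampleRecord("A", "A.tsv")])
    out, _ = deduplicate_lipids(exp, "merge_sum")
    assert out.assay.iloc[0, 0] == pytest.approx(160.0)


def test_deduplicate_no_duplicates_identity(mixed_experiment):
    out, report = deduplicate_lipids(mixed_experiment)
    assert report.n_removed == 0
    assert list(out.assay.index) == list(mixed_experiment.assay.index)


@pytest.mark.parametrize(
    "threshold, expect_removed",
    [(0.5, True), (1.0, False), (0.0, True)],
)
def test_missingness_thresholds(threshold, expect_removed):
    # lipid missing in 3 of 4 samples (fraction 0.75)
    per_sample = {
        "S1": [("PC(34:1)", "PC", 34, 1, 12.0, 5.0), ("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S2": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S3": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S4": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
    }
    exp = make_experiment(per_sample)
    out, report = filter_missingness(exp, threshold)
    assert ("PC(34:1)" not in out.assay.index) is expect_removed
    assert report.n_removed + report.n_retained == report.n_input


def test_missingness_per_group_keeps_group_specific_lipids():
    # lipid fully observed in group A, fully missing in group B
    per_sample = {
        "S1": [("PC(34:1)", "PC", 34, 1, 12.0, 5.0), ("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S2": [("PC(34:1)", "PC", 34, 1, 12.0, 5.0), ("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S3": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
        "S4": [("PE(36:2)", "PE", 36, 2, 10.0, 5.0)],
    }
    factors = {s: {"condition": "A" if s in ("S1", "S2") else "B"} for s in per_sample}
    exp = make_experiment(per_sample, factors=factors)
    overall, _ = filter_missingness(exp, 0.3, scope="overall")
    assert "PC(34:1)" not in overall.assay.index
    grouped, _ = filter_missingness(exp, 0.3, scope="per_group", group_factor="condition")
    assert "PC(34:1)" in grouped.assay.index


def test_missingness_errors():
    exp = five_lipid_experiment()
    with pytest.raises(ExperimentError, match="group_factor"):
        filter_missingness(exp, 0.5, scope="per_group")
    with pytest.raises(ExperimentError, match="0, 1"):
        filter_missingness(exp, 1.5)
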