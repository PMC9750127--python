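"""Moderated differential testing, batch handling, BH, set enrichment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidomics.differential import (
    DesignSpec,
    DifferentialError,
    bh_adjust,
    build_lipid_sets,
    enrich_lipid_sets,
    fit_differential,
    ma_volcano_tables,
    remove_batch,
    squeeze_variances,
)
from lipidomics.synthetic import simulate_annotation, simulate_log2_experiment


def test_prior_df_zero_equals_classical_two_sample_t():
    exp, _ = simulate_log2_experiment(25, 10, seed=1)
    diff = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1")), prior_df=0)
    Y = exp.assay.to_numpy()
    g = (exp.samples["condition"] == "G2").to_numpy()
    classic = np.array(
        [stats.ttest_ind(Y[i, g], Y[i, ~g], equal_var=True).statistic for i in range(25)]
    )
    assert np.allclose(diff["moderated_t"].to_numpy(), classic, atol=1e-10)


def test_two_group_log2fc_is_difference_of_means():
    exp, _ = simulate_log2_experiment(1, 4, seed=2)
    exp.assay.iloc[0] = [1.0, 1.0, 3.0, 3.0]  # G1: 1,1  G2: 3,3
    diff = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1")), prior_df=0)
    assert diff["log2_fold_change"].iloc[0] == pytest.approx(2.0)


def test_moderated_t_matches_limma_reference():
    """Cross-validation against the Bioconductor limma implementation."""
    exp, _ = simulate_log2_experiment(40, 10, n_effects=4, seed=11)
    diff = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1")))
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        exp.assay.to_csv(f"{d}/y.csv")
        exp.samples[["condition"]].to_csv(f"{d}/g.csv")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv("{d}/y.csv", row.names=1))
            g <- read.csv("{d}/g.csv", row.names=1)$condition
            design <- model.matrix(~0+factor(g))
            colnames(design) <- levels(factor(g))
            fit <- lmFit(y, design)
            fit <- contrasts.fit(fit, makeContrasts(G2-G1, levels=design))
            fit <- eBayes(fit)
            write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior),
                      "{d}/ref.csv")
            """
        )
        with open(f"{d}/run.R", "w") as fh:
            fh.write(script)
        proc = subprocess.run(
            ["Rscript", f"{d}/run.R"], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[:200]}")
        ref = pd.read_csv(f"{d}/ref.csv", index_col=0)
    assert np.allclose(diff["moderated_t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
    assert diff["df_prior"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)


def test_variance_moderation_shrinks_dispersion():
    exp, _ = simulate_log2_experiment(300, 8, seed=3)
    Y = exp.assay.to_numpy()
    g = (exp.samples["condition"] == "G2").to_numpy()
    resid_var = np.array(
        [
            (Y[i, g].var(ddof=1) * (g.sum() - 1) + Y[i, ~g].var(ddof=1) * ((~g).sum() - 1))
            / (len(g) - 2)
            for i in range(Y.shape[0])
        ]
    )
    post, d0, s0 = squeeze_variances(resid_var, len(g) - 2)
    assert d0 > 0
    assert np.var(post) < np.var(resid_var)


def test_batch_covariate_equals_remove_then_test_on_orthogonal_design():
    exp, _ = simulate_log2_experiment(
        60, 12, n_effects=6, seed=4, n_batches=2, batch_log2_shift=0.8
    )
    d_cov = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1"), "covariate"))
    d_rm = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1"), "remove_first"))
    assert np.allclose(
        d_cov["log2_fold_change"].to_numpy(),
        d_rm["log2_fold_change"].to_numpy(),
        atol=1e-8,
    )


def test_remove_batch_centers_batches_and_keeps_orthogonal_effects():
    exp, eff = simulate_log2_experiment(
        40, 12, n_effects=4, seed=5, n_batches=2, batch_log2_shift=1.0
    )
    out = remove_batch(exp)
    batches = out.samples["batch"]
    m1 = out.assay.loc[:, (batches == "B1").to_numpy()].mean(axis=1)
    m2 = out.assay.loc[:, (batches == "B2").to_numpy()].mean(axis=1)
    assert float((m1 - m2).abs().max()) < 1e-10
    # condition effect estimate unchanged by removal (orthogonal design)
    d_before = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1"), "covariate"))
    d_after = fit_differential(out, DesignSpec(("condition",), ("G2", "G1")))
    assert np.allclose(
        d_before["log2_fold_change"], d_after["log2_fold_change"], atol=1e-8
    )


def test_remove_batch_single_batch_identity():
    exp, _ = simulate_log2_experiment(10, 6, seed=6, n_batches=1)
    out = remove_batch(exp)
    pd.testing.assert_frame_equal(out.assay, exp.assay)


def test_confounded_batch_raises_naming_columns():
    exp, _ = simulate_log2_experiment(10, 8, seed=7, n_batches=1)
    # batch == condition -> aliased
    exp.samples["batch"] = np.where(exp.samples["condition"] == "G1", "B1", "B2")
    with pytest.raises(DifferentialError, match="aliased"):
        fit_differential(exp, DesignSpec(("condition",), ("G2", "G1"), "covariate"))


def test_bh_adjust_step_up_oracle():
    """Hand-executed step-up: (0.01,0.02,0.03,0.04) -> all 0.04."""
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    assert np.allclose(bh_adjust([0.7]), [0.7])
    sorted_p = np.sort(np.random.default_rng(0).uniform(size=50))
    adj = bh_adjust(sorted_p)
    assert np.all(np.diff(adj) >= -1e-15)
    assert np.all(adj >= sorted_p)
    assert np.all(adj <= 1.0)
    with pytest.raises(DifferentialError):
        bh_adjust([0.5, 1.5])


def test_enrichment_hypergeometric_oracle():
    """10-lipid set with 5 hits among 100 lipids / 10 significant."""
    ann = simulate_annotation(100, n_classes=10, seed=8)
    # construct significance so the first class (10 lipids) holds 5 of 10 hits
    first_class = ann.index[ann["lipid_class"] == "PC"]
    others = ann.index[ann["lipid_class"] != "PC"]
    sig = first_class[:5].append(others[:5])
    diff = pd.DataFrame({"adjusted_p": 1.0}, index=ann.index)
    res = enrich_lipid_sets(diff, ann, significant=sig)
    expected = stats.hypergeom.sf(4, 100, 10, 10)
    assert res.loc["class:PC", "p_value"] == pytest.approx(expected)
    assert res.loc["class:PC", "overlap"] == 5


def test_enrichment_set_equal_to_significant_is_extreme():
    ann = simulate_annotation(80, n_classes=4, seed=9)
    sig = ann.index[ann["lipid_class"] == "PC"]
    diff = pd.DataFrame({"adjusted_p": 1.0}, index=ann.index)
    res = enrich_lipid_sets(diff, ann, significant=sig)
    assert np.isinf(res.loc["class:PC", "odds_ratio"])
    assert res.loc["class:PC", "p_value"] == res["p_value"].min()


def test_enrichment_no_significant_gives_empty_with_notice():
    ann = simulate_annotation(20, seed=10)
    diff = pd.DataFrame({"adjusted_p": 1.0}, index=ann.index)
    with pytest.warns(UserWarning, match="no significant"):
        res = enrich_lipid_sets(diff, ann)
    assert res.empty


def test_build_lipid_sets_partitions_each_family():
    ann = simulate_annotation(160, seed=11)
    sets = build_lipid_sets(ann)
    for family in ("class:", "chain:", "db:"):
        members = [s for k, s in sets.items() if k.startswith(family)]
        total = sum(len(m) for m in members)
        assert total == len(ann)


def test_ma_volcano_conventions():
    exp, _ = simulate_log2_experiment(30, 8, seed=12)
    diff = fit_differential(exp, DesignSpec(("condition",), ("G2", "G1")))
    diff.loc[diff.index[0], "adjusted_p"] = 0.05  # exactly alpha
    diff.loc[diff.index[1], "adjusted_p"] = 1.0
    ma, volcano = ma_volcano_tables(diff, alpha=0.05)
    assert len(ma) == len(diff) and len(volcano) == len(diff)
    assert not ma["significant"].iloc[0]  # strict inequality at the boundary
    assert volcano["neg_log10_adjusted_p"].iloc[1] == 0.0


def test_contrast_level_validation():
    exp, _ = simulate_log2_experiment(10, 8, seed=13)
    with pytest.raises(DifferentialError, match="not found"):
        fit_differential(exp, DesignSpec(("condition",), ("G9", "G1")))
    with pytest.raises(DifferentialError, match="distinct"):
        DesignSpec(("condition",), ("G1", "G1"))
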