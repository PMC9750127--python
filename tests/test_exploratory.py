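"""Ordination and summary profiles: PCA identities, PLS-DA separation."""

import numpy as np
import pandas as pd
import pytest

from lipidomics.containers import ExperimentError, log2_transform
from lipidomics.exploratory import (
    hierarchical_order,
    run_pca,
    run_plsda,
    summary_profiles,
)
from lipidomics.synthetic import simulate_log2_experiment

from conftest import make_experiment


def test_pca_rank_one_data_explains_everything():
    exp, _ = simulate_log2_experiment(6, 8, seed=1)
    direction = np.arange(6, dtype=float)
    t = np.linspace(-1, 1, 8)
    exp.assay.iloc[:, :] = 5.0 + np.outer(direction, t)
    res = run_pca(exp, n_components=2, scale=False)
    assert res.explained_variance[0] == pytest.approx(1.0)


def test_pca_duplicated_sample_gives_identical_scores():
    exp, _ = simulate_log2_experiment(10, 6, seed=2)
    exp.assay.iloc[:, 1] = exp.assay.iloc[:, 0]
    res = run_pca(exp, 2, scale=False)
    assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])


def test_pca_full_rank_reconstruction():
    """scores @ loadings.T reconstructs the centered (scaled) matrix."""
    exp, _ = simulate_log2_experiment(6, 10, seed=3)
    res = run_pca(exp, n_components=6, scale=False)
    X = exp.assay.to_numpy().T
    Xc = X - X.mean(axis=0)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, Xc, atol=1e-10)


def test_pca_scores_centered_and_loadings_orthonormal():
    exp, _ = simulate_log2_experiment(20, 10, seed=4)
    res = run_pca(exp, 3)
    assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
    L = res.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(3), atol=1e-10)
    assert np.all(np.diff(res.explained_variance) <= 1e-12)
    assert res.explained_variance.sum() <= 1.0 + 1e-12


def test_pca_explained_variance_matches_eigendecomposition():
    """Independent oracle: eigenvalues of the covariance matrix (6x4)."""
    exp, _ = simulate_log2_experiment(4, 6, seed=5)
    X = exp.assay.to_numpy().T
    Xc = X - X.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    res = run_pca(exp, 3, scale=False)
    assert np.allclose(res.explained_variance, eig[:3] / eig.sum(), atol=1e-10)


def test_pca_requires_complete_matrix(mixed_experiment):
    exp = mixed_experiment
    exp.assay.iat[0, 0] = np.nan
    with pytest.raises(ExperimentError, match="impute"):
        run_pca(exp, 1)


def test_plsda_separates_planted_groups_and_permutation_degrades():
    exp, eff = simulate_log2_experiment(50, 12, n_effects=10, log2fc=3.0,
                                        sigma=0.3, seed=6)
    res = run_plsda(exp, "condition", 2)
    g = exp.samples["condition"].to_numpy()
    s1 = res.scores.iloc[:, 0].to_numpy()
    # component-1 scores separate groups with no overlap
    a, b = s1[g == "G1"], s1[g == "G2"]
    assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()

    def separation(scores, labels):
        a, b = scores[labels == "G1"], scores[labels == "G2"]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        return abs(a.mean() - b.mean()) / pooled

    rng = np.random.default_rng(0)
    perm = rng.permutation(g)
    exp_perm = exp.copy()
    exp_perm.samples["condition"] = perm
    res_perm = run_plsda(exp_perm, "condition", 2)
    assert separation(res_perm.scores.iloc[:, 0].to_numpy(), perm) < separation(s1, g)


def test_plsda_input_validation():
    exp, _ = simulate_log2_experiment(10, 8, seed=7)
    exp.samples["condition"] = "G1"
    with pytest.raises(ExperimentError, match="single level"):
        run_plsda(exp, "condition", 1)
    exp2, _ = simulate_log2_experiment(10, 8, seed=8)
    with pytest.raises(ExperimentError, match=">= 1"):
        run_plsda(exp2, "condition", 0)


def test_summary_profiles_total_equals_grand_total_single_class():
    per_sample = {
        "S1": [("PC(34:1)", "PC", 34, 1, 12.0, 3.0), ("PC(36:2)", "PC", 36, 2, 12.5, 4.0)],
        "S2": [("PC(34:1)", "PC", 34, 1, 12.0, 5.0), ("PC(36:2)", "PC", 36, 2, 12.5, 6.0)],
    }
    exp = make_experiment(per_sample)
    prof = summary_profiles(exp, by="class", statistic="total")
    assert prof.shape == (1, 2)
    assert prof.loc["PC", "S1"] == pytest.approx(7.0)
    assert prof.loc["PC", "S2"] == pytest.approx(11.0)


def test_summary_profiles_strata_and_statistics(mixed_experiment):
    by_db = summary_profiles(mixed_experiment, by="double_bonds")
    assert list(by_db.index) == [1, 2, 3]
    mean = summary_profiles(mixed_experiment, by="class", statistic="mean")
    total = summary_profiles(mixed_experiment, by="class", statistic="total")
    sizes = mixed_experiment.lipids.groupby("lipid_class").size()
    for cls in sizes.index:
        assert np.allclose(total.loc[cls], mean.loc[cls] * sizes[cls])


def test_hierarchical_order_returns_permutation(mixed_experiment):
    order = hierarchical_order(mixed_experiment, axis="samples")
    assert sorted(order) == sorted(mixed_experiment.sample_ids)
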