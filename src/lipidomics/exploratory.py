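"""Exploratory views: PCA, PLS-DA, stratified summary profiles, clustering.

PCA (unsupervised) and PLS-DA (supervised, on a one-hot group response)
give low-dimensional sample maps; summary profiles aggregate abundance by
the lipid strata produced by name parsing (class, total chain length,
double bonds) — the numeric layer under density/spider/heat-map style
graphics.  All analyses expect an imputed matrix (no NaN); they are
normally run on log2 concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cross_decomposition import PLSRegression

from .containers import ExperimentError, LipidExperiment

__all__ = ["OrdinationResult", "run_pca", "run_plsda", "summary_profiles", "hierarchical_order"]


@dataclass
class OrdinationResult:
    """Scores (samples), loadings (lipids) and explained variance."""

    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # lipids x components
    explained_variance: np.ndarray  # per-component proportion of total variance
    method: str


def _check_complete(exp: LipidExperiment) -> np.ndarray:
    vals = exp.assay.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ExperimentError("missing values present; impute before ordination")
    return vals


def run_pca(
    exp: LipidExperiment, n_components: int = 2, scale: bool = True
) -> OrdinationResult:
    """Principal component analysis of samples in lipid space.

    Columns (lipids) are mean-centered and optionally scaled to unit
    variance, then decomposed by SVD.  Sign convention: within each
    component the largest-magnitude loading is positive, making results
    reproducible across runs and platforms.
    """
    vals = _check_complete(exp).T  # samples x lipids
    n, p = vals.shape
    max_rank = min(n - 1, p)
    if not (1 <= n_components <= max_rank):
        raise ExperimentError(
            f"n_components must be in [1, {max_rank}] for {n} samples x {p} lipids"
        )
    X = vals - vals.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant lipids carry no variance; leave centered
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(len(S)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total_var = (S**2).sum()
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(
            U[:, :n_components] * S[:n_components], index=exp.assay.columns, columns=comps
        ),
        loadings=pd.DataFrame(Vt[:n_components].T, index=exp.assay.index, columns=comps),
        explained_variance=(S[:n_components] ** 2) / total_var,
        method="pca",
    )


def run_plsda(
    exp: LipidExperiment, group_factor: str, n_components: int = 2
) -> OrdinationResult:
    """Partial least squares discriminant analysis against a group factor.

    The group labels become a one-hot response matrix and a NIPALS PLS2
    model is fitted on the centered assay.  Explained variance is the
    proportion of (centered) X variance captured by each component.
    """
    if n_components < 1:
        raise ExperimentError("n_components must be >= 1")
    vals = _check_complete(exp).T
    groups = exp.factor_levels(group_factor)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ExperimentError(
            f"group factor {group_factor!r} has a single level; PLS-DA needs >= 2"
        )
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ExperimentError(
            f"every level of {group_factor!r} needs >= 2 samples, got {counts.to_dict()}"
        )
    Y = pd.get_dummies(groups).to_numpy(dtype=float)
    max_comp = min(vals.shape[0] - 1, vals.shape[1])
    if n_components > max_comp:
        raise ExperimentError(f"n_components must be <= {max_comp}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(vals, Y)
    Xc = vals - vals.mean(axis=0)
    total = (Xc**2).sum()
    expl = np.array(
        [
            (np.outer(pls.x_scores_[:, j], pls.x_loadings_[:, j]) ** 2).sum() / total
            for j in range(n_components)
        ]
    )
    comps = [f"LV{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(pls.x_scores_, index=exp.assay.columns, columns=comps),
        loadings=pd.DataFrame(pls.x_loadings_, index=exp.assay.index, columns=comps),
        explained_variance=expl,
        method="plsda",
    )


_STRATA = {
    "class": "lipid_class",
    "chain_length": "total_carbons",
    "double_bonds": "total_double_bonds",
}


def summary_profiles(
    exp: LipidExperiment, by: str = "class", statistic: str = "total"
) -> pd.DataFrame:
    """Per-sample abundance aggregated by a lipid stratum.

    ``by`` is one of ``class``, ``chain_length``, ``double_bonds``;
    ``statistic`` one of ``mean``, ``median``, ``total``.  Returns a
    strata x samples table with strata in canonical (sorted) order.
    """
    if by not in _STRATA:
        raise ExperimentError(f"unknown stratification {by!r}")
    if statistic not in ("mean", "median", "total"):
        raise ExperimentError(f"unknown statistic {statistic!r}")
    key = exp.lipids[_STRATA[by]]
    agg = {"mean": "mean", "median": "median", "total": "sum"}[statistic]
    out = exp.assay.groupby(key.to_numpy()).agg(agg)
    out.index.name = by
    return out.sort_index()


def hierarchical_order(
    exp: LipidExperiment, axis: str = "samples", method: str = "average"
) -> list[str]:
    """Leaf order from average-linkage Euclidean hierarchical clustering.

    Utility for heat-map row/column ordering (``axis`` in
    ``{"samples", "lipids"}``).
    """
    vals = _check_complete(exp)
    if axis == "samples":
        mat, labels = vals.T, exp.sample_ids
    elif axis == "lipids":
        mat, labels = vals, exp.lipid_names
    else:
        raise ExperimentError(f"axis must be 'samples' or 'lipids', got {axis!r}")
    Z = linkage(mat, method=method, metric="euclidean")
    return [labels[i] for i in leaves_list(Z)]
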