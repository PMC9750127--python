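"""Missing-value imputation on the concentration scale.

Missingness in LC-MS lipidomics is mostly left-censored — low-abundance
species fall below the detection limit — so the default replaces each
lipid's missing entries with half its minimum observed value, a standard
lower-bound surrogate that also keeps log2 finite.  A k-nearest-neighbour
alternative borrows values from the most similar samples, and a zero fill
is available for purely exploratory use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import ExperimentError, LipidExperiment

__all__ = ["impute"]


def impute(
    exp: LipidExperiment,
    method: str = "half_min",
    k: int = 5,
) -> LipidExperiment:
    """Replace every missing assay value; observed cells are never altered.

    Methods
    -------
    ``half_min``
        Each lipid's missing entries become half that lipid's minimum
        observed value (left-censoring surrogate; strictly positive
        whenever observed values are).
    ``knn``
        Each missing cell is the mean of the ``k`` nearest samples by
        Euclidean distance over co-observed lipids (requires
        ``n_samples > k``; ties broken by sample order).
    ``zero``
        Substitute 0 — exploratory use only, flagged in provenance.

    A lipid with no observed value at all cannot be imputed; remove it
    first with :func:`lipidomics.filtering.filter_missingness`.
    """
    if method not in ("half_min", "knn", "zero"):
        raise ExperimentError(f"unknown imputation method {method!r}")
    vals = exp.assay.to_numpy(dtype=float)
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        bad = list(exp.assay.index[all_missing][:5])
        raise ExperimentError(
            f"lipids with all values missing cannot be imputed (e.g. {bad}); "
            "apply filter_missingness first"
        )
    if not np.isnan(vals).any():
        return exp.with_log("impute", {"method": method, "n_imputed": 0})

    n_missing = int(np.isnan(vals).sum())
    filled = vals.copy()
    if method == "half_min":
        row_min = np.nanmin(vals, axis=1)
        rows, cols = np.nonzero(np.isnan(vals))
        filled[rows, cols] = row_min[rows] / 2.0
    elif method == "zero":
        filled[np.isnan(filled)] = 0.0
    else:
        if exp.n_samples <= k:
            raise ExperimentError(
                f"knn imputation needs n_samples > k (n={exp.n_samples}, k={k})"
            )
        # samples as observations, lipids as features: neighbours are samples
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        filled = imputer.fit_transform(vals.T).T
        if filled.shape != vals.shape:  # a lipid missing everywhere was dropped
            raise ExperimentError("knn imputation dropped all-missing lipids")

    assay = pd.DataFrame(filled, index=exp.assay.index, columns=exp.assay.columns)
    params = {"method": method, "n_imputed": n_missing}
    if method == "knn":
        params["k"] = k
    if method == "zero":
        params["warning"] = "zero fill is for exploratory use only"
    return exp.with_log("impute", params, assay=assay)
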