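"""Differential lipid abundance with empirical-Bayes moderated statistics.

Per lipid, an ordinary least-squares linear model is fitted on a design
matrix built from the experimental factors (plus the batch as a covariate
when requested).  With only a handful of samples per group the per-lipid
residual variances s_i^2 are noisy, so they are shrunk toward a pooled
prior following the standard empirical-Bayes treatment for omics linear
models: assuming s_i^2 | sigma_i^2 ~ scaled chi^2 with d_i degrees of
freedom and 1/sigma_i^2 ~ scaled chi^2 with prior degrees of freedom d_0
and prior variance s_0^2, the posterior variance is

    s~_i^2 = (d_0 s_0^2 + d_i s_i^2) / (d_0 + d_i)

and the moderated t statistic t_i = beta_i / (u_i s~_i) follows a t
distribution with d_0 + d_i degrees of freedom (u_i the unscaled standard
error from the design).  (d_0, s_0^2) are estimated from the ensemble of
residual variances by moment matching on the scaled-F distribution of
s_i^2 / s_0^2, i.e. by matching the mean and variance of log s_i^2 using
digamma/trigamma identities.

Lipid-set enrichment is one-sided hypergeometric over-representation of
the significant lipids (BH-adjusted p below alpha) within sets defined by
class, total-chain-length bins and double-bond bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExperimentError, LipidExperiment

__all__ = [
    "DesignSpec",
    "DifferentialError",
    "fit_differential",
    "remove_batch",
    "bh_adjust",
    "enrich_lipid_sets",
    "ma_volcano_tables",
    "squeeze_variances",
    "DEFAULT_CHAIN_BINS",
    "DEFAULT_DB_BINS",
]

# Set granularity for enrichment; edges are inclusive upper bounds.
DEFAULT_CHAIN_BINS = (30, 40, 50)   # <=30, 31-40, 41-50, >50 total carbons
DEFAULT_DB_BINS = (0, 2, 5)         # 0, 1-2, 3-5, >5 double bonds


class DifferentialError(ValueError):
    """Invalid design, confounded batch, or other model failure."""


@dataclass(frozen=True)
class DesignSpec:
    """Model terms and the contrast to test.

    ``factors`` are sample-annotation column names entering the model as
    fixed effects; ``contrast`` is ``(level_a, level_b)`` on the *first*
    factor, reported as log2(a) - log2(b).  ``batch_mode``:

    * ``none`` — ignore batch,
    * ``covariate`` — batch dummies enter the design (recommended),
    * ``remove_first`` — apply :func:`remove_batch`, then fit without batch.
    """

    factors: tuple[str, ...]
    contrast: tuple[str, str]
    batch_mode: str = "none"

    def __post_init__(self) -> None:
        if not self.factors:
            raise DifferentialError("DesignSpec needs at least one factor")
        if self.batch_mode not in ("none", "covariate", "remove_first"):
            raise DifferentialError(f"unknown batch_mode {self.batch_mode!r}")
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise DifferentialError("contrast must name two distinct levels")


# -- empirical-Bayes variance moderation -----------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray, df: float
) -> tuple[np.ndarray, float, float]:
    """Shrink per-lipid residual variances toward a moment-matched prior.

    Returns ``(posterior variances, d0, s0_squared)``.  ``d0`` may be
    ``inf`` when the observed variances are under-dispersed relative to
    pure chi-squared sampling noise (all variances then collapse to the
    common value).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return s2, 0.0, float(np.nanmean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, float(d0), s0_2


# -- design matrices --------------------------------------------------------------


def _design_matrix(
    samples: pd.DataFrame, spec: DesignSpec, include_batch: bool
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build intercept + treatment-coded dummies; return (X, names, contrast c)."""
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    contrast_vec = None
    for k, factor in enumerate(spec.factors):
        if factor not in samples.columns:
            raise DifferentialError(f"factor {factor!r} missing from sample annotations")
        levels = sorted(samples[factor].astype(str).unique())
        if len(levels) < 2:
            raise DifferentialError(f"factor {factor!r} has a single level")
        ref = levels[0]
        for level in levels[1:]:
            cols.append((samples[factor].astype(str) == level).to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
        if k == 0:
            a, b = spec.contrast
            if a not in levels or b not in levels:
                raise DifferentialError(
                    f"contrast levels {spec.contrast} not found in factor {factor!r} "
                    f"(levels: {levels})"
                )
    if include_batch:
        if "batch" not in samples.columns or samples["batch"].isna().all():
            raise DifferentialError("batch_mode=covariate but no batch annotation present")
        batches = sorted(samples["batch"].astype(str).unique())
        for b_ in batches[1:]:
            cols.append((samples["batch"].astype(str) == b_).to_numpy(dtype=float))
            names.append(f"batch[{b_}]")
    X = np.column_stack(cols)

    # contrast vector on the first factor's treatment coding
    factor = spec.factors[0]
    a, b = spec.contrast
    c = np.zeros(X.shape[1])
    for lev, sign in ((a, 1.0), (b, -1.0)):
        col = f"{factor}[{lev}]"
        if col in names:
            c[names.index(col)] = sign
        # the reference level has implicit coefficient 0
    return X, names, c


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = sla.qr(X, pivoting=True)
        aliased = [names[i] for i in piv[rank:]]
        raise DifferentialError(
            f"design matrix is rank-deficient; aliased column(s): {aliased} "
            "(batch confounded with a condition?)"
        )


# -- differential fitting ---------------------------------------------------------


def fit_differential(
    exp: LipidExperiment,
    design: DesignSpec,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Per-lipid moderated linear-model test of the design's contrast.

    Expects an imputed, log2-scale experiment.  Returns one row per lipid:
    ``log2_fold_change``, ``average_abundance``, ``moderated_t``,
    ``p_value``, ``adjusted_p`` (Benjamini-Hochberg), ``contrast``, plus
    diagnostic columns (``residual_variance``, ``df_residual``,
    ``df_prior``, ``s0_squared``).

    ``prior_df`` overrides the estimated prior degrees of freedom d_0;
    ``prior_df=0`` disables moderation (classical t).
    """
    if exp.assay_kind != "log2":
        raise ExperimentError(
            f"differential testing expects log2 data, got {exp.assay_kind!r}"
        )
    Y = exp.assay.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ExperimentError("missing values present; impute before testing")

    samples = exp.samples
    if design.batch_mode == "remove_first":
        exp2 = remove_batch(exp, "batch")
        return fit_differential(
            exp2,
            DesignSpec(design.factors, design.contrast, batch_mode="none"),
            prior_df=prior_df,
        )

    X, names, c = _design_matrix(samples, design, include_batch=design.batch_mode == "covariate")
    _check_rank(X, names)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DifferentialError(f"no residual degrees of freedom (n={n}, p={p})")

    factor = design.factors[0]
    levels = samples[factor].astype(str)
    for lev in design.contrast:
        if (levels == lev).sum() < 2:
            raise DifferentialError(f"contrast level {lev!r} has fewer than 2 samples")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T          # lipids x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    effect = beta @ c
    u = float(np.sqrt(c @ XtX_inv @ c))  # unscaled SE multiplier

    if df_resid < 2 and prior_df is None:
        warnings.warn(
            "fewer than 2 residual degrees of freedom; falling back to unmoderated t"
        )
        prior_df = 0.0

    if prior_df is not None and prior_df == 0:
        post_s2, d0, s0_2 = s2, 0.0, float(np.mean(s2))
    else:
        post_s2, d0, s0_2 = squeeze_variances(s2, df_resid)
        if prior_df is not None:
            d0 = float(prior_df)
            post_s2 = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)

    se = u * np.sqrt(post_s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    df_total = d0 + df_resid
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    out = pd.DataFrame(
        {
            "log2_fold_change": effect,
            "average_abundance": Y.mean(axis=1),
            "moderated_t": tstat,
            "p_value": pvals,
            "adjusted_p": bh_adjust(pvals),
            "contrast": f"{design.contrast[0]} - {design.contrast[1]}",
            "residual_variance": s2,
            "df_residual": float(df_resid),
            "df_prior": d0,
            "s0_squared": s0_2,
        },
        index=exp.assay.index,
    )
    return out


def remove_batch(exp: LipidExperiment, batch_factor: str = "batch") -> LipidExperiment:
    """Center each lipid within batch, restoring the grand mean.

    Intended for exploration; for testing, prefer ``batch_mode=
    "covariate"`` so the batch term is part of the model.  Warns when the
    batch is confounded with a factor (removal would absorb real signal).
    """
    if batch_factor not in exp.samples.columns:
        raise ExperimentError(f"batch factor {batch_factor!r} not in sample annotations")
    batches = exp.samples[batch_factor].astype(str)
    uniq = pd.unique(batches)
    if len(uniq) < 2:
        return exp.with_log("remove_batch", {"batches": 1, "note": "single batch, identity"})
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ExperimentError("each batch needs >= 2 samples for mean removal")

    from .containers import RESERVED_TARGET_COLUMNS

    factor_cols = [c for c in exp.samples.columns if c not in RESERVED_TARGET_COLUMNS]
    for fc in factor_cols:
        tab = pd.crosstab(batches, exp.samples[fc].astype(str))
        if ((tab > 0).sum(axis=1) == 1).all():
            warnings.warn(
                f"batch is confounded with factor {fc!r}; removal will absorb its effect"
            )

    vals = exp.assay.to_numpy(dtype=float)
    grand = np.nanmean(vals, axis=1, keepdims=True)
    adjusted = vals.copy()
    for b in uniq:
        cols = (batches == b).to_numpy()
        bmean = np.nanmean(vals[:, cols], axis=1, keepdims=True)
        adjusted[:, cols] = vals[:, cols] - bmean + grand
    return exp.with_log(
        "remove_batch",
        {"batches": int(len(uniq))},
        assay=pd.DataFrame(adjusted, index=exp.assay.index, columns=exp.assay.columns),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DifferentialError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- lipid-set enrichment ---------------------------------------------------------


def _bin_labels(edges: Sequence[int], prefix: str) -> list[str]:
    labels = []
    prev = None
    for e in edges:
        if prev is None:
            labels.append(f"{prefix}<={e}")
        else:
            lo = prev + 1
            labels.append(f"{prefix}{lo}-{e}" if lo != e else f"{prefix}{e}")
        prev = e
    labels.append(f"{prefix}>{edges[-1]}")
    return labels


def build_lipid_sets(
    lipids: pd.DataFrame,
    chain_bins: Sequence[int] = DEFAULT_CHAIN_BINS,
    db_bins: Sequence[int] = DEFAULT_DB_BINS,
) -> dict[str, pd.Index]:
    """Lipid sets from parsing-derived strata: class, chain-length bin, DB bin."""
    chain_lab = np.array(_bin_labels(chain_bins, "C"))
    db_lab = np.array(_bin_labels(db_bins, "DB"))
    keys = {
        "class": "class:" + lipids["lipid_class"].astype(str),
        "chain": "chain:" + pd.Series(
            chain_lab[np.digitize(lipids["total_carbons"].to_numpy(int), chain_bins, right=True)],
            index=lipids.index,
        ),
        "db": "db:" + pd.Series(
            db_lab[np.digitize(lipids["total_double_bonds"].to_numpy(int), db_bins, right=True)],
            index=lipids.index,
        ),
    }
    sets: dict[str, pd.Index] = {}
    for series in keys.values():
        for label, idx in series.groupby(series.to_numpy()).groups.items():
            sets[str(label)] = pd.Index(idx)
    return sets


def enrich_lipid_sets(
    diff: pd.DataFrame,
    lipids: pd.DataFrame,
    alpha: float = 0.05,
    chain_bins: Sequence[int] = DEFAULT_CHAIN_BINS,
    db_bins: Sequence[int] = DEFAULT_DB_BINS,
    significant: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant lipids per set.

    Significant lipids are those with ``adjusted_p < alpha`` (strict); an
    explicit ``significant`` index overrides this (useful for permutation
    nulls).  For each set the one-sided tail P(X >= overlap) of the
    hypergeometric with (N tested, K significant, n set size) is reported,
    with BH adjustment across sets.  No significant lipids yields an
    empty table with a notice rather than an error.
    """
    if not (0 < alpha < 1):
        raise DifferentialError("alpha must be in (0, 1)")
    tested = diff.index
    if significant is None:
        significant = tested[diff["adjusted_p"].to_numpy() < alpha]
    N, K = len(tested), len(significant)
    if K == 0:
        warnings.warn("no significant lipids at the chosen alpha; empty enrichment result")
        return pd.DataFrame(
            columns=["set", "set_size", "overlap", "odds_ratio", "p_value", "adjusted_p"]
        ).set_index("set")
    sig = set(significant)
    sets = build_lipid_sets(lipids.loc[tested], chain_bins, db_bins)
    rows = []
    for set_name, members in sorted(sets.items()):
        n_set = len(members)
        k = int(members.isin(sig).sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, n_set))
        a, b = k, n_set - k
        c_, d_ = K - k, N - K - (n_set - k)
        odds = np.inf if b * c_ == 0 and a * d_ > 0 else (
            np.nan if b * c_ == 0 else (a * d_) / (b * c_)
        )
        rows.append(
            {
                "set": set_name,
                "set_size": n_set,
                "overlap": k,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def ma_volcano_tables(
    diff: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Numeric tables behind MA and volcano plots.

    Significance uses strict inequality ``adjusted_p < alpha``; a lipid
    sitting exactly at alpha is not flagged.
    """
    flag = diff["adjusted_p"].to_numpy() < alpha
    ma = pd.DataFrame(
        {
            "average_abundance": diff["average_abundance"],
            "log2_fold_change": diff["log2_fold_change"],
            "significant": flag,
        },
        index=diff.index,
    )
    with np.errstate(divide="ignore"):
        neglog = -np.log10(diff["adjusted_p"].to_numpy())
    volcano = pd.DataFrame(
        {
            "log2_fold_change": diff["log2_fold_change"],
            "neg_log10_adjusted_p": neglog,
            "significant": flag,
        },
        index=diff.index,
    )
    return ma, volcano
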