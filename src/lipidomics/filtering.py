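"""False-positive reduction: reference bounds, odd chains, duplicates, missingness.

LC-MS lipid identification produces false positives that show up as
chemically implausible species: retention times outside the class's
elution window, chain lengths or double-bond counts outside the range the
extraction can yield, or odd-carbon chains in matrices where they are
rare.  An internal reference file states, per lipid class, the plausible
retention-time window, total-carbon bounds, double-bond bounds and
whether odd chains are allowed; lipids violating a bound are removed.

Rules are applied in a fixed order — retention time, carbon bounds,
double-bond bounds, odd chain — and each removed lipid is attributed to
the *first* rule it violates, so per-rule counts add up to the total
removed (conservation: removed + retained = input).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExperimentError, LipidExperiment, subset
from .io_formats import InternalReferenceEntry

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "filter_by_reference",
    "deduplicate_lipids",
    "filter_missingness",
    "RULE_ORDER",
]

logger = logging.getLogger(__name__)

RULE_ORDER = ("rt_window", "carbon_bounds", "double_bond_bounds", "odd_chain")


@dataclass(frozen=True)
class FilterPolicy:
    """Knobs for reference-based filtering.

    ``unlisted_class``: what to do with lipids whose class has no reference
    entry — ``"keep_with_warning"`` (default) or ``"drop"``.
    """

    unlisted_class: str = "keep_with_warning"

    def __post_init__(self) -> None:
        if self.unlisted_class not in ("keep_with_warning", "drop"):
            raise ValueError(f"unknown unlisted_class policy {self.unlisted_class!r}")


@dataclass
class FilterReport:
    """Per-rule removal counts plus the removed (lipid, rule) records."""

    counts: dict = field(default_factory=dict)
    records: list[dict] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def add(self, lipid: str, rule: str, sample: Optional[str] = None, detail: str = "") -> None:
        self.counts[rule] = self.counts.get(rule, 0) + 1
        self.records.append({"lipid": lipid, "sample": sample, "rule": rule, "detail": detail})

    @property
    def n_removed(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["lipid", "sample", "rule", "detail"])

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "by_rule": dict(self.counts),
        }


def _first_violation(
    row: pd.Series, entry: InternalReferenceEntry
) -> Optional[tuple[str, str]]:
    """Return (rule, detail) for the first rule in RULE_ORDER violated, else None."""
    rt = row.get("retention_time_min")
    if rt is not None and np.isfinite(rt):
        if not (entry.rt_min <= rt <= entry.rt_max):
            return "rt_window", f"rt {rt:.3g} outside [{entry.rt_min}, {entry.rt_max}]"
    tc = int(row["total_carbons"])
    if not (entry.carbons_min <= tc <= entry.carbons_max):
        return "carbon_bounds", f"C{tc} outside [{entry.carbons_min}, {entry.carbons_max}]"
    db = int(row["total_double_bonds"])
    if not (entry.double_bonds_min <= db <= entry.double_bonds_max):
        return (
            "double_bond_bounds",
            f"DB{db} outside [{entry.double_bonds_min}, {entry.double_bonds_max}]",
        )
    if not entry.allow_odd_chains and bool(row["odd_chain"]):
        return "odd_chain", "odd-carbon chain disallowed for class"
    return None


def filter_by_reference(
    exp: LipidExperiment,
    reference: Sequence[InternalReferenceEntry],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[LipidExperiment, FilterReport]:
    """Remove lipids violating the per-class reference bounds.

    Internal-standard rows are exempt (they are spiked compounds needed by
    the calibration stage, not identifications to vet).  When no retention
    time is available for a lipid the rt rule is skipped for that lipid
    with a logged notice; the consensus (median-across-samples) retention
    time stored at import is the value tested.
    """
    by_class = {e.lipid_class: e for e in reference}
    report = FilterReport(n_input=exp.n_lipids)
    keep = np.ones(exp.n_lipids, dtype=bool)
    unlisted: set[str] = set()

    for i, (name, row) in enumerate(exp.lipids.iterrows()):
        if bool(row.get("is_internal_standard", False)):
            continue
        entry = by_class.get(row["lipid_class"])
        if entry is None:
            unlisted.add(row["lipid_class"])
            if policy.unlisted_class == "drop":
                keep[i] = False
                report.add(name, "unlisted_class", detail="class not in reference")
            continue
        hit = _first_violation(row, entry)
        if hit is not None:
            keep[i] = False
            report.add(name, hit[0], detail=hit[1])

    if unlisted and policy.unlisted_class == "keep_with_warning":
        warnings.warn(
            f"classes without reference entry kept unfiltered: {sorted(unlisted)}"
        )
    report.n_retained = int(keep.sum())
    if report.n_removed == 0:
        out = exp.with_log("filter_by_reference", {"removed": 0})
    else:
        out = subset(exp, lipid_predicate=keep)
        out.provenance[-1]["operation"] = "filter_by_reference"
        out.provenance[-1]["params"] = report.summary()
    return out, report


def deduplicate_lipids(
    exp: LipidExperiment, policy: str = "keep_max_area"
) -> tuple[LipidExperiment, FilterReport]:
    """Resolve rows sharing a canonical name (same class + totals + chains).

    Duplicates arise when the identification software reports one species
    several times (e.g. under different adduct ions).  Policies:

    * ``keep_max_area`` — the row with the largest total area survives
      (most intense identification wins; the common convention),
    * ``keep_nearest_rt`` — the row closest to the duplicate group's
      median retention time survives,
    * ``merge_sum`` — rows are summed per sample (missing treated as 0
      when at least one value is present; all-missing stays missing).
    """
    if policy not in ("keep_max_area", "keep_nearest_rt", "merge_sum"):
        raise ExperimentError(f"unknown deduplication policy {policy!r}")
    report = FilterReport(n_input=exp.n_lipids)
    names = exp.assay.index.to_numpy()
    if len(set(names)) == len(names):
        report.n_retained = exp.n_lipids
        return exp.with_log("deduplicate_lipids", {"policy": policy, "removed": 0}), report

    assay_vals = exp.assay.to_numpy(dtype=float)
    keep = np.ones(len(names), dtype=bool)
    merged_rows: dict[int, np.ndarray] = {}

    order: dict[str, list[int]] = {}
    for i, n in enumerate(names):
        order.setdefault(n, []).append(i)

    for name, idxs in order.items():
        if len(idxs) == 1:
            continue
        if policy == "merge_sum":
            block = assay_vals[idxs]
            if np.isnan(block).any():
                logger.info("merge_sum over missing areas for %s: missing treated as 0", name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                merged = np.nansum(block, axis=0)
                merged[np.isnan(block).all(axis=0)] = np.nan
            survivor = idxs[0]
            merged_rows[survivor] = merged
        elif policy == "keep_max_area":
            totals = np.nansum(np.nan_to_num(assay_vals[idxs], nan=0.0), axis=1)
            survivor = idxs[int(np.argmax(totals))]
        else:  # keep_nearest_rt
            rts = exp.lipids["retention_time_min"].to_numpy(dtype=float)[idxs]
            med = np.nanmedian(rts)
            dev = np.abs(rts - med)
            dev[np.isnan(dev)] = np.inf
            survivor = idxs[int(np.argmin(dev))]
        for i in idxs:
            if i != survivor:
                keep[i] = False
                report.add(name, "duplicate", detail=f"resolved by {policy}")

    new_assay = exp.assay.iloc[keep].copy()
    if merged_rows:
        # map original positional index -> new positional index
        pos = {orig: new for new, orig in enumerate(np.flatnonzero(keep))}
        for orig, vals in merged_rows.items():
            new_assay.iloc[pos[orig]] = vals
    report.n_retained = int(keep.sum())
    out = exp.with_log(
        "deduplicate_lipids",
        {"policy": policy, **report.summary()},
        assay=new_assay,
        lipids=exp.lipids.iloc[keep].copy(),
        flags=None if exp.flags is None else exp.flags.iloc[keep].copy(),
    )
    return out, report


def filter_missingness(
    exp: LipidExperiment,
    max_missing_fraction_per_lipid: float,
    scope: str = "overall",
    group_factor: Optional[str] = None,
) -> tuple[LipidExperiment, FilterReport]:
    """Drop lipids with too many missing values before imputation.

    ``overall``: remove a lipid when its missing fraction across all
    samples exceeds the threshold.  ``per_group``: remove a lipid only
    when its missing fraction exceeds the threshold in *every* level of
    ``group_factor`` (a lipid well-measured in at least one group is
    biologically informative and kept).
    """
    thr = float(max_missing_fraction_per_lipid)
    if not (0.0 <= thr <= 1.0):
        raise ExperimentError("max_missing_fraction_per_lipid must be in [0, 1]")
    if scope not in ("overall", "per_group"):
        raise ExperimentError(f"unknown scope {scope!r}")
    if scope == "per_group" and group_factor is None:
        raise ExperimentError("per_group missingness filtering requires group_factor")

    miss = exp.assay.isna().to_numpy()
    if scope == "overall":
        frac = miss.mean(axis=1)
        remove = frac > thr
        detail = frac
    else:
        levels = exp.factor_levels(group_factor)
        per_group = []
        for level in pd.unique(levels):
            cols = (levels == level).to_numpy()
            per_group.append(miss[:, cols].mean(axis=1))
        frac_matrix = np.column_stack(per_group)
        remove = (frac_matrix > thr).all(axis=1)
        detail = frac_matrix.min(axis=1)

    report = FilterReport(n_input=exp.n_lipids)
    for name, rm, fr in zip(exp.assay.index, remove, detail):
        if rm:
            report.add(name, "missingness", detail=f"missing fraction {fr:.2f} > {thr}")
    report.n_retained = int((~remove).sum())
    if remove.any():
        out = subset(exp, lipid_predicate=~remove)
        out.provenance[-1]["operation"] = "filter_missingness"
        out.provenance[-1]["params"] = {"threshold": thr, "scope": scope, **report.summary()}
    else:
        out = exp.with_log("filter_missingness", {"threshold": thr, "scope": scope, "removed": 0})
    return out, report
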