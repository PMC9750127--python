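"""The central experiment container: abundance matrix plus annotations.

A :class:`LipidExperiment` bundles a lipids × samples assay matrix with
per-lipid annotations (class, chain totals, retention time, internal
standard flag), per-sample annotations (experimental factors, batch,
replicate role) and an append-only provenance log.  Missing measurements
are represented by NaN, never 0.  Every transforming operation returns a
new container and appends exactly one provenance record.

Assay kinds progress along
``raw_area -> concentration -> normalized_concentration -> log2``
(or directly ``raw_area -> log2`` for experiments without internal
standards).
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, has_odd_chain

__all__ = [
    "SampleRecord",
    "LipidExperiment",
    "ExperimentError",
    "build_experiment",
    "subset",
    "aggregate_technical_replicates",
    "log2_transform",
    "save_experiment",
    "load_experiment",
    "ASSAY_KINDS",
]

ASSAY_KINDS = ("raw_area", "concentration", "normalized_concentration", "log2")
_KIND_TRANSITIONS = {
    ("raw_area", "concentration"),
    ("concentration", "normalized_concentration"),
    ("normalized_concentration", "log2"),
    ("raw_area", "log2"),
}

RESERVED_TARGET_COLUMNS = ("sample_id", "data_file", "batch", "replicate_role", "calibration_ref")

LIPID_ANNOTATION_COLUMNS = [
    "raw_name",
    "lipid_class",
    "total_carbons",
    "total_double_bonds",
    "n_chains",
    "resolution",
    "odd_chain",
    "is_internal_standard",
    "retention_time_min",
    "adduct",
]


class ExperimentError(ValueError):
    """Structural problem with an experiment or an operation on it."""


@dataclass(frozen=True)
class SampleRecord:
    """One row of the target file: sample identity and metadata."""

    sample_id: str
    data_file: str
    factors: Mapping[str, str] = field(default_factory=dict)
    batch: Optional[str] = None
    replicate_role: str = "biological"
    calibration_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.replicate_role not in ("biological", "technical"):
            raise ValueError(
                f"replicate_role must be 'biological' or 'technical', got {self.replicate_role!r}"
            )


@dataclass
class LipidExperiment:
    """Abundance matrix with lipid and sample annotations and provenance.

    ``assay``: DataFrame indexed by canonical lipid name (duplicates allowed
    until deduplication) with one column per sample.  ``lipids`` shares the
    assay index; ``samples`` is indexed by sample_id.  ``flags`` is an
    optional boolean matrix aligned with ``assay`` marking values outside
    the calibration linear range.
    """

    assay: pd.DataFrame
    lipids: pd.DataFrame
    samples: pd.DataFrame
    assay_kind: str = "raw_area"
    provenance: list[dict] = field(default_factory=list)
    flags: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.assay_kind not in ASSAY_KINDS:
            raise ExperimentError(f"unknown assay kind {self.assay_kind!r}")
        if self.assay.shape[0] != self.lipids.shape[0]:
            raise ExperimentError("assay rows and lipid annotations disagree")
        if self.assay.shape[1] != self.samples.shape[0]:
            raise ExperimentError("assay columns and sample annotations disagree")
        if not (self.assay.columns == self.samples.index).all():
            raise ExperimentError("assay columns must equal sample ids in order")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_lipids(self) -> int:
        return self.assay.shape[0]

    @property
    def n_samples(self) -> int:
        return self.assay.shape[1]

    @property
    def lipid_names(self) -> list[str]:
        return list(self.assay.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assay.columns)

    def factor_levels(self, factor: str) -> pd.Series:
        if factor not in self.samples.columns:
            raise ExperimentError(f"factor {factor!r} not present in sample annotations")
        return self.samples[factor]

    def copy(self) -> "LipidExperiment":
        return LipidExperiment(
            assay=self.assay.copy(),
            lipids=self.lipids.copy(),
            samples=self.samples.copy(),
            assay_kind=self.assay_kind,
            provenance=[dict(rec) for rec in self.provenance],
            flags=None if self.flags is None else self.flags.copy(),
        )

    def with_log(self, operation: str, params: Optional[dict] = None, **updates) -> "LipidExperiment":
        """Return a copy with ``updates`` applied and one provenance record appended."""
        new = self.copy()
        for key, value in updates.items():
            setattr(new, key, value)
        new.provenance.append(
            {
                "operation": operation,
                "params": params or {},
                "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
                "n_lipids": int(new.assay.shape[0]),
                "n_samples": int(new.assay.shape[1]),
            }
        )
        return new

    def set_kind(self, kind: str) -> None:
        if (self.assay_kind, kind) not in _KIND_TRANSITIONS:
            raise ExperimentError(
                f"illegal assay kind transition {self.assay_kind!r} -> {kind!r}"
            )
        self.assay_kind = kind


# -- construction ---------------------------------------------------------------


def _annotation_row(species: LipidSpecies, rt: float, adduct: Optional[str]) -> dict:
    return {
        "raw_name": species.raw_name,
        "lipid_class": species.lipid_class,
        "total_carbons": species.total_carbons,
        "total_double_bonds": species.total_double_bonds,
        "n_chains": len(species.chains),
        "resolution": species.resolution.value,
        "odd_chain": has_odd_chain(species),
        "is_internal_standard": species.is_internal_standard,
        "retention_time_min": rt,
        "adduct": adduct,
    }


def build_experiment(
    tables: Mapping[str, pd.DataFrame],
    targets: Sequence[SampleRecord],
    *,
    internal_standard_names: Iterable[str] = (),
) -> LipidExperiment:
    """Assemble per-sample lipid tables into a :class:`LipidExperiment`.

    ``tables`` maps data-file names to the reader output (one row per
    identified lipid, columns including ``canonical_name``, ``raw_name``,
    ``lipid_class``, ``total_carbons``, ``total_double_bonds``,
    ``n_chains``, ``resolution``, ``odd_chain``, ``retention_time_min``,
    ``adduct``, ``area``).  Rows are unioned across samples; a lipid absent
    from a sample gets NaN.  Duplicate canonical names within one table are
    kept as separate rows for the deduplication stage to resolve.

    Per-lipid retention time is the median of the per-sample values; the
    spread is retained in ``retention_time_spread_min`` so filtering can
    report disagreement.
    """
    if not targets:
        raise ExperimentError("empty target list")
    ids = [t.sample_id for t in targets]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ExperimentError(f"duplicate sample_id(s): {sorted(dup)}")
    orphans = [t.sample_id for t in targets if t.data_file not in tables]
    if orphans:
        raise ExperimentError(
            f"target rows with no matching abundance table: {orphans} "
            f"(available files: {sorted(tables)})"
        )
    is_names = set(internal_standard_names)

    # Union of (canonical_name, occurrence) keys so within-sample duplicates
    # survive as separate rows until deduplicate_lipids.
    row_keys: list[tuple[str, int]] = []
    seen_counts: dict[str, int] = {}
    ann_rows: dict[tuple[str, int], dict] = {}
    rts: dict[tuple[str, int], list[float]] = {}
    per_sample: dict[str, dict[tuple[str, int], float]] = {}

    for t in targets:
        table = tables[t.data_file]
        occur: dict[str, int] = {}
        values: dict[tuple[str, int], float] = {}
        for rec in table.to_dict("records"):
            name = rec["canonical_name"]
            k = occur.get(name, 0)
            occur[name] = k + 1
            key = (name, k)
            if key not in ann_rows:
                row_keys.append(key)
                ann_rows[key] = {
                    c: rec.get(c)
                    for c in LIPID_ANNOTATION_COLUMNS
                    if c != "retention_time_min"
                }
                ann_rows[key]["is_internal_standard"] = bool(
                    rec.get("is_internal_standard", False) or name in is_names
                )
                rts[key] = []
            rt = rec.get("retention_time_min")
            if rt is not None and np.isfinite(rt):
                rts[key].append(float(rt))
            values[key] = float(rec["area"])
        per_sample[t.sample_id] = values

    index = pd.Index([k[0] for k in row_keys], name="lipid")
    assay = pd.DataFrame(
        np.full((len(row_keys), len(targets)), np.nan),
        index=index,
        columns=pd.Index([t.sample_id for t in targets], name="sample_id"),
    )
    for t in targets:
        vals = per_sample[t.sample_id]
        col = assay.columns.get_loc(t.sample_id)
        for i, key in enumerate(row_keys):
            if key in vals:
                assay.iat[i, col] = vals[key]

    lipids = pd.DataFrame([ann_rows[k] for k in row_keys], index=index)
    lipids["retention_time_min"] = [
        float(np.median(rts[k])) if rts[k] else np.nan for k in row_keys
    ]
    lipids["retention_time_spread_min"] = [
        float(np.ptp(rts[k])) if len(rts[k]) > 1 else 0.0 for k in row_keys
    ]

    factor_names = sorted({f for t in targets for f in t.factors})
    samples = pd.DataFrame(
        {
            "data_file": [t.data_file for t in targets],
            "batch": [t.batch for t in targets],
            "replicate_role": [t.replicate_role for t in targets],
            "calibration_ref": [t.calibration_ref for t in targets],
            **{f: [t.factors.get(f) for t in targets] for f in factor_names},
        },
        index=pd.Index([t.sample_id for t in targets], name="sample_id"),
    )

    exp = LipidExperiment(assay=assay, lipids=lipids, samples=samples, assay_kind="raw_area")
    return exp.with_log(
        "import",
        {"n_files": len(targets), "factors": factor_names},
    )


# -- transformations -------------------------------------------------------------


def subset(
    exp: LipidExperiment,
    lipid_predicate: Optional[Callable[[pd.Series], bool] | Sequence[bool]] = None,
    sample_predicate: Optional[Callable[[pd.Series], bool] | Sequence[bool]] = None,
) -> LipidExperiment:
    """Slice lipids and/or samples consistently.

    Predicates are callables evaluated on each annotation row, or boolean
    masks.  A result with zero lipids or zero samples is an error because
    every downstream stage is undefined on an empty experiment.
    """

    def _mask(pred, frame: pd.DataFrame) -> np.ndarray:
        if pred is None:
            return np.ones(len(frame), dtype=bool)
        if callable(pred):
            return np.array([bool(pred(row)) for _, row in frame.iterrows()])
        mask = np.asarray(pred, dtype=bool)
        if mask.shape != (len(frame),):
            raise ExperimentError("boolean mask length does not match")
        return mask

    lmask = _mask(lipid_predicate, exp.lipids)
    smask = _mask(sample_predicate, exp.samples)
    if not lmask.any():
        raise ExperimentError("subset removes every lipid")
    if not smask.any():
        raise ExperimentError("subset removes every sample")
    new = exp.with_log(
        "subset",
        {"lipids_kept": int(lmask.sum()), "samples_kept": int(smask.sum())},
        assay=exp.assay.iloc[lmask, smask].copy(),
        lipids=exp.lipids.iloc[lmask].copy(),
        samples=exp.samples.iloc[smask].copy(),
        flags=None if exp.flags is None else exp.flags.iloc[lmask, smask].copy(),
    )
    return new


def aggregate_technical_replicates(
    exp: LipidExperiment, method: str = "mean"
) -> LipidExperiment:
    """Collapse technical replicates into one column per biological unit.

    Technical replicates are samples with ``replicate_role == 'technical'``
    sharing identical factor levels and batch; each group collapses to one
    column (NaN-ignoring mean or median; all-missing stays missing), named
    after the group's first sample.  Biological samples pass through.
    """
    if method not in ("mean", "median"):
        raise ExperimentError(f"unknown aggregation method {method!r}")
    samples = exp.samples
    factor_cols = [c for c in samples.columns if c not in RESERVED_TARGET_COLUMNS[1:]]
    groups: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for sid, row in samples.iterrows():
        if row["replicate_role"] == "technical":
            key = ("tech",) + tuple(str(row.get(c)) for c in factor_cols) + (str(row.get("batch")),)
        else:
            key = ("bio", sid)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sid)

    agg = np.nanmean if method == "mean" else np.nanmedian
    cols, col_names, sample_rows = [], [], []
    for key in order:
        members = groups[key]
        block = exp.assay[members].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            cols.append(agg(block, axis=1))
        col_names.append(members[0])
        rec = samples.loc[members[0]].copy()
        rec["replicate_role"] = "biological"
        sample_rows.append(rec)

    assay = pd.DataFrame(
        np.column_stack(cols), index=exp.assay.index,
        columns=pd.Index(col_names, name="sample_id"),
    )
    new_samples = pd.DataFrame(sample_rows)
    new_samples.index = pd.Index(col_names, name="sample_id")
    return exp.with_log(
        "aggregate_technical_replicates",
        {"method": method, "n_groups": len(order)},
        assay=assay,
        samples=new_samples,
        flags=None,
    )


def log2_transform(exp: LipidExperiment) -> LipidExperiment:
    """log2 of the assay; requires strictly positive values (impute first)."""
    vals = exp.assay.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ExperimentError(
            "log2 transform requires strictly positive abundances; "
            "impute (half_min) before transforming"
        )
    new = exp.with_log("log2_transform", {}, assay=np.log2(exp.assay))
    new.set_kind("log2")
    return new


# -- serialization ---------------------------------------------------------------


def save_experiment(exp: LipidExperiment, path: str | Path) -> Path:
    """Write the container as a directory of delimited tables + JSON provenance."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    exp.assay.to_csv(path / "assay.tsv", sep="\t")
    exp.lipids.to_csv(path / "lipids.tsv", sep="\t")
    exp.samples.to_csv(path / "samples.tsv", sep="\t")
    if exp.flags is not None:
        exp.flags.to_csv(path / "flags.tsv", sep="\t")
    meta = {"assay_kind": exp.assay_kind, "provenance": exp.provenance}
    (path / "provenance.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return path


def load_experiment(path: str | Path) -> LipidExperiment:
    path = Path(path)
    if not path.is_dir():
        raise ExperimentError(f"experiment directory not found: {path}")
    for fname in ("assay.tsv", "lipids.tsv", "samples.tsv", "provenance.json"):
        if not (path / fname).exists():
            raise ExperimentError(f"corrupt experiment directory: missing {fname}")
    assay = pd.read_csv(path / "assay.tsv", sep="\t", index_col=0)
    assay.columns.name = "sample_id"
    lipids = pd.read_csv(path / "lipids.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0, dtype=str)
    samples.index = samples.index.astype(str)
    samples.index.name = "sample_id"
    flags = None
    if (path / "flags.tsv").exists():
        flags = pd.read_csv(path / "flags.tsv", sep="\t", index_col=0).astype(bool)
        flags.columns.name = "sample_id"
    try:
        meta = json.loads((path / "provenance.json").read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ExperimentError(f"corrupt provenance.json: {exc}") from None
    # object columns read back as strings; restore booleans
    for col in ("odd_chain", "is_internal_standard"):
        if col in lipids.columns:
            lipids[col] = lipids[col].astype(bool)
    return LipidExperiment(
        assay=assay,
        lipids=lipids,
        samples=samples,
        assay_kind=meta["assay_kind"],
        provenance=meta["provenance"],
        flags=flags,
    )
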