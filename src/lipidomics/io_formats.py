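"""Readers for identification-software exports and experiment metadata files.

Supported inputs:

* LipidSearch-style per-sample exports (one delimited table per sample:
  lipid ion name, class, fatty-acid composition, retention time, peak area),
* LIQUID-style per-sample exports (same shape, different headers),
* Metabolomics Workbench mwTab text files (the ``MS_METABOLITE_DATA``
  block with its ``Samples`` / ``Factors`` lines),
* the target file (sample metadata), the internal reference file
  (per-class filtering bounds and internal-standard mapping) and
  calibration files (nominal concentration vs measured area per standard).

Exact export headers differ between software versions, so every reader
takes a :class:`ColumnMapping`; the shipped defaults are editable
configuration, not assumptions baked into the code.  Delimiters are
sniffed among tab/comma/semicolon on the header line, then locked per
file.  ``.xlsx`` input goes through a thin pandas/openpyxl adapter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import RESERVED_TARGET_COLUMNS, SampleRecord
from .nomenclature import LipidParseError, parse_lipid_name

__all__ = [
    "ColumnMapping",
    "InternalReferenceEntry",
    "ReaderError",
    "LIPIDSEARCH_MAPPING",
    "LIQUID_MAPPING",
    "read_lipidsearch",
    "read_liquid",
    "read_lipid_tables",
    "read_mwtab",
    "read_target_file",
    "read_internal_reference",
    "read_calibration_file",
]


class ReaderError(ValueError):
    """A structured input-file problem (missing column, bad cell, truncation)."""


@dataclass(frozen=True)
class ColumnMapping:
    """Maps semantic fields to source column headers for one export dialect."""

    dialect_name: str
    fields: Mapping[str, str]
    rt_units: str = "min"          # "min" or "s"
    zero_is_missing: bool = False  # some dialects export 0 for not-detected

    def __post_init__(self) -> None:
        for required in ("lipid_name", "peak_area"):
            if required not in self.fields:
                raise ValueError(f"ColumnMapping must map {required!r}")
        if self.rt_units not in ("min", "s"):
            raise ValueError("rt_units must be 'min' or 's'")


LIPIDSEARCH_MAPPING = ColumnMapping(
    dialect_name="lipidsearch",
    fields={
        "lipid_name": "LipidIon",
        "lipid_class": "Class",
        "fatty_acids": "FattyAcid",
        "retention_time_min": "Rt",
        "peak_area": "Area",
        "adduct": "Ion",
    },
)

LIQUID_MAPPING = ColumnMapping(
    dialect_name="liquid",
    fields={
        "lipid_name": "Common Name",
        "lipid_class": "Category",
        "retention_time_min": "Apex RT",
        "peak_area": "Intensity",
        "adduct": "Adduct",
    },
)


@dataclass(frozen=True)
class InternalReferenceEntry:
    """Per-class false-positive bounds and internal-standard mapping.

    Retention-time window in minutes, inclusive carbon and double-bond
    bounds on the species totals, whether odd-carbon chains are plausible
    for the class, and (optionally) the class-matched internal standard
    with its nominal spiked concentration.
    """

    lipid_class: str
    rt_min: float
    rt_max: float
    carbons_min: int
    carbons_max: int
    double_bonds_min: int
    double_bonds_max: int
    allow_odd_chains: bool = False
    internal_standard_name: Optional[str] = None
    is_nominal_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rt_min > self.rt_max:
            raise ValueError(f"{self.lipid_class}: rt_min > rt_max")
        if self.carbons_min > self.carbons_max:
            raise ValueError(f"{self.lipid_class}: carbons_min > carbons_max")
        if self.double_bonds_min > self.double_bonds_max:
            raise ValueError(f"{self.lipid_class}: double_bonds_min > double_bonds_max")


# -- generic delimited reading ---------------------------------------------------


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()
    if not header:
        raise ReaderError(f"empty file: {path}")
    line = header[0]
    counts = {sep: line.count(sep) for sep in ("\t", ",", ";")}
    sep = max(counts, key=counts.get)
    if counts[sep] == 0:
        return "\t"
    return sep


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited or spreadsheet table with delimiter sniffing."""
    path = Path(path)
    if not path.exists():
        raise ReaderError(f"file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.empty:
        raise ReaderError(f"no data rows in {path}")
    return frame


# -- identification-software exports ---------------------------------------------


def read_lipid_tables(
    files: Sequence[str | Path],
    mapping: ColumnMapping,
    *,
    known_classes: Optional[Iterable[str]] = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Read per-sample export tables into the normalized internal layout.

    Returns ``(tables, rejects)``: ``tables`` maps file basename to a
    DataFrame with columns ``canonical_name, raw_name, lipid_class,
    total_carbons, total_double_bonds, n_chains, resolution, odd_chain,
    adduct, retention_time_min, area``; ``rejects`` lists rows whose lipid
    name failed to parse (file, row number, name, error) — collected, never
    silently dropped.
    """
    tables: dict[str, pd.DataFrame] = {}
    rejects: list[dict] = []
    rt_scale = 1.0 if mapping.rt_units == "min" else 1.0 / 60.0
    for f in files:
        f = Path(f)
        frame = read_table(f)
        missing = [
            col for col in mapping.fields.values() if col not in frame.columns
        ]
        # only lipid_name and peak_area are hard requirements
        hard = {mapping.fields["lipid_name"], mapping.fields["peak_area"]}
        hard_missing = sorted(hard & set(missing))
        if hard_missing:
            raise ReaderError(
                f"{f.name}: missing mapped column(s) {hard_missing} "
                f"(dialect {mapping.dialect_name!r})"
            )
        rows = []
        name_col = mapping.fields["lipid_name"]
        area_col = mapping.fields["peak_area"]
        rt_col = mapping.fields.get("retention_time_min")
        adduct_col = mapping.fields.get("adduct")
        for i, rec in enumerate(frame.to_dict("records")):
            raw = str(rec[name_col])
            try:
                sp = parse_lipid_name(raw, known_classes=known_classes, warn_unknown_class=False)
            except LipidParseError as exc:
                rejects.append(
                    {"file": f.name, "row": i, "name": raw, "error": exc.reason}
                )
                continue
            area = rec[area_col]
            try:
                area = float(area)
            except (TypeError, ValueError):
                rejects.append(
                    {"file": f.name, "row": i, "name": raw, "error": f"non-numeric area {area!r}"}
                )
                continue
            if mapping.zero_is_missing and area == 0:
                area = math.nan
            rt = math.nan
            if rt_col and rt_col in frame.columns:
                try:
                    rt = float(rec[rt_col]) * rt_scale
                except (TypeError, ValueError):
                    rt = math.nan
            adduct = sp.adduct
            if adduct is None and adduct_col and adduct_col in frame.columns:
                val = rec.get(adduct_col)
                adduct = None if val is None or (isinstance(val, float) and math.isnan(val)) else str(val)
            rows.append(
                {
                    "canonical_name": sp.canonical_name,
                    "raw_name": raw,
                    "lipid_class": sp.lipid_class,
                    "total_carbons": sp.total_carbons,
                    "total_double_bonds": sp.total_double_bonds,
                    "n_chains": len(sp.chains),
                    "resolution": sp.resolution.value,
                    "odd_chain": _odd(sp),
                    "adduct": adduct,
                    "retention_time_min": rt,
                    "area": area,
                }
            )
        if not rows:
            raise ReaderError(f"{f.name}: no parseable lipid rows")
        tables[f.name] = pd.DataFrame(rows)
    rejects_frame = pd.DataFrame(rejects, columns=["file", "row", "name", "error"])
    return tables, rejects_frame


def _odd(sp) -> bool:
    from .nomenclature import has_odd_chain

    return has_odd_chain(sp)


def read_lipidsearch(
    files: Sequence[str | Path],
    mapping: Optional[ColumnMapping] = None,
    **kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """LipidSearch-dialect exports with the shipped default header mapping."""
    return read_lipid_tables(files, mapping or LIPIDSEARCH_MAPPING, **kwargs)


def read_liquid(
    files: Sequence[str | Path],
    mapping: Optional[ColumnMapping] = None,
    **kwargs,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """LIQUID-dialect exports with the shipped default header mapping."""
    return read_lipid_tables(files, mapping or LIQUID_MAPPING, **kwargs)


# -- Metabolomics Workbench mwTab -----------------------------------------------


def read_mwtab(path: str | Path) -> tuple[dict[str, pd.DataFrame], list[SampleRecord]]:
    """Parse the MS_METABOLITE_DATA block of an mwTab file.

    Returns per-sample tables in the normalized layout (retention time
    absent) plus :class:`SampleRecord` metadata from the ``Factors`` line.
    Factor cells follow the repository convention
    ``FactorA:level | FactorB:level``.  Only the metabolite-data named
    range is supported, not the full mwTab standard.
    """
    path = Path(path)
    if not path.exists():
        raise ReaderError(f"file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.strip().startswith("MS_METABOLITE_DATA_START")
        )
    except StopIteration:
        raise ReaderError(f"{path.name}: no MS_METABOLITE_DATA block") from None
    end = next(
        (i for i, l in enumerate(lines) if l.strip().startswith("MS_METABOLITE_DATA_END")),
        len(lines),
    )
    block = [l for l in lines[start + 1 : end] if l.strip()]
    if len(block) < 3:
        raise ReaderError(f"{path.name}: truncated MS_METABOLITE_DATA block")

    header = block[0].split("\t")
    if header[0].strip().lower() != "samples":
        raise ReaderError(f"{path.name}: expected Samples line, got {header[0]!r}")
    sample_ids = [h.strip() for h in header[1:]]

    factors_line = block[1].split("\t")
    if factors_line[0].strip().lower() != "factors":
        raise ReaderError(f"{path.name}: expected Factors line, got {factors_line[0]!r}")
    factor_cells = [c.strip() for c in factors_line[1:]]
    if len(factor_cells) != len(sample_ids):
        raise ReaderError(
            f"{path.name}: {len(sample_ids)} samples but {len(factor_cells)} factor cells"
        )

    records = []
    for sid, cell in zip(sample_ids, factor_cells):
        factors = {}
        for part in cell.split("|"):
            part = part.strip()
            if not part:
                continue
            if ":" in part:
                k, v = part.split(":", 1)
                factors[k.strip()] = v.strip()
            else:
                factors["factor"] = part
        records.append(SampleRecord(sample_id=sid, data_file=sid, factors=factors))

    data: dict[str, list[dict]] = {sid: [] for sid in sample_ids}
    for lineno, line in enumerate(block[2:], start + 4):
        cells = line.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ReaderError(
                f"{path.name} line {lineno}: expected {len(sample_ids) + 1} cells, got {len(cells)}"
            )
        raw = cells[0].strip()
        try:
            sp = parse_lipid_name(raw, warn_unknown_class=False)
        except LipidParseError:
            continue  # non-lipid metabolite rows pass through to rejects upstream
        for sid, cell in zip(sample_ids, cells[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "ND", "nan"):
                area = math.nan
            else:
                try:
                    area = float(cell)
                except ValueError:
                    raise ReaderError(
                        f"{path.name} line {lineno}: non-numeric abundance {cell!r}"
                    ) from None
            data[sid].append(
                {
                    "canonical_name": sp.canonical_name,
                    "raw_name": raw,
                    "lipid_class": sp.lipid_class,
                    "total_carbons": sp.total_carbons,
                    "total_double_bonds": sp.total_double_bonds,
                    "n_chains": len(sp.chains),
                    "resolution": sp.resolution.value,
                    "odd_chain": _odd(sp),
                    "adduct": sp.adduct,
                    "retention_time_min": math.nan,
                    "area": area,
                }
            )
    tables = {sid: pd.DataFrame(rows) for sid, rows in data.items()}
    if any(t.empty for t in tables.values()):
        raise ReaderError(f"{path.name}: no parseable metabolite rows")
    return tables, records


# -- metadata files ---------------------------------------------------------------


def read_target_file(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata table.

    Requires ``sample_id`` and ``data_file`` columns; ``batch``,
    ``replicate_role`` and ``calibration_ref`` are reserved optional
    columns, and every remaining column becomes an experimental factor.
    """
    frame = read_table(path)
    for col in ("sample_id", "data_file"):
        if col not in frame.columns:
            raise ReaderError(f"target file missing required column {col!r}")
    ids = frame["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ReaderError(
            f"duplicate sample_id(s) in target file: {sorted(ids[ids.duplicated()].unique())}"
        )
    factor_cols = [c for c in frame.columns if c not in RESERVED_TARGET_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        batch = row.get("batch")
        if batch is not None and (isinstance(batch, float) and math.isnan(batch)):
            batch = None
        role = row.get("replicate_role")
        if role is None or (isinstance(role, float) and math.isnan(role)):
            role = "biological"
        cal = row.get("calibration_ref")
        if cal is not None and (isinstance(cal, float) and math.isnan(cal)):
            cal = None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                data_file=str(row["data_file"]),
                factors={c: str(row[c]) for c in factor_cols if pd.notna(row[c])},
                batch=None if batch is None else str(batch),
                replicate_role=str(role),
                calibration_ref=None if cal is None else str(cal),
            )
        )
    return records


_REF_COLUMNS = [
    "lipid_class",
    "rt_min",
    "rt_max",
    "carbons_min",
    "carbons_max",
    "double_bonds_min",
    "double_bonds_max",
]


def read_internal_reference(path: str | Path) -> list[InternalReferenceEntry]:
    """Read the per-class internal reference file (filter bounds + IS mapping)."""
    frame = read_table(path)
    missing = [c for c in _REF_COLUMNS if c not in frame.columns]
    if missing:
        raise ReaderError(f"internal reference file missing column(s) {missing}")
    entries = []
    for i, row in frame.iterrows():
        is_name = row.get("internal_standard_name")
        if pd.isna(is_name) or is_name == "":
            is_name = None
        nominal = row.get("is_nominal_concentration")
        nominal = None if pd.isna(nominal) else float(nominal)
        allow_odd = row.get("allow_odd_chains", False)
        if isinstance(allow_odd, str):
            allow_odd = allow_odd.strip().lower() in ("1", "true", "yes")
        try:
            entries.append(
                InternalReferenceEntry(
                    lipid_class=str(row["lipid_class"]),
                    rt_min=float(row["rt_min"]),
                    rt_max=float(row["rt_max"]),
                    carbons_min=int(row["carbons_min"]),
                    carbons_max=int(row["carbons_max"]),
                    double_bonds_min=int(row["double_bonds_min"]),
                    double_bonds_max=int(row["double_bonds_max"]),
                    allow_odd_chains=bool(allow_odd),
                    internal_standard_name=None if is_name is None else str(is_name),
                    is_nominal_concentration=nominal,
                )
            )
        except ValueError as exc:
            raise ReaderError(f"internal reference row {i}: {exc}") from None
    return entries


def read_calibration_file(path: str | Path) -> pd.DataFrame:
    """Read a calibration file into long-format triples.

    Expected columns: ``standard_name``, ``concentration``, ``area`` (one
    row per dilution level per standard).  Standards with fewer than two
    distinct levels trigger a warning here and an error at fit time.
    """
    import warnings

    frame = read_table(path)
    missing = [c for c in ("standard_name", "concentration", "area") if c not in frame.columns]
    if missing:
        raise ReaderError(f"calibration file missing column(s) {missing}")
    for col in ("concentration", "area"):
        for i, val in frame[col].items():
            try:
                float(val)
            except (TypeError, ValueError):
                raise ReaderError(
                    f"calibration file: non-numeric {col} at row {i}: {val!r}"
                ) from None
    frame = frame.assign(
        standard_name=frame["standard_name"].astype(str),
        concentration=frame["concentration"].astype(float),
        area=frame["area"].astype(float),
    )[["standard_name", "concentration", "area"]]
    for name, grp in frame.groupby("standard_name"):
        if grp["concentration"].nunique() < 2:
            warnings.warn(
                f"standard {name!r} has fewer than 2 distinct concentration levels; "
                "curve fitting will fail"
            )
    return frame
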