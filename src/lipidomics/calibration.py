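"""Internal-standard calibration: curves, linearity, recovery, normalization.

Each internal standard (IS) is a known lipid spiked into every sample at a
nominal concentration before extraction.  A dilution series of the pure
standard gives a calibration curve — an ordinary least-squares line of
measured peak area on nominal concentration — whose inverse converts
analyte areas into concentrations.  Instrument response is only linear
over part of the concentration range (detectors saturate at the top), so
the curve carries an explicit linear range: the longest contiguous run of
dilution levels whose fit reaches an r² threshold, found by trimming the
highest level first.

Because the IS is spiked at a *known* concentration, its measured
concentration in each sample estimates that sample's recovery — the
combined extraction and instrument efficiency:

    recovery% = 100 x measured IS concentration / nominal IS concentration

Dividing each analyte concentration by its class-matched standard's
recovery (as a fraction) cancels sample-wide intensity drift and puts all
samples on a common absolute-concentration scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExperimentError, LipidExperiment
from .io_formats import InternalReferenceEntry

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "RecoveryTable",
    "fit_calibration_curve",
    "fit_all_curves",
    "area_to_concentration",
    "compute_recovery",
    "normalize_by_recovery",
    "is_mapping_from_reference",
]

logger = logging.getLogger(__name__)

RECOVERY_PLAUSIBLE = (10.0, 200.0)  # percent; outside -> flagged, not dropped


class CalibrationError(ValueError):
    """Curve cannot be fitted or applied (too few levels, no linear run, ...)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response line and linearity range for one internal standard."""

    standard_name: str
    slope: float            # area per concentration unit
    intercept: float        # area
    r_squared: float
    linear_range: tuple[float, float]
    n_levels_used: int
    levels_excluded: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"{self.standard_name}: accepted curve requires positive slope "
                f"(got {self.slope:.4g})"
            )
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError(f"{self.standard_name}: r_squared outside [0, 1]")
        if not self.linear_range[0] < self.linear_range[1]:
            raise CalibrationError(f"{self.standard_name}: degenerate linear range")
        if self.n_levels_used < 2:
            raise CalibrationError(f"{self.standard_name}: need >= 2 levels")


def _ols(conc: np.ndarray, area: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(conc, area)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_calibration_curve(
    points: Sequence[tuple[float, float]],
    r2_threshold: float = 0.98,
    standard_name: str = "IS",
) -> CalibrationCurve:
    """Fit an OLS calibration line and determine its linear range.

    ``points`` are (nominal_concentration, measured_area) pairs; replicate
    areas per level are allowed.  The linear range is the largest
    contiguous run of at least 3 dilution levels (all levels when only
    2-3 exist) whose own OLS fit attains ``r_squared >= r2_threshold``.
    Saturation at the top of the series is the expected failure mode, so
    candidate runs trim the highest level first, then the lowest.
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise CalibrationError(f"{standard_name}: need >= 2 calibration points")
    if (pts[:, 1] < 0).any():
        raise CalibrationError(f"{standard_name}: negative measured area")
    levels = np.unique(pts[:, 0])
    if len(levels) < 2:
        raise CalibrationError(
            f"{standard_name}: need >= 2 distinct concentration levels, got {len(levels)}"
        )

    def fit_window(lo: int, hi: int):  # levels[lo:hi] inclusive-exclusive
        sel = (pts[:, 0] >= levels[lo]) & (pts[:, 0] <= levels[hi - 1])
        return _ols(pts[sel, 0], pts[sel, 1])

    n = len(levels)
    min_len = min(3, n)
    # Candidate windows: longest first; within a length, top-trimmed first
    # (ascending start index == more high levels removed).
    for length in range(n, min_len - 1, -1):
        for start in range(0, n - length + 1):
            slope, intercept, r2 = fit_window(start, start + length)
            if r2 >= r2_threshold and slope > 0:
                excluded = tuple(np.concatenate([levels[:start], levels[start + length :]]))
                return CalibrationCurve(
                    standard_name=standard_name,
                    slope=slope,
                    intercept=intercept,
                    r_squared=r2,
                    linear_range=(float(levels[start]), float(levels[start + length - 1])),
                    n_levels_used=length,
                    levels_excluded=excluded,
                )
    raise CalibrationError(
        f"{standard_name}: no contiguous run of >= {min_len} levels reaches "
        f"r_squared >= {r2_threshold}; calibration series needs manual review"
    )


def fit_all_curves(
    calibration: pd.DataFrame, r2_threshold: float = 0.98
) -> dict[str, CalibrationCurve]:
    """Fit one curve per standard from a long-format calibration table."""
    curves = {}
    for name, grp in calibration.groupby("standard_name"):
        curves[name] = fit_calibration_curve(
            list(zip(grp["concentration"], grp["area"])),
            r2_threshold=r2_threshold,
            standard_name=name,
        )
    return curves


def area_to_concentration(
    area: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Invert the calibration line: ``(area - intercept) / slope``.

    Returns ``(concentration, in_range)``.  A negative result (area below
    the intercept) becomes NaN with a log entry; ``in_range`` is False
    outside the curve's linear range.
    """
    if np.isnan(area):
        return np.nan, True
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        logger.info(
            "%s: area %.4g below intercept %.4g -> concentration set to missing",
            curve.standard_name, area, curve.intercept,
        )
        return np.nan, False
    in_range = curve.linear_range[0] <= conc <= curve.linear_range[1]
    return float(conc), bool(in_range)


@dataclass
class RecoveryTable:
    """Per-(sample, standard) recovery percentages with plausibility flags."""

    table: pd.DataFrame  # samples x standards, percent
    flagged: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def per_sample_mean(self) -> pd.Series:
        return self.table.mean(axis=1, skipna=True)

    def get(self, sample_id: str, standard_name: str) -> float:
        return float(self.table.at[sample_id, standard_name])


def compute_recovery(
    exp: LipidExperiment,
    reference: Sequence[InternalReferenceEntry],
    curves: Mapping[str, CalibrationCurve],
) -> RecoveryTable:
    """Estimate per-sample recovery from the spiked internal standards.

    For each IS species present in the experiment, its measured area in a
    sample is converted to a concentration through that standard's curve
    and divided by the nominal spiked concentration from the reference
    file.  Missing IS measurements yield missing recoveries with a
    warning; a standard without a nominal concentration is an error.
    """
    nominal = {
        e.internal_standard_name: e.is_nominal_concentration
        for e in reference
        if e.internal_standard_name is not None
    }
    is_rows = exp.lipids.index[exp.lipids["is_internal_standard"].astype(bool)]
    standards = [n for n in is_rows if n in curves]
    if not standards:
        raise CalibrationError("no internal-standard rows matching a fitted curve")
    table = pd.DataFrame(
        np.nan, index=pd.Index(exp.sample_ids, name="sample_id"),
        columns=pd.Index(standards, name="standard_name"),
    )
    flagged = []
    for name in standards:
        if nominal.get(name) is None:
            raise CalibrationError(f"internal standard {name!r} has no nominal concentration")
        curve = curves[name]
        areas = exp.assay.loc[name]
        if isinstance(areas, pd.DataFrame):  # duplicate IS rows: use the first
            areas = areas.iloc[0]
        for sid in exp.sample_ids:
            area = float(areas[sid])
            if np.isnan(area):
                warnings.warn(f"IS {name!r} missing in sample {sid!r}; recovery missing")
                continue
            conc, _ = area_to_concentration(area, curve)
            if np.isnan(conc):
                continue
            rec = 100.0 * conc / nominal[name]
            table.at[sid, name] = rec
            if not (RECOVERY_PLAUSIBLE[0] <= rec <= RECOVERY_PLAUSIBLE[1]):
                flagged.append((sid, name, rec))
    return RecoveryTable(table=table, flagged=flagged)


def is_mapping_from_reference(
    reference: Sequence[InternalReferenceEntry],
) -> dict[str, str]:
    """Class -> internal-standard-name mapping from the reference file."""
    return {
        e.lipid_class: e.internal_standard_name
        for e in reference
        if e.internal_standard_name is not None
    }


def normalize_by_recovery(
    exp: LipidExperiment,
    curves: Mapping[str, CalibrationCurve],
    recovery: RecoveryTable,
    is_mapping: Mapping[str, str],
    fallback: str = "error",
) -> LipidExperiment:
    """Convert raw areas to recovery-normalized concentrations.

    Each analyte's area becomes a concentration through its class-matched
    standard's curve, then is divided by that standard's recovery fraction
    in the same sample.  Internal-standard rows are removed from the
    analyte matrix (their names are archived in the provenance record).
    Out-of-linear-range values are kept but flagged in ``exp.flags``.

    ``fallback`` for classes with no mapped standard: ``"error"``
    (default — silent misnormalization is worse than failure) or
    ``"skip_normalization"`` (areas kept as NaN concentration, logged).
    """
    if exp.assay_kind != "raw_area":
        raise ExperimentError("normalization expects a raw_area experiment")
    if fallback not in ("error", "skip_normalization"):
        raise ExperimentError(f"unknown fallback {fallback!r}")

    is_mask = exp.lipids["is_internal_standard"].astype(bool).to_numpy()
    analyte_idx = np.flatnonzero(~is_mask)
    archived = [str(n) for n in exp.assay.index[is_mask]]

    assay = exp.assay.to_numpy(dtype=float)
    out = np.full((len(analyte_idx), exp.n_samples), np.nan)
    flags = np.zeros_like(out, dtype=bool)
    classes = exp.lipids["lipid_class"].to_numpy()
    skipped_classes: set[str] = set()

    for r, i in enumerate(analyte_idx):
        cls = classes[i]
        std = is_mapping.get(cls)
        if std is None or std not in curves:
            if fallback == "error":
                raise CalibrationError(
                    f"lipid class {cls!r} has no mapped internal-standard curve"
                )
            skipped_classes.add(cls)
            continue
        curve = curves[std]
        for c, sid in enumerate(exp.sample_ids):
            area = assay[i, c]
            if np.isnan(area):
                continue
            conc, in_range = area_to_concentration(area, curve)
            if np.isnan(conc):
                continue
            rec = recovery.table.at[sid, std] if std in recovery.table.columns else np.nan
            if np.isnan(rec):
                logger.warning(
                    "recovery missing for (sample %s, standard %s); cell set to missing",
                    sid, std,
                )
                continue
            out[r, c] = conc / (rec / 100.0)
            flags[r, c] = not in_range

    if skipped_classes:
        logger.warning("classes left unnormalized (no IS): %s", sorted(skipped_classes))

    index = exp.assay.index[analyte_idx]
    new = exp.with_log(
        "normalize_by_recovery",
        {
            "standards": sorted(set(is_mapping.values())),
            "archived_internal_standards": archived,
            "skipped_classes": sorted(skipped_classes),
        },
        assay=pd.DataFrame(out, index=index, columns=exp.assay.columns),
        lipids=exp.lipids.iloc[analyte_idx].copy(),
        flags=pd.DataFrame(flags, index=index, columns=exp.assay.columns),
    )
    new.assay_kind = "normalized_concentration"
    return new
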