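"""End-to-end orchestration: import -> filter -> calibrate -> impute -> explore -> test.

A single JSON or YAML config names the input files and per-stage
parameters; :func:`run_pipeline` executes the stages in order, skips
calibration when no calibration file is configured (area-only mode), and
writes a run report (per-stage counts, parameters, warnings) alongside
the analysis outputs.  Any stage error aborts with the stage name.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import containers, differential, exploratory, filtering, imputation, io_formats

__all__ = ["PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineError("config", f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


_DIALECTS = {
    "lipidsearch": io_formats.read_lipidsearch,
    "liquid": io_formats.read_liquid,
}


def run_pipeline(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Run the whole workflow from a config mapping or config-file path.

    Returns the run report (also written to ``run_report.json`` /
    ``run_report.md`` under the output directory).  Raises
    :class:`PipelineError` naming the failing stage on any error.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "lipidomics_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": {}, "warnings": []}

    def _stage(name: str, **info) -> None:
        report["stages"][name] = {"status": "ok", **info}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- import ------------------------------------------------------
        try:
            fmt = config.get("format", "lipidsearch")
            data_dir = Path(config.get("data_dir", "."))
            targets = io_formats.read_target_file(data_dir / config["targets"])
            reference = None
            if config.get("reference"):
                reference = io_formats.read_internal_reference(data_dir / config["reference"])
            is_names = [
                e.internal_standard_name
                for e in (reference or [])
                if e.internal_standard_name
            ]
            if fmt == "mwtab":
                tables, records = io_formats.read_mwtab(data_dir / config["data"])
                if not config.get("targets"):
                    targets = records
                rejects = pd.DataFrame()
            else:
                reader = _DIALECTS.get(fmt)
                if reader is None:
                    raise io_formats.ReaderError(f"unknown input format {fmt!r}")
                mapping = None
                if config.get("mapping"):
                    mdata = load_config(data_dir / config["mapping"])
                    mapping = io_formats.ColumnMapping(**mdata)
                files = [data_dir / t.data_file for t in targets]
                tables, rejects = reader(files, mapping)
            exp = containers.build_experiment(
                tables, targets, internal_standard_names=is_names
            )
            if len(rejects):
                rejects.to_csv(out_dir / "rejects.tsv", sep="\t", index=False)
            _stage(
                "import",
                n_lipids=exp.n_lipids,
                n_samples=exp.n_samples,
                n_rejects=int(len(rejects)),
            )
        except (OSError, KeyError, ValueError) as exc:
            raise PipelineError("import", str(exc)) from exc

        # ---- filter ------------------------------------------------------
        try:
            fcfg = config.get("filter", {})
            reports = {}
            if reference is not None:
                policy = filtering.FilterPolicy(
                    unlisted_class=fcfg.get("unlisted_class", "keep_with_warning")
                )
                exp, rep = filtering.filter_by_reference(exp, reference, policy)
                reports["reference"] = rep.summary()
            exp, rep = filtering.deduplicate_lipids(
                exp, policy=fcfg.get("dedup", "keep_max_area")
            )
            reports["duplicates"] = rep.summary()
            max_missing = fcfg.get("max_missing", 0.3)
            exp, rep = filtering.filter_missingness(
                exp,
                max_missing,
                scope=fcfg.get("missing_scope", "overall"),
                group_factor=fcfg.get("missing_group_factor"),
            )
            reports["missingness"] = rep.summary()
            pd.DataFrame(
                [
                    {"stage": k, **v["by_rule"]}
                    for k, v in reports.items()
                    if v.get("by_rule")
                ]
            ).to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
            _stage("filter", n_lipids=exp.n_lipids, reports=reports)
        except ValueError as exc:
            raise PipelineError("filter", str(exc)) from exc

        # ---- calibrate ---------------------------------------------------
        calibrated = False
        try:
            if config.get("calibration") and reference is not None:
                ccfg = config.get("calibrate", {})
                calib = io_formats.read_calibration_file(
                    data_dir / config["calibration"]
                )
                curves = cal.fit_all_curves(
                    calib, r2_threshold=ccfg.get("r2_threshold", 0.98)
                )
                recovery = cal.compute_recovery(exp, reference, curves)
                exp = cal.normalize_by_recovery(
                    exp,
                    curves,
                    recovery,
                    cal.is_mapping_from_reference(reference),
                    fallback=ccfg.get("fallback", "error"),
                )
                pd.DataFrame(
                    [
                        {
                            "standard_name": c.standard_name,
                            "slope": c.slope,
                            "intercept": c.intercept,
                            "r_squared": c.r_squared,
                            "range_min": c.linear_range[0],
                            "range_max": c.linear_range[1],
                            "n_levels_used": c.n_levels_used,
                        }
                        for c in curves.values()
                    ]
                ).to_csv(out_dir / "curves.tsv", sep="\t", index=False)
                recovery.table.to_csv(out_dir / "recovery.tsv", sep="\t")
                calibrated = True
                _stage(
                    "calibrate",
                    n_standards=len(curves),
                    mean_recovery_percent=float(recovery.per_sample_mean.mean()),
                )
            else:
                report["stages"]["calibrate"] = {
                    "status": "skipped (no IS)",
                }
        except ValueError as exc:
            raise PipelineError("calibrate", str(exc)) from exc

        # ---- impute + transform -----------------------------------------
        try:
            icfg = config.get("impute", {})
            if config.get("aggregate_technical", True):
                roles = exp.samples["replicate_role"]
                if (roles == "technical").any():
                    exp = containers.aggregate_technical_replicates(exp)
            exp = imputation.impute(
                exp, method=icfg.get("method", "half_min"), k=icfg.get("k", 5)
            )
            exp = containers.log2_transform(exp)
            _stage("impute", method=icfg.get("method", "half_min"))
        except ValueError as exc:
            raise PipelineError("impute", str(exc)) from exc

        # ---- explore -----------------------------------------------------
        try:
            ecfg = config.get("explore", {})
            n_comp = int(ecfg.get("pca_components", 2))
            n_comp = min(n_comp, exp.n_samples - 1, exp.n_lipids)
            pca = exploratory.run_pca(exp, n_components=n_comp)
            pca.scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
            pca.loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t")
            info = {"pca_explained": [float(v) for v in pca.explained_variance]}
            if ecfg.get("plsda_factor"):
                pls = exploratory.run_plsda(
                    exp, ecfg["plsda_factor"], n_components=n_comp
                )
                pls.scores.to_csv(out_dir / "plsda_scores.tsv", sep="\t")
                info["plsda_explained"] = [float(v) for v in pls.explained_variance]
            for by in ("class", "chain_length", "double_bonds"):
                exploratory.summary_profiles(exp, by=by, statistic="total").to_csv(
                    out_dir / f"profile_{by}.tsv", sep="\t"
                )
            _stage("explore", **info)
        except ValueError as exc:
            raise PipelineError("explore", str(exc)) from exc

        # ---- test --------------------------------------------------------
        try:
            tcfg = config.get("test", {})
            if tcfg:
                design = differential.DesignSpec(
                    factors=tuple(tcfg.get("factors", ["condition"])),
                    contrast=tuple(tcfg["contrast"]),
                    batch_mode=tcfg.get("batch_mode", "none"),
                )
                diff = differential.fit_differential(exp, design)
                diff.to_csv(out_dir / "differential.tsv", sep="\t")
                alpha = float(tcfg.get("alpha", 0.05))
                enrich = differential.enrich_lipid_sets(diff, exp.lipids, alpha=alpha)
                enrich.to_csv(out_dir / "enrichment.tsv", sep="\t")
                ma, volcano = differential.ma_volcano_tables(diff, alpha=alpha)
                ma.to_csv(out_dir / "ma.tsv", sep="\t")
                volcano.to_csv(out_dir / "volcano.tsv", sep="\t")
                _stage(
                    "test",
                    contrast=diff["contrast"].iloc[0],
                    n_significant=int((diff["adjusted_p"] < alpha).sum()),
                    n_enriched_sets=int((enrich["adjusted_p"] < alpha).sum())
                    if len(enrich)
                    else 0,
                )
            else:
                report["stages"]["test"] = {"status": "skipped (no design)"}
        except ValueError as exc:
            raise PipelineError("test", str(exc)) from exc

        containers.save_experiment(exp, out_dir / "experiment")
        report["warnings"] = [str(w.message) for w in caught]

    report["assay_kind"] = exp.assay_kind
    report["calibrated"] = calibrated
    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=2, default=str), encoding="utf-8"
    )
    lines = ["# Run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if report["warnings"]:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in report["warnings"])
    (out_dir / "run_report.md").write_text("\n".join(lines), encoding="utf-8")
    return report
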