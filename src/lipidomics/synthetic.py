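"""Ground-truth simulator for the full quantification workflow.

The generator emulates a LipidSearch-style internal-standard experiment
end to end: per-lipid true concentrations with planted group effects and
batch shifts, a planted linear instrument response per lipid class, a
planted per-sample recovery, multiplicative log-normal measurement noise,
and left-censored missingness (peak areas below a quantile of each
sample's analyte areas are not reported — the physically expected
mechanism for values under the detection limit).  It writes the complete
input file set (per-sample exports, target file, internal reference file,
calibration series) and returns the ground truth, so every pipeline stage
can be tested against known answers without any external data.

Deliberate decoys — odd-chain species and species outside the per-class
carbon/double-bond/retention-time bounds — are planted so the filtering
stage has true positives to remove; they are excluded from the
differential ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .containers import LipidExperiment, SampleRecord, build_experiment
from .io_formats import InternalReferenceEntry

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "make_experiment",
    "simulate_log2_experiment",
    "simulate_annotation",
]


# Per-class simulation profile: plausible chain-carbon range (even values),
# double-bond range, retention-time window (minutes) and IS chain.
_CLASS_PROFILES = {
    "PC": {"carbons": (28, 44), "db": (0, 8), "rt": (10.0, 14.0), "is_name": "PC(14:0/14:0)", "n_chains": 2},
    "PE": {"carbons": (28, 44), "db": (0, 8), "rt": (9.0, 13.0), "is_name": "PE(14:0/14:0)", "n_chains": 2},
    "PG": {"carbons": (28, 44), "db": (0, 8), "rt": (7.0, 11.0), "is_name": "PG(14:0/14:0)", "n_chains": 2},
    "TG": {"carbons": (42, 60), "db": (0, 10), "rt": (16.0, 20.0), "is_name": "TG(14:0/14:0/14:0)", "n_chains": 3},
    "Cer": {"carbons": (32, 44), "db": (0, 3), "rt": (12.0, 16.0), "is_name": "Cer(d18:1/12:0)", "n_chains": 2},
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated study; the seed fixes outputs byte-for-byte.

    Defaults describe a small two-group internal-standard experiment:
    12 samples in two balanced groups across two balanced batches,
    multiplicative log-normal measurement noise of sigma = 0.05 on areas,
    between-sample biological spread of 0.4 on the log2 scale, planted
    differential effects of log2FC 1.5 on 10% of analytes, per-sample
    recoveries around 70-90%, and 10% left-censored missingness.
    """

    classes: tuple[str, ...] = ("PC", "PE", "TG", "Cer")
    n_lipids_per_class: int = 25
    n_samples: int = 12
    n_groups: int = 2
    n_batches: int = 2
    effect_fraction: float = 0.10
    effect_log2fc: float = 1.5
    bio_sigma: float = 0.4          # log2-scale between-sample SD
    noise_sigma: float = 0.05       # multiplicative log-normal on areas (natural log SD)
    censor_quantile: float = 0.10   # left-censoring of per-sample analyte areas
    recovery_range: tuple[float, float] = (0.7, 0.9)
    recovery: Optional[Mapping[str, float]] = None  # fixed per-sample override
    batch_log2_shift: float = 0.0
    n_decoys_per_class: int = 2     # per decoy rule (odd chain / out of bounds)
    n_calibration_levels: int = 6
    calibration_noise_sigma: float = 0.0
    saturate_top_level: bool = False  # plant detector saturation at the top level
    nominal_is_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censor_quantile < 1):
            raise ValueError("censor_quantile must be in [0, 1)")
        if not (0 <= self.effect_fraction <= 1):
            raise ValueError("effect_fraction must be in [0, 1]")
        unknown = [c for c in self.classes if c not in _CLASS_PROFILES]
        if unknown:
            raise ValueError(f"no simulation profile for class(es) {unknown}")
        if self.n_samples % self.n_groups:
            raise ValueError("n_samples must divide evenly into n_groups")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if "classes" in data:
            data["classes"] = tuple(data["classes"])
        if "recovery_range" in data:
            data["recovery_range"] = tuple(data["recovery_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Everything the generator planted, for comparison after analysis."""

    config: SimulationConfig
    true_concentration: pd.DataFrame      # analytes (incl. decoys) x samples
    effects: pd.Series                    # log2FC per analyte (0 = null)
    da_lipids: list[str]                  # names with planted effects
    decoys: dict[str, list[str]]          # rule -> planted false-positive names
    recoveries: pd.Series                 # per sample, fraction
    curves: dict[str, tuple[float, float]]  # IS name -> (slope, intercept)
    reference: list[InternalReferenceEntry]
    targets: list[SampleRecord]
    files: dict[str, Path] = field(default_factory=dict)


def _make_names(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[list[dict], dict[str, list[str]]]:
    """Sample distinct analyte species per class, plus filter decoys."""
    rows: list[dict] = []
    decoys: dict[str, list[str]] = {"odd_chain": [], "carbon_bounds": [], "rt_window": []}
    for cls in cfg.classes:
        prof = _CLASS_PROFILES[cls]
        lo, hi = prof["carbons"]
        seen: set[str] = {prof["is_name"]}  # IS names must stay distinct from analytes
        n_made = 0
        attempts = 0
        while n_made < cfg.n_lipids_per_class:
            attempts += 1
            if attempts > 200 * cfg.n_lipids_per_class:
                raise ValueError(
                    f"cannot draw {cfg.n_lipids_per_class} distinct {cls} species; "
                    "reduce n_lipids_per_class"
                )
            total_c = int(rng.integers(lo // 2, hi // 2 + 1)) * 2
            max_db = min(prof["db"][1], total_c // 6)
            total_db = int(rng.integers(prof["db"][0], max_db + 1))
            name = _species_name(cls, total_c, total_db, prof, rng)
            if name in seen:
                continue
            seen.add(name)
            rt = float(rng.uniform(*prof["rt"]))
            rows.append({"name": name, "class": cls, "rt": rt, "decoy": None})
            n_made += 1
        for _ in range(cfg.n_decoys_per_class):
            # odd-chain decoy: one chain with odd carbons, totals still inside
            # the class carbon bounds so the odd-chain rule (last in order) fires
            total_c = int(rng.integers(lo // 2, hi // 2)) * 2 + 1
            name = _species_name(cls, total_c, 1, prof, rng, force_odd=True)
            if name in seen:
                continue
            seen.add(name)
            rows.append(
                {"name": name, "class": cls, "rt": float(rng.uniform(*prof["rt"])), "decoy": "odd_chain"}
            )
            decoys["odd_chain"].append(name)
        for _ in range(cfg.n_decoys_per_class):
            # out-of-bounds carbons decoy
            total_c = hi + 2 * int(rng.integers(2, 5))
            name = _species_name(cls, total_c, 0, prof, rng)
            if name in seen:
                continue
            seen.add(name)
            rows.append(
                {"name": name, "class": cls, "rt": float(rng.uniform(*prof["rt"])), "decoy": "carbon_bounds"}
            )
            decoys["carbon_bounds"].append(name)
        for _ in range(cfg.n_decoys_per_class):
            # retention-time decoy: plausible composition, wrong elution window
            total_c = int(rng.integers(lo // 2, hi // 2 + 1)) * 2
            name = _species_name(cls, total_c, 0, prof, rng)
            if name in seen:
                continue
            seen.add(name)
            rt = prof["rt"][1] + float(rng.uniform(2.0, 5.0))
            rows.append({"name": name, "class": cls, "rt": rt, "decoy": "rt_window"})
            decoys["rt_window"].append(name)
    return rows, decoys


_CER_BASES = ((18, 1), (18, 0), (16, 1), (18, 2))


def _species_name(
    cls: str,
    total_c: int,
    total_db: int,
    prof: dict,
    rng: np.random.Generator,
    force_odd: bool = False,
) -> str:
    """Chain-resolved shorthand name with the requested totals."""
    n_chains = prof["n_chains"]
    if cls == "Cer":
        base_c, base_db = _CER_BASES[int(rng.integers(0, len(_CER_BASES)))]
        c2 = total_c - base_c
        if force_odd and c2 % 2 == 0:
            c2 += 1
        db2 = max(0, total_db - base_db)
        return f"Cer(d{base_c}:{base_db}/{c2}:{db2})"
    cs = _split_total(total_c, n_chains, rng, force_odd=force_odd)
    dbs = _split_total(total_db, n_chains, rng, allow_zero=True)
    chains = "/".join(f"{c}:{min(d, c // 2)}" for c, d in zip(cs, dbs))
    return f"{cls}({chains})"


def _split_total(
    total: int, k: int, rng: np.random.Generator, allow_zero: bool = False, force_odd: bool = False
) -> list[int]:
    if allow_zero:
        parts = [0] * k
        for _ in range(total):
            parts[int(rng.integers(0, k))] += 1
        return parts
    # carbons split into even-length chains (biological chains come in pairs
    # of carbons); an odd total puts its leftover carbon on chain 0
    pairs = total // 2
    base = pairs // k
    parts = [2 * base] * k
    for i in range(pairs - base * k):
        parts[i % k] += 2
    # random even redistribution so chain pairs vary for a given total
    delta = 2 * int(rng.integers(0, 4))
    if parts[-1] - delta >= 8:
        parts[0] += delta
        parts[-1] -= delta
    if total % 2:
        parts[0] += 1
    elif force_odd:
        parts[0] += 1
        parts[1] -= 1
    return parts


def simulate_truth(cfg: SimulationConfig) -> GroundTruth:
    """Draw the planted quantities (no files, no measurement layer)."""
    rng = np.random.default_rng(cfg.seed)
    rows, decoys = _make_names(cfg, rng)
    names = [r["name"] for r in rows]
    classes = {r["name"]: r["class"] for r in rows}
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    per_group = cfg.n_samples // cfg.n_groups
    groups = {sid: f"G{(i // per_group) + 1}" for i, sid in enumerate(sample_ids)}
    batches = {sid: f"B{(i % cfg.n_batches) + 1}" for i, sid in enumerate(sample_ids)}

    # planted effects only on non-decoy analytes
    candidates = [r["name"] for r in rows if r["decoy"] is None]
    n_da = int(round(cfg.effect_fraction * len(candidates)))
    da = list(rng.choice(candidates, size=n_da, replace=False)) if n_da else []
    effects = pd.Series(0.0, index=pd.Index(names, name="lipid"))
    for i, name in enumerate(da):
        effects[name] = cfg.effect_log2fc if i % 2 == 0 else -cfg.effect_log2fc

    base_log2 = pd.Series(rng.uniform(0.0, 4.0, size=len(names)), index=effects.index)
    conc = np.empty((len(names), cfg.n_samples))
    for j, sid in enumerate(sample_ids):
        shift = np.where(np.array([groups[sid] == "G2"]), 1.0, 0.0)[0]
        batch_shift = cfg.batch_log2_shift * (1.0 if batches[sid] == "B1" else -1.0)
        log2c = (
            base_log2.to_numpy()
            + effects.to_numpy() * shift
            + batch_shift
            + rng.normal(0.0, cfg.bio_sigma, size=len(names))
        )
        conc[:, j] = 2.0**log2c
    true_conc = pd.DataFrame(conc, index=effects.index, columns=sample_ids)

    if cfg.recovery is not None:
        recov = pd.Series({sid: float(cfg.recovery[sid]) for sid in sample_ids})
    else:
        recov = pd.Series(
            rng.uniform(*cfg.recovery_range, size=cfg.n_samples), index=sample_ids
        )
    recov.index.name = "sample_id"

    curves = {}
    reference = []
    for cls in cfg.classes:
        prof = _CLASS_PROFILES[cls]
        slope = float(rng.uniform(2e4, 6e4))
        intercept = float(rng.uniform(0.0, 500.0))
        curves[prof["is_name"]] = (slope, intercept)
        reference.append(
            InternalReferenceEntry(
                lipid_class=cls,
                rt_min=prof["rt"][0],
                rt_max=prof["rt"][1],
                carbons_min=prof["carbons"][0],
                carbons_max=prof["carbons"][1],
                double_bonds_min=prof["db"][0],
                double_bonds_max=prof["db"][1],
                allow_odd_chains=False,
                internal_standard_name=prof["is_name"],
                is_nominal_concentration=cfg.nominal_is_concentration,
            )
        )

    targets = [
        SampleRecord(
            sample_id=sid,
            data_file=f"{sid}.tsv",
            factors={"condition": groups[sid]},
            batch=batches[sid],
            replicate_role="biological",
            calibration_ref="calib.tsv",
        )
        for sid in sample_ids
    ]
    rts = {r["name"]: r["rt"] for r in rows}
    truth = GroundTruth(
        config=cfg,
        true_concentration=true_conc,
        effects=effects,
        da_lipids=da,
        decoys=decoys,
        recoveries=recov,
        curves=curves,
        reference=reference,
        targets=targets,
    )
    truth._rts = rts  # retention times, used by the measurement layer
    truth._rng_state = rng  # continue the same stream for measurement noise
    return truth


def _measure(
    truth: GroundTruth,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Apply the measurement layer: response curve, recovery, noise, censoring.

    Returns per-sample export tables (internal layout of the readers) and
    the calibration table.
    """
    cfg = truth.config
    rng = truth._rng_state
    rts = truth._rts
    class_of = {}
    for entry in truth.reference:
        class_of[entry.lipid_class] = entry
    is_of_class = {e.lipid_class: e.internal_standard_name for e in truth.reference}

    tables: dict[str, pd.DataFrame] = {}
    lipid_classes = {
        name: name.split("(", 1)[0] for name in truth.true_concentration.index
    }
    for sid in truth.true_concentration.columns:
        rows = []
        rec = truth.recoveries[sid]
        for name in truth.true_concentration.index:
            cls = lipid_classes[name]
            slope, intercept = truth.curves[is_of_class[cls]]
            conc = truth.true_concentration.at[name, sid]
            noise = float(np.exp(rng.normal(0.0, cfg.noise_sigma))) if cfg.noise_sigma > 0 else 1.0
            area = (slope * conc * rec + intercept) * noise
            rows.append({"name": name, "class": cls, "rt": rts[name], "area": area, "is": False})
        # spiked internal standards measured in the same run
        for entry in truth.reference:
            slope, intercept = truth.curves[entry.internal_standard_name]
            noise = float(np.exp(rng.normal(0.0, cfg.noise_sigma))) if cfg.noise_sigma > 0 else 1.0
            area = (slope * entry.is_nominal_concentration * rec + intercept) * noise
            rt = (entry.rt_min + entry.rt_max) / 2.0
            rows.append(
                {"name": entry.internal_standard_name, "class": entry.lipid_class,
                 "rt": rt, "area": area, "is": True}
            )
        frame = pd.DataFrame(rows)
        if cfg.censor_quantile > 0:
            analyte = ~frame["is"]
            cutoff = frame.loc[analyte, "area"].quantile(cfg.censor_quantile)
            frame = frame[frame["is"] | (frame["area"] > cutoff)].reset_index(drop=True)
        tables[sid] = frame

    levels = cfg.nominal_is_concentration * (2.0 ** np.arange(-3, cfg.n_calibration_levels - 3))
    cal_rows = []
    for entry in truth.reference:
        slope, intercept = truth.curves[entry.internal_standard_name]
        for li, level in enumerate(levels):
            area = slope * level + intercept
            if cfg.saturate_top_level and li == len(levels) - 1:
                area = slope * levels[-2] * 1.05 + intercept  # detector saturation
            if cfg.calibration_noise_sigma > 0:
                area *= float(np.exp(rng.normal(0.0, cfg.calibration_noise_sigma)))
            cal_rows.append(
                {"standard_name": entry.internal_standard_name,
                 "concentration": level, "area": area}
            )
    calibration = pd.DataFrame(cal_rows)
    return tables, calibration


def generate(cfg: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Simulate a study and write the complete input file set.

    Writes one LipidSearch-dialect TSV per sample, ``target.tsv``,
    ``reference.tsv`` and ``calib.tsv`` under ``out_dir``; identical
    configs (same seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(cfg)
    tables, calibration = _measure(truth)

    for sid, frame in tables.items():
        export = pd.DataFrame(
            {
                "LipidIon": frame["name"],
                "Class": frame["class"],
                "FattyAcid": [n.split("(", 1)[1].rstrip(")") for n in frame["name"]],
                "Rt": frame["rt"].round(4),
                "Area": frame["area"].round(6),
            }
        )
        path = out_dir / f"{sid}.tsv"
        export.to_csv(path, sep="\t", index=False)
        truth.files[sid] = path

    target = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truth.targets],
            "data_file": [t.data_file for t in truth.targets],
            "condition": [t.factors["condition"] for t in truth.targets],
            "batch": [t.batch for t in truth.targets],
            "replicate_role": [t.replicate_role for t in truth.targets],
            "calibration_ref": [t.calibration_ref for t in truth.targets],
        }
    )
    target.to_csv(out_dir / "target.tsv", sep="\t", index=False)
    truth.files["target"] = out_dir / "target.tsv"

    ref = pd.DataFrame(
        [
            {
                "lipid_class": e.lipid_class,
                "rt_min": e.rt_min,
                "rt_max": e.rt_max,
                "carbons_min": e.carbons_min,
                "carbons_max": e.carbons_max,
                "double_bonds_min": e.double_bonds_min,
                "double_bonds_max": e.double_bonds_max,
                "allow_odd_chains": e.allow_odd_chains,
                "internal_standard_name": e.internal_standard_name,
                "is_nominal_concentration": e.is_nominal_concentration,
            }
            for e in truth.reference
        ]
    )
    ref.to_csv(out_dir / "reference.tsv", sep="\t", index=False)
    truth.files["reference"] = out_dir / "reference.tsv"

    calibration.to_csv(out_dir / "calib.tsv", sep="\t", index=False)
    truth.files["calibration"] = out_dir / "calib.tsv"
    return truth


def make_experiment(cfg: SimulationConfig) -> tuple[LipidExperiment, GroundTruth, pd.DataFrame]:
    """In-memory path: simulate and assemble the raw-area experiment directly.

    Equivalent to :func:`generate` followed by reading the files back, but
    without touching disk; used for simulation studies where file I/O
    would dominate.  Returns ``(experiment, truth, calibration_table)``.
    """
    from .nomenclature import parse_lipid_name

    truth = simulate_truth(cfg)
    tables, calibration = _measure(truth)
    norm_tables = {}
    for sid, frame in tables.items():
        rows = []
        for rec in frame.to_dict("records"):
            sp = parse_lipid_name(rec["name"], warn_unknown_class=False)
            from .nomenclature import has_odd_chain

            rows.append(
                {
                    "canonical_name": sp.canonical_name,
                    "raw_name": rec["name"],
                    "lipid_class": sp.lipid_class,
                    "total_carbons": sp.total_carbons,
                    "total_double_bonds": sp.total_double_bonds,
                    "n_chains": len(sp.chains),
                    "resolution": sp.resolution.value,
                    "odd_chain": has_odd_chain(sp),
                    "adduct": sp.adduct,
                    "retention_time_min": rec["rt"],
                    "area": rec["area"],
                }
            )
        norm_tables[f"{sid}.tsv"] = pd.DataFrame(rows)
    is_names = [e.internal_standard_name for e in truth.reference]
    exp = build_experiment(norm_tables, truth.targets, internal_standard_names=is_names)
    return exp, truth, calibration


# -- statistical-stage simulators ------------------------------------------------


def simulate_log2_experiment(
    n_lipids: int = 500,
    n_samples: int = 12,
    n_effects: int = 0,
    log2fc: float = 1.5,
    sigma: float = 0.4,
    seed: int = 0,
    n_batches: int = 1,
    batch_log2_shift: float = 0.0,
) -> tuple[LipidExperiment, pd.Series]:
    """Simulate a log2-scale two-group experiment directly (no measurement layer).

    Used for calibration studies of the differential stage (type-I error,
    false-discovery control, batch algebra), where the instrument layer
    would only add run time without changing the quantity under study:
    per-lipid log2 abundances are base + group effect + optional batch
    shift + N(0, sigma) noise.  Returns the experiment (assay_kind
    ``log2``) and the planted per-lipid log2 effects (0 = null).
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even (two balanced groups)")
    rng = np.random.default_rng(seed)
    ann = simulate_annotation(n_lipids, seed=seed)
    names = ann.index
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    half = n_samples // 2
    condition = ["G1"] * half + ["G2"] * half
    # batches interleaved across groups so batch is orthogonal to condition
    batch = [f"B{(i % n_batches) + 1}" for i in range(n_samples)]

    effects = pd.Series(0.0, index=names)
    if n_effects:
        chosen = rng.choice(n_lipids, size=n_effects, replace=False)
        signs = np.where(np.arange(n_effects) % 2 == 0, 1.0, -1.0)
        effects.iloc[chosen] = log2fc * signs

    base = rng.uniform(2.0, 10.0, size=n_lipids)
    Y = np.empty((n_lipids, n_samples))
    for j in range(n_samples):
        shift = effects.to_numpy() * (1.0 if condition[j] == "G2" else 0.0)
        bshift = batch_log2_shift * (1.0 if batch[j] == "B1" else -1.0) if n_batches > 1 else 0.0
        Y[:, j] = base + shift + bshift + rng.normal(0.0, sigma, size=n_lipids)

    assay = pd.DataFrame(
        Y, index=names, columns=pd.Index(sample_ids, name="sample_id")
    )
    samples = pd.DataFrame(
        {
            "data_file": [f"{s}.tsv" for s in sample_ids],
            "batch": batch,
            "replicate_role": "biological",
            "calibration_ref": None,
            "condition": condition,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    exp = LipidExperiment(
        assay=assay, lipids=ann, samples=samples, assay_kind="log2",
        provenance=[{"operation": "simulate_log2_experiment", "params": {"seed": seed}}],
    )
    return exp, effects


def simulate_annotation(
    n_lipids: int, n_classes: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Balanced lipid annotation frame for set-calibration studies.

    Classes, chain-length bins and double-bond bins are each assigned in
    balanced rotation (independent of one another), with the actual carbon
    and double-bond counts drawn uniformly inside the assigned bin, so the
    default enrichment set families partition the lipids into equal-sized
    sets.  Index entries are unique synthetic identifiers, not parseable
    shorthand names.
    """
    rng = np.random.default_rng(seed)
    codes = ["PC", "PE", "TG", "Cer", "PG", "SM", "PS", "PI", "DG", "LPC", "LPE", "CE"]
    if n_classes > len(codes):
        raise ValueError(f"at most {len(codes)} classes supported")
    class_codes = codes[:n_classes]
    carbon_bins = [(24, 30), (31, 40), (41, 50), (51, 58)]
    db_bins = [(0, 0), (1, 2), (3, 5), (6, 8)]
    idx = np.arange(n_lipids)
    cls = [class_codes[i % n_classes] for i in idx]
    cb = [(i // n_classes) % 4 for i in idx]
    db = [(i // (n_classes * 4)) % 4 for i in idx]
    carbons = [int(rng.integers(carbon_bins[b][0], carbon_bins[b][1] + 1)) for b in cb]
    dbs = [int(rng.integers(db_bins[b][0], db_bins[b][1] + 1)) for b in db]
    return pd.DataFrame(
        {
            "raw_name": [f"{c}({tc}:{d})" for c, tc, d in zip(cls, carbons, dbs)],
            "lipid_class": cls,
            "total_carbons": carbons,
            "total_double_bonds": dbs,
            "n_chains": 0,
            "resolution": "species_level",
            "odd_chain": [tc % 2 == 1 for tc in carbons],
            "is_internal_standard": False,
            "retention_time_min": np.nan,
            "adduct": None,
        },
        index=pd.Index([f"lipid_{i:05d}" for i in idx], name="lipid"),
    )
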