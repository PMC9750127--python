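import numpy as np
import pandas as pd
import pytest

from lipidomics.containers import SampleRecord, build_experiment
from lipidomics.nomenclature import (
    FattyAcylChain,
    Linkage,
    LipidSpecies,
)

CLASSES = ["PC", "PE", "PG", "TG", "Cer", "SM", "DG"]


def make_table(rows):
    """Reader-layout table from (name, class, tc, db, rt, area) tuples."""
    recs = []
    for name, cls, tc, db, rt, area in rows:
        recs.append(
            {
                "canonical_name": name,
                "raw_name": name,
                "lipid_class": cls,
                "total_carbons": tc,
                "total_double_bonds": db,
                "n_chains": 2,
                "resolution": "molecular_species_level",
                "odd_chain": tc % 2 == 1,
                "adduct": None,
                "retention_time_min": rt,
                "area": area,
            }
        )
    return pd.DataFrame(recs)


def make_experiment(per_sample, factors=None, batches=None, roles=None):
    """Experiment from {sample_id: [(name, cls, tc, db, rt, area), ...]}."""
    tables = {f"{sid}.tsv": make_table(rows) for sid, rows in per_sample.items()}
    targets = [
        SampleRecord(
            sample_id=sid,
            data_file=f"{sid}.tsv",
            factors=(factors or {}).get(sid, {"condition": "A"}),
            batch=(batches or {}).get(sid),
            replicate_role=(roles or {}).get(sid, "biological"),
        )
        for sid in per_sample
    ]
    return build_experiment(tables, targets)


@pytest.fixture
def mixed_experiment():
    """4 samples x 4 lipids (two classes), complete matrix."""
    rows = [
        ("PC(34:1)", "PC", 34, 1, 12.0),
        ("PC(36:2)", "PC", 36, 2, 12.5),
        ("PE(36:2)", "PE", 36, 2, 10.5),
        ("TG(52:3)", "TG", 52, 3, 18.0),
    ]
    per_sample = {
        sid: [(n, c, tc, db, rt, 100.0 * (i + 1) + j)
              for j, (n, c, tc, db, rt) in enumerate(rows)]
        for i, sid in enumerate(["S1", "S2", "S3", "S4"])
    }
    factors = {s: {"condition": "A" if s in ("S1", "S2") else "B"} for s in per_sample}
    return make_experiment(per_sample, factors=factors)


def random_species(rng: np.random.Generator) -> LipidSpecies:
    """A random valid chain-resolved or species-level lipid."""
    cls = CLASSES[int(rng.integers(0, len(CLASSES)))]
    if rng.random() < 0.3:
        tc = int(rng.integers(20, 60))
        return LipidSpecies.from_totals(cls, tc, int(rng.integers(0, 7)))
    # single unprefixed chains are excluded: in shorthand "LPC(16:0)" is
    # indistinguishable from a species-level descriptor, so it cannot
    # round-trip at molecular resolution
    n_chains = int(rng.integers(1, 4))
    chains = []
    for i in range(n_chains):
        c = int(rng.integers(10, 27))
        db = int(rng.integers(0, min(7, c // 2)))
        if i == 0 and (n_chains == 1 or rng.random() < 0.3):
            link = [Linkage.ETHER, Linkage.VINYL_ETHER, Linkage.SPHINGOID_D, Linkage.SPHINGOID_T][
                int(rng.integers(0, 4))
            ]
            oh = {Linkage.SPHINGOID_D: 2, Linkage.SPHINGOID_T: 3}.get(link, 0)
            chains.append(FattyAcylChain(c, db, link, oh))
        else:
            chains.append(FattyAcylChain(c, db))
    return LipidSpecies.from_chains(cls, chains, positions_known=bool(rng.random() < 0.8))
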