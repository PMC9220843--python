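"""Merge two database-search engines with a de novo engine into one catalog.

The de novo engine has no database-grounded FDR, so its score cutoff is
calibrated from the peptides it shares with the database engines: the shared
best-score distribution's q-th percentile (default 25, linear-interpolation
quantile) becomes the acceptance threshold for de novo-only peptides.
Scores are never compared across engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import PsmRecord

logger = logging.getLogger(__name__)

ENGINES = ("db1", "db2", "denovo")

CATALOG_COLUMNS = [
    "peptide", "len", "db1", "db2", "denovo_pass", "psm_count",
    "charges", "best_score_db1", "best_score_db2", "best_score_denovo", "rts",
]


def _il_collapse(peptide: str) -> str:
    return peptide.replace("I", "L")


def length_filter(records: Sequence[PsmRecord], len_min: int = 8,
                  len_max: int = 15) -> List[PsmRecord]:
    """Keep 8-15-mers (inclusive); drops are logged per engine."""
    kept = [r for r in records if len_min <= len(r.peptide) <= len_max]
    dropped: Dict[str, int] = {}
    for r in records:
        if not len_min <= len(r.peptide) <= len_max:
            dropped[r.engine] = dropped.get(r.engine, 0) + 1
    for engine, n in sorted(dropped.items()):
        logger.info("length filter dropped %d %s PSMs", n, engine)
    return kept


def best_scores(records: Iterable[PsmRecord], agg: str = "best") -> Dict[str, float]:
    """Per-peptide score summary on one engine's own scale."""
    if agg not in ("best", "mean"):
        raise ValueError("agg must be 'best' or 'mean'")
    acc: Dict[str, List[float]] = {}
    for r in records:
        acc.setdefault(r.peptide, []).append(r.score)
    if agg == "best":
        return {p: max(v) for p, v in acc.items()}
    return {p: float(np.mean(v)) for p, v in acc.items()}


@dataclass(frozen=True)
class DenovoCalibration:
    """Shared-score vector and the percentile cutoff derived from it."""

    shared_scores: Tuple[float, ...]
    q: float
    cutoff: float


def calibrate_denovo_cutoff(denovo_records: Sequence[PsmRecord],
                            db_peptides: Set[str], q: float = 25.0,
                            agg: str = "best",
                            il_equivalent: bool = False) -> DenovoCalibration:
    """Cutoff = q-th percentile (linear interpolation, quantile type 7) of
    the best de novo scores of peptides also reported by a database engine."""
    scores = best_scores(denovo_records, agg=agg)
    if il_equivalent:
        db_keys = {_il_collapse(p) for p in db_peptides}
        shared = [s for p, s in scores.items() if _il_collapse(p) in db_keys]
    else:
        shared = [s for p, s in scores.items() if p in db_peptides]
    if not shared:
        raise ValueError(
            "no overlap between de novo and database peptides; "
            "supply an explicit cutoff instead of calibrating"
        )
    cutoff = float(np.percentile(np.asarray(shared, dtype=float), q))
    return DenovoCalibration(shared_scores=tuple(sorted(shared)), q=float(q), cutoff=cutoff)


def filter_denovo(denovo_records: Sequence[PsmRecord],
                  calibration: DenovoCalibration | float,
                  agg: str = "best") -> Set[str]:
    """Peptides whose best de novo score passes the cutoff (inclusive >=)."""
    cutoff = calibration.cutoff if isinstance(calibration, DenovoCalibration) else float(calibration)
    return {p for p, s in best_scores(denovo_records, agg=agg).items() if s >= cutoff}


def combine(db1: Sequence[PsmRecord], db2: Sequence[PsmRecord],
            denovo: Sequence[PsmRecord], denovo_pass: Set[str]) -> pd.DataFrame:
    """Union by exact sequence into the peptide catalog.

    A de novo peptide contributes evidence (and its PSMs are counted) only if
    it passed the calibrated cutoff; db evidence stands on its own.  Inputs
    are assumed length-filtered.
    """
    by_engine = {"db1": db1, "db2": db2, "denovo": denovo}
    rows: Dict[str, Dict] = {}

    def entry(pep: str) -> Dict:
        return rows.setdefault(pep, {
            "peptide": pep, "len": len(pep), "db1": False, "db2": False,
            "denovo_pass": False, "psm_count": 0, "charges": [],
            "best_score_db1": None, "best_score_db2": None,
            "best_score_denovo": None, "rts": [],
        })

    for engine, records in by_engine.items():
        for r in records:
            if engine == "denovo" and r.peptide not in denovo_pass:
                continue
            e = entry(r.peptide)
            e["db1" if engine == "db1" else "db2" if engine == "db2" else "denovo_pass"] = True
            e["psm_count"] += 1
            e["charges"].append(r.charge)
            key = f"best_score_{engine}"
            e[key] = r.score if e[key] is None else max(e[key], r.score)
            if r.rt is not None:
                e["rts"].append(r.rt)

    catalog = pd.DataFrame(list(rows.values()), columns=CATALOG_COLUMNS)
    return catalog.sort_values("peptide", kind="mergesort").reset_index(drop=True)


VENN_CATEGORIES = (
    ("db1",), ("db2",), ("denovo",),
    ("db1", "db2"), ("db1", "denovo"), ("db2", "denovo"),
    ("db1", "db2", "denovo"),
)


def venn_counts(catalog: pd.DataFrame) -> Dict[Tuple[str, ...], int]:
    """Sizes of the seven evidence categories; they partition the catalog."""
    counts = {cat: 0 for cat in VENN_CATEGORIES}
    for row in catalog.itertuples(index=False):
        cat = tuple(name for name, flag in
                    (("db1", row.db1), ("db2", row.db2), ("denovo", row.denovo_pass)) if flag)
        counts[cat] += 1
    return counts


def summarize(catalog: pd.DataFrame) -> Dict[str, pd.Series]:
    """Length, precursor-charge and PSM-count distributions as fractions."""
    if catalog.empty:
        raise ValueError("catalog is empty")
    n = len(catalog)
    length = catalog["len"].value_counts().sort_index() / n
    charges = pd.Series([c for cs in catalog["charges"] for c in cs])
    charge = charges.value_counts().sort_index() / len(charges)
    multi = (catalog["psm_count"] > 1).sum()
    psm = pd.Series({"1": (n - multi) / n, ">1": multi / n})
    return {"length": length, "charge": charge, "psm": psm}


def write_catalog(catalog: pd.DataFrame, path) -> None:
    out = catalog.copy()
    out["charges"] = out["charges"].map(lambda cs: ",".join(map(str, cs)))
    out["rts"] = out["rts"].map(lambda rs: ",".join(f"{r:.3f}" for r in rs))
    out.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["charges"] = df["charges"].map(
        lambda s: [int(x) for x in str(s).split(",")] if pd.notna(s) and str(s) else [])
    df["rts"] = df["rts"].map(
        lambda s: [float(x) for x in str(s).split(",")] if pd.notna(s) and str(s) else [])
    for col in ("db1", "db2", "denovo_pass"):
        df[col] = df[col].astype(bool)
    return df
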