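"""In-silico quality control: HLA binder classes and retention-time agreement.

Binder classes follow the standard percentile-rank convention: rank <= 0.5%
strong binder, 0.5% < rank <= 2% weak binder, rank > 2% non-binder; a peptide
predicted against several alleles is assigned its best-ranked allele.

Retention-time (RT) agreement between measured and predicted values is
summarized by a least-squares fit, the squared Pearson correlation, and
DeltaRT90: the 90th percentile (nearest-rank) of |measured - predicted|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRONG_RANK = 0.5
WEAK_RANK = 2.0


def classify_binder(rank_percent: float) -> str:
    """strong | weak | non; thresholds inclusive (<=)."""
    if rank_percent < 0:
        raise ValueError("percentile rank cannot be negative")
    if rank_percent <= STRONG_RANK:
        return "strong"
    if rank_percent <= WEAK_RANK:
        return "weak"
    return "non"


@dataclass(frozen=True)
class BinderCall:
    peptide: str
    allele: str
    rank_percent: float
    ic50_nm: float
    binder_class: str


def best_allele(predictions: pd.DataFrame) -> BinderCall:
    """Minimal-rank allele for one peptide's prediction rows, ties broken by
    allele name; its IC50 is the one carried forward."""
    if predictions.empty:
        raise ValueError("no prediction rows")
    row = predictions.sort_values(["rank_percent", "allele"], kind="mergesort").iloc[0]
    return BinderCall(
        peptide=str(row["peptide"]), allele=str(row["allele"]),
        rank_percent=float(row["rank_percent"]), ic50_nm=float(row["ic50_nm"]),
        binder_class=classify_binder(float(row["rank_percent"])),
    )


def binder_calls(predictions: pd.DataFrame) -> pd.DataFrame:
    """Vectorized best_allele over an affinity table; one row per peptide."""
    best = (predictions.sort_values(["peptide", "rank_percent", "allele"], kind="mergesort")
            .drop_duplicates("peptide", keep="first")
            .reset_index(drop=True).copy())
    best["binder_class"] = best["rank_percent"].map(classify_binder)
    return best[["peptide", "allele", "rank_percent", "ic50_nm", "binder_class"]]


def binder_summary(calls: pd.DataFrame) -> Dict[str, object]:
    """Class fractions, per-allele assignment proportions among binders, and
    IC50 summaries including the fraction below 500 nM."""
    n = len(calls)
    if n == 0:
        raise ValueError("no binder calls")
    class_fractions = (calls["binder_class"].value_counts()
                       .reindex(["strong", "weak", "non"], fill_value=0) / n)
    binders = calls.loc[calls["binder_class"] != "non"]
    allele_fractions = (binders["allele"].value_counts() / len(binders)
                        if len(binders) else pd.Series(dtype=float))
    ic50 = calls["ic50_nm"].astype(float)
    return {
        "class_fractions": class_fractions,
        "binder_fraction": float(class_fractions["strong"] + class_fractions["weak"]),
        "allele_fractions": allele_fractions,
        "ic50_below_500nm_fraction": float((ic50 < 500).mean()),
        "ic50_median_nm": float(ic50.median()),
    }


# ---------------------------------------------------------------------------
# Retention time

def delta_rt90(deltas: Sequence[float]) -> float:
    """Nearest-rank 90th percentile of |delta| (seconds)."""
    a = np.sort(np.abs(np.asarray(deltas, dtype=float)))
    if a.size == 0:
        raise ValueError("no RT differences")
    rank = math.ceil(0.9 * a.size)  # nearest-rank definition
    return float(a[rank - 1])


@dataclass
class RtAgreement:
    n: int
    slope: float
    intercept: float
    pearson_r: Optional[float]
    r_squared: Optional[float]
    delta_rt90_s: float
    deltas: np.ndarray  # measured - predicted, seconds


def rt_agreement(rt: pd.DataFrame) -> RtAgreement:
    """Agreement metrics from a table with columns peptide, measured_s,
    predicted_s (batch optional).  Peptides with multiple PSMs contribute the
    mean of their measured RTs.  Zero variance in either vector leaves the
    correlation undefined (None)."""
    grouped = (rt.groupby("peptide", sort=True)
               .agg(measured=("measured_s", "mean"), predicted=("predicted_s", "mean"))
               .reset_index())
    if len(grouped) < 3:
        raise ValueError("need >= 3 paired observations")
    measured = grouped["measured"].to_numpy(dtype=float)
    predicted = grouped["predicted"].to_numpy(dtype=float)
    deltas = measured - predicted
    if np.ptp(measured) == 0 or np.ptp(predicted) == 0:
        logger.warning("zero variance in RT vector; correlation undefined")
        slope, intercept = 0.0, float(np.mean(measured))
        r: Optional[float] = None
    else:
        fit = stats.linregress(predicted, measured)
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    return RtAgreement(
        n=len(grouped), slope=slope, intercept=intercept,
        pearson_r=r, r_squared=None if r is None else r * r,
        delta_rt90_s=delta_rt90(deltas), deltas=deltas,
    )


def rt_agreement_by_batch(rt: pd.DataFrame) -> Dict[str, RtAgreement]:
    """Per-batch metrics plus the pooled result under key 'pooled'
    (prediction models are trained per acquisition batch, so agreement is
    reported at both granularities)."""
    out = {"pooled": rt_agreement(rt)}
    if "batch" in rt.columns:
        for batch, sub in rt.groupby("batch"):
            try:
                out[str(batch)] = rt_agreement(sub)
            except ValueError:
                logger.warning("batch %s has < 3 peptides; skipped", batch)
    return out
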