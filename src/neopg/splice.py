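"""Cis-spliced peptide inference for non-canonical peptides.

A peptide is a candidate proteasome-generated cis-spliced product when it can
be cut once into an N- and a C-terminal sub-fragment (each >= 3 residues)
such that both fragments occur, at disjoint positions, in the same protein.
Fragments in N->C order along the parent are "normal", the other order
"reverse"; the parent residues between the two occurrence intervals form the
intervening sequence.  Among all candidates the least-intervening one is
selected as the parental assignment.  A peptide that occurs verbatim in some
protein is linear, never spliced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AA_ORDER, ProteomeDB

logger = logging.getLogger(__name__)

MIN_FRAGMENT = 3


@dataclass(frozen=True)
class SplicedCandidate:
    """One (peptide, split, parent, occurrence-pair) configuration."""

    peptide: str
    split: int                       # N-fragment = peptide[:split]
    parent: str                      # protein accession
    n_start: int                     # N-fragment interval in parent, 0-based
    n_end: int
    c_start: int                     # C-fragment interval in parent
    c_end: int
    orientation: str                 # normal | reverse
    intervening: int                 # residues between the two intervals

    @property
    def n_fragment(self) -> str:
        return self.peptide[: self.split]

    @property
    def c_fragment(self) -> str:
        return self.peptide[self.split:]


def enumerate_splits(peptide: str, min_frag: int = MIN_FRAGMENT) -> List[int]:
    """Split points s with both fragments >= min_frag residues."""
    n = len(peptide)
    if n < 2 * min_frag:
        return []
    return list(range(min_frag, n - min_frag + 1))


def _occurrences(needle: str, haystack: str) -> List[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def classify_orientation(n_start: int, n_end: int, c_start: int, c_end: int) -> Optional[str]:
    """normal iff the N-fragment interval precedes the C-fragment interval;
    None when the intervals overlap (not a physical splicing product)."""
    if n_end <= c_start:
        return "normal"
    if c_end <= n_start:
        return "reverse"
    return None


def find_cis_candidates(peptide: str, proteome: ProteomeDB,
                        min_frag: int = MIN_FRAGMENT,
                        max_intervening: Optional[int] = None,
                        linear_check: bool = True) -> List[SplicedCandidate]:
    """Exhaustive candidates over all splits x proteins x disjoint
    occurrence pairs.  Returns [] for linear peptides (verbatim proteome
    substrings) unless ``linear_check`` is disabled."""
    if linear_check and proteome.contains(peptide):
        return []
    splits = enumerate_splits(peptide, min_frag)
    out: List[SplicedCandidate] = []
    for acc, seq in proteome.items():
        for s in splits:
            nfrag, cfrag = peptide[:s], peptide[s:]
            if nfrag not in seq or cfrag not in seq:
                continue
            n_occ = _occurrences(nfrag, seq)
            c_occ = _occurrences(cfrag, seq)
            for i in n_occ:
                for j in c_occ:
                    orient = classify_orientation(i, i + s, j, j + len(cfrag))
                    if orient is None:
                        continue
                    gap = j - (i + s) if orient == "normal" else i - (j + len(cfrag))
                    if max_intervening is not None and gap > max_intervening:
                        continue
                    out.append(SplicedCandidate(
                        peptide=peptide, split=s, parent=acc,
                        n_start=i, n_end=i + s,
                        c_start=j, c_end=j + len(cfrag),
                        orientation=orient, intervening=gap,
                    ))
    return out


def select_parent(candidates: Sequence[SplicedCandidate]) -> Optional[SplicedCandidate]:
    """Least-intervening candidate; ties broken by accession, then split,
    then leftmost N-fragment occurrence."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c.intervening, c.parent, c.split, c.n_start))


def infer_spliced(peptides: Iterable[str], proteome: ProteomeDB,
                  min_frag: int = MIN_FRAGMENT,
                  max_intervening: Optional[int] = None) -> Dict[str, Optional[SplicedCandidate]]:
    """Selected cis-splice assignment per peptide (None = no evidence)."""
    return {
        pep: select_parent(find_cis_candidates(pep, proteome, min_frag=min_frag,
                                               max_intervening=max_intervening))
        for pep in peptides
    }


# ---------------------------------------------------------------------------
# Statistics

TERMINAL_POSITIONS = ("P_N", "P_1", "P_1p", "P_C")


@dataclass
class SpliceStats:
    """Descriptive statistics over selected cis-splice candidates.

    * intervening-length histograms per orientation
    * N-/C-fragment length histograms
    * 20 x 9 positional residue frequency matrix over 9-mer peptides
    * residue frequencies at the four splice-defining positions:
      P_N (peptide N-terminus), P_1 (last residue of the N-fragment),
      P_1' (first residue of the C-fragment), P_C (peptide C-terminus)
    """

    intervening: Dict[str, pd.Series]
    n_fragment_lengths: pd.Series
    c_fragment_lengths: pd.Series
    matrix9: pd.DataFrame
    terminal_freqs: Dict[str, pd.Series]


def _freq(residues: Sequence[str]) -> pd.Series:
    counts = pd.Series(0.0, index=list(AA_ORDER))
    for r in residues:
        counts[r] += 1
    total = counts.sum()
    return counts / total if total else counts


def splice_statistics(candidates: Sequence[SplicedCandidate]) -> SpliceStats:
    if not candidates:
        raise ValueError("no candidates to summarize")
    by_orient: Dict[str, List[int]] = {"normal": [], "reverse": []}
    for c in candidates:
        by_orient[c.orientation].append(c.intervening)
    intervening = {
        orient: pd.Series(vals, dtype=int).value_counts().sort_index()
        for orient, vals in by_orient.items()
    }
    n_lens = pd.Series([c.split for c in candidates]).value_counts().sort_index()
    c_lens = pd.Series([len(c.peptide) - c.split for c in candidates]).value_counts().sort_index()

    nine = [c.peptide for c in candidates if len(c.peptide) == 9]
    matrix9 = pd.DataFrame(
        {pos + 1: _freq([p[pos] for p in nine]) for pos in range(9)}
        if nine else {pos + 1: pd.Series(0.0, index=list(AA_ORDER)) for pos in range(9)}
    )

    terminal_freqs = {
        "P_N": _freq([c.peptide[0] for c in candidates]),
        "P_1": _freq([c.peptide[c.split - 1] for c in candidates]),
        "P_1p": _freq([c.peptide[c.split] for c in candidates]),
        "P_C": _freq([c.peptide[-1] for c in candidates]),
    }
    return SpliceStats(
        intervening=intervening,
        n_fragment_lengths=n_lens,
        c_fragment_lengths=c_lens,
        matrix9=matrix9,
        terminal_freqs=terminal_freqs,
    )


def candidates_frame(assignments: Mapping[str, Optional[SplicedCandidate]]) -> pd.DataFrame:
    """Tabular view of selected assignments (unevidenced peptides omitted)."""
    rows = [
        (c.peptide, c.split, c.parent, c.n_start, c.n_end, c.c_start, c.c_end,
         c.orientation, c.intervening)
        for c in assignments.values() if c is not None
    ]
    return pd.DataFrame(rows, columns=[
        "peptide", "split", "parent", "n_start", "n_end", "c_start", "c_end",
        "orientation", "intervening",
    ])
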