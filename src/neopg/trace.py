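"""Origin tracing of non-canonical peptides via translated k-mer datasets.

Every k-substring (k = 24..45 nt, step 3, i.e. 8-15 residues) of the input
sequences and of their reverse complements is translated in its own frame;
translations containing a stop codon (or an ambiguous base) are excluded.
A peptide "has evidence of origin" at an omics level if it occurs verbatim
in that level's k-mer peptide set at k = 3 x length.

Genome-level matches can additionally be mapped back to their loci and
classified by genomic region: "Unique-Tag" when every encoding locus falls
in a single common region type, otherwise "Multi-Tag".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import Seq

from .core import GenomeRef, ProteomeDB, RegionAnnotation, revcomp

logger = logging.getLogger(__name__)

KMER_MIN = 24
KMER_MAX = 45
KMER_STEP = 3

OMICS_LEVELS = ("genome", "exome", "transcriptome")
FLAG_COLUMNS = ("genome", "exome", "transcriptome", "sorf")


def kmer_lengths() -> List[int]:
    """Nucleotide k-mer lengths: 24..45 step 3 (peptides of 8-15 residues)."""
    return list(range(KMER_MIN, KMER_MAX + 1, KMER_STEP))


Locus = Tuple[str, int, str]  # (chrom/sequence id, 0-based start, strand)


@dataclass
class KmerPeptideIndex:
    """Translated k-mer peptide sets for one omics level.

    ``peptides[k]`` holds every stop-free translation of a k-mer from either
    strand.  When ``loci`` is populated (genome level), each peptide maps to
    the genomic intervals that encode it.
    """

    level: str
    peptides: Dict[int, Set[str]]
    loci: Optional[Dict[str, List[Locus]]] = None

    def contains(self, peptide: str) -> bool:
        k = 3 * len(peptide)
        return k in self.peptides and peptide in self.peptides[k]


def build_kmer_index(sequences: Mapping[str, str] | Iterable[Tuple[str, str]],
                     level: str, store_loci: bool = False,
                     ks: Optional[Sequence[int]] = None) -> KmerPeptideIndex:
    """Index every k-mer of every sequence and its reverse complement.

    A k-mer starting at offset i is translated in its own frame, which equals
    the corresponding slice of the whole-sequence frame-(i mod 3) translation;
    the three forward and three reverse frame translations are therefore
    computed once per sequence and k-mer peptides taken as substrings.
    Peptides containing a stop ('*') or an ambiguous residue from N ('X')
    are excluded.
    """
    ks = list(ks) if ks is not None else kmer_lengths()
    if any(k % 3 != 0 or k <= 0 for k in ks):
        raise ValueError("k-mer lengths must be positive multiples of 3")
    peptides: Dict[int, Set[str]] = {k: set() for k in ks}
    loci: Optional[Dict[str, List[Locus]]] = {} if store_loci else None

    items = sequences.items() if hasattr(sequences, "items") else sequences
    for sid, seq in items:
        seq = str(seq).upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            frame_aa = []
            for f in range(3):
                trimmed = s[f : f + 3 * ((n - f) // 3)]
                frame_aa.append(str(Seq(trimmed).translate()) if trimmed else "")
            for k in ks:
                plen = k // 3
                store = peptides[k]
                for f in range(3):
                    aa = frame_aa[f]
                    for r in range(len(aa) - plen + 1):
                        pep = aa[r : r + plen]
                        if "*" in pep or "X" in pep:
                            continue
                        store.add(pep)
                        if loci is not None:
                            i = f + 3 * r  # offset on this strand's sequence
                            start = i if strand == "+" else n - i - k
                            loci.setdefault(pep, []).append((sid, start, strand))
    return KmerPeptideIndex(level=level, peptides=peptides, loci=loci)


def trace_peptides(peptides: Sequence[str],
                   indexes: Mapping[str, KmerPeptideIndex],
                   sorf_db: Optional[ProteomeDB] = None) -> pd.DataFrame:
    """Evidence matrix: one row per peptide, one boolean column per level
    (plus sORF when a database is given).  Peptides outside 8-15 residues
    are skipped with a warning."""
    rows = []
    for pep in peptides:
        if not 8 <= len(pep) <= 15:
            logger.warning("skipping peptide %r: length outside 8-15", pep)
            continue
        row = {"peptide": pep}
        for level in OMICS_LEVELS:
            idx = indexes.get(level)
            row[level] = bool(idx.contains(pep)) if idx is not None else False
        row["sorf"] = sorf_match(pep, sorf_db) if sorf_db is not None else False
        rows.append(row)
    return pd.DataFrame(rows, columns=["peptide", *FLAG_COLUMNS])


def sorf_match(peptide: str, sorf_db: ProteomeDB) -> bool:
    """True iff the peptide occurs verbatim in >=1 sORF sequence."""
    return sorf_db.contains(peptide)


def tag_region(peptide: str, index: KmerPeptideIndex,
               annotation: RegionAnnotation) -> str:
    """Region tag of a genome-matched peptide.

    Each encoding locus [start, start + 3*len) is assigned the set of region
    types it overlaps (intergenic by complement).  All loci resolving to one
    common single type gives ``Unique-Tag:<type>``; anything else gives
    ``Multi-Tag:<sorted+joined types>``.  Peptides without stored loci tag as
    ``none``.
    """
    if index.loci is None:
        raise ValueError("tag_region needs an index built with store_loci=True")
    loci = index.loci.get(peptide)
    if not loci:
        return "none"
    span = 3 * len(peptide)
    per_locus: List[Set[str]] = [
        annotation.types_in(chrom, start, start + span) for chrom, start, _ in loci
    ]
    union = set().union(*per_locus)
    if len(union) == 1 and all(len(t) == 1 for t in per_locus):
        return f"Unique-Tag:{next(iter(union))}"
    return "Multi-Tag:" + "+".join(sorted(union))


def tag_regions(evidence: pd.DataFrame, index: KmerPeptideIndex,
                annotation: RegionAnnotation) -> pd.DataFrame:
    """Add a region_tag column: tags only genome-flagged peptides."""
    out = evidence.copy()
    out["region_tag"] = [
        tag_region(pep, index, annotation) if flag else "none"
        for pep, flag in zip(out["peptide"], out["genome"])
    ]
    return out


def upset_counts(evidence: pd.DataFrame,
                 flag_columns: Sequence[str] = FLAG_COLUMNS) -> Dict[Tuple[str, ...], int]:
    """Disjoint intersection sizes per flag combination (the upset-plot
    counts); the empty tuple holds peptides with no evidence."""
    cols = [c for c in flag_columns if c in evidence.columns]
    counts: Dict[Tuple[str, ...], int] = {}
    for row in evidence.itertuples(index=False):
        d = row._asdict()
        key = tuple(c for c in cols if d[c])
        counts[key] = counts.get(key, 0) + 1
    return counts
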