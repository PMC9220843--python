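"""Shared domain types for the proteogenomic pipeline.

Coordinate convention: everything in memory is 0-based half-open.  File
readers convert at the boundary (VCF and GFF-style annotations are 1-based
inclusive on disk, BED-style annotations are already 0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA_ORDER)

#: Genome alphabet (uppercase; N = ambiguous).
NT_ALPHABET = frozenset("ACGTN")

#: Region types used throughout; intergenic is the complement of gene bodies.
REGION_TYPES = ("exon", "intron", "intergenic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeRef:
    """Reference genome: chromosome id -> uppercase nucleotide sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs: Dict[str, str] = {}
        for chrom, seq in sequences.items():
            if chrom in seqs:
                raise ValueError(f"duplicate chromosome id {chrom!r}")
            s = str(seq).upper()
            if not s:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            bad = set(s) - NT_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            seqs[chrom] = s
        self._seqs = seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self) -> Iterable[Tuple[str, str]]:
        return self._seqs.items()

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice [start, end) clipped to chromosome bounds."""
        seq = self._seqs[chrom]
        return seq[max(0, start) : min(len(seq), end)]


class ProteomeDB:
    """Accession -> protein sequence, with a concatenated view for fast
    substring ("is this peptide anywhere in the canonical proteome") queries.

    Records with residues outside the 20-letter alphabet are dropped with a
    logged warning, mirroring how search engines treat such entries.
    """

    SEPARATOR = "|"  # never a valid residue, so matches cannot span records

    def __init__(self, sequences: Mapping[str, str]):
        seqs: Dict[str, str] = {}
        n_dropped = 0
        for acc, seq in sequences.items():
            if acc in seqs:
                raise ValueError(f"duplicate accession {acc!r}")
            s = str(seq).upper()
            if not s or set(s) - AA_ALPHABET:
                n_dropped += 1
                logger.warning("dropping record %s: non-standard residues", acc)
                continue
            seqs[acc] = s
        if n_dropped:
            logger.warning("dropped %d proteome records with non-standard residues", n_dropped)
        self._seqs = seqs
        self.n_dropped = n_dropped
        self._joined: Optional[str] = None

    @property
    def _concat(self) -> str:
        if self._joined is None:
            self._joined = self.SEPARATOR + self.SEPARATOR.join(self._seqs.values()) + self.SEPARATOR
        return self._joined

    def contains(self, peptide: str) -> bool:
        """True iff the peptide is an exact substring of >=1 protein."""
        return peptide in self._concat

    def __getitem__(self, acc: str) -> str:
        return self._seqs[acc]

    def __contains__(self, acc: str) -> bool:
        return acc in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self) -> Iterable[Tuple[str, str]]:
        return self._seqs.items()


@dataclass(frozen=True)
class Variant:
    """A somatic variant, VCF-style: pos is 1-based, ref matches the genome."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty (VCF anchor-base style)")

    @property
    def pos0(self) -> int:
        """0-based start of the REF allele."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the REF allele."""
        return self.pos0 + len(self.ref)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "INS"
        if len(self.alt) < len(self.ref):
            return "DEL"
        return "MNV"

    @property
    def is_frameshift(self) -> bool:
        return abs(len(self.alt) - len(self.ref)) % 3 != 0

    def check_against(self, genome: GenomeRef) -> None:
        observed = genome.fetch(self.chrom, self.pos0, self.end0)
        if observed != self.ref:
            raise ValueError(
                f"REF mismatch at {self.chrom}:{self.pos}: "
                f"VCF says {self.ref!r}, genome has {observed!r}"
            )


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from a search or de novo engine."""

    peptide: str
    engine: str  # "db1" | "db2" | "denovo"
    score: float
    charge: int = 2
    rt: Optional[float] = None  # seconds
    spectrum_id: str = ""
    batch_id: str = ""

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if set(self.peptide) - AA_ALPHABET:
            raise ValueError(f"peptide {self.peptide!r} has non-standard residues")


@dataclass(frozen=True)
class RegionInterval:
    """One annotated interval; exon intervals carry gene_id, strand and the
    cumulative CDS offset of their first base (strand-aware), from which the
    reading frame of any position inside the exon follows."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    region_type: str  # exon | intron
    strand: str  # + | - | .
    gene_id: str = ""
    cds_offset: Optional[int] = None  # exons only

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty interval")
        if self.region_type not in ("exon", "intron"):
            raise ValueError("annotated intervals are exon or intron; intergenic is implied")


class RegionAnnotation:
    """Exon/intron intervals per chromosome; intergenic is the complement.

    Every genomic position therefore resolves to at least one region type.
    """

    def __init__(self, intervals: Sequence[RegionInterval]):
        self.intervals = list(intervals)
        self._trees: Dict[str, IntervalTree] = {}
        self._gene_bounds: Dict[str, Tuple[str, int, int, str]] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            if iv.gene_id:
                chrom, lo, hi, strand = self._gene_bounds.get(
                    iv.gene_id, (iv.chrom, iv.start, iv.end, iv.strand)
                )
                self._gene_bounds[iv.gene_id] = (
                    chrom,
                    min(lo, iv.start),
                    max(hi, iv.end),
                    strand,
                )

    def intervals_at(self, chrom: str, start: int, end: int) -> List[RegionInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(start, end)),
                      key=lambda iv: (iv.start, iv.end, iv.region_type))

    def region_at(self, chrom: str, pos: int) -> str:
        """Region type of a single position; exon wins over intron if an
        annotation ever overlapped them (they do not in well-formed input)."""
        hits = self.intervals_at(chrom, pos, pos + 1)
        types = {iv.region_type for iv in hits}
        if "exon" in types:
            return "exon"
        if "intron" in types:
            return "intron"
        return "intergenic"

    def types_in(self, chrom: str, start: int, end: int) -> Set[str]:
        """All region types overlapped by [start, end), intergenic included
        whenever the annotated intervals do not cover the span completely."""
        hits = self.intervals_at(chrom, start, end)
        types = {iv.region_type for iv in hits}
        covered = 0
        last = start
        for iv in sorted(hits, key=lambda iv: iv.start):
            s, e = max(iv.start, last), min(iv.end, end)
            if e > s:
                covered += e - s
                last = max(last, e)
        if covered < end - start:
            types.add("intergenic")
        return types

    def exon_at(self, chrom: str, pos: int) -> Optional[RegionInterval]:
        for iv in self.intervals_at(chrom, pos, pos + 1):
            if iv.region_type == "exon":
                return iv
        return None

    def intron_at(self, chrom: str, pos: int) -> Optional[RegionInterval]:
        for iv in self.intervals_at(chrom, pos, pos + 1):
            if iv.region_type == "intron":
                return iv
        return None

    def gene_ids(self) -> List[str]:
        return sorted(self._gene_bounds)

    def gene_span(self, gene_id: str) -> Tuple[str, int, int, str]:
        """(chrom, start, end, strand) of the full gene body."""
        return self._gene_bounds[gene_id]

    def flanking_gene_strands(self, chrom: str, pos: int, max_dist: int) -> Set[str]:
        """Strands of the nearest gene on each side within max_dist bp.

        Used to orient translation of intergenic variant windows.
        """
        strands: Set[str] = set()
        best_left: Tuple[int, str] = (max_dist + 1, "")
        best_right: Tuple[int, str] = (max_dist + 1, "")
        for gene_id, (gchrom, lo, hi, strand) in self._gene_bounds.items():
            if gchrom != chrom:
                continue
            if hi <= pos:  # gene entirely left of pos
                d = pos - hi
                if d < best_left[0]:
                    best_left = (d, strand)
            elif lo > pos:  # entirely right
                d = lo - pos
                if d < best_right[0]:
                    best_right = (d, strand)
            else:  # pos inside the gene body
                strands.add(strand)
        for d, strand in (best_left, best_right):
            if strand:
                strands.add(strand)
        return strands
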