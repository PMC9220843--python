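"""Personalized protein database construction from somatic variants.

For each variant a nucleotide context window (the variant plus 24-45 nt of
flank on each side, ALT substituted for REF) is translated according to the
genomic region it falls in:

* exon        -> single reading frame, derived from the gene annotation
* intron      -> three frames on the host gene's strand
* intergenic  -> three frames on the consensus strand of the flanking genes,
                 or all six frames when they disagree or no gene is nearby

Mutation-covering 8-15-mers are enumerated, peptides already present in the
canonical proteome are subtracted, and the survivors are filtered by
predicted HLA binding (percentile rank <= 2% on the best allele) before
being appended to the canonical proteome as the search database.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import Seq

from .core import GenomeRef, ProteomeDB, RegionAnnotation, RegionInterval, Variant, revcomp
from .io import write_fasta

logger = logging.getLogger(__name__)

#: The six HLA class I alleles of the HCT116 cell line, the default allele
#: panel for the built-in mock predictor.
DEFAULT_ALLELES = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-B*18:01",
    "HLA-B*45:01", "HLA-C*05:01", "HLA-C*07:01",
)

PEPTIDE_LEN_MIN = 8
PEPTIDE_LEN_MAX = 15
FLANK_MIN = 24
FLANK_MAX = 45


@dataclass
class MutationContext:
    """A variant with its ALT-substituted nucleotide window and the
    translation policy its genomic region dictates."""

    variant: Variant
    window: str              # nucleotides, ALT already substituted
    window_start: int        # genomic, 0-based (reference coordinates)
    window_end: int          # genomic, half-open (reference coordinates)
    offset: int              # start of the ALT allele within window
    region_type: str
    frame_mode: str          # one_frame | three_frame | six_frame
    strands: Tuple[str, ...]
    flank: int
    exon: Optional[RegionInterval] = None
    gene_id: str = ""


@dataclass(frozen=True)
class TranslatedFragment:
    """One stop-free translation product of a context window, tagged with the
    residue indices altered by the variant."""

    seq: str
    strand: str
    frame: int
    mutant_residues: FrozenSet[int]
    frameshift: bool = False


@dataclass
class CandidatePeptide:
    """A mutation-covering 8-15-mer; the unit of the personalized database."""

    peptide: str
    variant: Variant
    strand: str
    frame: int
    frameshift: bool
    mutant_start: int        # within peptide, 0-based
    mutant_end: int          # half-open
    region_type: str = ""
    gene_id: str = ""
    aa_change: str = ""
    allele: Optional[str] = None
    rank_percent: Optional[float] = None
    ic50_nm: Optional[float] = None


# ---------------------------------------------------------------------------
# Context extraction

def extract_mutation_context(variant: Variant, genome: GenomeRef,
                             annotation: RegionAnnotation, flank: int = FLANK_MAX,
                             six_frame_search_dist: int = 100_000) -> MutationContext:
    """Build the ALT-substituted context window and pick the frame policy."""
    if not FLANK_MIN <= flank <= FLANK_MAX:
        raise ValueError(f"flank must be in [{FLANK_MIN}, {FLANK_MAX}]")
    chrom = variant.chrom
    if chrom not in genome:
        raise ValueError(f"variant on unknown contig {chrom!r}")
    known_chroms = {iv.chrom for iv in annotation.intervals}
    if chrom not in known_chroms:
        raise ValueError(f"variant on unannotated contig {chrom!r}")
    variant.check_against(genome)

    chrom_len = genome.length(chrom)
    win_start = max(0, variant.pos0 - flank)
    win_end = min(chrom_len, variant.end0 + flank)
    left = genome.fetch(chrom, win_start, variant.pos0)
    right = genome.fetch(chrom, variant.end0, win_end)
    window = left + variant.alt + right
    if len(window) < FLANK_MIN:
        logger.warning("context window at %s:%d clipped to %d nt", chrom, variant.pos, len(window))

    region = annotation.region_at(chrom, variant.pos0)
    exon = None
    gene_id = ""
    if region == "exon":
        exon = annotation.exon_at(chrom, variant.pos0)
        gene_id = exon.gene_id
        frame_mode, strands = "one_frame", (exon.strand,)
    elif region == "intron":
        intron = annotation.intron_at(chrom, variant.pos0)
        gene_id = intron.gene_id
        frame_mode, strands = "three_frame", (intron.strand,)
    else:
        flank_strands = annotation.flanking_gene_strands(chrom, variant.pos0,
                                                         six_frame_search_dist)
        if len(flank_strands) == 1:
            frame_mode, strands = "three_frame", (next(iter(flank_strands)),)
        else:
            frame_mode, strands = "six_frame", ("+", "-")

    return MutationContext(
        variant=variant, window=window, window_start=win_start, window_end=win_end,
        offset=len(left), region_type=region, frame_mode=frame_mode,
        strands=strands, flank=flank, exon=exon, gene_id=gene_id,
    )


def _exon_frame_offset(ctx: MutationContext) -> int:
    """Offset (0-2) into the window (or its reverse complement for '-' genes)
    at which codons of the annotated CDS begin."""
    exon = ctx.exon
    if exon is None or exon.cds_offset is None:
        raise ValueError("one_frame translation needs an exon with a known cds_offset")
    if exon.strand == "+":
        for phi in range(3):
            if (exon.cds_offset + (ctx.window_start + phi) - exon.start) % 3 == 0:
                return phi
    else:
        # reverse-complement coordinates: rc index i maps to genomic
        # win_end-1-i for the portion downstream of the variant, which is
        # where translation starts for '-' genes.
        for phi in range(3):
            g = ctx.window_end - 1 - phi
            if (exon.cds_offset + (exon.end - 1 - g)) % 3 == 0:
                return phi
    raise AssertionError("unreachable: some phi in 0..2 always aligns")


# ---------------------------------------------------------------------------
# Translation

def translate_context(ctx: MutationContext) -> List[TranslatedFragment]:
    """Translate the window per the context's frame policy.

    Each frame's translation is split at stop codons; a sub-fragment is kept
    only if it carries at least one variant-altered residue.  For frameshift
    indels every residue from the variant codon to the end of its stop-free
    fragment is novel-frame and counts as altered.  Frames whose nucleotides
    include N are skipped with a warning.
    """
    v = ctx.variant
    frameshift = v.is_frameshift
    fragments: List[TranslatedFragment] = []
    for strand in ctx.strands:
        if strand == "+":
            seq = ctx.window
            alt_a, alt_b = ctx.offset, ctx.offset + len(v.alt)
        else:
            seq = revcomp(ctx.window)
            alt_a = len(ctx.window) - (ctx.offset + len(v.alt))
            alt_b = len(ctx.window) - ctx.offset
        frames = [_exon_frame_offset(ctx)] if ctx.frame_mode == "one_frame" else [0, 1, 2]
        for f in frames:
            trimmed = seq[f : f + 3 * ((len(seq) - f) // 3)]
            if not trimmed:
                continue
            if "N" in trimmed:
                logger.warning("N in window at %s:%d; skipping strand %s frame %d",
                               v.chrom, v.pos, strand, f)
                continue
            aa = str(Seq(trimmed).translate())
            if alt_b - 1 < f:
                continue  # variant bases fell upstream of this frame's start
            r_start = max(0, (alt_a - f) // 3)
            if frameshift:
                mutant = None  # handled per stop-fragment below
            else:
                r_end = (alt_b - 1 - f) // 3
                mutant = set(range(r_start, min(r_end + 1, len(aa))))
                if not mutant:
                    continue
            # split at stop codons, tracking residue offsets
            s0 = 0
            for part in aa.split("*"):
                if part:
                    if frameshift:
                        if s0 <= r_start < s0 + len(part):
                            local = frozenset(range(r_start - s0, len(part)))
                        else:
                            local = frozenset()
                    else:
                        local = frozenset(m - s0 for m in mutant if s0 <= m < s0 + len(part))
                    if local:
                        fragments.append(TranslatedFragment(
                            seq=part, strand=strand, frame=f,
                            mutant_residues=local, frameshift=frameshift,
                        ))
                s0 += len(part) + 1  # +1 for the stop
    return fragments


# ---------------------------------------------------------------------------
# Candidate enumeration and filtering

def enumerate_mutant_peptides(fragments: Sequence[TranslatedFragment], ctx: MutationContext,
                              len_min: int = PEPTIDE_LEN_MIN,
                              len_max: int = PEPTIDE_LEN_MAX) -> Dict[str, CandidatePeptide]:
    """All length 8-15 substrings covering >=1 altered residue, deduplicated
    by sequence with first-seen provenance kept."""
    out: Dict[str, CandidatePeptide] = {}
    for frag in fragments:
        n = len(frag.seq)
        if n < len_min or not frag.mutant_residues:
            continue
        lo, hi = min(frag.mutant_residues), max(frag.mutant_residues)
        for start in range(0, n - len_min + 1):
            for length in range(len_min, min(len_max, n - start) + 1):
                end = start + length
                if end <= lo or start > hi:
                    if end <= lo:
                        continue
                    break
                covered = [m for m in frag.mutant_residues if start <= m < end]
                if not covered:
                    continue
                pep = frag.seq[start:end]
                if pep not in out:
                    out[pep] = CandidatePeptide(
                        peptide=pep, variant=ctx.variant, strand=frag.strand,
                        frame=frag.frame, frameshift=frag.frameshift,
                        mutant_start=min(covered) - start,
                        mutant_end=max(covered) - start + 1,
                        region_type=ctx.region_type, gene_id=ctx.gene_id,
                    )
    return out


def subtract_canonical(candidates: Mapping[str, CandidatePeptide],
                       proteome: ProteomeDB) -> Dict[str, CandidatePeptide]:
    """Drop candidates occurring verbatim in any canonical protein."""
    kept = {seq: c for seq, c in candidates.items() if not proteome.contains(seq)}
    removed = len(candidates) - len(kept)
    if removed:
        logger.info("canonical subtraction removed %d / %d candidates", removed, len(candidates))
    return kept


def affinity_filter(candidates: Mapping[str, CandidatePeptide],
                    predictions: pd.DataFrame, rank_threshold: float = 2.0,
                    keep_missing: bool = False) -> Dict[str, CandidatePeptide]:
    """Keep candidates whose best-allele percentile rank is <= threshold.

    ``predictions`` uses columns peptide, allele, rank_percent, ic50_nm.
    The best (minimal-rank) allele is recorded on each kept candidate, ties
    broken by allele name.  Prediction rows for unknown peptides are ignored
    with a count; candidates lacking any prediction are dropped (or kept
    un-annotated with ``keep_missing=True``).
    """
    known = set(candidates)
    unknown = predictions.loc[~predictions["peptide"].isin(known)]
    if len(unknown):
        logger.info("ignoring %d prediction rows for unknown peptides", len(unknown))
    best = (predictions.loc[predictions["peptide"].isin(known)]
            .sort_values(["peptide", "rank_percent", "allele"], kind="mergesort")
            .drop_duplicates("peptide", keep="first")
            .set_index("peptide"))
    out: Dict[str, CandidatePeptide] = {}
    n_missing = 0
    for seq, cand in candidates.items():
        if seq not in best.index:
            n_missing += 1
            if keep_missing:
                out[seq] = cand
            continue
        row = best.loc[seq]
        if float(row["rank_percent"]) <= rank_threshold:
            cand.allele = str(row["allele"])
            cand.rank_percent = float(row["rank_percent"])
            cand.ic50_nm = float(row["ic50_nm"])
            out[seq] = cand
    if n_missing:
        logger.warning("%d candidates had no affinity prediction (%s)",
                       n_missing, "kept" if keep_missing else "dropped")
    return out


# ---------------------------------------------------------------------------
# Mock affinity predictor

class MockAffinityPredictor:
    """Deterministic hash-based stand-in for an external pMHC binding
    predictor, so the rank filter is testable without network tools.

    Each peptide is designated a binder with probability ``binder_fraction``
    (decided by a hash of peptide and seed, so the call is reproducible and
    order-independent).  Binders get a best-allele rank in (0, 2],
    non-binders ranks in (2, 90].  IC50 is a monotone map of rank.
    """

    def __init__(self, alleles: Sequence[str] = DEFAULT_ALLELES, seed: int = 0,
                 binder_fraction: float = 0.7):
        if not 0.0 <= binder_fraction <= 1.0:
            raise ValueError("binder_fraction must be in [0, 1]")
        self.alleles = tuple(alleles)
        self.seed = int(seed)
        self.binder_fraction = float(binder_fraction)

    def _u(self, *parts: str) -> float:
        digest = hashlib.blake2b(":".join(parts).encode(), digest_size=8).digest()
        return int.from_bytes(digest, "big") / 2**64

    @staticmethod
    def rank_to_ic50(rank: float) -> float:
        """Monotone rank -> IC50 (nM) map; ~500 nM near rank 2%."""
        return 12.0 * math.exp(1.87 * rank)

    def predict(self, peptides: Iterable[str]) -> pd.DataFrame:
        rows = []
        for pep in peptides:
            is_binder = self._u(str(self.seed), pep, "binder") < self.binder_fraction
            best_idx = int(self._u(str(self.seed), pep, "best") * len(self.alleles))
            for i, allele in enumerate(self.alleles):
                u = self._u(str(self.seed), pep, allele)
                if is_binder and i == best_idx:
                    rank = 0.05 + u * 1.95
                else:
                    rank = 2.0001 + u * 88.0
                rows.append((pep, allele, round(rank, 4), round(self.rank_to_ic50(rank), 2)))
        return pd.DataFrame(rows, columns=["peptide", "allele", "rank_percent", "ic50_nm"])


# ---------------------------------------------------------------------------
# Protein-level annotation of exonic changes

def protein_change(variant: Variant, annotation: RegionAnnotation,
                   genome: GenomeRef) -> Optional[str]:
    """HGVS-like p. description for an exonic variant (codon fully inside one
    exon), e.g. ``p.A324T`` for a missense SNV or ``p.K88fs`` for a
    frameshift.  Returns None outside exons or when the codon cannot be
    reconstructed from one exon."""
    exon = annotation.exon_at(variant.chrom, variant.pos0)
    if exon is None or exon.cds_offset is None:
        return None
    if exon.strand == "+":
        cds_pos = exon.cds_offset + (variant.pos0 - exon.start)
        idx = cds_pos % 3
        codon_start = variant.pos0 - idx
        if codon_start < exon.start or codon_start + 3 > exon.end:
            return None
        codon = genome.fetch(variant.chrom, codon_start, codon_start + 3)
        alt_base = variant.alt
    else:
        cds_pos = exon.cds_offset + (exon.end - 1 - variant.pos0)
        idx = cds_pos % 3
        codon_start = variant.pos0 + idx - 2
        if codon_start < exon.start or codon_start + 3 > exon.end:
            return None
        codon = revcomp(genome.fetch(variant.chrom, codon_start, codon_start + 3))
        alt_base = revcomp(variant.alt)
        idx = idx  # position within the 5'->3' codon already correct
    residue = cds_pos // 3 + 1  # 1-based protein position
    wild_aa = str(Seq(codon).translate())
    if variant.is_frameshift:
        return f"p.{wild_aa}{residue}fs"
    if variant.variant_class == "SNV":
        mut_codon = codon[:idx] + alt_base + codon[idx + 1:]
        mut_aa = str(Seq(mut_codon).translate())
        return f"p.{wild_aa}{residue}{mut_aa}"
    return f"p.{wild_aa}{residue}delins"


# ---------------------------------------------------------------------------
# FASTA emission

_HEADER_RE = re.compile(
    r"NEOPEP\|(?P<chrom>[^:|]+):(?P<pos>\d+)\|(?P<ref>[A-Z]+)>(?P<alt>[A-Z]+)\|"
    r"(?P<gene>[^|]*)\|(?P<region>[^|]*)\|(?P<strand>[+-])(?P<frame>\d)\|(?P<aa_change>[^|]*)"
)


def mutant_header(cand: CandidatePeptide) -> str:
    v = cand.variant
    return (f"NEOPEP|{v.chrom}:{v.pos}|{v.ref}>{v.alt}|{cand.gene_id or '.'}|"
            f"{cand.region_type or '.'}|{cand.strand}{cand.frame}|{cand.aa_change or '.'}")


def parse_mutant_header(header: str) -> Dict[str, str]:
    """Recover variant locus, gene, region and AA change from a record id."""
    m = _HEADER_RE.search(header)
    if not m:
        raise ValueError(f"not a personalized-database mutant header: {header!r}")
    d = m.groupdict()
    d["pos"] = int(d["pos"])
    return d


def build_personalized_fasta(retained: Mapping[str, CandidatePeptide],
                             proteome: ProteomeDB, out_path,
                             allow_empty: bool = False) -> None:
    """Canonical records (by accession) then mutant peptides (by locus and
    sequence), with structured headers; deterministic byte-for-byte."""
    if not retained and not allow_empty:
        raise ValueError("no mutant peptides retained; pass allow_empty=True to emit anyway")
    records: List[Tuple[str, str]] = [(acc, proteome[acc]) for acc in sorted(proteome)]
    mutants = sorted(retained.values(),
                     key=lambda c: (c.variant.chrom, c.variant.pos, c.peptide))
    records.extend((mutant_header(c), c.peptide) for c in mutants)
    write_fasta(records, out_path)


# ---------------------------------------------------------------------------
# One-call pipeline for a variant set

def build_candidates(variants: Sequence[Variant], genome: GenomeRef,
                     annotation: RegionAnnotation, flank: int = FLANK_MAX,
                     len_min: int = PEPTIDE_LEN_MIN,
                     len_max: int = PEPTIDE_LEN_MAX) -> Dict[str, CandidatePeptide]:
    """Window + translate + enumerate for every variant; dedup by sequence."""
    out: Dict[str, CandidatePeptide] = {}
    for v in variants:
        ctx = extract_mutation_context(v, genome, annotation, flank=flank)
        frags = translate_context(ctx)
        cands = enumerate_mutant_peptides(frags, ctx, len_min=len_min, len_max=len_max)
        for seq, c in cands.items():
            if seq not in out:
                if c.region_type == "exon":
                    c.aa_change = protein_change(v, annotation, genome) or ""
                out[seq] = c
    return out
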