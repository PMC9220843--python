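"""Deterministic synthetic-data generator with planted ground truth.

Generates every input the pipeline consumes — genome, gene annotation,
proteome, somatic variants, sORF database, three engine PSM tables, affinity
and retention-time tables — from a single seed, and records what was
planted so every stage can be checked for exact recovery:

* exonic SNVs and frameshift indels, with the mutation-covering 8-15-mers
  and protein-level change they should yield;
* non-canonical peptides of intronic, intergenic, sORF and cis-splice
  origin, with their encoding loci / parent configurations;
* an engine-overlap (Venn) structure over the peptide catalog, with de novo
  decoys whose scores sit well below the calibration quantile.

One SeedSequence is split into named child streams (genome, variants,
peptides, engines, affinity, rt) so sub-generators are independently
reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .core import GenomeRef, ProteomeDB, RegionAnnotation, RegionInterval, Variant, revcomp
from .persdb import DEFAULT_ALLELES, MockAffinityPredictor

logger = logging.getLogger(__name__)

AA_CHOICES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT_CHOICES = np.array(list("ACGT"))

#: amino acid -> synonymous codons (standard genetic code)
_CODONS: Dict[str, List[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)


def _rand_seq(rng: np.random.Generator, n: int, choices: np.ndarray = NT_CHOICES) -> str:
    return "".join(choices[rng.integers(0, len(choices), n)])


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + _rand_seq(rng, n - 1, AA_CHOICES)


def _translate(seq: str) -> str:
    return str(Seq(seq[: 3 * (len(seq) // 3)]).translate())


# ---------------------------------------------------------------------------
# Specification

DEFAULT_VARIANT_COUNTS: Dict[Tuple[str, str], int] = {
    ("exon", "SNV"): 30,
    ("exon", "DEL"): 3,
    ("exon", "INS"): 2,
    ("intron", "SNV"): 10,
    ("intergenic", "SNV"): 5,
}

DEFAULT_OVERLAP: Dict[Tuple[str, ...], int] = {
    ("db1",): 40,
    ("db2",): 40,
    ("denovo",): 90,
    ("db1", "db2"): 50,
    ("db1", "denovo"): 30,
    ("db2", "denovo"): 30,
    ("db1", "db2", "denovo"): 100,
}


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset.

    Scores of true peptides must dominate decoys by at least five standard
    deviations so the calibrated de novo cutoff separates them exactly.
    """

    seed: int = 0
    # genome / gene models
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    protein_length_range: Tuple[int, int] = (140, 300)   # aa
    exon_count_range: Tuple[int, int] = (2, 4)
    min_exon_nt: int = 120
    intron_length_range: Tuple[int, int] = (200, 800)
    min_intergenic_nt: int = 800
    # variants
    flank: int = 45
    variant_counts: Mapping[Tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_COUNTS))
    # peptide pools
    n_canonical: int = 400
    n_noncanon_intron: int = 20
    n_noncanon_intergenic: int = 20
    n_sorf_records: int = 30
    sorf_length_range: Tuple[int, int] = (20, 60)
    n_noncanon_sorf: int = 20
    n_noncanon_splice: int = 20
    splice_fragment_range: Tuple[int, int] = (4, 7)
    splice_intervening_range: Tuple[int, int] = (3, 40)
    # engine evidence structure
    overlap: Mapping[Tuple[str, ...], int] = field(default_factory=lambda: dict(DEFAULT_OVERLAP))
    n_denovo_decoys: int = 50
    denovo_q: float = 25.0
    true_score_mean: float = 100.0
    true_score_sd: float = 3.0
    #: fraction of shared de novo peptides whose best score sits exactly at
    #: the calibration floor (must exceed denovo_q/100 so the inclusive
    #: percentile cutoff lands on the floor and retains every shared peptide)
    shared_floor_fraction: float = 0.30
    decoy_score_mean: float = 60.0
    decoy_score_sd: float = 3.0
    db1_score_mean: float = 150.0
    db1_score_sd: float = 30.0
    db2_score_mean: float = 20.0
    db2_score_sd: float = 4.0
    psm_extra_mean: float = 1.0      # extra PSMs ~ Poisson -> ~63% multi-PSM
    charge_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.03, 2: 0.728, 3: 0.2, 4: 0.042})
    # affinity / RT
    alleles: Tuple[str, ...] = DEFAULT_ALLELES
    binder_fraction: float = 0.7
    rt_sigma_s: float = 10.0
    rt_range_s: Tuple[float, float] = (600.0, 5400.0)
    n_batches: int = 3

    @property
    def score_floor(self) -> float:
        """De novo score at the calibration floor (5 SD below the true mean)."""
        return self.true_score_mean - 5 * self.true_score_sd

    def __post_init__(self):
        if any(n < 0 for n in self.variant_counts.values()):
            raise ValueError("variant counts must be >= 0")
        if any(n < 0 for n in self.overlap.values()):
            raise ValueError("overlap counts must be >= 0")
        gap = self.true_score_mean - self.decoy_score_mean
        if gap < 5 * max(self.true_score_sd, self.decoy_score_sd):
            raise ValueError(
                "true scores must dominate decoys by >= 5 SD for exact separation")
        if not self.denovo_q / 100.0 < self.shared_floor_fraction <= 1.0:
            raise ValueError("shared_floor_fraction must exceed denovo_q/100")
        if self.score_floor <= self.decoy_score_mean + 5 * self.decoy_score_sd:
            raise ValueError("calibration floor must sit >= 5 SD above decoy scores")
        n_noncanon = (self.n_noncanon_intron + self.n_noncanon_intergenic
                      + self.n_noncanon_sorf + self.n_noncanon_splice)
        if self.overlap.get(("denovo",), 0) < n_noncanon:
            raise ValueError(
                "the denovo-only overlap cell must hold all planted non-canonical peptides")
        if not 0 <= self.binder_fraction <= 1:
            raise ValueError("binder_fraction in [0, 1]")


# ---------------------------------------------------------------------------
# Planted-truth records

@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]       # genomic order
    cds_offsets: List[int]             # per genomic exon, strand-aware CDS offset
    cds: str
    protein: str

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass
class PlantedVariant:
    variant: Variant
    region: str
    gene_id: str = ""
    aa_change: str = ""
    truth_peptides: Tuple[str, ...] = ()
    altered_residue: Optional[int] = None  # 0-based, in the mutant protein


@dataclass
class SpliceTruth:
    peptide: str
    parent: str
    split: int
    n_start: int
    n_end: int
    c_start: int
    c_end: int
    orientation: str
    intervening: int


@dataclass
class PlantedNoncanon:
    peptide: str
    origin: str                        # intron | intergenic | sorf | splice
    locus: Optional[Tuple[str, int, str]] = None   # (chrom, start, strand)
    sorf_acc: str = ""
    splice: Optional[SpliceTruth] = None


@dataclass
class SynthData:
    spec: SynthSpec
    genome: GenomeRef
    annotation: RegionAnnotation
    proteome: ProteomeDB
    genes: List[Gene]
    variants: List[PlantedVariant]
    noncanon: List[PlantedNoncanon]
    sorf_db: ProteomeDB
    canonical_peptides: List[str]
    mutant_catalog: Dict[str, str]           # representative peptide -> aa_change
    assignment: Dict[Tuple[str, ...], List[str]]   # overlap cell -> peptides
    decoys: List[str]
    tables: Dict[str, pd.DataFrame]          # db1, db2, denovo, affinity, rt
    transcripts: Dict[str, str]
    exon_seqs: Dict[str, str]


# ---------------------------------------------------------------------------
# Genome and annotation

def make_genome_and_annotation(spec: SynthSpec, rng: np.random.Generator
                               ) -> Tuple[GenomeRef, RegionAnnotation, ProteomeDB, List[Gene]]:
    """Random genome with non-overlapping gene models on both strands; the
    proteome is the translation of each gene's CDS; exon/intron intervals
    cover gene bodies and intergenic is the complement."""
    chrom_ids = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    parts: Dict[str, List[str]] = {c: [] for c in chrom_ids}
    cursors: Dict[str, int] = {c: 0 for c in chrom_ids}
    genes: List[Gene] = []
    intervals: List[RegionInterval] = []

    for gi in range(spec.n_genes):
        gene_id = f"GENE{gi + 1:03d}"
        chrom = chrom_ids[gi % spec.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        plen = int(rng.integers(*spec.protein_length_range))
        protein = _rand_protein(rng, plen)
        codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
        cds = "".join(codons) + STOP_CODONS[rng.integers(0, len(STOP_CODONS))]

        # split the CDS into exon pieces, each >= min_exon_nt
        max_exons = max(1, len(cds) // spec.min_exon_nt)
        n_exons = int(min(rng.integers(spec.exon_count_range[0],
                                       spec.exon_count_range[1] + 1), max_exons))
        cuts = [0]
        for i in range(1, n_exons):
            lo = cuts[-1] + spec.min_exon_nt
            hi = len(cds) - (n_exons - i) * spec.min_exon_nt
            cuts.append(int(rng.integers(lo, hi + 1)) if hi >= lo else cuts[-1])
        cuts.append(len(cds))
        pieces = [cds[cuts[i]:cuts[i + 1]] for i in range(n_exons) if cuts[i + 1] > cuts[i]]
        offsets = list(itertools.accumulate([0] + [len(p) for p in pieces]))[:-1]

        intron_seqs = [_rand_seq(rng, int(rng.integers(*spec.intron_length_range)))
                       for _ in range(len(pieces) - 1)]
        gene_seq = pieces[0]
        exon_local = [(0, len(pieces[0]))]
        for piece, intr in zip(pieces[1:], intron_seqs):
            gene_seq += intr
            exon_local.append((len(gene_seq), len(gene_seq) + len(piece)))
            gene_seq += piece

        gap = int(rng.integers(spec.min_intergenic_nt, 2 * spec.min_intergenic_nt))
        gstart = cursors[chrom] + gap
        gend = gstart + len(gene_seq)
        if gend + spec.min_intergenic_nt > spec.chrom_length:
            raise ValueError(
                f"infeasible packing: gene models exceed {chrom} length {spec.chrom_length}")
        parts[chrom].append(_rand_seq(rng, gap))
        if strand == "+":
            parts[chrom].append(gene_seq)
            exons = [(gstart + a, gstart + b) for a, b in exon_local]
            cds_offsets = list(offsets)
        else:
            parts[chrom].append(revcomp(gene_seq))
            # local interval (a, b) maps to genomic (gstart + L - b, gstart + L - a)
            L = len(gene_seq)
            exons = [(gstart + L - b, gstart + L - a) for a, b in reversed(exon_local)]
            cds_offsets = list(reversed(offsets))
        cursors[chrom] = gend

        genes.append(Gene(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons,
                          cds_offsets=cds_offsets, cds=cds, protein=protein))
        for (a, b), off in zip(exons, cds_offsets):
            intervals.append(RegionInterval(chrom=chrom, start=a, end=b, region_type="exon",
                                            strand=strand, gene_id=gene_id, cds_offset=off))
        for a, b in genes[-1].introns:
            intervals.append(RegionInterval(chrom=chrom, start=a, end=b, region_type="intron",
                                            strand=strand, gene_id=gene_id))

    seqs = {}
    for chrom in chrom_ids:
        tail = spec.chrom_length - cursors[chrom]
        parts[chrom].append(_rand_seq(rng, tail))
        seqs[chrom] = "".join(parts[chrom])

    genome = GenomeRef(seqs)
    annotation = RegionAnnotation(intervals)
    proteome = ProteomeDB({g.gene_id: g.protein for g in genes})
    return genome, annotation, proteome, genes


# ---------------------------------------------------------------------------
# Variant planting

def _codon_sites(gene: Gene, margin: int) -> List[Tuple[int, int]]:
    """(residue index, genomic exon index) of codons fully inside one exon
    with >= margin nt of exon on both sides."""
    sites = []
    for ei, ((a, b), off) in enumerate(zip(gene.exons, gene.cds_offsets)):
        elen = b - a
        for u in range(0, elen - 2):
            if (off + u) % 3 != 0:
                continue
            if u >= margin and elen - (u + 3) >= margin:
                sites.append(((off + u) // 3, ei))
    return sites


def _codon_genomic_start(gene: Gene, exon_idx: int, residue: int) -> int:
    """Genomic coordinate of the strand-aware first base of a codon."""
    a, b = gene.exons[exon_idx]
    u = 3 * residue - gene.cds_offsets[exon_idx]
    return a + u if gene.strand == "+" else b - 1 - u


def _first_difference(wild: str, mutant: str) -> Optional[int]:
    """Index of the first residue where the proteins differ; when one is a
    strict prefix of the other the index is the shorter length; None when
    identical."""
    for i, (w, m) in enumerate(zip(wild, mutant)):
        if w != m:
            return i
    if len(mutant) != len(wild):
        return min(len(mutant), len(wild))
    return None


def _truth_peptides(mut_prot: str, r0: int, proteome: ProteomeDB,
                    len_min: int = 8, len_max: int = 15) -> Tuple[str, ...]:
    """All 8-15-mers of the mutant protein covering residue r0, minus any
    that also occur in the canonical proteome."""
    peps = set()
    for length in range(len_min, len_max + 1):
        for start in range(max(0, r0 - length + 1), r0 + 1):
            end = start + length
            if end <= len(mut_prot):
                pep = mut_prot[start:end]
                if not proteome.contains(pep):
                    peps.add(pep)
    return tuple(sorted(peps))


def plant_variants(spec: SynthSpec, genome: GenomeRef, annotation: RegionAnnotation,
                   proteome: ProteomeDB, genes: List[Gene],
                   rng: np.random.Generator) -> List[PlantedVariant]:
    planted: List[PlantedVariant] = []
    used_pos: Set[Tuple[str, int]] = set()
    margin = spec.flank + 6  # keeps the whole context window inside one exon
    comp = str.maketrans("ACGT", "TGCA")

    def register(pv: PlantedVariant) -> bool:
        key = (pv.variant.chrom, pv.variant.pos)
        if key in used_pos:
            return False
        pv.variant.check_against(genome)
        used_pos.add(key)
        planted.append(pv)
        return True

    exonic_genes = [g for g in genes if _codon_sites(g, margin)]
    for (region, vclass), count in spec.variant_counts.items():
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * max(count, 1):
                raise RuntimeError(f"could not plant {count} {region}/{vclass} variants")
            if region == "exon":
                gene = exonic_genes[rng.integers(0, len(exonic_genes))]
                sites = _codon_sites(gene, margin)
                r, ei = sites[rng.integers(0, len(sites))]
                wild = gene.protein
                if vclass == "SNV":
                    b = int(rng.integers(0, 3))
                    q = 3 * r + b
                    old = gene.cds[q]
                    alts = [c for c in "ACGT" if c != old]
                    c = alts[rng.integers(0, 3)]
                    codon = gene.cds[3 * r: 3 * r + 3]
                    mut_codon = codon[:b] + c + codon[b + 1:]
                    mut_aa = _translate(mut_codon)
                    if mut_aa in ("*", wild[r]):
                        continue
                    g0 = _codon_genomic_start(gene, ei, r)
                    gpos = g0 + b if gene.strand == "+" else g0 - b
                    ref_g = genome[gene.chrom][gpos]
                    alt_g = c if gene.strand == "+" else c.translate(comp)
                    mut_prot = wild[:r] + mut_aa + wild[r + 1:]
                    truth = _truth_peptides(mut_prot, r, proteome)
                    if not truth:
                        continue
                    pv = PlantedVariant(
                        variant=Variant(gene.chrom, gpos + 1, ref_g, alt_g),
                        region="exon", gene_id=gene.gene_id,
                        aa_change=f"p.{wild[r]}{r + 1}{mut_aa}",
                        truth_peptides=truth, altered_residue=r)
                elif vclass in ("DEL", "INS"):
                    d = int(rng.integers(1, 3))  # 1 or 2 nt -> frameshift
                    q = 3 * r
                    if vclass == "DEL":
                        mut_cds = gene.cds[:q] + gene.cds[q + d:]
                    else:
                        ins = _rand_seq(rng, d)
                        mut_cds = gene.cds[:q] + ins + gene.cds[q:]
                    mut_prot = _translate(mut_cds).split("*")[0]
                    r0 = _first_difference(wild, mut_prot)
                    # require the first novel residue at the planted codon
                    # itself (a coincidental wild-type match there would push
                    # the 15-mer truth window one codon past the flank reach)
                    if r0 is None or r0 != r or r0 >= len(mut_prot):
                        continue
                    truth = _truth_peptides(mut_prot, r0, proteome)
                    if not truth:
                        continue
                    g0 = _codon_genomic_start(gene, ei, r)  # genomic pos of cds base q
                    chrom_seq = genome[gene.chrom]
                    if vclass == "DEL":
                        if gene.strand == "+":
                            pos0 = g0 - 1                     # anchor = cds base q-1
                            ref_g = chrom_seq[pos0: pos0 + d + 1]
                            alt_g = chrom_seq[pos0]
                            q_anchor = q - 1
                        else:
                            pos0 = g0 - d                     # leftmost deleted base - 1
                            ref_g = chrom_seq[pos0: pos0 + d + 1]
                            alt_g = chrom_seq[pos0]
                            q_anchor = q + d                  # anchor base is cds q+d... see below
                    else:  # INS
                        if gene.strand == "+":
                            pos0 = g0 - 1
                            ref_g = chrom_seq[pos0]
                            alt_g = ref_g + ins
                            q_anchor = q - 1
                        else:
                            pos0 = g0                         # anchor = cds base q
                            ref_g = chrom_seq[pos0]
                            alt_g = ref_g + revcomp(ins)
                            q_anchor = q
                    anchor_res = q_anchor // 3
                    pv = PlantedVariant(
                        variant=Variant(gene.chrom, pos0 + 1, ref_g, alt_g),
                        region="exon", gene_id=gene.gene_id,
                        aa_change=f"p.{wild[anchor_res]}{anchor_res + 1}fs",
                        truth_peptides=truth, altered_residue=r0)
                else:
                    raise ValueError(f"unsupported exonic class {vclass}")
            elif region == "intron":
                with_introns = [g for g in genes if g.introns]
                gene = with_introns[rng.integers(0, len(with_introns))]
                a, b = gene.introns[rng.integers(0, len(gene.introns))]
                pos0 = int(rng.integers(a + 5, b - 5))
                ref_g = genome[gene.chrom][pos0]
                alt_g = [c for c in "ACGT" if c != ref_g][rng.integers(0, 3)]
                pv = PlantedVariant(variant=Variant(gene.chrom, pos0 + 1, ref_g, alt_g),
                                    region="intron", gene_id=gene.gene_id)
            elif region == "intergenic":
                chrom = f"chr{int(rng.integers(1, spec.n_chroms + 1))}"
                pos0 = int(rng.integers(0, genome.length(chrom)))
                if annotation.region_at(chrom, pos0) != "intergenic":
                    continue
                ref_g = genome[chrom][pos0]
                if ref_g == "N":
                    continue
                alt_g = [c for c in "ACGT" if c != ref_g][rng.integers(0, 3)]
                pv = PlantedVariant(variant=Variant(chrom, pos0 + 1, ref_g, alt_g),
                                    region="intergenic")
            else:
                raise ValueError(f"unknown region {region}")
            if register(pv):
                made += 1
    return planted


# ---------------------------------------------------------------------------
# Non-canonical peptide planting

def _plant_window_peptide(genome: GenomeRef, proteome: ProteomeDB, chrom: str,
                          lo: int, hi: int, rng: np.random.Generator,
                          used: Set[str]) -> Optional[Tuple[str, Tuple[str, int, str]]]:
    """Translate a random in-frame window of [lo, hi) on a random strand into
    a stop-free peptide absent from the canonical proteome."""
    length = int(rng.integers(8, 12))
    span = 3 * length
    if hi - lo <= span:
        return None
    start = int(rng.integers(lo, hi - span))
    strand = "+" if rng.random() < 0.5 else "-"
    nt = genome.fetch(chrom, start, start + span)
    pep = _translate(nt if strand == "+" else revcomp(nt))
    if "*" in pep or "X" in pep or pep in used or proteome.contains(pep):
        return None
    return pep, (chrom, start, strand)


def _brute_min_splice(peptide: str, proteome: ProteomeDB, min_frag: int = 3
                      ) -> Optional[Tuple[int, str, int, int, int, str]]:
    """Generator-internal exhaustive scan for the least-intervening
    (intervening, parent, split, n_start, c_start, orientation) configuration,
    with the selection tie-break applied; used to certify planted cis-splice
    peptides as the unique global optimum."""
    n = len(peptide)
    best = None
    for acc in sorted(proteome):
        seq = proteome[acc]
        for s in range(min_frag, n - min_frag + 1):
            nfrag, cfrag = peptide[:s], peptide[s:]
            i = seq.find(nfrag)
            n_occ = []
            while i != -1:
                n_occ.append(i)
                i = seq.find(nfrag, i + 1)
            j = seq.find(cfrag)
            c_occ = []
            while j != -1:
                c_occ.append(j)
                j = seq.find(cfrag, j + 1)
            for i in n_occ:
                for j in c_occ:
                    if i + s <= j:
                        gap, orient = j - (i + s), "normal"
                    elif j + (n - s) <= i:
                        gap, orient = i - (j + (n - s)), "reverse"
                    else:
                        continue
                    key = (gap, acc, s, i)
                    if best is None or key < best[:4]:
                        best = (gap, acc, s, i, j, orient)
    return best


def plant_noncanonical(spec: SynthSpec, genome: GenomeRef, annotation: RegionAnnotation,
                       proteome: ProteomeDB, genes: List[Gene],
                       rng: np.random.Generator) -> Tuple[List[PlantedNoncanon], ProteomeDB]:
    planted: List[PlantedNoncanon] = []
    used: Set[str] = set()

    def attempt_loop(n_target: int, fn, what: str):
        made, attempts = 0, 0
        while made < n_target:
            attempts += 1
            if attempts > 500 * max(n_target, 1):
                raise RuntimeError(f"could not plant {n_target} {what} peptides")
            item = fn()
            if item is not None:
                planted.append(item)
                used.add(item.peptide)
                made += 1

    with_introns = [g for g in genes if g.introns]

    def intron_fn():
        gene = with_introns[rng.integers(0, len(with_introns))]
        a, b = gene.introns[rng.integers(0, len(gene.introns))]
        got = _plant_window_peptide(genome, proteome, gene.chrom, a, b, rng, used)
        if got is None:
            return None
        pep, locus = got
        return PlantedNoncanon(peptide=pep, origin="intron", locus=locus)

    def intergenic_fn():
        chrom = f"chr{int(rng.integers(1, spec.n_chroms + 1))}"
        pos = int(rng.integers(0, genome.length(chrom) - 50))
        span_probe = 3 * 11
        if annotation.types_in(chrom, pos, pos + span_probe) != {"intergenic"}:
            return None
        got = _plant_window_peptide(genome, proteome, chrom, pos, pos + span_probe + 1,
                                    rng, used)
        if got is None:
            return None
        pep, locus = got
        return PlantedNoncanon(peptide=pep, origin="intergenic", locus=locus)

    attempt_loop(spec.n_noncanon_intron, intron_fn, "intronic")
    attempt_loop(spec.n_noncanon_intergenic, intergenic_fn, "intergenic")

    # sORF database and sORF-derived peptides
    sorf_seqs = {
        f"SORF{i + 1:04d}": _rand_seq(rng, int(rng.integers(*spec.sorf_length_range)),
                                      AA_CHOICES)
        for i in range(spec.n_sorf_records)
    }
    sorf_db = ProteomeDB(sorf_seqs)
    sorf_accs = sorted(sorf_seqs)

    def sorf_fn():
        acc = sorf_accs[rng.integers(0, len(sorf_accs))]
        seq = sorf_seqs[acc]
        length = int(rng.integers(8, 12))
        if len(seq) <= length:
            return None
        start = int(rng.integers(0, len(seq) - length))
        pep = seq[start: start + length]
        if pep in used or proteome.contains(pep):
            return None
        return PlantedNoncanon(peptide=pep, origin="sorf", sorf_acc=acc)

    attempt_loop(spec.n_noncanon_sorf, sorf_fn, "sORF")

    accs = sorted(proteome)

    def splice_fn():
        acc = accs[rng.integers(0, len(accs))]
        seq = proteome[acc]
        nlen = int(rng.integers(*spec.splice_fragment_range))
        clen = int(rng.integers(*spec.splice_fragment_range))
        gap = int(rng.integers(*spec.splice_intervening_range))
        orient = "normal" if rng.random() < 0.5 else "reverse"
        total = nlen + gap + clen
        if len(seq) <= total:
            return None
        i = int(rng.integers(0, len(seq) - total))
        if orient == "normal":
            n_start, c_start = i, i + nlen + gap
        else:
            c_start, n_start = i, i + clen + gap
        nfrag = seq[n_start: n_start + nlen]
        cfrag = seq[c_start: c_start + clen]
        pep = nfrag + cfrag
        if pep in used or proteome.contains(pep):
            return None
        best = _brute_min_splice(pep, proteome)
        if best is None:
            return None
        b_gap, b_acc, b_split, b_i, b_j, b_orient = best
        if (b_gap, b_acc, b_split, b_i, b_orient) != (gap, acc, nlen, n_start, orient):
            return None  # a cheaper configuration exists elsewhere; resample
        return PlantedNoncanon(
            peptide=pep, origin="splice",
            splice=SpliceTruth(peptide=pep, parent=acc, split=nlen,
                               n_start=n_start, n_end=n_start + nlen,
                               c_start=c_start, c_end=c_start + clen,
                               orientation=orient, intervening=gap))

    attempt_loop(spec.n_noncanon_splice, splice_fn, "cis-splice")
    return planted, sorf_db


# ---------------------------------------------------------------------------
# Catalog pools and engine tables

_LENGTH_DIST = {8: 0.15, 9: 0.45, 10: 0.20, 11: 0.12, 12: 0.04, 13: 0.02, 14: 0.01, 15: 0.01}


def sample_canonical_peptides(spec: SynthSpec, proteome: ProteomeDB,
                              rng: np.random.Generator,
                              exclude: Set[str]) -> List[str]:
    accs = sorted(proteome)
    lengths = np.array(sorted(_LENGTH_DIST))
    probs = np.array([_LENGTH_DIST[k] for k in lengths], dtype=float)
    probs /= probs.sum()
    out: List[str] = []
    seen: Set[str] = set(exclude)
    attempts = 0
    while len(out) < spec.n_canonical:
        attempts += 1
        if attempts > 500 * spec.n_canonical:
            raise RuntimeError("could not sample enough canonical peptides")
        acc = accs[rng.integers(0, len(accs))]
        seq = proteome[acc]
        length = int(rng.choice(lengths, p=probs))
        if len(seq) <= length:
            continue
        start = int(rng.integers(0, len(seq) - length))
        pep = seq[start: start + length]
        if pep in seen:
            continue
        seen.add(pep)
        out.append(pep)
    return out


def pick_mutant_representatives(variants: Sequence[PlantedVariant]) -> Dict[str, str]:
    """One catalog peptide per exonic variant (a 9-mer when available)."""
    reps: Dict[str, str] = {}
    for pv in variants:
        if not pv.truth_peptides:
            continue
        nine = [p for p in pv.truth_peptides if len(p) == 9]
        pep = nine[len(nine) // 2] if nine else pv.truth_peptides[0]
        if pep not in reps:
            reps[pep] = pv.aa_change
    return reps


def _sample_charge(spec: SynthSpec, rng: np.random.Generator) -> int:
    charges = sorted(spec.charge_probs)
    probs = np.array([spec.charge_probs[c] for c in charges], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(charges, p=probs))


def simulate_engine_tables(spec: SynthSpec, canonical: List[str],
                           noncanon: List[PlantedNoncanon],
                           mutant_catalog: Dict[str, str],
                           proteome: ProteomeDB,
                           rng: np.random.Generator
                           ) -> Tuple[Dict[Tuple[str, ...], List[str]], List[str],
                                      Dict[str, pd.DataFrame]]:
    """Engine PSM tables realizing the configured evidence (Venn) structure,
    plus matching affinity and RT tables.

    All non-canonical peptides go to the denovo-only cell (database engines
    cannot report peptides outside the search database); the remaining cells
    draw from canonical and mutant peptides.  De novo-private true peptides
    are scored above the calibration quantile of the shared-score vector, and
    decoys below it, so the planted structure is exactly recoverable.
    """
    noncanon_peps = [p.peptide for p in noncanon]
    pool = canonical + [p for p in mutant_catalog if p not in set(canonical)]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    assignment: Dict[Tuple[str, ...], List[str]] = {}
    for cell in sorted(spec.overlap, key=lambda c: (len(c), c)):
        count = spec.overlap[cell]
        members: List[str] = []
        if cell == ("denovo",):
            members.extend(noncanon_peps)
        while len(members) < count:
            members.append(next(pool_iter))
        assignment[cell] = members[:count]

    # decoy peptides: random 9-mers private to the de novo engine
    all_assigned = {p for peps in assignment.values() for p in peps}
    decoys: List[str] = []
    while len(decoys) < spec.n_denovo_decoys:
        pep = _rand_seq(rng, 9, AA_CHOICES)
        if pep in all_assigned or proteome.contains(pep) or pep in decoys:
            continue
        decoys.append(pep)

    predicted_rt = {}
    for pep in sorted(all_assigned | set(decoys)):
        predicted_rt[pep] = float(rng.uniform(*spec.rt_range_s))

    def psm_rows(pep: str, engine_scores: List[float], batch: str) -> List[Dict]:
        rows = []
        for k, score in enumerate(engine_scores):
            rows.append({
                "peptide": pep, "score": round(score, 5),
                "charge": _sample_charge(spec, rng),
                "rt": round(predicted_rt[pep] + rng.normal(0.0, spec.rt_sigma_s), 3),
                "spectrum": f"{batch}.{pep}.{k}", "batch": batch,
            })
        return rows

    tables: Dict[str, List[Dict]] = {"db1": [], "db2": [], "denovo": []}
    denovo_scores: Dict[str, List[float]] = {}

    # db engine scores; de novo peptides are split into shared vs private
    shared: List[str] = []
    denovo_only: List[str] = []
    for cell, peps in assignment.items():
        for pep in peps:
            batch = f"B{int(rng.integers(1, spec.n_batches + 1))}"
            n_psm = 1 + int(rng.poisson(spec.psm_extra_mean))
            if "db1" in cell:
                scores = rng.normal(spec.db1_score_mean, spec.db1_score_sd, n_psm)
                tables["db1"].extend(psm_rows(pep, list(scores), batch))
            if "db2" in cell:
                scores = rng.normal(spec.db2_score_mean, spec.db2_score_sd, n_psm)
                tables["db2"].extend(psm_rows(pep, list(scores), batch))
            if "denovo" in cell:
                (denovo_only if cell == ("denovo",) else shared).append(pep)

    # Shared de novo scores: the bottom shared_floor_fraction of peptides sit
    # exactly at the calibration floor, the rest strictly above it, so the
    # inclusive percentile cutoff equals the floor and keeps every shared
    # peptide while any decoy (>= 5 SD lower) is excluded.
    floor = spec.score_floor
    n_shared = len(shared)
    if n_shared:
        h = spec.denovo_q / 100.0 * (n_shared - 1)
        m = min(n_shared, max(int(np.ceil(spec.shared_floor_fraction * n_shared)),
                              int(np.ceil(h)) + 1))
        at_floor = set(rng.choice(n_shared, size=m, replace=False).tolist())
    else:
        at_floor = set()
    for i, pep in enumerate(shared):
        n_psm = 1 + int(rng.poisson(spec.psm_extra_mean))
        if i in at_floor:
            scores = [floor] + list(rng.uniform(floor - 5.0, floor, n_psm - 1))
        else:
            scores = [max(s, floor + 0.01)
                      for s in rng.normal(spec.true_score_mean, spec.true_score_sd, n_psm)]
        denovo_scores[pep] = scores
    for pep in denovo_only:
        n_psm = 1 + int(rng.poisson(spec.psm_extra_mean))
        scores = [max(s, floor + 0.01)
                  for s in rng.normal(spec.true_score_mean, spec.true_score_sd, n_psm)]
        denovo_scores[pep] = scores
    for pep in decoys:
        n_psm = 1 + int(rng.poisson(spec.psm_extra_mean))
        scores = [min(s, floor - 1.0)
                  for s in rng.normal(spec.decoy_score_mean, spec.decoy_score_sd, n_psm)]
        denovo_scores[pep] = scores

    for pep, scores in denovo_scores.items():
        batch = f"B{int(rng.integers(1, spec.n_batches + 1))}"
        tables["denovo"].extend(psm_rows(pep, scores, batch))

    frames = {name: pd.DataFrame(rows).sort_values(["peptide", "spectrum"],
                                                   kind="mergesort").reset_index(drop=True)
              for name, rows in tables.items()}
    return assignment, decoys, frames


def simulate_affinity_table(peptides: Sequence[str], spec: SynthSpec,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Per-peptide x per-allele percentile ranks with the configured planted
    binder fraction; IC50 is a monotone map of rank."""
    rows = []
    for pep in peptides:
        is_binder = rng.random() < spec.binder_fraction
        best_idx = int(rng.integers(0, len(spec.alleles)))
        for i, allele in enumerate(spec.alleles):
            if is_binder and i == best_idx:
                rank = float(rng.uniform(0.05, 2.0))
            else:
                rank = float(rng.uniform(2.1, 90.0))
            rows.append((pep, allele, round(rank, 4),
                         round(MockAffinityPredictor.rank_to_ic50(rank), 2)))
    return pd.DataFrame(rows, columns=["peptide", "allele", "rank_percent", "ic50_nm"])


def simulate_rt_table(peptides: Sequence[str], spec: SynthSpec,
                      rng: np.random.Generator,
                      single_observation: bool = False) -> pd.DataFrame:
    """Per-PSM measured/predicted RT pairs with Gaussian noise sigma.

    With ``single_observation`` each peptide contributes exactly one PSM, so
    per-peptide measured RTs carry one N(0, sigma) deviation — the condition
    under which the 90th percentile of |measured - predicted| has the closed
    form 1.645 sigma."""
    rows = []
    for pep in peptides:
        predicted = float(rng.uniform(*spec.rt_range_s))
        batch = f"B{int(rng.integers(1, spec.n_batches + 1))}"
        n_obs = 1 if single_observation else 1 + int(rng.poisson(spec.psm_extra_mean))
        for _ in range(n_obs):
            rows.append((pep, batch, round(predicted + rng.normal(0.0, spec.rt_sigma_s), 3),
                         round(predicted, 3)))
    return pd.DataFrame(rows, columns=["peptide", "batch", "measured_s", "predicted_s"])


# ---------------------------------------------------------------------------
# Orchestration

def generate(spec: SynthSpec) -> SynthData:
    """Build a complete synthetic study from one seed."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_genome, rng_var, rng_pep, rng_engine, rng_affinity, rng_rt = (
        np.random.default_rng(s) for s in streams)

    genome, annotation, proteome, genes = make_genome_and_annotation(spec, rng_genome)
    variants = plant_variants(spec, genome, annotation, proteome, genes, rng_var)
    noncanon, sorf_db = plant_noncanonical(spec, genome, annotation, proteome, genes, rng_pep)

    mutant_catalog = pick_mutant_representatives(variants)
    exclude = {p.peptide for p in noncanon} | set(mutant_catalog)
    canonical = sample_canonical_peptides(spec, proteome, rng_pep, exclude)

    assignment, decoys, tables = simulate_engine_tables(
        spec, canonical, noncanon, mutant_catalog, proteome, rng_engine)
    all_assigned = sorted({p for peps in assignment.values() for p in peps})
    tables["affinity"] = simulate_affinity_table(all_assigned, spec, rng_affinity)
    tables["rt"] = simulate_rt_table(all_assigned, spec, rng_rt)

    transcripts = {g.gene_id: g.cds for g in genes}
    exon_seqs = {}
    for g in genes:
        for i, (a, b) in enumerate(g.exons):
            exon_seqs[f"{g.gene_id}.exon{i + 1}"] = genome.fetch(g.chrom, a, b)

    return SynthData(
        spec=spec, genome=genome, annotation=annotation, proteome=proteome,
        genes=genes, variants=variants, noncanon=noncanon, sorf_db=sorf_db,
        canonical_peptides=canonical, mutant_catalog=mutant_catalog,
        assignment=assignment, decoys=decoys, tables=tables,
        transcripts=transcripts, exon_seqs=exon_seqs,
    )


def truth_frame(data: SynthData) -> pd.DataFrame:
    """Flat table of every planted item, for the truth.tsv fixture."""
    rows = []
    for pv in data.variants:
        v = pv.variant
        rows.append({
            "kind": f"variant_{pv.region}", "peptide": ";".join(pv.truth_peptides),
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": pv.gene_id, "detail": pv.aa_change,
        })
    for pn in data.noncanon:
        detail = ""
        chrom = pos = ""
        if pn.origin in ("intron", "intergenic") and pn.locus:
            chrom, start, strand = pn.locus
            pos, detail = start, strand
        elif pn.origin == "sorf":
            detail = pn.sorf_acc
        elif pn.splice is not None:
            s = pn.splice
            detail = (f"{s.parent}:split={s.split}:n={s.n_start}-{s.n_end}:"
                      f"c={s.c_start}-{s.c_end}:{s.orientation}:gap={s.intervening}")
        rows.append({"kind": f"noncanon_{pn.origin}", "peptide": pn.peptide,
                     "chrom": chrom, "pos": pos, "ref": "", "alt": "",
                     "gene": "", "detail": detail})
    return pd.DataFrame(rows)


def write_fixture_dir(data: SynthData, outdir) -> None:
    """Emit every pipeline input as plain-text files."""
    from pathlib import Path

    from .io import write_annotation, write_fasta, write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dict(data.genome.items()), out / "genome.fa")
    write_annotation(data.annotation, out / "annotation.bed")
    write_vcf([pv.variant for pv in data.variants], data.genome, out / "variants.vcf")
    write_fasta(dict(data.proteome.items()), out / "proteome.fa")
    write_fasta(dict(data.sorf_db.items()), out / "sorf.fa")
    write_fasta(data.transcripts, out / "transcripts.fa")
    for name in ("db1", "db2", "denovo", "affinity", "rt"):
        data.tables[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
    truth_frame(data).to_csv(out / "truth.tsv", sep="\t", index=False)
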