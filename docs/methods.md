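# Methods

This note documents the models and procedures `neopg` implements, the
parameters that matter, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. File readers convert at the
boundary: VCF positions are 1-based (kept as such on the `Variant` type,
with 0-based accessors), region annotations are read as BED-style 0-based
half-open by default with a `dialect="gff"` flag for 1-based inclusive
input. FASTA goes through Bio.SeqIO, VCF through pysam, tables through
pandas. Engine PSM exports are normalized by a per-engine column map and a
modification-stripping dialect (`parenthetical` removes `(...)` groups,
`bracket` removes `[...]`; engines mark modifications inside the sequence
string in one of these ways). Rows whose stripped sequence leaves the
20-letter alphabet are dropped and counted.

## Personalized database construction

For a somatic variant, the context window is
`[pos − flank, pos + len(REF) + flank)` with ALT substituted, clipped at
chromosome bounds (a clipped window shorter than 24 nt still yields a
context, with a warning). `flank` is configurable in 24–45 nt and defaults
to 45, the maximum of the range: with 45 nt (15 codons) of flank every
8–15-mer crossing the variant is reachable, which shorter flanks cannot
guarantee for 15-mers.

Frame policy by region of the variant position:

* **exon** — one frame, derived from the exon's annotated cumulative CDS
  offset and the gene strand. The window is genomic; exonic windows that
  would cross a splice boundary are translated as genomic sequence (the
  windowed method deliberately ignores splicing — a simplification shared
  with the underlying strategy; the synthetic generator places variants far
  enough from exon boundaries that this never matters in testing).
* **intron** — three frames on the host gene's strand.
* **intergenic** — three frames on the consensus strand of the nearest
  flanking genes within 100 kb (configurable); six frames when the flanking
  genes disagree or none is near.

Each frame translation is split at stop codons. A sub-fragment is kept only
if it carries ≥ 1 variant-altered residue. For substitutions the altered
residues are the codons overlapping the ALT span; for frameshift indels
translation continues from the variant codon to the first stop or the
window end, and every residue from the variant codon onward counts as
novel-frame. Frames containing an ambiguous base (N) are skipped
individually, not the whole window.

Candidate peptides are all 8–15-mers covering ≥ 1 altered residue,
deduplicated by exact sequence (I and L are distinct here — the genomic
source is known). Candidates occurring verbatim in the canonical proteome
are removed (substring query against a separator-joined concatenation of
the proteome, so matches cannot span records). The affinity filter keeps a
candidate iff its best (minimum) percentile rank over alleles is ≤ 2%
(inclusive), recording the best allele, its rank, and IC50; ties between
alleles break lexicographically. Candidates without predictions are dropped
by default (`keep_missing` retains them un-annotated).

A deterministic hash-based mock predictor (`MockAffinityPredictor`) stands
in for an external pMHC predictor so the filter is testable offline; a TSV
import path (`peptide, allele, rank_percent, ic50_nm`) accepts real
predictor output. The mock designates each peptide a binder with a
configurable probability via a seeded hash (order-independent), gives
binders a best-allele rank in (0, 2] and non-binders ranks in (2, 90], and
maps rank to IC50 monotonically (≈ 500 nM near rank 2%).

The emitted database FASTA lists canonical records (sorted by accession)
then mutant peptides (sorted by locus and sequence) with structured headers
`NEOPEP|chrom:pos|REF>ALT|gene|region|strand+frame|p.change` that parse
back to the variant locus and protein-level change. Protein changes are
HGVS-like: `p.A324T` for missense, `p.K88fs` for frameshifts (residue
derived from the VCF anchor base's CDS position).

## Engine integration and de novo calibration

Only 8–15-mers enter the catalog (inclusive bounds; HLA-I ligand range).
The de novo cutoff is the q-th percentile — linear interpolation, quantile
type 7, the numpy default; chosen because a fractional published cutoff
implies interpolation — of the best de novo score per peptide among
peptides also reported by ≥ 1 database engine. q defaults to 25. The
comparison is inclusive (≥); scores are never compared across engines. An
optional I/L-equivalent mode collapses I to L for cross-engine matching
(off by default; de novo sequencing cannot distinguish the isobaric pair,
so the mode doubles as a sensitivity analysis). Whether "score" is the best
or the mean per peptide is configurable (default best).

`combine` unions by exact sequence. De novo PSMs contribute evidence and
counts only when the peptide passes the cutoff; database evidence stands on
its own, so a peptide below the de novo cutoff but reported by an engine
stays in the catalog without the de novo flag. The seven evidence
categories partition the catalog by construction. Summaries (length,
precursor charge, single-vs-multiple PSM) are reported as fractions that
sum to one.

## Traceability

k ∈ {24, 27, …, 45} nt — peptide lengths 8–15. A k-mer starting at offset
i is translated in its own frame, which equals a slice of the
whole-sequence frame-(i mod 3) translation; the index therefore translates
each strand three times and takes substrings, which is exactly equivalent
to per-k-mer translation (verified against a naive oracle) and avoids
redundant work. Both strands are always indexed (the superset of
strand-collapsed counting); translations containing a stop (`*`) or an
ambiguity from N (`X`) are excluded. Evidence at a level means exact
membership at k = 3·length.

Genome indexes can store loci. A locus interval `[start, start + 3·len)` is
assigned the set of region types it overlaps, with intergenic defined as
the complement of annotated gene bodies; a locus spanning a boundary gets
every type it touches and therefore forces Multi-Tag. Unique-Tag requires
all loci to resolve to one common single type. sORF evidence is an exact
substring match against the sORF database.

## Cis-splice inference

Split points leave ≥ 3 residues on each side (so an n-mer has
n − 5 splits, none below 6 residues). For every split, every protein, and
every pair of disjoint exact occurrences of the two fragments, a candidate
is recorded with orientation (normal iff the N-fragment interval ends
before the C-fragment interval starts; overlapping occurrences are not a
physical splicing product and are rejected) and intervening length — the
half-open gap between the earlier interval's end and the later interval's
start, the same formula for both orientations. A peptide occurring verbatim
in any protein is linear and never reported as spliced. The selected parent
minimises intervening length, ties broken by accession, then split point,
then leftmost N-occurrence. No intervening-length cap is applied by default
(`max_intervening` is available). Only the two-fragment cis model is
implemented; trans-splicing is out of scope.

Statistics over selected candidates: intervening-length histograms per
orientation, N-/C-fragment length histograms, a 20 × 9 positional residue
frequency matrix over 9-mers, and residue frequencies at P_N (peptide
N-terminus), P_1 (last residue of the N-fragment), P_1′ (first residue of
the C-fragment) and P_C (peptide C-terminus). All frequency vectors sum to
one.

## Quality control

Binder classes: strong ≤ 0.5% < weak ≤ 2% < non, thresholds inclusive.
Best-allele assignment takes the minimum rank, ties lexicographic. The
summary reports class fractions, per-allele assignment proportions among
binders, and the fraction of IC50 values below 500 nM.

RT agreement: peptides with multiple PSMs contribute the mean measured RT;
the module reports the least-squares slope/intercept, both Pearson r and
r², and ΔRT90 — the nearest-rank 90th percentile of |measured − predicted|
in seconds. Zero variance in either vector leaves the correlation undefined
(reported as None) rather than raising. Because RT predictors are trained
per acquisition batch, metrics are computed per batch and pooled.

## Synthetic data generator

One `SynthSpec` seed drives a `numpy.random.SeedSequence` split into six
named child streams (genome, variants, peptides, engines, affinity, rt), so
sub-generators are independently reproducible and the whole dataset is
byte-stable under a fixed seed.

Default study conditions: 2 chromosomes × 100 kb, 20 non-overlapping genes
on random strands (proteins 140–300 aa, 2–4 exons of ≥ 120 nt, introns
200–800 nt), 50 variants (30 exonic SNVs, 5 exonic frameshift indels, 10
intronic and 5 intergenic SNVs), 400 canonical peptides sampled from the
proteome with an HLA-I-like length distribution peaking at 9-mers, 20
planted non-canonical peptides each of intronic, intergenic, sORF and
cis-splice origin, precursor charges predominantly 2+ (72.8%), PSM counts
1 + Poisson(1) (≈ 63% multi-PSM), RT noise σ = 10 s, binder fraction 0.7
over six HLA alleles. These sizes keep full generation plus all downstream
stages within seconds while leaving every phenomenon representable.

Planting guarantees, chosen so that "exact recovery" is well-defined:

* Exonic variants sit ≥ flank + 6 nt from exon boundaries, so the genomic
  context window coincides with the spliced CDS context and the truth set
  (all 8–15-mers of the mutant protein covering the altered residue, minus
  canonical substrings) is exactly the windowed method's reach. For
  frameshifts the truth covers the *first* novel-frame residue, and
  configurations where the first mutated codon coincidentally reproduces
  the wild-type residue are resampled (they would push 15-mer truth one
  codon past the flank's reach).
* Planted intronic/intergenic peptides are stop-free in-frame translations
  of windows lying entirely inside one region; their encoding loci are
  recorded and re-translate to the peptide.
* Planted cis-splice peptides are certified by an internal exhaustive scan
  to be the global least-intervening configuration under the selection
  tie-break; otherwise they are resampled.
* The engine tables realize a configured evidence (Venn) structure exactly.
  All non-canonical peptides go to the de novo-only cell (database engines
  cannot report peptides absent from the search database). The bottom
  `shared_floor_fraction` (default 0.30 > q/100) of shared de novo best
  scores is placed as a point mass at a calibration floor (true mean −
  5 SD): the type-7 percentile then equals the floor and the inclusive
  cutoff retains every shared peptide, while decoy scores — required by
  validation to sit ≥ 5 SD lower — are always excluded. De novo-private
  true peptides are clipped to lie above the floor. Without this
  construction the q-th percentile of a continuous sample would by
  definition strand ~q% of the shared peptides below the cutoff and no
  exact planted structure could exist.

What the generator does **not** emulate: spectral noise and search-engine
error (engine tables are noiseless realizations of the planted structure),
modification chemistry, germline variation, expression levels, splice-site
biology in intron sequence, homology/repeat structure of real genomes
(sequences are i.i.d. uniform), or realistic score distributions. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
bookkeeping and algorithms under the stated model, not its behaviour on
real LC-MS/MS data, where FDR control and predictor accuracy dominate.

## Numerical conventions

* Percentile cutoff: numpy type-7 linear interpolation; ΔRT90:
  nearest-rank.
* Inclusive comparisons at all published thresholds (rank ≤ 2%, ≤ 0.5%;
  score ≥ cutoff; lengths 8 ≤ L ≤ 15).
* Ties: allele and parent-protein selection break lexicographically, then
  by split point and leftmost occurrence; sorting everywhere uses stable
  mergesort so outputs are deterministic.
* Degenerate inputs: empty calibration overlap raises with advice to set an
  explicit cutoff; < 3 RT pairs raises; zero-variance RT vectors report an
  undefined correlation; empty retained sets require `allow_empty` to emit
  a database.

## Problem sizes used in validation

Oracle-equivalence checks run the translated k-mer index against a
per-substring naive scan on 12 kb of random sequence for every k, and the
cis-splice search against exhaustive enumeration on 60 proteins × 300 aa;
end-to-end recovery runs the full default study (200 kb genome, 50
variants, 80 non-canonical peptides); statistical recovery uses n = 5000
peptides. These sizes were chosen to exercise every code path many times
over while keeping the whole suite fast enough to run on every change.
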