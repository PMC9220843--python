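# neopg

Proteogenomic identification of canonical, non-canonical and
mutation-bearing HLA class I peptides from immunopeptidomics search results.

## The problem

LC-MS/MS immunopeptidomics samples the peptides presented on the cell
surface by HLA-I molecules. Conventional database searches only see peptides
encoded in annotated protein-coding ORFs, yet tumour neo-epitopes also arise
from somatic mutations, introns, intergenic regions, small ORFs (sORFs) and
proteasome-catalysed peptide splicing. `neopg` implements the computational
pipeline that broadens the search to all of these sources:

1. **Personalized database** (`neopg.persdb`) — for each somatic variant
   (SNV or frameshift indel) the ±24–45 nt nucleotide context window is
   extracted with the ALT allele substituted and translated region-aware:
   1-frame in exons (using the annotated reading frame), 3-frame on the host
   gene's strand in introns, 3- or 6-frame in intergenic regions depending
   on the flanking genes' strands. Mutation-covering 8–15-mers are
   enumerated, peptides already present in the canonical proteome are
   subtracted, and only predicted HLA binders (best-allele percentile rank
   ≤ 2%) are appended to the canonical proteome as the search database.
2. **Engine integration** (`neopg.integrate`) — PSMs from two database
   search engines and one de novo sequencing engine are length-filtered
   (8–15 aa) and merged by exact sequence. The de novo engine has no
   database-grounded FDR, so its score threshold is calibrated from the
   peptides it shares with the database engines: the cutoff is the q-th
   percentile (default q = 25, linear-interpolation quantile) of the shared
   best-score distribution, and de novo peptides with best score ≥ cutoff
   pass. The catalog records per-peptide evidence flags, PSM counts,
   charges, scores and retention times, and the seven evidence (Venn)
   categories.
3. **Traceability** (`neopg.trace`) — every k-mer (k = 24…45 nt, step 3) of
   the genome, exome and transcriptome sequences and of their reverse
   complements is translated in its own frame (stop-containing translations
   excluded) into per-level peptide sets; a non-canonical peptide has
   evidence of origin at a level if it occurs verbatim at k = 3·length.
   Genome matches are mapped back to their loci and tagged
   `Unique-Tag:<region>` when all encoding loci fall in one region type
   (exon/intron/intergenic), otherwise `Multi-Tag`. sORF origins are exact
   substring matches against an sORF database.
4. **Cis-splice inference** (`neopg.splice`) — a peptide with no linear
   origin is cut once into two sub-fragments (each ≥ 3 aa); if both
   fragments occur at disjoint positions in the same protein it is a
   candidate cis-spliced peptide, oriented *normal* (N-fragment before
   C-fragment in the parent) or *reverse*, and the parent with the least
   intervening sequence is selected. Fragment-length, intervening-length
   and positional amino-acid statistics (P_N, P_1, P_1′, P_C) summarise the
   candidate set.
5. **Quality control** (`neopg.qc`) — best-allele binder calls
   (strong ≤ 0.5% < weak ≤ 2% < non), IC50 summaries, and retention-time
   agreement: least-squares fit, Pearson R², and ΔRT90 (the nearest-rank
   90th percentile of |measured − predicted| RT).
6. **Synthetic data** (`neopg.synth`) — a deterministic, seedable generator
   that produces every input the pipeline consumes (genome, annotation,
   proteome, VCF, engine PSM tables, affinity and RT tables, sORF FASTA)
   with planted ground truth, so each stage can be verified for exact
   recovery without external data.

## Worked example

```python
from neopg import synth, persdb, integrate, io

data = synth.generate(synth.SynthSpec(seed=1))

# build the personalized database from the planted somatic variants
cands = persdb.build_candidates([pv.variant for pv in data.variants],
                                data.genome, data.annotation)
cands = persdb.subtract_canonical(cands, data.proteome)
pred = persdb.MockAffinityPredictor(seed=1, binder_fraction=1.0).predict(cands)
retained = persdb.affinity_filter(cands, pred)
print(len(retained))                       # 5053 binder-filtered mutant 8-15-mers

# integrate the three engines
db1 = io.psm_records_from_frame(data.tables["db1"], "db1")
db2 = io.psm_records_from_frame(data.tables["db2"], "db2")
dn  = io.psm_records_from_frame(data.tables["denovo"], "denovo")
db_peps = {r.peptide for r in db1} | {r.peptide for r in db2}
cal = integrate.calibrate_denovo_cutoff(dn, db_peps, q=25)
print(round(cal.cutoff, 2))                # 85.0  (25th pct of shared de novo scores)
catalog = integrate.combine(db1, db2, dn, integrate.filter_denovo(dn, cal))
print(len(catalog))                        # 380 unique peptides
print(integrate.venn_counts(catalog)[("db1", "db2", "denovo")])   # 100 triple-evidence
```

The printed numbers mean: 5053 mutation-covering candidate peptides survive
canonical subtraction and the rank ≤ 2% binder filter; the de novo cutoff
calibrated from engine-shared peptides is 85.0 on this synthetic score
scale; the merged catalog holds 380 unique peptides of which 100 carry
evidence from all three engines — exactly the evidence structure the
generator planted.

The same stages are available as a CLI (`neopg simulate`, `neopg build-db`,
`neopg integrate`, `neopg trace`, `neopg splice`, `neopg qc`); run
`neopg --help` for the file-level interfaces.

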