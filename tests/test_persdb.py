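"""Personalized database construction: windows, frames, enumeration, filters."""

import numpy as np
import pytest

from neopg import persdb
from neopg.core import Variant
from neopg.persdb import (
    CandidatePeptide,
    MockAffinityPredictor,
    MutationContext,
    TranslatedFragment,
    affinity_filter,
    build_personalized_fasta,
    enumerate_mutant_peptides,
    extract_mutation_context,
    parse_mutant_header,
    protein_change,
    subtract_canonical,
    translate_context,
)

from oracles import naive_substring_scan


def _ctx(window, offset, variant, frame_mode="three_frame", strands=("+",)):
    return MutationContext(variant=variant, window=window, window_start=0,
                           window_end=len(window), offset=offset,
                           region_type="intron", frame_mode=frame_mode,
                           strands=strands, flank=45)


class TestContextExtraction:
    def test_window_arithmetic_interior(self, synth_small):
        data = synth_small
        pv = next(p for p in data.variants if p.region == "exon"
                  and p.variant.variant_class == "SNV")
        ctx = extract_mutation_context(pv.variant, data.genome, data.annotation, flank=45)
        assert ctx.window_end - ctx.window_start == 91  # 45 + 1 + 45
        assert len(ctx.window) == 91 and ctx.offset == 45
        assert ctx.frame_mode == "one_frame"

    def test_window_clipped_at_chromosome_start(self, toy_genome):
        genome, annotation = toy_genome
        ref = genome["chr1"][9]
        alt = "A" if ref != "A" else "C"
        v = Variant("chr1", 10, ref, alt)  # pos0 = 9
        ctx = extract_mutation_context(v, genome, annotation, flank=45)
        assert ctx.window_start == 0 and ctx.offset == 9

    def test_intron_variant_three_frames_on_gene_strand(self, toy_genome):
        genome, annotation = toy_genome
        ref = genome["chr1"][44]
        alt = "A" if ref != "A" else "C"
        ctx = extract_mutation_context(Variant("chr1", 45, ref, alt), genome, annotation)
        assert ctx.frame_mode == "three_frame" and ctx.strands == ("+",)

    def test_intergenic_with_one_flanking_gene_uses_its_strand(self, toy_genome):
        genome, annotation = toy_genome
        ref = genome["chr1"][55]
        alt = "A" if ref != "A" else "C"
        ctx = extract_mutation_context(Variant("chr1", 56, ref, alt), genome, annotation)
        assert ctx.frame_mode == "three_frame" and ctx.strands == ("+",)

    def test_unannotated_contig_rejected(self, toy_genome):
        from neopg.core import GenomeRef

        genome, annotation = toy_genome
        with_extra = GenomeRef({"chr1": genome["chr1"], "chrX": "ACGTACGTACGT"})
        with pytest.raises(ValueError, match="unannotated"):
            extract_mutation_context(Variant("chrX", 5, "A", "T"), with_extra, annotation)

    def test_flank_range_enforced(self, toy_genome):
        genome, annotation = toy_genome
        with pytest.raises(ValueError, match="flank"):
            extract_mutation_context(Variant("chr1", 20, genome["chr1"][19], "A"),
                                     genome, annotation, flank=10)


class TestTranslation:
    snv = Variant("c", 50, "A", "C")

    def test_genetic_code_frame0(self):
        frags = translate_context(_ctx("ATGGCC", offset=3, variant=self.snv))
        frame0 = next(f for f in frags if f.frame == 0)
        assert frame0.seq == "MA" and frame0.mutant_residues == frozenset({1})

    def test_stop_codon_splits_fragments(self):
        # variant in the GGG codon: only the post-stop fragment carries it
        frags = translate_context(_ctx("ATGTAAGGG", offset=7, variant=self.snv))
        frame0 = [f for f in frags if f.frame == 0]
        assert [f.seq for f in frame0] == ["G"]
        assert frame0[0].mutant_residues == frozenset({0})

    def test_six_frame_context_yields_six_fragments(self):
        ctx = _ctx("ATTGCCGCTATA", offset=6, variant=self.snv,
                   frame_mode="six_frame", strands=("+", "-"))
        frags = translate_context(ctx)
        assert len(frags) == 6
        assert {(f.strand, f.frame) for f in frags} == {
            (s, f) for s in "+-" for f in range(3)}

    def test_ambiguous_base_skips_frame(self):
        frags = translate_context(_ctx("ATGNCC", offset=3, variant=self.snv))
        assert frags == []

    def test_frameshift_runs_to_fragment_end(self):
        fs = Variant("c", 50, "AT", "A")  # 1 nt deletion
        frags = translate_context(_ctx("ATGGCCAAATTTGGG", offset=3, variant=fs))
        frame0 = next(f for f in frags if f.frame == 0)
        # every residue from the variant codon onward is novel-frame
        assert frame0.mutant_residues == frozenset(range(1, len(frame0.seq)))


class TestEnumeration:
    fragment31 = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLM"  # 31 aa, all local windows unique

    def _fragments(self, mutant_at):
        return [TranslatedFragment(seq=self.fragment31, strand="+", frame=0,
                                   mutant_residues=frozenset({mutant_at}))]

    def _ctx31(self):
        return _ctx("A" * 93, offset=48, variant=Variant("c", 50, "A", "C"))

    def test_nine_mers_covering_interior_residue(self):
        peps = enumerate_mutant_peptides(self._fragments(16), self._ctx31(),
                                         len_min=9, len_max=9)
        assert len(peps) == 9
        assert all(p[c.mutant_start] == self.fragment31[16] for p, c in peps.items())

    def test_total_covering_peptides_all_lengths(self):
        # sum over L = 8..15 of L windows = 92 for a deep-interior residue
        peps = enumerate_mutant_peptides(self._fragments(16), self._ctx31())
        assert len(peps) == 92

    def test_short_fragment_yields_nothing(self):
        frags = [TranslatedFragment(seq="ACDEFGH", strand="+", frame=0,
                                    mutant_residues=frozenset({3}))]
        assert enumerate_mutant_peptides(frags, self._ctx31()) == {}


class TestSubtraction:
    def test_exact_substring_removed_one_mismatch_kept(self, synth_small):
        proteome = synth_small.proteome
        acc = sorted(proteome)[0]
        inside = proteome[acc][5:14]
        mutated = ("A" if inside[4] != "A" else "C").join([inside[:4], inside[5:]])
        cands = {p: CandidatePeptide(peptide=p, variant=Variant("c", 1, "A", "C"),
                                     strand="+", frame=0, frameshift=False,
                                     mutant_start=0, mutant_end=1)
                 for p in (inside, mutated)}
        kept = subtract_canonical(cands, proteome)
        assert inside not in kept
        assert (mutated in kept) == (not proteome.contains(mutated))

    def test_agrees_with_naive_scan_on_random_peptides(self, synth_small):
        proteome = synth_small.proteome
        raw = dict(proteome.items())
        rng = np.random.default_rng(3)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peps = ["".join(aas[rng.integers(0, 20, 9)]) for _ in range(50)]
        peps += [proteome[a][i:i + 9] for a, i in
                 zip(sorted(proteome), range(0, 100, 10)) if len(proteome[a]) > i + 9][:50]
        for pep in peps:
            assert proteome.contains(pep) == naive_substring_scan(pep, raw)


class TestAffinityFilter:
    def _cand(self, pep):
        return CandidatePeptide(peptide=pep, variant=Variant("c", 1, "A", "C"),
                                strand="+", frame=0, frameshift=False,
                                mutant_start=0, mutant_end=1)

    def _table(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["peptide", "allele", "rank_percent", "ic50_nm"])

    def test_best_allele_wins_and_threshold_inclusive(self):
        cands = {p: self._cand(p) for p in ("AAAAAAAK", "CCCCCCCK", "DDDDDDDK")}
        table = self._table([
            ("AAAAAAAK", "HLA-A*01:01", 0.3, 20.0), ("AAAAAAAK", "HLA-B*18:01", 5.0, 9000.0),
            ("CCCCCCCK", "HLA-A*01:01", 3.0, 800.0), ("CCCCCCCK", "HLA-B*18:01", 3.0, 900.0),
            ("DDDDDDDK", "HLA-A*01:01", 2.0, 500.0),
        ])
        kept = affinity_filter(cands, table)
        assert set(kept) == {"AAAAAAAK", "DDDDDDDK"}  # 2.0 is inclusive
        assert kept["AAAAAAAK"].allele == "HLA-A*01:01"
        assert kept["AAAAAAAK"].rank_percent == 0.3

    def test_missing_prediction_dropped_or_kept(self):
        cands = {"AAAAAAAK": self._cand("AAAAAAAK")}
        empty = self._table([])
        assert affinity_filter(cands, empty) == {}
        assert set(affinity_filter(cands, empty, keep_missing=True)) == {"AAAAAAAK"}

    def test_raising_threshold_never_shrinks(self):
        predictor = MockAffinityPredictor(seed=1, binder_fraction=0.5)
        peps = [f"ACDEFGHI{aa}" for aa in "KLMNPQRSTVWY"]
        cands = {p: self._cand(p) for p in peps}
        table = predictor.predict(peps)
        kept_tight = set(affinity_filter(dict(cands), table, rank_threshold=0.5))
        kept_loose = set(affinity_filter(dict(cands), table, rank_threshold=2.0))
        assert kept_tight <= kept_loose


class TestMockPredictor:
    def test_deterministic_and_order_independent(self):
        peps = ["ACDEFGHIK", "LMNPQRSTV", "WYACDEFGH"]
        a = MockAffinityPredictor(seed=7).predict(peps)
        b = MockAffinityPredictor(seed=7).predict(list(reversed(peps)))
        merged = b.sort_values(["peptide", "allele"]).reset_index(drop=True)
        assert a.sort_values(["peptide", "allele"]).reset_index(drop=True).equals(merged)

    def test_binder_fraction_one_means_all_pass(self):
        peps = [f"ACDEFGHI{aa}" for aa in "KLMNPQRSTVWY"]
        table = MockAffinityPredictor(seed=2, binder_fraction=1.0).predict(peps)
        best = table.groupby("peptide")["rank_percent"].min()
        assert (best <= 2.0).all()


class TestProteinChange:
    def test_plus_strand_missense(self, toy_genome):
        genome, annotation = toy_genome
        # exon CDS starts at 10; codon 2 is GCC (Ala) at positions 13-15
        assert genome["chr1"][13] == "G"
        change = protein_change(Variant("chr1", 14, "G", "A"), annotation, genome)
        assert change == "p.A2T"

    def test_planted_changes_recovered(self, synth_small):
        data = synth_small
        for pv in data.variants:
            if pv.region == "exon":
                assert protein_change(pv.variant, data.annotation, data.genome) == pv.aa_change


class TestFastaEmission:
    def _retained(self):
        cand = CandidatePeptide(
            peptide="QTDQMVFNTY", variant=Variant("chr8", 23258741, "G", "A"),
            strand="+", frame=0, frameshift=False, mutant_start=3, mutant_end=4,
            region_type="exon", gene_id="CHMP7", aa_change="p.A324T")
        return {"QTDQMVFNTY": cand}

    def test_record_order_and_determinism(self, tmp_path, synth_small):
        proteome = synth_small.proteome
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        build_personalized_fasta(self._retained(), proteome, p1)
        build_personalized_fasta(self._retained(), proteome, p2)
        assert p1.read_bytes() == p2.read_bytes()
        ids = [line[1:].split()[0] for line in p1.read_text().splitlines()
               if line.startswith(">")]
        assert len(ids) == len(proteome) + 1
        assert ids[:len(proteome)] == sorted(proteome)  # canonical first

    def test_header_parse_back(self, tmp_path, synth_small):
        path = tmp_path / "db.fa"
        build_personalized_fasta(self._retained(), synth_small.proteome, path)
        header = [l for l in path.read_text().splitlines() if "NEOPEP" in l][0]
        d = parse_mutant_header(header)
        assert (d["chrom"], d["pos"], d["gene"], d["aa_change"]) == (
            "chr8", 23258741, "CHMP7", "p.A324T")

    def test_empty_retained_requires_flag(self, tmp_path, synth_small):
        with pytest.raises(ValueError, match="allow_empty"):
            build_personalized_fasta({}, synth_small.proteome, tmp_path / "e.fa")


class TestPipelineInvariants:
    def test_lengths_and_no_canonical_leakage(self, synth_small):
        data = synth_small
        cands = persdb.build_candidates([pv.variant for pv in data.variants],
                                        data.genome, data.annotation)
        cands = subtract_canonical(cands, data.proteome)
        assert cands, "expected some candidates"
        assert all(8 <= len(p) <= 15 for p in cands)
        assert not any(data.proteome.contains(p) for p in cands)

    def test_widening_flank_never_shrinks_candidates(self, synth_small):
        data = synth_small
        exonic = [pv.variant for pv in data.variants if pv.region == "exon"][:4]
        narrow = persdb.build_candidates(exonic, data.genome, data.annotation, flank=24)
        wide = persdb.build_candidates(exonic, data.genome, data.annotation, flank=45)
        assert set(narrow) <= set(wide)
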