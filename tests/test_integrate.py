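"""Engine merging, de novo cutoff calibration and catalog summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopg import integrate
from neopg.core import PsmRecord


def rec(pep, engine="denovo", score=50.0, charge=2, rt=None):
    return PsmRecord(peptide=pep, engine=engine, score=score, charge=charge, rt=rt)


PEP8 = "ACDEFGHI"
PEP9 = "ACDEFGHIK"
PEP15 = "ACDEFGHIKLMNPQR"
PEP16 = "ACDEFGHIKLMNPQRS"


class TestLengthFilter:
    @pytest.mark.parametrize("pep,kept", [
        ("ACDEFGH", False),   # 7-mer
        (PEP8, True),         # 8-mer inclusive
        (PEP15, True),        # 15-mer inclusive
        (PEP16, False),       # 16-mer
    ])
    def test_bounds(self, pep, kept):
        out = integrate.length_filter([rec(pep)])
        assert (len(out) == 1) == kept


class TestCalibration:
    def test_quantile_of_1_to_100_is_25_75(self):
        # type-7 linear interpolation closed form: 1 + 0.25 * 99
        records = [rec(f"ACDEFGHI{i:03d}".replace("0", "K").replace("1", "L")
                       .replace("2", "M").replace("3", "N").replace("4", "P")
                       .replace("5", "Q").replace("6", "R").replace("7", "S")
                       .replace("8", "T").replace("9", "V"), score=float(i))
                   for i in range(1, 101)]
        db = {r.peptide for r in records}
        cal = integrate.calibrate_denovo_cutoff(records, db, q=25)
        assert cal.cutoff == pytest.approx(25.75)

    def test_constant_and_singleton_scores(self):
        records = [rec(PEP9, score=7.5), rec(PEP8, score=7.5)]
        cal = integrate.calibrate_denovo_cutoff(records, {PEP9, PEP8}, q=25)
        assert cal.cutoff == 7.5
        single = integrate.calibrate_denovo_cutoff([rec(PEP9, score=3.25)], {PEP9})
        assert single.cutoff == 3.25

    def test_best_score_per_peptide_used(self):
        records = [rec(PEP9, score=10.0), rec(PEP9, score=90.0)]
        cal = integrate.calibrate_denovo_cutoff(records, {PEP9})
        assert cal.shared_scores == (90.0,)

    def test_empty_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="explicit cutoff"):
            integrate.calibrate_denovo_cutoff([rec(PEP9)], {"WWWWWWWW"})

    def test_il_equivalent_mode_widens_overlap(self):
        records = [rec("ACDEFGHI", score=5.0)]
        db = {"ACDEFGHL"}  # differs only I vs L at the end
        with pytest.raises(ValueError):
            integrate.calibrate_denovo_cutoff(records, db)
        cal = integrate.calibrate_denovo_cutoff(records, db, il_equivalent=True)
        assert cal.cutoff == 5.0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e3, allow_nan=False),
                    min_size=2, max_size=50),
           st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    def test_lower_q_never_shrinks_pass_set(self, scores, q1, q2):
        lo, hi = sorted((q1, q2))
        peps = [f"ACDEFGH{aa}K" for aa in "ACDEFGHIKLMNPQRSTVWY"]
        records = [rec(peps[i % len(peps)], score=s) for i, s in enumerate(scores)]
        db = {r.peptide for r in records}
        pass_lo = integrate.filter_denovo(
            records, integrate.calibrate_denovo_cutoff(records, db, q=lo))
        pass_hi = integrate.filter_denovo(
            records, integrate.calibrate_denovo_cutoff(records, db, q=hi))
        assert pass_hi <= pass_lo


class TestFilterDenovo:
    def test_cutoff_is_inclusive(self):
        records = [rec(PEP9, score=10.0), rec(PEP8, score=9.999)]
        assert integrate.filter_denovo(records, 10.0) == {PEP9}


class TestCombine:
    def test_disjoint_inputs_all_single_evidence(self):
        db1 = [rec(f"AAAAAAA{a}", "db1") for a in "CD"]
        db2 = [rec(f"CCCCCCC{a}", "db2") for a in "DEF"]
        dn = [rec(f"DDDDDDD{a}", "denovo") for a in "EFGH"]
        catalog = integrate.combine(db1, db2, dn, {r.peptide for r in dn})
        assert len(catalog) == 9
        counts = integrate.venn_counts(catalog)
        assert counts[("db1",)] == 2 and counts[("db2",)] == 3 and counts[("denovo",)] == 4

    def test_identical_inputs_all_triple_evidence(self):
        peps = [f"AAAAAAA{a}" for a in "CDE"]
        db1 = [rec(p, "db1") for p in peps]
        db2 = [rec(p, "db2") for p in peps]
        dn = [rec(p, "denovo") for p in peps]
        catalog = integrate.combine(db1, db2, dn, set(peps))
        assert len(catalog) == 3
        assert integrate.venn_counts(catalog)[("db1", "db2", "denovo")] == 3

    def test_failing_denovo_peptide_survives_via_db_evidence(self):
        db1 = [rec(PEP9, "db1", score=1.0)]
        dn = [rec(PEP9, "denovo", score=5.0)]
        catalog = integrate.combine(db1, [], dn, denovo_pass=set())
        row = catalog.iloc[0]
        assert bool(row.db1) and not bool(row.denovo_pass)

    def test_venn_partitions_catalog(self, synth_small):
        from neopg.io import psm_records_from_frame

        data = synth_small
        db1 = psm_records_from_frame(data.tables["db1"], "db1")
        db2 = psm_records_from_frame(data.tables["db2"], "db2")
        dn = psm_records_from_frame(data.tables["denovo"], "denovo")
        db_peps = {r.peptide for r in db1} | {r.peptide for r in db2}
        cal = integrate.calibrate_denovo_cutoff(dn, db_peps)
        catalog = integrate.combine(db1, db2, dn, integrate.filter_denovo(dn, cal))
        counts = integrate.venn_counts(catalog)
        assert sum(counts.values()) == len(catalog)
        assert len(set(catalog["peptide"])) == len(catalog)  # catalog is a set

    def test_combine_idempotent_on_reexport(self):
        db1 = [rec(PEP9, "db1", score=4.0, rt=100.0), rec(PEP9, "db1", score=6.0, rt=110.0)]
        dn = [rec(PEP8, "denovo", score=50.0)]
        first = integrate.combine(db1, [], dn, {PEP8})
        # rebuild PSM records from the catalog rows and re-combine
        db1_again = [rec(r.peptide, "db1", score=r.best_score_db1, charge=c, rt=t)
                     for r in first.itertuples() if r.db1
                     for c, t in zip(r.charges, r.rts or [None] * len(r.charges))]
        dn_again = [rec(r.peptide, "denovo", score=r.best_score_denovo)
                    for r in first.itertuples() if r.denovo_pass]
        second = integrate.combine(db1_again, [], dn_again, {PEP8})
        assert list(second.peptide) == list(first.peptide)
        assert list(second.db1) == list(first.db1)
        assert list(second.denovo_pass) == list(first.denovo_pass)


class TestSummarize:
    def test_point_mass_length_table(self):
        catalog = integrate.combine([rec(PEP9, "db1"), rec("CCCCCCCCC", "db1")], [], [], set())
        tables = integrate.summarize(catalog)
        assert tables["length"].to_dict() == {9: 1.0}

    def test_single_psm_means_no_multi_fraction(self):
        catalog = integrate.combine([rec(PEP9, "db1")], [], [], set())
        assert integrate.summarize(catalog)["psm"][">1"] == 0.0

    def test_fractions_sum_to_one(self, synth_small):
        from neopg.io import psm_records_from_frame

        data = synth_small
        db1 = psm_records_from_frame(data.tables["db1"], "db1")
        catalog = integrate.combine(db1, [], [], set())
        tables = integrate.summarize(catalog)
        for name, table in tables.items():
            assert abs(table.sum() - 1.0) < 1e-12, name


class TestCatalogIO:
    def test_write_read_round_trip(self, tmp_path):
        db1 = [rec(PEP9, "db1", score=4.0, rt=100.0)]
        dn = [rec(PEP8, "denovo", score=50.0)]
        catalog = integrate.combine(db1, [], dn, {PEP8})
        path = tmp_path / "catalog.tsv"
        integrate.write_catalog(catalog, path)
        back = integrate.read_catalog(path)
        assert list(back.peptide) == list(catalog.peptide)
        assert list(back.psm_count) == list(catalog.psm_count)
        assert back.charges.tolist() == catalog.charges.tolist()
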