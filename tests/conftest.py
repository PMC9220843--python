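"""Shared fixtures: a hand-built toy locus and session-scoped synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from neopg import synth
from neopg.core import GenomeRef, ProteomeDB, RegionAnnotation, RegionInterval


@pytest.fixture(scope="session")
def synth_small():
    """A reduced synthetic study kept fast for unit tests."""
    spec = synth.SynthSpec(
        seed=11,
        n_chroms=1, chrom_length=30_000, n_genes=5,
        protein_length_range=(140, 220), min_intergenic_nt=400,
        variant_counts={("exon", "SNV"): 6, ("exon", "DEL"): 1, ("exon", "INS"): 1,
                        ("intron", "SNV"): 2, ("intergenic", "SNV"): 2},
        n_canonical=60,
        n_noncanon_intron=4, n_noncanon_intergenic=4,
        n_sorf_records=10, n_noncanon_sorf=4, n_noncanon_splice=4,
        overlap={("db1",): 6, ("db2",): 6, ("denovo",): 20,
                 ("db1", "db2"): 8, ("db1", "denovo"): 6, ("db2", "denovo"): 6,
                 ("db1", "db2", "denovo"): 15},
        n_denovo_decoys=10,
    )
    return synth.generate(spec)


@pytest.fixture(scope="session")
def synth_default():
    """Full default-sized synthetic study (used by the end-to-end checks)."""
    return synth.generate(synth.SynthSpec(seed=20260926 % 2**31))


@pytest.fixture()
def toy_genome():
    """60 bp chromosome with a hand-placed '+'-strand single-exon gene.

    Layout: positions [10, 40) are an exon of GENE1 whose CDS starts at 10
    (cds_offset 0); [40, 50) is an intron stub; the rest is intergenic.
    """
    rng = np.random.default_rng(5)
    prefix = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
    cds = "ATGGCCATTGTAATGGGCCGCTGAAAGGGT"  # 30 nt, frame 0 at position 10
    suffix = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
    genome = GenomeRef({"chr1": prefix + cds + suffix})
    annotation = RegionAnnotation([
        RegionInterval("chr1", 10, 40, "exon", "+", "GENE1", cds_offset=0),
        RegionInterval("chr1", 40, 50, "intron", "+", "GENE1"),
    ])
    return genome, annotation
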