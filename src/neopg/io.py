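"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, VCF through pysam, tabular files through
pandas.  All coordinate conversion to the internal 0-based half-open
convention happens here and nowhere else.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AA_ALPHABET,
    GenomeRef,
    ProteomeDB,
    PsmRecord,
    RegionAnnotation,
    RegionInterval,
    Variant,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def _read_fasta_records(path: PathLike) -> Dict[str, str]:
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_genome_fasta(path: PathLike) -> GenomeRef:
    return GenomeRef(_read_fasta_records(path))


def read_proteome_fasta(path: PathLike) -> ProteomeDB:
    """Accessions are the first |-delimited token after the db tag for
    Swiss-Prot style headers (``sp|P12345|NAME``), else the full id."""
    raw = _read_fasta_records(path)
    out: Dict[str, str] = {}
    for rid, seq in raw.items():
        parts = rid.split("|")
        acc = parts[1] if len(parts) >= 3 and parts[0] in ("sp", "tr") else rid
        if acc in out:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        out[acc] = seq
    return ProteomeDB(out)


def write_fasta(records: Union[Mapping[str, str], Iterable[Tuple[str, str]]],
                path: PathLike, description: Mapping[str, str] | None = None) -> None:
    items = records.items() if hasattr(records, "items") else records
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description=(description or {}).get(rid, ""))
        for rid, seq in items
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: PathLike, genome: Optional[GenomeRef] = None) -> List[Variant]:
    """One Variant per ALT allele; REF is checked against the genome when one
    is supplied.  Symbolic/spanning alleles are skipped with a warning."""
    variants: List[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if not re.fullmatch(r"[ACGTN]+", alt or ""):
                    logger.warning("skipping non-sequence ALT %r at %s:%d", alt, rec.chrom, rec.pos)
                    continue
                v = Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                if genome is not None:
                    v.check_against(genome)
                variants.append(v)
    return variants


def write_vcf(variants: Sequence[Variant], genome: GenomeRef, path: PathLike) -> None:
    """Minimal site-only VCF 4.2 with contig headers, for fixtures."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genome:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Region annotation (BED-like TSV, or GFF-style 1-based via dialect flag)

_ANNOT_COLUMNS = ["chrom", "start", "end", "region_type", "strand", "gene_id", "cds_offset"]


def read_annotation(path: PathLike, dialect: str = "bed") -> RegionAnnotation:
    """Read exon/intron intervals.

    Columns: chrom, start, end, region_type, strand, gene_id, cds_offset
    ('.' where not applicable).  dialect='bed' means 0-based half-open;
    dialect='gff' means 1-based inclusive and is converted on read.
    """
    if dialect not in ("bed", "gff"):
        raise ValueError("dialect must be 'bed' or 'gff'")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_ANNOT_COLUMNS,
                     dtype=str)
    intervals = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        end = int(row.end)
        if dialect == "gff":
            start -= 1  # 1-based inclusive -> 0-based half-open
        cds = None if row.cds_offset in (".", "", None) else int(row.cds_offset)
        intervals.append(
            RegionInterval(chrom=row.chrom, start=start, end=end,
                           region_type=row.region_type, strand=row.strand,
                           gene_id="" if row.gene_id == "." else row.gene_id,
                           cds_offset=cds)
        )
    return RegionAnnotation(intervals)


def write_annotation(annotation: RegionAnnotation, path: PathLike) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, iv.region_type, iv.strand,
         iv.gene_id or ".", "." if iv.cds_offset is None else iv.cds_offset)
        for iv in sorted(annotation.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# PSM tables

#: How engine exports mark modifications inside the sequence string.
MOD_DIALECTS = {
    "parenthetical": re.compile(r"\([^()]*\)"),   # PEM(ox)TIDE
    "bracket": re.compile(r"\[[^\[\]]*\]"),        # PEM[+15.995]TIDE
    "none": None,
}

DEFAULT_PSM_COLUMNS = {
    "peptide": "peptide",
    "score": "score",
    "charge": "charge",
    "rt": "rt",
    "spectrum": "spectrum",
    "batch": "batch",
}


def strip_modifications(sequence: str, dialect: str = "parenthetical") -> str:
    """Remove modification annotations per the configured dialect and the
    leading/trailing underscores some engines add."""
    if dialect not in MOD_DIALECTS:
        raise ValueError(f"unknown modification dialect {dialect!r}")
    seq = sequence.strip("_.")
    pattern = MOD_DIALECTS[dialect]
    if pattern is not None:
        seq = pattern.sub("", seq)
    return seq


def read_psm_table(path: PathLike, engine: str,
                   column_map: Optional[Mapping[str, str]] = None,
                   mod_dialect: str = "parenthetical") -> List[PsmRecord]:
    """Normalize one engine's TSV export into PsmRecords.

    Required columns (post-mapping): peptide, score.  Optional: charge, rt,
    spectrum, batch.  Rows whose stripped sequence still contains residues
    outside the 20-letter alphabet are dropped and counted.
    """
    colmap = dict(DEFAULT_PSM_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    for logical in ("peptide", "score"):
        if colmap[logical] not in df.columns:
            raise ValueError(
                f"required column {colmap[logical]!r} not found; table has {list(df.columns)}"
            )
    records: List[PsmRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        seq = strip_modifications(str(d[colmap["peptide"]]), mod_dialect).upper()
        if not seq or set(seq) - AA_ALPHABET:
            n_dropped += 1
            continue
        charge = d.get(colmap["charge"])
        rt = d.get(colmap["rt"])
        records.append(PsmRecord(
            peptide=seq,
            engine=engine,
            score=float(d[colmap["score"]]),
            charge=int(charge) if charge is not None and not pd.isna(charge) else 2,
            rt=float(rt) if rt is not None and not pd.isna(rt) else None,
            spectrum_id=str(d.get(colmap["spectrum"], "") or ""),
            batch_id=str(d.get(colmap["batch"], "") or ""),
        ))
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-standard residues", path, n_dropped)
    return records


def psm_records_from_frame(df: pd.DataFrame, engine: str) -> List[PsmRecord]:
    """In-memory counterpart of read_psm_table for already-normalized frames."""
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(PsmRecord(
            peptide=str(d["peptide"]),
            engine=engine,
            score=float(d["score"]),
            charge=int(d.get("charge", 2)),
            rt=float(d["rt"]) if d.get("rt") is not None and not pd.isna(d.get("rt")) else None,
            spectrum_id=str(d.get("spectrum", "") or ""),
            batch_id=str(d.get("batch", "") or ""),
        ))
    return records


# ---------------------------------------------------------------------------
# Affinity / RT tables

AFFINITY_COLUMNS = ["peptide", "allele", "rank_percent", "ic50_nm"]
RT_COLUMNS = ["peptide", "batch", "measured_s", "predicted_s"]


def read_affinity_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(AFFINITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"affinity table missing columns {sorted(missing)}")
    return df[AFFINITY_COLUMNS].copy()


def read_rt_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"RT table missing columns {sorted(missing)}")
    return df[RT_COLUMNS].copy()


def read_peptide_list(path: PathLike) -> List[str]:
    """Plain text, one peptide per line (first TSV column tolerated)."""
    peptides = []
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token and not token.startswith("#"):
                peptides.append(token.upper())
    return peptides
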