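"""Naive reference implementations used as independent oracles.

These deliberately re-derive results by direct enumeration (per-substring
translation, exhaustive occurrence scans) without sharing code with the
package, so agreement is meaningful.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Set, Tuple

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_kmer_peptides(sequences: Mapping[str, str], k: int) -> Set[str]:
    """Translate every k-substring of every sequence and its reverse
    complement individually; exclude stops and ambiguous residues."""
    peptides: Set[str] = set()
    for seq in sequences.values():
        for s in (seq, naive_revcomp(seq)):
            for i in range(len(s) - k + 1):
                pep = naive_translate(s[i : i + k])
                if "*" not in pep and "X" not in pep:
                    peptides.add(pep)
    return peptides


def naive_kmer_loci(sequences: Mapping[str, str], k: int) -> Dict[str, Set[Tuple[str, int, str]]]:
    """Peptide -> set of (seq id, 0-based genomic start, strand)."""
    loci: Dict[str, Set[Tuple[str, int, str]]] = {}
    for sid, seq in sequences.items():
        n = len(seq)
        for strand, s in (("+", seq), ("-", naive_revcomp(seq))):
            for i in range(n - k + 1):
                pep = naive_translate(s[i : i + k])
                if "*" in pep or "X" in pep:
                    continue
                start = i if strand == "+" else n - i - k
                loci.setdefault(pep, set()).add((sid, start, strand))
    return loci


def naive_substring_scan(peptide: str, proteome: Mapping[str, str]) -> bool:
    return any(peptide in seq for seq in proteome.values())


def naive_splice_candidates(peptide: str, proteome: Mapping[str, str],
                            min_frag: int = 3) -> List[Tuple]:
    """All (split, parent, n_start, n_end, c_start, c_end, orientation, gap)
    configurations over every split and every disjoint occurrence pair."""
    n = len(peptide)
    out: List[Tuple] = []
    for acc, seq in proteome.items():
        for s in range(min_frag, n - min_frag + 1):
            nfrag, cfrag = peptide[:s], peptide[s:]
            n_occ = [i for i in range(len(seq) - len(nfrag) + 1)
                     if seq[i : i + len(nfrag)] == nfrag]
            c_occ = [j for j in range(len(seq) - len(cfrag) + 1)
                     if seq[j : j + len(cfrag)] == cfrag]
            for i in n_occ:
                for j in c_occ:
                    n_end, c_end = i + len(nfrag), j + len(cfrag)
                    if n_end <= j:
                        out.append((s, acc, i, n_end, j, c_end, "normal", j - n_end))
                    elif c_end <= i:
                        out.append((s, acc, i, n_end, j, c_end, "reverse", i - c_end))
    return out
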