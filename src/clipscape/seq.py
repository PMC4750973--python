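"""Small nucleotide-string helpers shared across the package.

Sequences are stored internally in the DNA alphabet (A/C/G/T/N); motifs and
tags are presented in an RNA view (U for T) on request, because binding
preferences of RNA-binding proteins are conventionally written as RNA.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS_DNA = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA view (T becomes U). Presentation only."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    """RNA -> DNA view (U becomes T)."""
    return seq.replace("U", "T").replace("u", "t")


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and check the alphabet; raises ValueError on other letters."""
    up = seq.upper()
    if not up:
        raise ValueError(f"{context} is empty")
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{context} contains non-ACGTN characters: {sorted(bad)}")
    return up


def count_overlapping(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of *motif* in *seq*."""
    n, i = 0, seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def find_all(seq: str, query: str) -> list[int]:
    """All start positions of *query* in *seq* (overlaps allowed)."""
    hits, i = [], seq.find(query)
    while i != -1:
        hits.append(i)
        i = seq.find(query, i + 1)
    return hits
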