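"""Small shared nucleotide-sequence helpers (DNA/RNA alphabets, complements)."""

from __future__ import annotations

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def complement_dna(seq: str) -> str:
    return dna(seq).translate(_DNA_COMP)


def revcomp_dna(seq: str) -> str:
    """Reverse complement in DNA alphabet; accepts RNA input."""
    return complement_dna(seq)[::-1]


def is_watson_crick(a: str, b: str) -> bool:
    """True if DNA bases a and b form a Watson-Crick pair."""
    return (dna(a), dna(b)) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_gu_wobble(a: str, b: str) -> bool:
    """True if DNA bases a and b form a G:U (G:T in DNA) wobble pair."""
    return (dna(a), dna(b)) in {("G", "T"), ("T", "G")}
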