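"""Nucleotide alphabet helpers.

All analysis code works on uppercase RNA (``ACGU``).  Interchange files may
be DNA (``T``) or lowercase; conversion is centralized here so the rest of
the package never special-cases the alphabet.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_TO_RNA = str.maketrans("acgtuACGTU", "ACGUUACGUU")
_RNA_TO_DNA = str.maketrans("acgtuACGTU", "ACGTTACGTT")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.translate(_DNA_TO_RNA)


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.translate(_RNA_TO_DNA)


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (input normalized first)."""
    return to_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def check_rna(seq: str, *, what: str = "sequence") -> str:
    """Normalize to RNA and raise ``ValueError`` naming the first bad position."""
    s = to_rna(seq)
    for i, c in enumerate(s):
        if c not in RNA_ALPHABET:
            raise ValueError(f"{what} contains non-ACGU character {c!r} at position {i}")
    return s
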