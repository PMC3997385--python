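"""Packaged miniature reference sets.

Mature miRNA sequences are well-known, broadly conserved plant miRNAs from
the public mature-miRNA catalog (miRBase naming dialect), one per family.
Everything else — precursor flanks and the per-category non-coding-RNA
sequences — is *synthetic*: deterministic pseudo-random stand-ins generated
at import time from fixed seeds.  They provide category identity for
classification tests, not sequence realism.
"""

from __future__ import annotations

import zlib

import numpy as np

_BASES = np.array(list("ACGU"))

#: mature miRNAs, miRBase-style names (family parsed from the name)
MATURE_MIRNAS: dict[str, str] = {
    "ath-miR156a-5p": "UGACAGAAGAGAGUGAGCAC",
    "ath-miR159a": "UUUGGAUUGAAGGGAGCUCUA",
    "ath-miR160a-5p": "UGCCUGGCUCCCUGUAUGCCA",
    "ath-miR166a-3p": "UCGGACCAGGCUUCAUUCCCC",
    "ath-miR167a-5p": "UGAAGCUGCCAGCAUGAUCUA",
    "ath-miR168a-5p": "UCGCUUGGUGCAGGUCGGGAA",
    "ath-miR172a-3p": "AGAAUCUUGAUGAUGCUGCAU",
    "ath-miR319a": "UUGGACUGAAGGGAGCUCCCU",
    "ath-miR390a-5p": "AAGCUCAGGAGGGAUAGCGCC",
    "ath-miR396a-5p": "UUCCACAGCUUUCUUGAACUG",
}

_FLANK_LEN = 15


def _rand_rna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=n))


def _flank(name: str, side: str) -> str:
    # stable per-miRNA pseudo-random flank (synthetic precursor context)
    return _rand_rna(_FLANK_LEN, zlib.crc32(f"{name}:{side}".encode()))


#: synthetic precursor-like context: 5' flank + mature + 3' flank.
#: 5'-anchored isomiR slices of any length up to mature+15 are substrings.
PRECURSORS: dict[str, str] = {
    name: _flank(name, "5p") + seq + _flank(name, "3p")
    for name, seq in MATURE_MIRNAS.items()
}

#: start of the mature sequence within each precursor
MATURE_OFFSET = _FLANK_LEN

#: synthetic non-coding-RNA reference sequences per category
NCRNA_REFS: dict[str, list[tuple[str, str]]] = {
    "rRNA": [(f"synthetic_rRNA_{i}", _rand_rna(200, 1000 + i)) for i in range(3)],
    "tRNA": [(f"synthetic_tRNA_{i}", _rand_rna(76, 2000 + i)) for i in range(3)],
    "snRNA": [(f"synthetic_snRNA_{i}", _rand_rna(120, 3000 + i)) for i in range(2)],
    "snoRNA": [(f"synthetic_snoRNA_{i}", _rand_rna(100, 4000 + i)) for i in range(2)],
}


def mature_reference() -> list[tuple[str, str]]:
    """(name, mature sequence) pairs, reference order."""
    return list(MATURE_MIRNAS.items())


def classification_references() -> dict[str, list[tuple[str, str]]]:
    """Per-category reference sets for tag classification.

    The miRNA category uses the precursor-like sequences so that
    3'-extended isomiR reads still match by exact substring.
    """
    refs: dict[str, list[tuple[str, str]]] = {
        cat: list(seqs) for cat, seqs in NCRNA_REFS.items()
    }
    refs["miRNA"] = [(name, seq) for name, seq in PRECURSORS.items()]
    return refs
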