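"""Nearest-neighbor free-energy model and duplex minimum free energy.

The duplex model considers *intermolecular* base pairs only: two RNA strands
bound antiparallel, no intramolecular hairpins, no pseudoknots (pair lists
are non-crossing).  Admissible pairs are the Watson-Crick pairs plus the G-U
wobble.  The free energy of a structure is

    duplex_init
    + terminal penalty for each of the two outermost pairs that is AU or GU
    + for each pair of consecutive base pairs:
        * the stacking energy if they are directly adjacent on both strands,
        * otherwise a flat per-unpaired-nucleotide loop/bulge penalty.

Watson-Crick stacking energies follow the Turner nearest-neighbor set.
Wobble-containing stacks are derived from a Watson-Crick "parent" stack
(G-U read as a weakened G-C, U-G as a weakened U-A, +0.7 kcal/mol per
wobble, capped at 0), with strand a as the guide (miRNA) strand.  This
guarantees that mutating a perfectly complementary site can never lower
the duplex energy.  Because the target-prediction criterion consumes only
the *ratio* of two energies from the same model, relative consistency
matters more than absolute calibration.

``duplex_mfe`` minimizes this energy by dynamic programming in O(n*m);
``enumerate_duplex_mfe`` is an exhaustive brute-force reference for short
strands, used to validate the DP.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

from .seq import check_rna

WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
ALLOWED_PAIRS = WC_PAIRS | WOBBLE_PAIRS

#: sha256 of the packaged stack-energy table; guards against silent edits.
_STACK_TABLE_SHA256 = "1b66c92201727f9ac8a9c32c2f7509677fd44ca9267c9a64bb802f9607d4d1ad"


@dataclass(frozen=True)
class NNEnergyModel:
    """Parameter set for the duplex free-energy model (kcal/mol)."""

    stack_energy: Mapping[tuple[str, str], float] = field(repr=False)
    terminal_au_penalty: float = 0.45
    internal_mismatch_penalty: float = 0.8  # per unpaired nucleotide
    duplex_init: float = 4.09

    def __post_init__(self) -> None:
        for (p, q), e in self.stack_energy.items():
            if p not in ALLOWED_PAIRS or q not in ALLOWED_PAIRS:
                raise ValueError(f"stack table contains non-admissible pair {(p, q)}")
            if e > 0:
                raise ValueError(f"stacking energy for {(p, q)} must be <= 0, got {e}")


def load_default_model() -> NNEnergyModel:
    """Load the packaged stack table, verifying its checksum."""
    data = resources.files("srnapipe").joinpath("data/nn_stack.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _STACK_TABLE_SHA256:
        raise RuntimeError(
            f"nn_stack.tsv checksum mismatch: {digest} (expected {_STACK_TABLE_SHA256})"
        )
    stack: dict[tuple[str, str], float] = {}
    lines = data.decode().splitlines()
    for line in lines[1:]:
        p1, p2, e = line.split("\t")
        stack[(p1, p2)] = float(e)
    return NNEnergyModel(stack_energy=stack)


_DEFAULT_MODEL: NNEnergyModel | None = None


def default_model() -> NNEnergyModel:
    """Cached default model instance."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_default_model()
    return _DEFAULT_MODEL


def _terminal_penalty(pair: str, model: NNEnergyModel) -> float:
    return model.terminal_au_penalty if pair in ({"AU", "UA"} | WOBBLE_PAIRS) else 0.0


def structure_energy(
    a: str, b: str, pairs: list[tuple[int, int]], model: NNEnergyModel
) -> float:
    """Energy of an explicit structure.

    ``pairs`` are (i, j) indices into ``a`` and reversed ``b`` (antiparallel
    orientation), strictly increasing in both coordinates.  An empty pair
    list scores the initiation term only.
    """
    a = check_rna(a, what="strand a")
    r = check_rna(b, what="strand b")[::-1]
    e = model.duplex_init
    if not pairs:
        return e
    prev = None
    for i, j in pairs:
        pair = a[i] + r[j]
        if pair not in ALLOWED_PAIRS:
            raise ValueError(f"({i}, {j}) is not an admissible pair: {pair}")
        if prev is not None:
            pi, pj = prev
            if i <= pi or j <= pj:
                raise ValueError("pair list must be strictly increasing (non-crossing)")
            if i == pi + 1 and j == pj + 1:
                e += model.stack_energy[(a[pi] + r[pj], pair)]
            else:
                e += model.internal_mismatch_penalty * ((i - pi - 1) + (j - pj - 1))
        prev = (i, j)
    first = a[pairs[0][0]] + r[pairs[0][1]]
    last = a[pairs[-1][0]] + r[pairs[-1][1]]
    e += _terminal_penalty(first, model) + _terminal_penalty(last, model)
    return e


def duplex_mfe(strand_a: str, strand_b: str, model: NNEnergyModel | None = None) -> float:
    """Minimum free energy (kcal/mol) of the intermolecular duplex.

    The minimum runs over all non-crossing sets of admissible pairs,
    including the empty set (whose energy is the initiation term alone).
    """
    model = model or default_model()
    a = check_rna(strand_a, what="strand a")
    r = check_rna(strand_b, what="strand b")[::-1]
    n, m = len(a), len(r)
    pen = model.internal_mismatch_penalty
    INF = math.inf

    # best[i][j]: min energy (terminal penalty of the first pair included,
    # last pair's excluded) of a structure whose last pair is (i, j).
    best = [[INF] * m for _ in range(n)]
    # mprev[i][j]: min over i'<=i, j'<=j of best[i'][j'] - pen*(i'+j')
    mrow = [[INF] * m for _ in range(n)]
    overall = INF
    for i in range(n):
        for j in range(m):
            pair = a[i] + r[j]
            if pair in ALLOWED_PAIRS:
                v = _terminal_penalty(pair, model)  # (i, j) is the first pair
                if i > 0 and j > 0:
                    # flat loop/bulge transition from any earlier pair
                    rect = mrow[i - 1][j - 1]
                    if rect < INF:
                        v = min(v, pen * (i + j - 2) + rect)
                    # stacked transition (adjacent on both strands)
                    prev = best[i - 1][j - 1]
                    if prev < INF:
                        stacked = model.stack_energy.get((a[i - 1] + r[j - 1], pair))
                        if stacked is not None:
                            v = min(v, prev + stacked)
                best[i][j] = v
                overall = min(overall, v + _terminal_penalty(pair, model))
            cand = best[i][j] - pen * (i + j) if best[i][j] < INF else INF
            up = mrow[i - 1][j] if i > 0 else INF
            left = mrow[i][j - 1] if j > 0 else INF
            mrow[i][j] = min(cand, up, left)
    return model.duplex_init + min(0.0, overall)


def _enumerate_structures(
    allowed: list[list[bool]], n: int, m: int
) -> Iterator[list[tuple[int, int]]]:
    """Yield every non-empty, strictly increasing list of admissible pairs."""
    stack: list[tuple[int, int]] = []

    def rec(i0: int, j0: int) -> Iterator[list[tuple[int, int]]]:
        for i in range(i0, n):
            for j in range(j0, m):
                if allowed[i][j]:
                    stack.append((i, j))
                    yield list(stack)
                    yield from rec(i + 1, j + 1)
                    stack.pop()

    yield from rec(0, 0)


def enumerate_duplex_mfe(
    strand_a: str, strand_b: str, model: NNEnergyModel | None = None
) -> float:
    """Brute-force MFE by exhaustive structure enumeration (short strands).

    Reference implementation for validating :func:`duplex_mfe`; cost grows
    combinatorially, so strands are capped at 12 nt.
    """
    model = model or default_model()
    a = check_rna(strand_a, what="strand a")
    b = check_rna(strand_b, what="strand b")
    if len(a) > 12 or len(b) > 12:
        raise ValueError("enumeration oracle is limited to strands of <= 12 nt")
    r = b[::-1]
    allowed = [[a[i] + r[j] in ALLOWED_PAIRS for j in range(len(r))] for i in range(len(a))]
    mfe = model.duplex_init  # empty structure
    for pairs in _enumerate_structures(allowed, len(a), len(r)):
        mfe = min(mfe, structure_energy(a, b, pairs, model))
    return mfe
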