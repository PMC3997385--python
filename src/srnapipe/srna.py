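"""Small-RNA read cleaning, collapsing, classification and conserved miRNAs.

The cleaning stage trims the 3' sequencing adaptor, drops low-quality
(N-containing) and out-of-range reads (clean inserts are kept between 16
and 30 nt), and collapses identical sequences into unique tags with counts.
Tags are then classified against per-category non-coding-RNA reference sets
by exact substring matching, and conserved miRNAs are identified by
seed-anchored matching against a mature miRNA reference.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq import revcomp_rna, to_rna

logger = logging.getLogger(__name__)

MIN_TAG_LEN = 16
MAX_TAG_LEN = 30

#: seed region of a mature miRNA: 1-based positions 2-8 from the 5' end
SEED_START, SEED_END = 2, 8

#: priority when a tag matches several reference categories; abundant
#: structural RNA classes absorb ambiguous tags first.
CLASS_PRIORITY = ("rRNA", "tRNA", "snoRNA", "snRNA", "miRNA", "other-Rfam")

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class SmallRNATag:
    """A unique cleaned read sequence with its copy count."""

    sequence: str  # uppercase RNA
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if not (MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN):
            raise ValueError(
                f"tag length {len(self.sequence)} outside {MIN_TAG_LEN}-{MAX_TAG_LEN} nt"
            )


@dataclass(frozen=True)
class MiRNARecord:
    """A mature reference miRNA with the read count assigned to it."""

    name: str
    family: str
    sequence: str
    matched_count: int


@dataclass
class CategoryCensus:
    """Per-category tallies of distinct tags and total read counts."""

    tags: dict[str, int]
    reads: dict[str, int]

    def total_reads(self) -> int:
        return sum(self.reads.values())

    def total_tags(self) -> int:
        return sum(self.tags.values())


def trim_adaptor(read: str, adaptor3: str, min_overlap: int = 6) -> tuple[str, bool]:
    """Remove the 3' adaptor from a read.

    Finds the leftmost position where the read's remainder matches a prefix
    of the adaptor (exact match, at least ``min_overlap`` bases, or a full
    internal adaptor occurrence) and cuts there.  Returns
    ``(trimmed, adaptor_found)``; reads with no adaptor evidence are
    returned whole with ``adaptor_found=False``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not read:
        raise ValueError("empty read")
    r = to_rna(read)
    ad = to_rna(adaptor3)
    for i in range(len(r)):
        seg = r[i : i + len(ad)]
        if len(seg) < min_overlap:
            break
        if ad.startswith(seg) or seg == ad:
            return read[:i], True
    return read, False


def clean_and_collapse(
    reads: Iterable[str],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[list[SmallRNATag], Counter]:
    """Filter trimmed reads and collapse them into unique tags.

    Reads containing ambiguous bases or with length outside
    [``min_len``, ``max_len``] are dropped and tallied by reason
    ("ambiguous-base", "too-short", "too-long", "empty").  Kept reads are
    normalized to uppercase RNA and collapsed; tags are sorted by
    (count desc, sequence asc).
    """
    rejections: Counter = Counter()
    counts: Counter = Counter()
    for read in reads:
        if not read:
            rejections["empty"] += 1
            continue
        s = to_rna(read)
        if any(c not in "ACGU" for c in s):
            rejections["ambiguous-base"] += 1
            continue
        if len(s) < min_len:
            rejections["too-short"] += 1
            continue
        if len(s) > max_len:
            rejections["too-long"] += 1
            continue
        counts[s] += 1
    tags = [SmallRNATag(seq, n) for seq, n in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags, rejections


def classify_tags(
    tags: Sequence[SmallRNATag],
    references: Mapping[str, Sequence[tuple[str, str]]],
) -> tuple[CategoryCensus, list[str]]:
    """Assign each tag to a non-coding-RNA category by exact substring match.

    A tag belongs to a category when it (or its reverse complement) is an
    exact substring of any reference sequence of that category.  Categories
    are tried in :data:`CLASS_PRIORITY` order (unknown categories follow
    alphabetically), so multi-category matches resolve deterministically.
    Unmatched tags are labelled ``unannotated``.
    """
    if not references:
        raise ValueError("reference map is empty")
    for cat, seqs in references.items():
        if not seqs:
            raise ValueError(f"reference category {cat!r} is empty")
    normalized = {
        cat: [to_rna(seq) for _name, seq in seqs] for cat, seqs in references.items()
    }
    order = [c for c in CLASS_PRIORITY if c in normalized]
    order += sorted(c for c in normalized if c not in CLASS_PRIORITY)

    labels: list[str] = []
    tag_tally: Counter = Counter()
    read_tally: Counter = Counter()
    for tag in tags:
        fwd, rev = tag.sequence, revcomp_rna(tag.sequence)
        label = UNANNOTATED
        for cat in order:
            if any(fwd in ref or rev in ref for ref in normalized[cat]):
                label = cat
                break
        labels.append(label)
        tag_tally[label] += 1
        read_tally[label] += tag.count
    return CategoryCensus(tags=dict(tag_tally), reads=dict(read_tally)), labels


def length_distribution(tags: Sequence[SmallRNATag]) -> dict[int, float]:
    """Fraction of total *read count* at each tag length."""
    if not tags:
        raise ValueError("no tags: length distribution undefined")
    by_len: Counter = Counter()
    for t in tags:
        by_len[len(t.sequence)] += t.count
    total = sum(by_len.values())
    return {L: by_len[L] / total for L in sorted(by_len)}


_FAMILY_RE = re.compile(r"miR-?(\d+)", re.IGNORECASE)


def family_of(mirna_name: str) -> str:
    """miRNA family from a miRBase-style name: ath-miR166a-5p -> miR166."""
    m = _FAMILY_RE.search(mirna_name)
    if not m:
        logger.warning("cannot parse miRNA family from name %r", mirna_name)
        return "unknown"
    return f"miR{m.group(1)}"


def _tag_matches(tag: str, mature: str, max_mismatch: int) -> int | None:
    """Mismatch count if the tag is assignable to the mature miRNA, else None.

    Matching is anchored at the 5' end (isomiR variation is 3'-dominant):
    lengths may differ by at most 2 nt, mismatches are counted over the
    5'-aligned overlap, and the seed (miRNA positions 2-8) must be exact.
    """
    if abs(len(tag) - len(mature)) > 2:
        return None
    overlap = min(len(tag), len(mature))
    if overlap < SEED_END:
        return None
    mismatches = sum(1 for i in range(overlap) if tag[i] != mature[i])
    if mismatches > max_mismatch:
        return None
    if any(tag[i] != mature[i] for i in range(SEED_START - 1, SEED_END)):
        return None
    return mismatches


def identify_conserved_mirnas(
    tags: Sequence[SmallRNATag],
    mature_ref: Sequence[tuple[str, str]],
    max_mismatch: int = 2,
) -> list[MiRNARecord]:
    """Tally tag counts onto a mature miRNA reference by seed-anchored matching.

    Each tag is assigned to at most one reference miRNA: the one with the
    fewest mismatches (ties broken by lexicographically first name).  A tag
    matches when lengths agree within 2 nt, total mismatches over the
    5'-aligned overlap are <= ``max_mismatch``, and the seed region
    (positions 2-8) is mismatch-free.  Returns one record per reference
    entry (zero counts included), in reference order.
    """
    ref: list[tuple[str, str]] = []
    for idx, entry in enumerate(mature_ref):
        try:
            name, seq = entry
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed mature miRNA record at index {idx}") from exc
        if not name or not seq:
            raise ValueError(f"malformed mature miRNA record at index {idx}")
        ref.append((name, to_rna(seq)))

    counts: Counter = Counter()
    for tag in tags:
        best: tuple[int, str] | None = None
        for name, mseq in ref:
            mm = _tag_matches(tag.sequence, mseq, max_mismatch)
            if mm is not None and (best is None or (mm, name) < best):
                best = (mm, name)
        if best is not None:
            counts[best[1]] += tag.count
    return [
        MiRNARecord(name=n, family=family_of(n), sequence=s, matched_count=counts[n])
        for n, s in ref
    ]
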