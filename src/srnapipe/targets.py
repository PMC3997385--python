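"""miRNA target prediction on transcripts under six complementarity criteria.

Plant miRNA targets are recognized by near-perfect, ungapped antiparallel
pairing of the miRNA against the transcript.  Candidate sites are scored
position-by-position from the miRNA 5' end (position 1), pairing the site's
3'-most base; Watson-Crick pairs score 0 mismatches, G-U wobbles 0.5, and
anything else 1.  A site is a predicted target when it satisfies all six of
the classic stringency criteria (the Allen/Schwab rule set):

1. total mismatch score <= 4;
2. no run of more than two adjacent mismatches;
3. no adjacent mismatches within positions 2-12;
4. positions 10-11 perfectly paired (the expected cleavage site);
5. mismatch score over positions 1-12 <= 2.5;
6. duplex minimum free energy >= 74% of the MFE of the miRNA bound to its
   perfect complement (compared on magnitudes).

Whether a G-U wobble counts as a "mismatch" for the positional rules 2-4 is
ambiguous in common usage; it does here by default (it always contributes
0.5 to the score sums) and is switchable via ``gu_is_mismatch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .energy import NNEnergyModel, WC_PAIRS, WOBBLE_PAIRS, default_model, duplex_mfe
from .seq import check_rna, revcomp_rna

#: per-position pair classes
WC, GU, MM = "WC", "GU", "MM"

_SCORE = {WC: 0.0, GU: 0.5, MM: 1.0}

DEFAULT_MAX_SCORE = 4.0
DEFAULT_MFE_RATIO = 0.74


@dataclass(frozen=True)
class DuplexAlignment:
    """Ungapped pairing of a miRNA against a same-length transcript window.

    ``per_position[k]`` is the pair class at miRNA position ``k + 1``
    (1-based from the miRNA 5' end), which faces the site's 3'-most-minus-k
    base on the transcript sense strand.
    """

    mirna: str
    site: str
    per_position: tuple[str, ...]
    transcript_id: str | None = None
    site_start: int | None = None  # 0-based half-open on the transcript
    site_end: int | None = None

    def __post_init__(self) -> None:
        if len(self.per_position) != len(self.mirna):
            raise ValueError("per_position length must equal miRNA length")
        if len(self.site) != len(self.mirna):
            raise ValueError("ungapped alignment requires equal lengths")

    @property
    def total_score(self) -> float:
        return sum(_SCORE[c] for c in self.per_position)

    def mismatch_score(self, position: int) -> float:
        """Score of 1-based miRNA ``position`` (0 WC, 0.5 GU, 1 MM)."""
        return _SCORE[self.per_position[position - 1]]


@dataclass
class RuleReport:
    """Outcome of the six criteria for one duplex."""

    rules: dict[int, bool]
    total_score: float
    mfe_duplex: float = float("nan")
    mfe_perfect: float = float("nan")
    mfe_ratio: float = float("nan")

    @property
    def passed(self) -> bool:
        return all(self.rules.get(r, False) for r in range(1, 7))

    def failing_rules(self) -> list[int]:
        return [r for r in sorted(self.rules) if not self.rules[r]]


@dataclass(frozen=True)
class TargetHit:
    """A site that satisfies all six criteria."""

    mirna_name: str
    transcript_id: str
    site_start: int
    site_end: int
    report: RuleReport = field(compare=False)


def classify_pair(mirna_base: str, site_base: str) -> str:
    """Pair class for one miRNA base facing one site base (both RNA)."""
    pair = mirna_base + site_base
    if pair in WC_PAIRS:
        return WC
    if pair in WOBBLE_PAIRS:
        return GU
    return MM


def align_window(
    mirna: str,
    window: str,
    transcript_id: str | None = None,
    start: int | None = None,
) -> DuplexAlignment:
    """Pair a miRNA against one transcript window (antiparallel, ungapped)."""
    L = len(mirna)
    per = tuple(classify_pair(mirna[p], window[L - 1 - p]) for p in range(L))
    return DuplexAlignment(
        mirna=mirna,
        site=window,
        per_position=per,
        transcript_id=transcript_id,
        site_start=start,
        site_end=None if start is None else start + L,
    )


def scan_candidates(
    mirna: str,
    transcript: str,
    max_score: float = DEFAULT_MAX_SCORE,
    transcript_id: str | None = None,
) -> list[DuplexAlignment]:
    """All transcript windows whose total mismatch score is <= ``max_score``.

    Every window of miRNA length on the transcript sense strand is paired
    ungapped and antiparallel (miRNA 5' end against the window's 3' end).
    """
    m = check_rna(mirna, what="miRNA")
    t = check_rna(transcript, what="transcript")
    if len(m) < 16:
        raise ValueError(f"miRNA shorter than 16 nt ({len(m)})")
    if len(t) < len(m):
        raise ValueError("transcript shorter than the miRNA")
    out = []
    for start in range(len(t) - len(m) + 1):
        d = align_window(m, t[start : start + len(m)], transcript_id, start)
        if d.total_score <= max_score + 1e-9:
            out.append(d)
    return out


def apply_rules(
    d: DuplexAlignment,
    max_score: float = DEFAULT_MAX_SCORE,
    gu_is_mismatch: bool = True,
) -> RuleReport:
    """Evaluate the positional criteria 1-5 (criterion 6 needs energies).

    A position counts as "mismatched" for rules 2-4 when its class is MM,
    or GU if ``gu_is_mismatch`` (the default, conservative reading).
    Score sums always count GU as 0.5.
    """
    L = len(d.per_position)
    bad = [
        c == MM or (gu_is_mismatch and c == GU) for c in d.per_position
    ]  # index k = position k+1
    total = d.total_score

    r1 = total <= max_score + 1e-9

    run = maxrun = 0
    for b in bad:
        run = run + 1 if b else 0
        maxrun = max(maxrun, run)
    r2 = maxrun <= 2

    # both members of the adjacent pair must lie within positions 2..12
    r3 = not any(bad[k] and bad[k + 1] for k in range(1, min(11, L - 1)))

    r4 = True
    for pos in (10, 11):
        if pos <= L and bad[pos - 1]:
            r4 = False

    r5 = sum(d.mismatch_score(p) for p in range(1, min(12, L) + 1)) <= 2.5 + 1e-9

    return RuleReport(rules={1: r1, 2: r2, 3: r3, 4: r4, 5: r5}, total_score=total)


def perfect_complement_mfe(mirna: str, model: NNEnergyModel | None = None) -> float:
    """MFE of the miRNA bound to its exact reverse complement."""
    return duplex_mfe(mirna, revcomp_rna(mirna), model)


def mfe_ratio_test(
    mirna: str,
    site: str,
    model: NNEnergyModel | None = None,
    threshold: float = DEFAULT_MFE_RATIO,
    mfe_perfect: float | None = None,
) -> tuple[float, bool, float, float]:
    """Criterion 6: duplex MFE must reach ``threshold`` of the perfect duplex.

    Returns ``(ratio, passed, mfe_duplex, mfe_perfect)`` where the ratio is
    computed on magnitudes.  ``mfe_perfect`` may be passed in when cached by
    the caller (it depends only on the miRNA).
    """
    model = model or default_model()
    if mfe_perfect is None:
        mfe_perfect = perfect_complement_mfe(mirna, model)
    if abs(mfe_perfect) < 1e-9:
        raise ValueError("perfect-complement MFE is zero; cannot normalize")
    mfe_d = duplex_mfe(mirna, site, model)
    ratio = abs(mfe_d) / abs(mfe_perfect) if mfe_d < 0 else 0.0
    return ratio, ratio >= threshold - 1e-9, mfe_d, mfe_perfect


def evaluate_site(
    mirna: str,
    site: str,
    model: NNEnergyModel | None = None,
    max_score: float = DEFAULT_MAX_SCORE,
    mfe_ratio: float = DEFAULT_MFE_RATIO,
    gu_is_mismatch: bool = True,
    mfe_perfect: float | None = None,
) -> RuleReport:
    """Full six-criteria report for one miRNA/site pair of equal length."""
    d = align_window(check_rna(mirna, what="miRNA"), check_rna(site, what="site"))
    report = apply_rules(d, max_score=max_score, gu_is_mismatch=gu_is_mismatch)
    ratio, ok, mfe_d, mfe_p = mfe_ratio_test(
        d.mirna, d.site, model, threshold=mfe_ratio, mfe_perfect=mfe_perfect
    )
    report.rules[6] = ok
    report.mfe_duplex = mfe_d
    report.mfe_perfect = mfe_p
    report.mfe_ratio = ratio
    return report


def predict_targets(
    mirnas: Iterable[tuple[str, str]],
    transcripts: Iterable[tuple[str, str]],
    model: NNEnergyModel | None = None,
    max_score: float = DEFAULT_MAX_SCORE,
    mfe_ratio: float = DEFAULT_MFE_RATIO,
    gu_is_mismatch: bool = True,
) -> list[TargetHit]:
    """Predict target sites for every (name, sequence) miRNA on every transcript.

    Only sites passing all six criteria are returned, ordered by
    (mirna_name, transcript_id, site_start).  Overlapping hits are all
    reported; no greedy merging.
    """
    model = model or default_model()
    transcripts = [(tid, check_rna(s, what=f"transcript {tid}")) for tid, s in transcripts]
    hits: list[TargetHit] = []
    for name, mseq in mirnas:
        m = check_rna(mseq, what=f"miRNA {name}")
        mfe_p = perfect_complement_mfe(m, model)  # cached per miRNA
        for tid, tseq in transcripts:
            if len(tseq) < len(m):
                continue
            for d in scan_candidates(m, tseq, max_score=max_score, transcript_id=tid):
                report = apply_rules(d, max_score=max_score, gu_is_mismatch=gu_is_mismatch)
                if not all(report.rules.values()):
                    continue
                ratio, ok, mfe_d, _ = mfe_ratio_test(
                    m, d.site, model, threshold=mfe_ratio, mfe_perfect=mfe_p
                )
                report.rules[6] = ok
                report.mfe_duplex = mfe_d
                report.mfe_perfect = mfe_p
                report.mfe_ratio = ratio
                if ok:
                    hits.append(
                        TargetHit(
                            mirna_name=name,
                            transcript_id=tid,
                            site_start=d.site_start,
                            site_end=d.site_end,
                            report=report,
                        )
                    )
    hits.sort(key=lambda h: (h.mirna_name, h.transcript_id, h.site_start))
    return hits
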