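"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the study conditions of a plant leaf small-RNA +
transcriptome experiment:

* :func:`simulate_srna_reads` — raw FASTQ-style reads drawn from a
  category mixture (miRNA / rRNA / tRNA / snRNA / snoRNA / unannotated)
  with a configurable insert-length distribution whose default follows the
  canonical leaf profile (21- and 24-nt peaks; 20-24 nt at
  4.1/19.5/22.4/5.3/30.0% of reads), a 3' adaptor appended and the read
  truncated to the machine read length.
* :func:`simulate_transcriptome` — random transcripts carrying planted
  miRNA target sites that satisfy all six complementarity criteria, plus
  decoy sites that each violate exactly one named rule.  Sites are built by
  randomized mutation search and verified with the real scoring engine.
* :func:`simulate_counts` — a two-sample count table with known per-gene
  log2 fold changes under Poisson (or optionally negative-binomial) noise.

Identical configurations (including the seed) give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _refdata
from .energy import NNEnergyModel, default_model
from .seq import revcomp_rna, to_dna, to_rna
from .targets import (
    DEFAULT_MAX_SCORE,
    DEFAULT_MFE_RATIO,
    DuplexAlignment,
    apply_rules,
    evaluate_site,
    mfe_ratio_test,
    scan_candidates,
)

CATEGORIES = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "unannotated")

#: read census of a typical plant leaf sRNA library: of ~5.5M cleaned reads,
#: ~1.1M match annotated ncRNA classes, dominated by miRNA (61.6% of the
#: annotated fraction), rRNA (25.9%) and tRNA (10.7%).
_CENSUS_COUNTS = {
    "miRNA": 674_825,
    "rRNA": 283_314,
    "tRNA": 116_982,
    "snRNA": 1_366,
    "snoRNA": 3_490,
}
_CENSUS_TOTAL = 5_499_903

#: canonical leaf-library insert length profile (fractions of total reads);
#: the remaining mass is spread uniformly over the other 18-30 nt lengths.
_PEAK_LENGTH_FRACTIONS = {20: 0.041, 21: 0.195, 22: 0.224, 23: 0.053, 24: 0.300}

_DEPTH_REFERENCE = 1_500_000  # library size at which count means equal base means


def default_length_weights() -> dict[int, float]:
    w = dict(_PEAK_LENGTH_FRACTIONS)
    rest = [L for L in range(18, 31) if L not in w]
    remainder = 1.0 - sum(w.values())
    for L in rest:
        w[L] = remainder / len(rest)
    return {L: w[L] for L in sorted(w)}


def default_category_fractions() -> dict[str, float]:
    f = {c: n / _CENSUS_TOTAL for c, n in _CENSUS_COUNTS.items()}
    f["unannotated"] = 1.0 - sum(f.values())
    return {c: f[c] for c in CATEGORIES}


class SimulationError(RuntimeError):
    """A generator could not satisfy its construction contract."""


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators (one seed fixes everything)."""

    seed: int = 0
    n_reads: int = 50_000
    length_weights: dict[int, float] = field(default_factory=default_length_weights)
    category_fractions: dict[str, float] = field(default_factory=default_category_fractions)
    adaptor3: str = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adaptor
    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (300, 1500)
    n_planted_targets: int = 20
    n_decoy_targets: int = 60
    n_genes_dge: int = 2_000
    frac_de: float = 0.1
    log2fc_magnitude: float = 2.0
    library_sizes: tuple[int, int] = (_DEPTH_REFERENCE, _DEPTH_REFERENCE)
    read_length_nt: int = 36
    #: "isomir": miRNA reads are 5'-anchored precursor slices at the drawn
    #: length; "exact": the mature sequence verbatim (ignores drawn length).
    mirna_length_mode: str = "isomir"
    count_noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1

    def validate(self) -> None:
        if abs(sum(self.length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("length_weights must sum to 1")
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category_fractions must sum to 1")
        if any(L < 16 or L > 30 for L in self.length_weights):
            raise ValueError("length_weights keys must lie in 16..30 nt")
        if any(p < 0 for p in self.length_weights.values()) or any(
            p < 0 for p in self.category_fractions.values()
        ):
            raise ValueError("probabilities must be >= 0")
        if set(self.category_fractions) - set(CATEGORIES):
            raise ValueError(f"unknown categories {set(self.category_fractions) - set(CATEGORIES)}")
        if any(c not in "ACGTU" for c in self.adaptor3.upper()):
            raise ValueError("adaptor3 must be over A/C/G/T/U")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.mirna_length_mode not in ("isomir", "exact"):
            raise ValueError("mirna_length_mode must be 'isomir' or 'exact'")
        if self.count_noise not in ("poisson", "nb"):
            raise ValueError("count_noise must be 'poisson' or 'nb'")
        if min(self.library_sizes) < 1:
            raise ValueError("library sizes must be >= 1")


@dataclass(frozen=True)
class PlantedSite:
    """A target site written into a transcript (0-based half-open coords)."""

    transcript_id: str
    site_start: int
    site_end: int
    mirna_name: str
    violated_rule: int | None  # None for valid sites, 1..6 for decoys


@dataclass
class GroundTruth:
    """What the generators planted, for post-hoc comparison."""

    planted_mirnas: list[tuple[str, str, str, int]] = field(default_factory=list)
    planted_targets: list[PlantedSite] = field(default_factory=list)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    read_categories: list[str] = field(default_factory=list)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# small RNA reads


def simulate_srna_reads(
    config: SimConfig,
    mirna_ref: Sequence[tuple[str, str]] | None = None,
    references: dict[str, list[tuple[str, str]]] | None = None,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Raw small-RNA reads as (id, sequence, quality) FASTQ triples.

    Each read draws a category and an insert length, takes its insert from
    the matching reference fixture (or random sequence for "unannotated"),
    appends the 3' adaptor and truncates to ``read_length_nt``.  Sequences
    are emitted as DNA with uniform high quality.
    """
    config.validate()
    if mirna_ref is None:
        mirna_ref = _refdata.mature_reference()
    if not mirna_ref:
        raise ValueError("mature miRNA reference is empty")
    if references is None:
        references = dict(_refdata.NCRNA_REFS)
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        if not references.get(cat):
            raise ValueError(f"reference category {cat!r} is empty")

    rng = _rng(config, 0)
    cats = list(CATEGORIES)
    cat_p = np.array([config.category_fractions.get(c, 0.0) for c in cats])
    lens = np.array(sorted(config.length_weights))
    len_p = np.array([config.length_weights[L] for L in lens])

    cat_draw = rng.choice(len(cats), size=config.n_reads, p=cat_p)
    len_draw = lens[rng.choice(len(lens), size=config.n_reads, p=len_p)]

    mir_names = [name for name, _ in mirna_ref]
    precursors = {
        name: _refdata.PRECURSORS.get(name, to_rna(seq)) for name, seq in mirna_ref
    }
    matures = {name: to_rna(seq) for name, seq in mirna_ref}
    ref_seqs = {cat: [to_rna(s) for _n, s in seqs] for cat, seqs in references.items()}
    all_ref = [s for seqs in ref_seqs.values() for s in seqs] + list(precursors.values())

    adaptor = to_dna(config.adaptor3)
    reads: list[tuple[str, str, str]] = []
    truth = GroundTruth()
    mir_tally: dict[str, int] = {name: 0 for name in mir_names}

    for i in range(config.n_reads):
        cat = cats[cat_draw[i]]
        L = int(len_draw[i])
        if cat == "miRNA":
            name = mir_names[rng.integers(len(mir_names))]
            mir_tally[name] += 1
            if config.mirna_length_mode == "exact":
                insert = matures[name]
            else:
                pre = precursors[name]
                off = pre.find(matures[name])  # 5'-anchored isomiR slice
                insert = pre[off : off + L]
        elif cat == "unannotated":
            insert = None
            for _ in range(50):
                cand = _random_rna(rng, L)
                rc = revcomp_rna(cand)
                if not any(cand in ref or rc in ref for ref in all_ref):
                    insert = cand
                    break
            if insert is None:  # pragma: no cover - astronomically unlikely
                raise SimulationError("could not draw an unannotated read")
        else:
            seqs = ref_seqs[cat]
            src = seqs[rng.integers(len(seqs))]
            start = int(rng.integers(0, len(src) - L + 1))
            insert = src[start : start + L]
            if rng.random() < 0.5:
                insert = revcomp_rna(insert)
        read_seq = (to_dna(insert) + adaptor)[: config.read_length_nt]
        reads.append((f"read{i:07d}", read_seq, "I" * len(read_seq)))
        truth.read_categories.append(cat)

    truth.planted_mirnas = [
        (name, _family(name), matures[name], mir_tally[name]) for name in mir_names
    ]
    return reads, truth


def _family(name: str) -> str:
    from .srna import family_of

    return family_of(name)


# ---------------------------------------------------------------------------
# transcriptome with planted target sites

_WOBBLE_PARTNER = {"G": "U", "U": "G"}
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _site_from_classes(mirna: str, classes: dict[int, str], rng: np.random.Generator) -> str | None:
    """Build a site whose pairing against ``mirna`` has the given classes.

    ``classes`` maps 1-based miRNA positions to "GU" or "MM"; unlisted
    positions pair Watson-Crick.  Returns None when a requested wobble is
    impossible for the miRNA base at that position.
    """
    L = len(mirna)
    opposite = []
    for p in range(1, L + 1):
        b = mirna[p - 1]
        cls = classes.get(p, "WC")
        if cls == "WC":
            opposite.append(_COMPLEMENT[b])
        elif cls == "GU":
            partner = _WOBBLE_PARTNER.get(b)
            if partner is None:
                return None
            opposite.append(partner)
        else:  # MM: any base that neither pairs nor wobbles
            banned = {_COMPLEMENT[b], _WOBBLE_PARTNER.get(b, "")}
            choices = [c for c in "ACGU" if c not in banned]
            opposite.append(choices[rng.integers(len(choices))])
    # opposite[p-1] is the site base facing miRNA position p, i.e. the
    # site's 3'-most-minus-(p-1) base: reverse to get the sense strand 5'->3'
    return "".join(reversed(opposite))


def _gu_eligible(mirna: str) -> list[int]:
    return [p for p in range(1, len(mirna) + 1) if mirna[p - 1] in _WOBBLE_PARTNER]


def _non_adjacent_sample(rng: np.random.Generator, pool: list[int], k: int) -> list[int] | None:
    """Random k-subset of ``pool`` with no two members adjacent."""
    pool = sorted(pool)
    for _ in range(30):
        picked: list[int] = []
        cand = list(pool)
        rng.shuffle(cand)
        for p in cand:
            if all(abs(p - q) > 1 for q in picked):
                picked.append(p)
            if len(picked) == k:
                return sorted(picked)
    return None


def _positional_rules(mirna: str, classes: dict[int, str]) -> dict[int, bool]:
    """Rules 1-5 for a hypothetical class assignment (no site needed)."""
    L = len(mirna)
    per = tuple(classes.get(p, "WC") for p in range(1, L + 1))
    d = DuplexAlignment(mirna=mirna, site="A" * L, per_position=per)
    return apply_rules(d).rules


def _propose_decoy_classes(
    mirna: str, rule: int, rng: np.random.Generator
) -> dict[int, str] | None:
    """Heuristic mutation set intended to violate exactly ``rule``.

    Wobbles are preferred wherever the energy must stay high (rules 1-5:
    the MFE-ratio criterion must still pass); true mismatches are used for
    the rule-6 decoy, where the energy must drop.  The caller verifies the
    outcome with the real scorer.
    """
    L = len(mirna)
    gu = set(_gu_eligible(mirna))

    def cls(p: int) -> str:
        return "GU" if p in gu else "MM"

    if rule == 1:
        # push the total score just past 4 while rules 2-5 stay satisfied;
        # greedy over wobble-eligible positions first, then 3'-half
        # mismatches, rechecking the positional rules after each addition
        elig = [p for p in range(1, L + 1) if p in gu and p not in (10, 11)]
        mm_tail = [p for p in range(13, L + 1) if p not in gu]
        rng.shuffle(elig)
        rng.shuffle(mm_tail)
        classes: dict[int, str] = {}
        score = 0.0
        for p in elig + mm_tail:
            trial = dict(classes)
            trial[p] = cls(p)
            rules = _positional_rules(mirna, trial)
            if not (rules[2] and rules[3] and rules[4] and rules[5]):
                continue
            classes = trial
            score += 0.5 if trial[p] == "GU" else 1.0
            if score > 4.0:
                return classes
        return None

    if rule == 2:
        # a run of exactly three non-WC positions outside 2-12; prefer
        # starts rich in wobble-eligible positions (energy survives)
        starts = list(range(13, L - 1))
        if not starts:
            return None
        weights = [sum(p in gu for p in (s, s + 1, s + 2)) + rng.random() for s in starts]
        s = starts[int(np.argmax(weights))]
        return {p: cls(p) for p in (s, s + 1, s + 2)}

    if rule == 3:
        # two adjacent non-WC positions inside 2-12, clear of 10-11
        starts = list(range(2, 9))  # pair (s, s+1) within 2..9
        weights = [sum(p in gu for p in (s, s + 1)) + rng.random() for s in starts]
        s = starts[int(np.argmax(weights))]
        return {p: cls(p) for p in (s, s + 1)}

    if rule == 4:
        p = int(rng.integers(10, 12))
        return {p: cls(p)}

    if rule == 5:
        # push the 1-12 score past 2.5 (total staying <= 4) while rules
        # 2-4 hold; wobble-eligible positions first so the energy survives
        elig = [p for p in range(1, 13) if p in gu and p not in (10, 11)]
        other = [p for p in range(1, 13) if p not in gu and p not in (10, 11)]
        rng.shuffle(elig)
        rng.shuffle(other)
        classes = {}
        score = 0.0
        for p in elig + other:
            add = 0.5 if p in gu else 1.0
            if score + add > 4.0:
                continue
            trial = dict(classes)
            trial[p] = cls(p)
            rules = _positional_rules(mirna, trial)
            if not (rules[2] and rules[3] and rules[4]):
                continue
            classes = trial
            score += add
            if score > 2.5:
                return classes
        return None

    if rule == 6:
        # true mismatches spread over the 3' half: positional rules hold,
        # but enough stacking is lost to sink the energy ratio
        pool = list(range(13, L + 1))
        picked = _non_adjacent_sample(rng, pool, 4)
        if picked is None:
            return None
        return {p: "MM" for p in picked}

    raise ValueError(f"unknown rule {rule}")


def _no_foreign_hit(
    site: str,
    own_name: str,
    panel: Sequence[tuple[str, str]],
    model: NNEnergyModel,
    max_score: float,
    mfe_ratio: float,
) -> bool:
    """True when no *other* panel miRNA fully accepts this site."""
    for name, mseq in panel:
        if name == own_name or len(mseq) > len(site):
            continue
        for d in scan_candidates(mseq, site, max_score=max_score):
            rep = apply_rules(d, max_score=max_score)
            if not all(rep.rules.values()):
                continue
            _, ok, _, _ = mfe_ratio_test(mseq, d.site, model, threshold=mfe_ratio)
            if ok:
                return False
    return True


def _build_site(
    mirna_name: str,
    mirna: str,
    rule: int | None,
    panel: Sequence[tuple[str, str]],
    model: NNEnergyModel,
    rng: np.random.Generator,
    max_score: float = DEFAULT_MAX_SCORE,
    mfe_ratio: float = DEFAULT_MFE_RATIO,
    attempts: int = 300,
) -> str:
    """Search for a site that passes all six criteria (rule=None) or fails
    exactly the named rule, verified with the real scoring engine."""
    for _ in range(attempts):
        if rule is None:
            k = int(rng.integers(0, 3))
            pool = [p for p in range(13, len(mirna) + 1) if p in _gu_eligible(mirna)]
            picked = _non_adjacent_sample(rng, pool, min(k, len(pool)))
            classes = {p: "GU" for p in (picked or [])}
        else:
            maybe = _propose_decoy_classes(mirna, rule, rng)
            if maybe is None:
                continue
            classes = maybe
        site = _site_from_classes(mirna, classes, rng)
        if site is None:
            continue
        rep = evaluate_site(mirna, site, model, max_score=max_score, mfe_ratio=mfe_ratio)
        failing = rep.failing_rules()
        if rule is None and failing:
            continue
        if rule is not None and failing != [rule]:
            continue
        if not _no_foreign_hit(site, mirna_name, panel, model, max_score, mfe_ratio):
            continue
        return site
    kind = "valid site" if rule is None else f"decoy for rule {rule}"
    raise SimulationError(
        f"could not construct a {kind} for {mirna_name} after {attempts} attempts"
    )


def simulate_transcriptome(
    config: SimConfig,
    mirna_ref: Sequence[tuple[str, str]] | None = None,
    model: NNEnergyModel | None = None,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Random transcripts (DNA FASTA records) with planted target sites.

    Plants ``n_planted_targets`` sites satisfying all six criteria and
    ``n_decoy_targets`` decoys cycling through rules 1-6, each verified to
    violate exactly its named rule.  Site coordinates are 0-based half-open
    on the transcript sense strand.
    """
    config.validate()
    if mirna_ref is None:
        mirna_ref = _refdata.mature_reference()
    if not mirna_ref:
        raise ValueError("mature miRNA reference is empty")
    panel = [(name, to_rna(seq)) for name, seq in mirna_ref]
    model = model or default_model()
    rng = _rng(config, 1)

    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    transcripts = [
        [f"transcript{i:03d}", list(to_dna(_random_rna(rng, int(n))))]
        for i, n in enumerate(lengths)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(transcripts))}

    plan: list[int | None] = [None] * config.n_planted_targets
    plan += [1 + (k % 6) for k in range(config.n_decoy_targets)]

    truth = GroundTruth()
    for rule in plan:
        site_rna = None
        last_err: SimulationError | None = None
        for _ in range(max(10, 2 * len(panel))):  # not every miRNA can host every decoy
            name, mseq = panel[rng.integers(len(panel))]
            try:
                site_rna = _build_site(name, mseq, rule, panel, model, rng, attempts=60)
                break
            except SimulationError as err:
                last_err = err
        if site_rna is None:
            raise SimulationError(str(last_err))
        placed = False
        for _ in range(200):
            ti = int(rng.integers(len(transcripts)))
            tlen = len(transcripts[ti][1])
            if tlen < len(site_rna):
                continue
            start = int(rng.integers(0, tlen - len(site_rna) + 1))
            end = start + len(site_rna)
            if any(start < e and s < end for s, e in occupied[ti]):
                continue
            transcripts[ti][1][start:end] = list(to_dna(site_rna))
            occupied[ti].append((start, end))
            truth.planted_targets.append(
                PlantedSite(
                    transcript_id=transcripts[ti][0],
                    site_start=start,
                    site_end=end,
                    mirna_name=name,
                    violated_rule=rule,
                )
            )
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place a site (rule={rule}) without overlap; "
                "increase transcript number or length"
            )
    records = [(tid, "".join(seq)) for tid, seq in transcripts]
    return records, truth


# ---------------------------------------------------------------------------
# two-sample count tables

_MEAN_RANGE = (5.0, 1000.0)  # log-uniform base-mean range at reference depth
_GENE_LENGTH_RANGE = (200, 2000)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-sample count table with known log2 fold changes.

    Per-gene base means are log-uniform over [5, 1000] at the reference
    depth; a ``frac_de`` subset gets the sample-2 mean multiplied by
    2^(±log2fc_magnitude) (sign random, recorded).  Counts are Poisson
    (or gamma-Poisson when ``count_noise='nb'``); library-size settings
    scale the means of both samples proportionally.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_genes_dge
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    log_lo, log_hi = math.log10(_MEAN_RANGE[0]), math.log10(_MEAN_RANGE[1])
    base = 10.0 ** rng.uniform(log_lo, log_hi, size=n)
    lengths = rng.integers(_GENE_LENGTH_RANGE[0], _GENE_LENGTH_RANGE[1] + 1, size=n)

    lfc = np.zeros(n)
    n_de = int(round(config.frac_de * n))
    if n_de:
        idx = rng.choice(n, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[idx] = signs * config.log2fc_magnitude

    N1, N2 = config.library_sizes
    mu1 = base * (N1 / _DEPTH_REFERENCE)
    mu2 = base * (2.0**lfc) * (N2 / _DEPTH_REFERENCE)
    if config.count_noise == "poisson":
        x = rng.poisson(mu1)
        y = rng.poisson(mu2)
    else:
        shape = 1.0 / config.nb_dispersion
        x = rng.poisson(rng.gamma(shape, mu1 / shape))
        y = rng.poisson(rng.gamma(shape, mu2 / shape))

    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "count_s1": x.astype(int),
            "count_s2": y.astype(int),
            "length_nt": lengths.astype(int),
        }
    )
    truth = GroundTruth(de_genes=list(zip(gene_ids, lfc.tolist())))
    return df, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
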