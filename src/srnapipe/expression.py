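"""Two-sample differential expression for digital count data.

Expression is normalized to RPKM (reads per kilobase of transcript per
million mapped reads).  Significance of a per-transcript count difference
between two libraries of sizes N1 and N2 uses the Audic-Claverie exact
statistic: under a common Poisson rate with a flat prior, the predictive
probability of observing y counts in library 2 given x in library 1 is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

which equals a negative-binomial pmf with size x+1 and success probability
N1/(N1+N2).  Everything is computed in log space via log-gamma, so large
counts are safe.  Multiple testing is controlled with Benjamini-Hochberg,
and differential calls combine an FDR cutoff with a minimum |log2 ratio|
of RPKM (defaults 0.001 and 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_LOG2 = 1.0


@dataclass(frozen=True)
class CountRecord:
    """Per-transcript counts in the two samples."""

    gene_id: str
    x: int  # count in sample 1
    y: int  # count in sample 2
    length_nt: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"{self.gene_id}: counts must be >= 0")
        if self.length_nt < 1:
            raise ValueError(f"{self.gene_id}: length must be >= 1 nt")


@dataclass
class DEGResult:
    gene_id: str
    rpkm1: float
    rpkm2: float
    log2_ratio: float  # NaN when either count is zero
    p_value: float
    fdr: float
    call: str  # up | down | not-DE | sample1-only | sample2-only


def rpkm(c: int, N: int, L: int) -> float:
    """Reads per kilobase per million mapped reads: 1e9 * c / (N * L)."""
    if N < 1:
        raise ValueError("library size must be >= 1")
    if L < 1:
        raise ValueError("transcript length must be >= 1")
    return 1e9 * c / (N * L)


def ac_pmf(y, x: int, n1: int, n2: int):
    """Audic-Claverie predictive probability p(y | x).

    ``y`` may be a scalar or array.  Computed via log-gamma:
    log p = y*log(N2/N1) + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
            - (x+y+1)*log(1 + N2/N1).
    """
    if x < 0 or n1 < 1 or n2 < 1:
        raise ValueError("require x >= 0 and N1, N2 >= 1")
    ya = np.asarray(y, dtype=float)
    if np.any(ya < 0):
        raise ValueError("y must be >= 0")
    logr = math.log(n2) - math.log(n1)
    log1pr = math.log1p(n2 / n1)
    logp = (
        ya * logr
        + gammaln(x + ya + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ya + 1.0)
        - (x + ya + 1.0) * log1pr
    )
    out = np.exp(logp)
    return float(out) if np.isscalar(y) or ya.ndim == 0 else out


def _upper_tail(x: int, y: int, n1: int, n2: int) -> float:
    """P(Y >= y | x), summed directly until the geometric tail is negligible."""
    q = n2 / (n1 + n2)
    total = 0.0
    k = y
    chunk = 256
    while True:
        ks = np.arange(k, k + chunk)
        terms = ac_pmf(ks, x, n1, n2)
        total += float(terms.sum())
        k += chunk
        last = float(terms[-1])
        # ratio p(k+1)/p(k) = (x+k+1)/(k+1) * q -> q < 1 for large k
        ratio = (x + k) / k * q
        if ratio < 1.0 and last / (1.0 - ratio) < 1e-16 * max(total, 1e-300):
            break
        if k > y + 10_000_000:  # pragma: no cover - safety valve
            break
    return min(total, 1.0)


def _lower_tail(x: int, y: int, n1: int, n2: int) -> float:
    """P(Y <= y | x) by compensated summation."""
    terms = ac_pmf(np.arange(0, y + 1), x, n1, n2)
    return min(math.fsum(terms.tolist()), 1.0)


def ac_test(x: int, y: int, n1: int, n2: int, tail: str = "two") -> float:
    """Audic-Claverie p-value for counts (x, y) in libraries (N1, N2).

    ``tail='greater'`` tests enrichment in sample 2 (P(Y >= y | x)),
    ``'less'`` depletion (P(Y <= y | x)).  The default two-sided p doubles
    the smaller of the two *directional mid-p* tails

        P(Y >= y | x; N1, N2) - p(y|x)/2   and
        P(X >= x | y; N2, N1) - p(x|y)/2,

    capped at 1.  The mid-p correction counters the conservatism that raw
    tail-doubling inherits from the discreteness of count data, and this
    construction is exactly symmetric under swapping the two samples:
    ac_test(x, y, N1, N2) == ac_test(y, x, N2, N1).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if tail == "two":
        u1 = _upper_tail(x, y, n1, n2) - 0.5 * ac_pmf(y, x, n1, n2)
        u2 = _upper_tail(y, x, n2, n1) - 0.5 * ac_pmf(x, y, n2, n1)
        return min(1.0, 2.0 * min(u1, u2))
    if tail == "greater":
        return _upper_tail(x, y, n1, n2)
    if tail == "less":
        return _lower_tail(x, y, n1, n2)
    raise ValueError(f"unknown tail {tail!r}")


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def call_degs(
    records: Iterable[CountRecord],
    N1: int | None = None,
    N2: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_log2: float = DEFAULT_MIN_LOG2,
    tail: str = "two",
) -> tuple[list[DEGResult], dict]:
    """Differential-expression calls for a two-sample count table.

    Library sizes default to the column sums.  Genes expressed in only one
    sample are routed to the ``sample1-only`` / ``sample2-only`` categories
    (their RPKM log2 ratio is undefined); genes expressed in both samples
    are called ``up``/``down`` (sample 2 relative to sample 1) when the BH
    FDR is <= ``alpha`` and |log2 RPKM ratio| >= ``min_log2``.
    """
    recs = list(records)
    if N1 is None:
        N1 = sum(r.x for r in recs)
    if N2 is None:
        N2 = sum(r.y for r in recs)
    if recs and (N1 < 1 or N2 < 1):
        raise ValueError("library sizes must be >= 1")

    pvals = [ac_test(r.x, r.y, N1, N2, tail=tail) for r in recs]
    qvals = bh_fdr(pvals)

    results: list[DEGResult] = []
    summary = {
        "n_genes": len(recs),
        "up": 0,
        "down": 0,
        "not-DE": 0,
        "sample1-only": 0,
        "sample2-only": 0,
        "shared_expressed": 0,
        "N1": N1,
        "N2": N2,
        "alpha": alpha,
        "min_log2": min_log2,
    }
    for r, p, q in zip(recs, pvals, qvals):
        r1 = rpkm(r.x, N1, r.length_nt)
        r2 = rpkm(r.y, N2, r.length_nt)
        if r.x > 0 and r.y > 0:
            lr = math.log2(r2 / r1)
            summary["shared_expressed"] += 1
            if q <= alpha and lr >= min_log2:
                call = "up"
            elif q <= alpha and lr <= -min_log2:
                call = "down"
            else:
                call = "not-DE"
        else:
            lr = math.nan
            if r.x > 0:
                call = "sample1-only"
            elif r.y > 0:
                call = "sample2-only"
            else:
                call = "not-DE"
        summary[call] += 1
        results.append(
            DEGResult(
                gene_id=r.gene_id,
                rpkm1=r1,
                rpkm2=r2,
                log2_ratio=lr,
                p_value=p,
                fdr=q,
                call=call,
            )
        )
    return results, summary


def ddct(
    ct_target_s1: float, ct_ref_s1: float, ct_target_s2: float, ct_ref_s2: float
) -> float:
    """Relative expression of sample 2 vs sample 1 by the delta-delta-Ct rule.

    Returns 2^-((Ct_target,s2 - Ct_ref,s2) - (Ct_target,s1 - Ct_ref,s1)).
    """
    ddct_value = (ct_target_s2 - ct_ref_s2) - (ct_target_s1 - ct_ref_s1)
    return 2.0 ** (-ddct_value)
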