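# Methods

This note records the models, parameter choices and numerical conventions
behind `srnapipe`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Small-RNA cleaning and classification

Adaptor trimming removes, at the leftmost position, either a full internal
occurrence of the 3' adaptor or a read suffix that exactly matches an
adaptor prefix of at least `min_overlap` (default 6) bases. No
quality-score model is applied beyond discarding reads containing `N`:
quality filtering upstream of tag collapsing is assumed done, and the
simulator emits uniformly high qualities accordingly. Cleaned inserts are
kept between 16 and 30 nt, converted to uppercase RNA, and collapsed.

Classification is exact substring matching of a tag (or its reverse
complement — reference strand conventions vary) against per-category
reference sequences. No alignment is attempted: with short tags and small
curated reference sets, exact matching is deterministic and auditable.
Ties across categories resolve by the fixed priority
rRNA > tRNA > snoRNA > snRNA > miRNA > other, so abundant structural
classes absorb ambiguous tags first.

Conserved-miRNA assignment is anchored at the 5' end because isomiR
variability is predominantly 3'-sided: a tag matches a mature reference
when lengths differ by ≤ 2 nt, mismatches over the 5'-aligned overlap are
≤ `max_mismatch` (default 2), and the seed — defined here as miRNA
positions 2–8 — is mismatch-free. Each tag counts toward at most one
miRNA (fewest mismatches, then lexicographically first name). Families
are parsed from the name (`ath-miR166a-5p → miR166`).

## Duplex energy model

The minimum free energy of a miRNA/site duplex is minimized over all
non-crossing sets of intermolecular pairs (Watson–Crick + G-U wobble); no
intramolecular structure, no pseudoknots. The energy of a structure is

    E = E_init + Σ stacks + Σ loop penalties + terminal penalties

with `E_init = +4.09`, a terminal penalty of `+0.45` for an outermost
AU/GU pair, stacking energies for directly adjacent pairs, and a flat
`+0.8` kcal/mol per unpaired nucleotide in interior loops and bulges.
Watson–Crick stacks use the standard Turner nearest-neighbor values.
Wobble-containing stacks are derived from a Watson–Crick parent — G-U is
treated as a weakened G-C and U-G as a weakened U-A, `+0.7` per wobble,
capped at 0 — with strand *a* fixed as the guide (miRNA) strand. This
parent-derivation is deliberate: it guarantees the monotonicity contract
that mutating a perfectly complementary site can never *lower* the duplex
energy (a uniform wobble energy can beat a weak A-U stack and break it).
The cost is that the wobble part of the table is orientation-dependent,
which is acceptable because the model is only ever evaluated with the
miRNA as strand *a*, and because the target criterion consumes the
*ratio* |MFE(site)| / |MFE(perfect complement)|, making relative
consistency — not absolute kcal/mol calibration — the requirement. The
table ships as `data/nn_stack.tsv` and is checksummed at load.

The minimization is an O(n·m) dynamic program over "last pair" states
with an incremental prefix minimum handling the flat loop transition; it
is exact for this model because stacking energies are ≤ 0, so an adjacent
predecessor always prefers the stack branch. `enumerate_duplex_mfe`
recomputes the minimum by exhaustively scoring every structure (strands
≤ 12 nt) and is the independent oracle in the tests.

## Target rules

Positions are 1-based from the miRNA 5' end; position 1 faces the site's
3'-most base. G-U wobbles always contribute 0.5 to score sums; whether
they also count as "mismatches" for the positional rules 2–4 is
ambiguous in common usage — they do here by default (`gu_is_mismatch`,
switchable). Rule 2 ("no more than two adjacent mismatches") is read as
"no run of three or more consecutive non-paired positions anywhere"; rule
3 requires both members of an adjacent pair to lie within positions 2–12.
Alignment is strictly ungapped: the criteria count mismatches, never
gaps, so bulged sites are out of scope. Overlapping hits are all
reported. The perfect-complement MFE is computed once per miRNA and
cached.

## Differential expression

The Audic–Claverie predictive probability is computed in log space via
log-gamma; it equals the negative-binomial pmf with size x+1 and success
probability N1/(N1+N2), which the tests use as an independent oracle.
Lower tails are compensated sums; upper tails are summed directly from
the observation upward until the geometric tail bound is negligible
(computing an upper tail as 1 − lower cancels catastrophically exactly
when the result matters).

The two-sided p-value is twice the smaller of the two *directional mid-p*
tails, P(Y ≥ y | x; N1, N2) − p(y|x)/2 and its sample-swapped
counterpart, capped at 1. Two properties motivated this construction
over plain doubling of the smaller inclusive tail: it is exactly
symmetric under swapping the samples (each component maps onto the other,
so `ac_test(x, y, N1, N2) == ac_test(y, x, N2, N1)` to machine
precision), and the mid-p correction removes most of the conservatism
that discrete tails impose at low counts. One-sided options
(`tail='greater'/'less'`) use the plain inclusive sums.

Even with mid-p, doubled discrete tails remain slightly conservative: on
the default null simulation the empirical rejection rate at α = 0.05 is
≈ 0.041–0.045 rather than 0.050, driven by the ~25 % of genes with mean
counts below ~20. This is a property of any valid exact test on such a
mixture, not a defect of the implementation; at the pipeline's operating
point (FDR ≤ 0.001) it only makes calls marginally safer.

Calls: BH step-up FDR (statsmodels) on all genes; `up`/`down` require
FDR ≤ α (default 0.001) and |log2 RPKM ratio| ≥ δ (default 1). The log2
ratio is defined only when both counts are positive; genes observed in a
single sample are routed to `sample1-only`/`sample2-only` instead of
producing infinite ratios. Raw counts feed the exact test (its model is
count-based); RPKM feeds the ratio and reporting.

## Synthetic data: what it emulates, and what it does not

`simulate_srna_reads` draws, per read, a category from
{miRNA, rRNA, tRNA, snRNA, snoRNA, unannotated} and an insert length from
a configurable distribution. The default category fractions reproduce
the census proportions of a typical plant leaf library (miRNA ≈ 12.3 %,
rRNA ≈ 5.2 %, tRNA ≈ 2.1 %, ~80 % unannotated) and the default length
profile puts 4.1 / 19.5 / 22.4 / 5.3 / 30.0 % of reads at 20–24 nt, the
canonical 21/24-nt two-peak shape, with the remainder uniform over the
other 18–30 nt lengths. Inserts come from packaged references: mature
plant miRNAs (public, broadly conserved sequences) and *synthetic*
per-category ncRNA sequences that carry category identity only — no
sequence realism is attempted or needed for exact-substring
classification. miRNA reads are, by default, 5'-anchored slices of a
synthetic precursor context at the drawn length (isomiR-like), so the
configured length distribution governs every read; `mirna_length_mode=
"exact"` instead plants verbatim mature copies, the mode under which
lossless recovery is asserted. Reads are emitted as DNA with the TruSeq
small-RNA 3' adaptor appended and truncated to a 36-nt machine read.

`simulate_transcriptome` plants target sites by randomized mutation
search: candidate mutation sets are proposed per rule (wobble-preferring
where the energy ratio must survive, true mismatches for the rule-6
decoy) and accepted only when the real scoring engine confirms that
exactly the named rule fails (decoys) or all six pass (valid sites), and
that no other panel miRNA fully accepts the site. Construction failures
raise an error naming the rule. Because miR159a/miR319a are genuinely
3'-homologous, planted miR319a sites can additionally be hit by miR159a
at a 1-nt offset; spike-in metrics are defined on the planted/decoy
coordinates and are unaffected.

`simulate_counts` draws per-gene base means log-uniform on [5, 1000]
(chosen to span weakly to strongly expressed genes at the default
1.5 M-read depth), multiplies the sample-2 mean by 2^±lfc for a random
`frac_de` subset (sign recorded), and adds Poisson noise — the matched
test bed for the Poisson-derived exact statistic; a gamma-Poisson option
exists for over-dispersion robustness checks. Library-size settings scale
both means; the caller's realized column sums are what enter the test, so
strong asymmetric DE shifts effective depth exactly as in real libraries.

Passing tests on these simulations demonstrate algorithmic correctness
(recovery of planted truth under the model's own assumptions), not
performance on real libraries: sequencing error, expression-coupled
isomiR distributions, genomic multi-mapping and reference incompleteness
are all absent by design.

## Scale and determinism

Default problem sizes — 50,000 reads, 50 transcripts with 20 + 60 planted
sites, 2,000 genes (10,000 for null calibration runs) — keep a full
pipeline run under ~10 s on one CPU while leaving multinomial 3σ checks
tight enough to be meaningful. Every generator derives its stream from
`SimConfig.seed` via separate spawn keys, so identical configurations are
bit-identical end to end, including all written tables.

## Known limitations

- Ungapped sites only; bulged or translational-repression sites are out
  of scope, as is novel-miRNA discovery from hairpin prediction.
- The energy model is intentionally small: no dangling ends, no
  length-dependent loop terms, no coaxial stacking; absolute energies are
  not calibrated to experiment.
- Exact-substring classification cannot express partial/diverged homology
  (no alignment against full Rfam-scale references).
- The exact test assumes Poisson sampling; biological replicate
  over-dispersion is not modeled in the test itself.
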