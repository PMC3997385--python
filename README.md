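# srnapipe

Plant small-RNA analysis as a reusable, fully testable Python library:
read cleaning and tag collapsing, non-coding-RNA classification, conserved
miRNA identification, six-criteria miRNA target prediction with an RNA
duplex free-energy test, and two-sample differential expression with the
Audic–Claverie exact statistic. A synthetic-data module generates every
input with planted ground truth, so the whole pipeline runs and validates
offline — no sequencing archives or external databases required.

It is aimed at researchers analysing plant small-RNA + transcriptome
experiments (the package's defaults emulate a konjac, *Amorphophallus*,
leaf library) and at anyone who needs a transparent, scriptable
reimplementation of these classic desk-scale methods.

## The methods

**Cleaning and classification.** Raw reads are 3'-adaptor trimmed (exact
prefix match, configurable minimum overlap), filtered (no ambiguous bases,
insert length 16–30 nt) and collapsed to unique tags with counts. A tag is
assigned to rRNA / tRNA / snoRNA / snRNA / miRNA by exact substring match
against per-category reference sequences (both strands), with a fixed
priority for multi-category matches; everything else is *unannotated*.
Conserved miRNAs are identified by seed-anchored matching: length within
±2 nt, ≤ 2 mismatches over the 5'-aligned overlap, and a perfect seed
(miRNA positions 2–8).

**Target prediction.** Each miRNA is paired ungapped and antiparallel
against every transcript window (miRNA position 1 = 5' end, facing the
window's 3'-most base). Watson–Crick pairs score 0, G-U wobbles 0.5,
mismatches 1. A site is a predicted target when

1. total score ≤ 4;
2. no more than two adjacent mismatches;
3. no adjacent mismatches in positions 2–12;
4. no mismatches at positions 10–11;
5. score over positions 1–12 ≤ 2.5;
6. duplex MFE ≥ 74 % of the MFE of the miRNA bound to its perfect
   complement (on magnitudes).

The duplex MFE is computed by an exact dynamic program over all
non-crossing intermolecular pairings under a nearest-neighbor model
(Turner Watson–Crick stack energies, parent-derived wobble stacks, flat
loop penalties); a brute-force enumeration oracle validates it.

**Differential expression.** Counts x, y in libraries of sizes N1, N2 are
compared with the Audic–Claverie predictive probability

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

(the negative-binomial form, computed in log space). The two-sided
p-value doubles the smaller of the two directional mid-p tails and is
exactly symmetric under swapping the samples. Expression is reported as
RPKM = 10^9·c/(N·L); calls require Benjamini–Hochberg FDR ≤ 0.001 and
|log2 RPKM ratio| ≥ 1 (genes observed in only one sample are reported as
`sample1-only`/`sample2-only`). qPCR-style 2^−ΔΔCt arithmetic is included.

All interchange coordinates are 0-based, half-open, on the sense strand.

## Worked example

`examples/03_predict_targets.py` simulates 50 transcripts carrying 20
planted valid target sites and 60 decoys (each violating exactly one of
the six criteria), then runs the predictor:

```
25 predicted sites on 18 transcripts
planted valid sites recovered: 20/20
decoys (one rule violated each) wrongly accepted: 0/60
decoy rules planted: {1: 10, 2: 10, 3: 10, 4: 10, 5: 10, 6: 10}
  ath-miR159a -> transcript007[1122:1143] score=1.0 MFE=-33.5 ratio=0.92
```

Every planted site is recovered and no single-rule decoy is accepted; the
extra hits beyond 20 are miR159a recognizing miR319a sites, a real
cross-family homology. Each hit reports its mismatch score, duplex MFE
(kcal/mol) and energy ratio against the perfect duplex.

The other examples cover read cleaning/classification
(`01_clean_and_classify_reads.py`), conserved-miRNA identification
(`02_conserved_mirnas.py`), differential expression and ΔΔCt
(`04_differential_expression.py`), and the full pipeline plus the
glucomannan/starch enzyme census (`05_full_pipeline_and_census.py`).

A thin CLI wraps the same functions:

```bash
srnapipe run --seed 1 --outdir out        # full pipeline on synthetic inputs
srnapipe clean reads.fastq --adaptor TGGAATTCTCGGGTGCCAAGG
srnapipe targets --transcripts transcripts.fasta --out targets.tsv
srnapipe dge counts.tsv --alpha 0.001 --min-log2 1.0
```

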