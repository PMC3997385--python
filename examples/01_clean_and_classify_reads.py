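"""Clean simulated small-RNA reads and classify them by ncRNA category.

Generates a 20k-read synthetic library, trims the 3' adaptor, collapses
reads to unique tags, classifies tags against the packaged reference sets
and prints the census plus the length profile around the 21/24-nt peaks.
"""

from srnapipe import SimConfig, simulate_srna_reads
from srnapipe._refdata import classification_references
from srnapipe.srna import classify_tags, clean_and_collapse, length_distribution, trim_adaptor

cfg = SimConfig(seed=1, n_reads=20_000)
reads, truth = simulate_srna_reads(cfg)

trimmed = [trim_adaptor(seq, cfg.adaptor3)[0] for _id, seq, _q in reads]
tags, rejections = clean_and_collapse(trimmed)
census, _labels = classify_tags(tags, classification_references())
dist = length_distribution(tags)

print(f"{len(reads)} raw reads -> {sum(t.count for t in tags)} kept in {len(tags)} tags "
      f"({dict(rejections) or 'nothing rejected'})")
print("category census (reads):", dict(sorted(census.reads.items())))
print("length fractions 20-24 nt:", {L: round(dist.get(L, 0), 3) for L in range(20, 25)})
# The census should mirror the configured mixture (miRNA ~12%, rRNA ~5%,
# tRNA ~2%, mostly unannotated) and the length profile should peak at 24 nt
# (~30% of reads) with a secondary 21/22-nt shoulder.
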