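"""Predict miRNA target sites under the six complementarity criteria.

Simulates a transcriptome with 20 planted valid sites and 60 decoys that
each violate exactly one rule, runs the predictor, and compares against
the planted truth.
"""

from collections import Counter

from srnapipe import SimConfig, predict_targets, simulate_transcriptome
from srnapipe._refdata import mature_reference

cfg = SimConfig(seed=3)
transcripts, truth = simulate_transcriptome(cfg)
hits = predict_targets(mature_reference(), transcripts)

hit_keys = {(h.transcript_id, h.site_start, h.mirna_name) for h in hits}
planted = [s for s in truth.planted_targets if s.violated_rule is None]
decoys = [s for s in truth.planted_targets if s.violated_rule is not None]
found = sum((s.transcript_id, s.site_start, s.mirna_name) in hit_keys for s in planted)
decoy_hits = sum((s.transcript_id, s.site_start, s.mirna_name) in hit_keys for s in decoys)

print(f"{len(hits)} predicted sites on {len({h.transcript_id for h in hits})} transcripts")
print(f"planted valid sites recovered: {found}/{len(planted)}")
print(f"decoys (one rule violated each) wrongly accepted: {decoy_hits}/{len(decoys)}")
print("decoy rules planted:", dict(sorted(Counter(s.violated_rule for s in decoys).items())))
for h in hits[:3]:
    r = h.report
    print(f"  {h.mirna_name} -> {h.transcript_id}[{h.site_start}:{h.site_end}] "
          f"score={r.total_score:.1f} MFE={r.mfe_duplex:.1f} ratio={r.mfe_ratio:.2f}")
# Expect 20/20 recovered, 0/60 decoys accepted: the rule engine plus the
# >= 74% duplex-energy criterion separates true sites from single-rule decoys.
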