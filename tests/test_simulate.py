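"""Synthetic-data generators: determinism, planted-truth contracts."""

import math

import numpy as np
import pytest

from srnapipe import simulate as sim
from srnapipe._refdata import MATURE_MIRNAS, mature_reference
from srnapipe.seq import revcomp_rna, to_rna
from srnapipe.targets import align_window, evaluate_site


def small_cfg(**kw):
    defaults = dict(seed=42, n_reads=2000)
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestReads:
    def test_same_seed_gives_byte_identical_output(self):
        r1, t1 = sim.simulate_srna_reads(small_cfg())
        r2, t2 = sim.simulate_srna_reads(small_cfg())
        assert r1 == r2
        assert t1.read_categories == t2.read_categories

    def test_degenerate_mixture_all_mirna(self):
        cfg = small_cfg(
            n_reads=100,
            category_fractions={c: (1.0 if c == "miRNA" else 0.0) for c in sim.CATEGORIES},
            mirna_length_mode="exact",
        )
        reads, truth = sim.simulate_srna_reads(cfg)
        assert len(reads) == 100
        assert truth.read_categories == ["miRNA"] * 100
        matures = {to_rna(s) for s in MATURE_MIRNAS.values()}
        adaptor = cfg.adaptor3
        for _id, seq, _q in reads:
            insert = to_rna(seq[: seq.replace("U", "T").find(adaptor[:6])])
            assert insert in matures

    def test_24nt_fraction_recovers_configured_weight(self):
        cfg = small_cfg(n_reads=20_000)
        _reads, truth = sim.simulate_srna_reads(cfg)
        # recompute insert lengths from the fastq by trimming the adaptor
        reads, _ = sim.simulate_srna_reads(cfg)
        from srnapipe.srna import clean_and_collapse, length_distribution, trim_adaptor

        trimmed = [trim_adaptor(s, cfg.adaptor3)[0] for _i, s, _q in reads]
        tags, _rej = clean_and_collapse(trimmed)
        frac24 = length_distribution(tags).get(24, 0.0)
        p = cfg.length_weights[24]
        sigma = math.sqrt(p * (1 - p) / cfg.n_reads)
        assert abs(frac24 - p) <= 3 * sigma

    def test_read_count_and_truth_cover_every_read(self):
        reads, truth = sim.simulate_srna_reads(small_cfg())
        assert len(reads) == len(truth.read_categories) == 2000

    def test_category_fractions_within_3_sigma(self):
        cfg = small_cfg(n_reads=20_000)
        _reads, truth = sim.simulate_srna_reads(cfg)
        n = cfg.n_reads
        for cat, p in cfg.category_fractions.items():
            got = truth.read_categories.count(cat) / n
            sigma = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(got - p) <= max(3 * sigma, 2 / n), cat

    def test_bad_probability_map_rejected(self):
        cfg = small_cfg()
        cfg.length_weights = {21: 0.5, 24: 0.6}
        with pytest.raises(ValueError, match="sum to 1"):
            sim.simulate_srna_reads(cfg)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sim.simulate_srna_reads(small_cfg(), mirna_ref=[])


@pytest.fixture(scope="module")
def planted_transcriptome():
    cfg = sim.SimConfig(seed=99, n_planted_targets=6, n_decoy_targets=12, n_transcripts=20)
    return cfg, *sim.simulate_transcriptome(cfg)


class TestTranscriptome:
    def test_deterministic(self):
        cfg = sim.SimConfig(seed=7, n_planted_targets=3, n_decoy_targets=6, n_transcripts=12)
        a = sim.simulate_transcriptome(cfg)
        b = sim.simulate_transcriptome(cfg)
        assert a[0] == b[0]
        assert a[1].planted_targets == b[1].planted_targets

    def test_every_valid_site_passes_and_each_decoy_fails_its_rule(self, planted_transcriptome, model):
        cfg, records, truth = planted_transcriptome
        seqs = dict(records)
        matures = dict(mature_reference())
        assert len(truth.planted_targets) == 18
        for site in truth.planted_targets:
            window = to_rna(seqs[site.transcript_id][site.site_start : site.site_end])
            rep = evaluate_site(to_rna(matures[site.mirna_name]), window, model)
            if site.violated_rule is None:
                assert rep.passed
            else:
                assert rep.failing_rules() == [site.violated_rule]

    def test_rule4_decoys_are_perfect_except_positions_10_11(self, planted_transcriptome):
        cfg, records, truth = planted_transcriptome
        seqs = dict(records)
        matures = dict(mature_reference())
        rule4 = [s for s in truth.planted_targets if s.violated_rule == 4]
        assert rule4
        for site in rule4:
            window = to_rna(seqs[site.transcript_id][site.site_start : site.site_end])
            d = align_window(to_rna(matures[site.mirna_name]), window)
            nonwc = [p + 1 for p, c in enumerate(d.per_position) if c != "WC"]
            assert nonwc and set(nonwc) <= {10, 11}

    def test_rule1_decoys_score_above_four_with_positional_rules_satisfied(self, planted_transcriptome, model):
        cfg, records, truth = planted_transcriptome
        seqs = dict(records)
        matures = dict(mature_reference())
        rule1 = [s for s in truth.planted_targets if s.violated_rule == 1]
        assert rule1
        for site in rule1:
            window = to_rna(seqs[site.transcript_id][site.site_start : site.site_end])
            rep = evaluate_site(to_rna(matures[site.mirna_name]), window, model)
            assert rep.total_score > 4.0
            assert rep.rules[2] and rep.rules[3] and rep.rules[4] and rep.rules[5]
            assert rep.rules[6]  # energy still high: only rule 1 violated

    def test_exact_complement_sites_exist_among_planted(self, planted_transcriptome):
        """Zero-mutation planted sites are exact reverse complements."""
        cfg, records, truth = planted_transcriptome
        seqs = dict(records)
        matures = dict(mature_reference())
        exact = 0
        for site in truth.planted_targets:
            if site.violated_rule is not None:
                continue
            window = to_rna(seqs[site.transcript_id][site.site_start : site.site_end])
            if window == revcomp_rna(to_rna(matures[site.mirna_name])):
                exact += 1
        assert exact >= 1

    def test_impossible_placement_raises_naming_the_problem(self):
        cfg = sim.SimConfig(
            seed=1, n_transcripts=1, transcript_length_range=(40, 50),
            n_planted_targets=6, n_decoy_targets=0,
        )
        with pytest.raises(sim.SimulationError):
            sim.simulate_transcriptome(cfg)


class TestCounts:
    def test_no_de_means_all_true_lfc_zero(self):
        cfg = small_cfg(n_genes_dge=300, frac_de=0.0)
        _df, truth = sim.simulate_counts(cfg)
        assert all(l == 0.0 for _g, l in truth.de_genes)

    def test_symmetric_gene_log_ratio_near_zero(self):
        cfg = small_cfg(n_genes_dge=4000, frac_de=0.0)
        df, _ = sim.simulate_counts(cfg)
        big = df[(df.count_s1 >= 500)]
        ratios = np.log2(big.count_s2 / big.count_s1)
        assert abs(ratios.mean()) < 0.05

    def test_deterministic_table(self):
        cfg = small_cfg(n_genes_dge=200)
        a, _ = sim.simulate_counts(cfg)
        b, _ = sim.simulate_counts(cfg)
        assert a.equals(b)

    def test_de_fraction_and_magnitude(self):
        cfg = small_cfg(n_genes_dge=1000, frac_de=0.2, log2fc_magnitude=3.0)
        _df, truth = sim.simulate_counts(cfg)
        lfcs = [l for _g, l in truth.de_genes if l != 0.0]
        assert len(lfcs) == 200
        assert all(abs(l) == 3.0 for l in lfcs)

    def test_nb_noise_option_runs(self):
        cfg = small_cfg(n_genes_dge=100, count_noise="nb")
        df, _ = sim.simulate_counts(cfg)
        assert (df.count_s1 >= 0).all()
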