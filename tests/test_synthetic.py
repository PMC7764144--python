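import filecmp

import numpy as np
import pytest

from lncmode import SimConfig, revcomp, simulate_dataset, simulate_genome
from lncmode.synthetic import plant_lncrna, simulate_contacts, simulate_knockdown
from lncmode.targets import build_cotx_target, build_posttx_target


def longest_complementary_run(a: str, b: str) -> int:
    """Exhaustive longest exact reverse-complement substring shared by a and b."""
    rb = revcomp(b)
    best = 0
    # classic O(nm) longest-common-substring scan, independent of the predictor
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(rb, 1):
            v = prev[j - 1] + 1 if ca == cb else 0
            cur.append(v)
            best = max(best, v)
        prev = cur
    return best


class TestGenome:
    def test_gc_content_matches_request(self):
        genome, _ = simulate_genome(SimConfig(seed=1, n_genes=10, n_chroms=1))
        seq = genome.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert len(seq) > 20_000
        assert 0.48 < gc < 0.52

    def test_deterministic_artifacts(self, tmp_path):
        cfg = SimConfig(seed=5, n_genes=12, n_true_targets=4)
        simulate_dataset(cfg, tmp_path / "a")
        simulate_dataset(cfg, tmp_path / "b")
        for name in ("genome.fa", "genes.gtf", "lncrna.fa", "knockdown.tsv", "peaks.bed", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_single_exon_config(self):
        cfg = SimConfig(seed=2, n_genes=8, exon_count_range=(1, 1), planted_mode="none")
        _, genes = simulate_genome(cfg)
        assert all(len(g.transcripts[0].exons) == 1 for g in genes)

    def test_genes_do_not_overlap(self):
        _, genes = simulate_genome(SimConfig(seed=3, n_genes=20))
        by_chrom = {}
        for g in genes:
            s, e = g.transcripts[0].span
            by_chrom.setdefault(g.chrom, []).append((s, e))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError, match="larger chromosomes"):
            simulate_genome(SimConfig(seed=1, n_genes=10, n_chroms=1, chrom_length=5000))


class TestPlanting:
    def test_zero_mutation_co_plant_is_exact_revcomp(self):
        cfg = SimConfig(seed=11, planted_mode="co", planted_mutation_rate=0.0,
                        n_genes=10, n_true_targets=3)
        genome, genes = simulate_genome(cfg)
        lnc, truth = plant_lncrna(genome, genes, cfg)
        by_id = {g.promoters[0][0]: g for g in genes}
        for pid in truth.true_target_ids:
            info = truth.planted[pid]
            q0, q1 = info["query_interval"]
            t0, t1 = info["target_interval"]
            gene = by_id[pid]
            nascent = build_cotx_target(gene, pid, genome, 1000).sequence
            assert lnc[q0:q1] == revcomp(nascent[t0:t1])

    def test_co_plant_absent_from_mature_transcript(self):
        cfg = SimConfig(seed=12, planted_mode="co", planted_mutation_rate=0.0,
                        n_genes=10, n_true_targets=3)
        genome, genes = simulate_genome(cfg)
        lnc, truth = plant_lncrna(genome, genes, cfg)
        by_id = {g.promoters[0][0]: g for g in genes}
        for pid in truth.true_target_ids:
            q0, q1 = truth.planted[pid]["query_interval"]
            mature = build_posttx_target(by_id[pid], pid, genome).sequence
            run = longest_complementary_run(lnc[q0:q1], mature)
            assert run < cfg.planted_match_len // 2

    def test_post_plant_broken_in_nascent_window(self):
        cfg = SimConfig(seed=13, planted_mode="post", planted_mutation_rate=0.0,
                        n_genes=10, n_true_targets=3)
        genome, genes = simulate_genome(cfg)
        lnc, truth = plant_lncrna(genome, genes, cfg)
        by_id = {g.promoters[0][0]: g for g in genes}
        for pid in truth.true_target_ids:
            q0, q1 = truth.planted[pid]["query_interval"]
            gene = by_id[pid]
            mature = build_posttx_target(gene, pid, genome).sequence
            nascent = build_cotx_target(gene, pid, genome, 1000).sequence
            assert longest_complementary_run(lnc[q0:q1], mature) == q1 - q0
            assert longest_complementary_run(lnc[q0:q1], nascent) < cfg.planted_match_len

    def test_none_mode_has_no_long_complement_to_any_target(self):
        cfg = SimConfig(seed=14, planted_mode="none", n_genes=8)
        genome, genes = simulate_genome(cfg)
        lnc, truth = plant_lncrna(genome, genes, cfg)
        assert truth.true_target_ids == []
        for gene in genes[:4]:
            pid = gene.promoters[0][0]
            nascent = build_cotx_target(gene, pid, genome, 1000).sequence
            assert longest_complementary_run(lnc, nascent) < 16

    def test_co_mode_without_introns_rejected(self):
        cfg = SimConfig(seed=15, planted_mode="co", n_genes=8, n_true_targets=3,
                        exon_count_range=(1, 1))
        genome, genes = simulate_genome(cfg)
        with pytest.raises(ValueError, match="intron"):
            plant_lncrna(genome, genes, cfg)


class TestKnockdown:
    def test_true_targets_mostly_flagged(self):
        cfg = SimConfig(seed=21, planted_mode="co", n_genes=60, n_true_targets=20,
                        effect_log2fc_mean=-2.0, null_log2fc_sd=0.2)
        genome, genes = simulate_genome(cfg)
        _, truth = plant_lncrna(genome, genes, cfg)
        kd = simulate_knockdown(genes, truth, cfg)
        flagged = sum(kd.rows[p][1] for p in truth.true_target_ids)
        assert flagged >= 0.95 * len(truth.true_target_ids)
        down = sum(kd.rows[p][0] < 0 for p in truth.true_target_ids)
        assert down == len(truth.true_target_ids)

    def test_null_flag_rate_near_alpha(self):
        # no effect at all: flag rate must sit at the nominal alpha
        cfg = SimConfig(seed=22, planted_mode="none", n_genes=400, n_chroms=4,
                        deg_alpha=0.05)
        genome, genes = simulate_genome(cfg)
        _, truth = plant_lncrna(genome, genes, cfg)
        kd = simulate_knockdown(genes, truth, cfg)
        rate = np.mean([flag for _, flag in kd.rows.values()])
        # binomial 99% interval around 0.05 at n=400
        assert 0.022 <= rate <= 0.081


class TestContacts:
    def test_fully_planted_peaks_near_true_tss(self):
        cfg = SimConfig(seed=31, planted_mode="co", n_genes=12, n_true_targets=5,
                        peak_true_frac=1.0, n_background_peaks=0)
        genome, genes = simulate_genome(cfg)
        _, truth = plant_lncrna(genome, genes, cfg)
        peaks = simulate_contacts(genes, truth, cfg, genome.chrom_sizes)
        assert len(peaks) == 5
        tss = {pid: (g.chrom, t) for g in genes for pid, t in g.promoters}
        true_pos = [tss[p] for p in truth.true_target_ids]
        for chrom, start, end in peaks.intervals:
            center = (start + end) / 2
            near = min(
                abs(center - t) for c, t in true_pos if c == chrom
            )
            assert near <= cfg.peak_window + cfg.peak_width / 2

    def test_no_planted_peaks_when_frac_zero(self):
        cfg = SimConfig(seed=32, planted_mode="co", n_genes=12, n_true_targets=5,
                        peak_true_frac=0.0, n_background_peaks=7)
        genome, genes = simulate_genome(cfg)
        _, truth = plant_lncrna(genome, genes, cfg)
        peaks = simulate_contacts(genes, truth, cfg, genome.chrom_sizes)
        assert len(peaks) == 7
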