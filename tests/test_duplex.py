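import math
from collections import Counter

import numpy as np
import pytest

from lncmode import (
    DuplexParams,
    best_hit_bruteforce,
    calibrate_null,
    dinucleotide_shuffle,
    duplex_energy,
    extend_seed,
    find_seed_matches,
    hit_pvalue,
    predict_interactions,
    revcomp,
)
from lncmode.duplex import (
    DEFAULT_SCORES,
    DUPLEX_INITIATION,
    _WC_STACK,
    _batch_extend,
    best_pair_score,
)

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestSeeds:
    def test_full_length_complement_single_seed(self):
        assert find_seed_matches("AAAAAAAA", "TTTTTTTT", 8) == [(0, 0)]

    def test_planted_complement_gives_run_of_seeds(self, rng):
        target = rand_seq(rng, 60)
        query = rand_seq(rng, 20) + revcomp(target[5:25]) + rand_seq(rng, 20)
        matches = find_seed_matches(query, target, 8)
        for q_pos, t_pos in matches:
            assert query[q_pos : q_pos + 8] == revcomp(target[t_pos : t_pos + 8])
        planted = [m for m in matches if 20 <= m[0] <= 32]
        assert len(planted) >= 13

    def test_too_short_sequences_give_empty(self):
        assert find_seed_matches("ACG", "CGT", 8) == []

    def test_word_len_below_four_rejected(self):
        with pytest.raises(ValueError):
            find_seed_matches("ACGTACGT", "ACGTACGT", 3)


class TestExtension:
    def test_perfect_complement_recovered_exactly(self, rng):
        core = rand_seq(rng, 30)
        query = rand_seq(rng, 25) + core + rand_seq(rng, 25)
        target = rand_seq(rng, 20) + revcomp(core) + rand_seq(rng, 20)
        score, q_iv, t_iv = best_hit_bruteforce(query, target)
        seeds = find_seed_matches(query, target, 6)
        hits = [extend_seed(query, target, s, 6, xdrop=300) for s in seeds]
        best = max(hits, key=lambda h: h.align_score)
        assert best.align_score == score
        assert best.align_score >= 60  # at least the planted 30-mer
        assert best.query_interval[0] <= 25 and best.query_interval[1] >= 55

    def test_xdrop_zero_stops_at_first_mismatch(self):
        # seed word flanked by mismatches on both sides
        core = "ACGTAC"
        query = "AAA" + core + "AAA"
        target = "CCC" + revcomp(core) + "CCC"
        hit = extend_seed(query, target, (3, 3), 6, xdrop=0)
        assert hit.query_interval == (3, 9)
        assert hit.target_interval == (3, 9)
        assert hit.align_score == 12

    def test_batch_extension_matches_scalar(self, rng):
        for _ in range(40):
            q = rand_seq(rng, int(rng.integers(20, 200)))
            t = rand_seq(rng, int(rng.integers(20, 200)))
            w = int(rng.choice([4, 5, 6]))
            xd = int(rng.choice([0, 6, 12, 40]))
            seeds = find_seed_matches(q, t, w)
            if not seeds:
                continue
            align, energy, q_iv, t_iv = _batch_extend(q, t, seeds, w, DEFAULT_SCORES, xd)
            for i, s in enumerate(seeds):
                ref = extend_seed(q, t, s, w, DEFAULT_SCORES, xd)
                assert ref.align_score == align[i]
                assert ref.energy == pytest.approx(float(energy[i]))
                assert tuple(ref.query_interval) == tuple(map(int, q_iv[i]))
                assert tuple(ref.target_interval) == tuple(map(int, t_iv[i]))


class TestEnergy:
    def test_gc_duplex_more_stable_than_at(self):
        gc = duplex_energy("G" * 10, "C" * 10, ["WC"] * 10)
        at = duplex_energy("A" * 10, "T" * 10, ["WC"] * 10)
        assert gc < at < 0

    def test_single_pair_is_initiation_only(self):
        assert duplex_energy("G", "C", ["WC"]) == DUPLEX_INITIATION

    def test_energy_monotone_in_duplex_length(self):
        energies = [
            duplex_energy("GA" * k, "TC" * k, ["WC"] * (2 * k)) for k in range(1, 8)
        ]
        assert all(b < a for a, b in zip(energies, energies[1:]))

    def test_all_stack_terms_stabilising(self):
        assert all(v < 0 for v in _WC_STACK.values())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            duplex_energy("AC", "GT", ["WC"])


class TestShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(20):
            seq = rand_seq(rng, int(rng.integers(10, 300)))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


@pytest.fixture(scope="module")
def calibrated():
    rng = np.random.default_rng(31)
    query = rand_seq(rng, 500)
    targets = {f"t{i}": rand_seq(rng, 400) for i in range(10)}
    cal = calibrate_null(query, targets, n_null=60, seed=3)
    return query, targets, cal


class TestCalibration:
    def test_parameters_positive_and_deterministic(self, calibrated):
        query, targets, cal = calibrated
        for lam, K in cal.params.values():
            assert lam > 0 and K > 0
        cal2 = calibrate_null(query, targets, n_null=60, seed=3)
        assert cal.params == cal2.params

    def test_pvalue_monotone_in_score_and_search_space(self, calibrated):
        _, _, cal = calibrated
        ps = [hit_pvalue(s, 500, 400, cal) for s in (5, 10, 20, 40)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        assert hit_pvalue(15, 500, 800, cal) > hit_pvalue(15, 500, 400, cal)

    def test_nonpositive_score_gives_p_one(self, calibrated):
        _, _, cal = calibrated
        assert hit_pvalue(0.0, 500, 400, cal) == 1.0
        assert hit_pvalue(-3.0, 500, 400, cal) == 1.0

    def test_small_n_null_rejected(self):
        with pytest.raises(ValueError):
            calibrate_null("ACGT" * 50, {"t": "ACGT" * 50}, n_null=10, seed=0)


class TestPredict:
    def test_planted_target_ranks_first(self, rng):
        query = rand_seq(rng, 600)
        targets = {f"t{i:02d}": rand_seq(rng, 400) for i in range(12)}
        planted = targets["t05"]
        window = planted[100:140]
        query = query[:200] + revcomp(window) + query[240:]
        hits = predict_interactions(query, targets, seed=4)
        assert hits[0].target_id == "t05"
        assert hits[0].p_adj < 0.01

    def test_whole_target_complement_is_extreme(self, rng):
        target = rand_seq(rng, 500)
        query = revcomp(target)
        targets = {"hot": target}
        for i in range(9):
            targets[f"bg{i}"] = rand_seq(rng, 500)
        hits = predict_interactions(query, targets, seed=5)
        best = hits[0]
        assert best.target_id == "hot"
        covered = best.target_interval[1] - best.target_interval[0]
        assert covered >= 0.9 * 500
        assert best.p_adj == min(h.p_adj for h in hits)

    def test_empty_target_set(self):
        assert predict_interactions("ACGT" * 100, {}) == []

    def test_determinism(self, rng):
        query = rand_seq(rng, 400)
        targets = {f"t{i}": rand_seq(rng, 300) for i in range(8)}
        a = predict_interactions(query, targets, seed=9)
        b = predict_interactions(query, targets, seed=9)
        assert [(h.target_id, h.score, h.p_raw, h.p_adj) for h in a] == [
            (h.target_id, h.score, h.p_raw, h.p_adj) for h in b
        ]


class TestOracle:
    def test_symmetry_of_best_alignment_score(self, rng):
        for _ in range(20):
            q = rand_seq(rng, 50)
            t = rand_seq(rng, 50)
            s1, _, _ = best_hit_bruteforce(q, t)
            s2, _, _ = best_hit_bruteforce(t, q)
            assert s1 == s2

    def test_seed_extend_equals_bruteforce_on_planted_pairs(self, rng):
        params = DuplexParams(word_len=6, xdrop=200)
        for _ in range(50):
            m = int(rng.integers(40, 61))
            q = rand_seq(rng, m)
            t = rand_seq(rng, m)
            core_len = 20
            qs = int(rng.integers(0, m - core_len))
            ts = int(rng.integers(0, m - core_len))
            core = q[qs : qs + core_len]
            t = t[:ts] + revcomp(core) + t[ts + core_len :]
            score, q_iv, t_iv = best_hit_bruteforce(q, t)
            seeds = find_seed_matches(q, t, 6)
            hits = [extend_seed(q, t, s, 6, xdrop=200) for s in seeds]
            assert hits, "planted core must produce a seed"
            best = max(h.align_score for h in hits)
            assert best == score
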