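"""PSSM scanning and adaptive-cutoff enrichment.

The scanning oracle is a naive per-window, per-column summation over both
strands; enrichment minimality and direction symmetry are asserted
directly from the definitions.
"""

import numpy as np
import pytest

from tfcoreg.motif import (
    BASES,
    PositionWeightMatrix,
    calibrate_by_label_permutation,
    matched_random_regions,
    optimal_cutoff_binomial,
    pssm_score,
    reverse_complement,
    scan_best,
)
from tfcoreg.simulate import MotifSimSpec, simulate_sequences
from tfcoreg.types import GenomicInterval


def naive_score(pwm, window):
    total = 0.0
    for j, base in enumerate(window.upper()):
        if base in BASES:
            i = BASES.index(base)
            total += np.log2(pwm.probs[i, j] / pwm.background[i])
    return total


def naive_scan_best(pwm, seq):
    best = -np.inf
    L = pwm.width
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(len(s) - L + 1):
            sc = naive_score(pwm, s[off:off + L])
            best = max(best, sc)
    return best


def random_pwm(rng, L):
    return PositionWeightMatrix("rnd", rng.integers(0, 20, size=(4, L)) + 1)


class TestPwm:
    def test_consensus_maximal_and_positive(self, ebox_pwm):
        score = pssm_score(ebox_pwm, "CATGTG")
        assert score > 0
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = "".join(rng.choice(list(BASES), 6))
            assert pssm_score(ebox_pwm, w) <= score

    def test_all_ambiguous_window_scores_zero(self, ebox_pwm):
        assert pssm_score(ebox_pwm, "NNNNNN") == 0.0

    def test_matches_naive_summation(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, 8)
            w = "".join(rng.choice(list(BASES), 8))
            assert pssm_score(pwm, w) == pytest.approx(naive_score(pwm, w), abs=1e-12)

    def test_length_mismatch_rejected(self, ebox_pwm):
        with pytest.raises(ValueError):
            pssm_score(ebox_pwm, "CATG")

    def test_jaspar_parse(self):
        text = ">MA0001.1 TEST\nA [ 1 2 0 3 ]\nC [0 1 2 1]\nG [ 3 0 1 0 ]\nT [0 1 1 0]\n"
        pwm = PositionWeightMatrix.from_jaspar(text)
        assert pwm.motif_id == "MA0001.1"
        assert pwm.width == 4
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            PositionWeightMatrix("x", np.ones((4, 5)), background=np.array([1, 0, 0, 0.0]))


class TestScanBest:
    def test_forward_hit_location(self, ebox_pwm):
        score, off, strand = scan_best(ebox_pwm, "GGCATGTGAA")
        assert (off, strand) == (2, "+")
        assert score == pytest.approx(pssm_score(ebox_pwm, "CATGTG"))

    def test_consensus_at_origin(self, ebox_pwm):
        score, off, strand = scan_best(ebox_pwm, "CATGTG")
        assert (off, strand) == (0, "+")

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, 6)
            seq = "".join(rng.choice(list(BASES), 40))
            s1 = scan_best(pwm, seq)[0]
            s2 = scan_best(pwm, reverse_complement(seq))[0]
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_matches_brute_force_on_100_random_cases(self, rng):
        for _ in range(100):
            pwm = random_pwm(rng, int(rng.integers(4, 10)))
            seq = "".join(rng.choice(list(BASES), int(rng.integers(pwm.width, 60))))
            assert scan_best(pwm, seq)[0] == pytest.approx(
                naive_scan_best(pwm, seq), abs=1e-9)

    def test_too_short_sequence_rejected(self, ebox_pwm):
        with pytest.raises(ValueError):
            scan_best(ebox_pwm, "CAT")


class TestOptimalCutoff:
    def test_planted_signal_over_represented(self, ebox_pwm):
        spec = MotifSimSpec(pwm=ebox_pwm, plant_rate_fg=0.4, plant_rate_bg=0.05,
                            n_fg=300, n_bg=300, seed=5)
        fg, bg, _ = simulate_sequences(spec)
        fs = np.array([scan_best(ebox_pwm, s)[0] for s in fg.values()])
        bs = np.array([scan_best(ebox_pwm, s)[0] for s in bg.values()])
        res = optimal_cutoff_binomial(fs, bs, "ebox")
        assert res.direction == "over"
        assert res.p_binomial < 1e-6

    def test_reported_p_is_minimal_over_candidates(self, rng):
        from scipy import stats

        fs = rng.normal(1, 1, 80)
        bs = rng.normal(0, 1, 120)
        res = optimal_cutoff_binomial(fs, bs)
        F, B = fs.size, bs.size
        for c in res.candidate_cutoffs:
            f = int((fs >= c).sum())
            b = int((bs >= c).sum())
            rate = np.clip(b / B, 1 / (2 * B), 1 - 1 / (2 * B))
            p_c = min(stats.binom.sf(f - 1, F, rate), stats.binom.cdf(f, F, rate))
            assert res.p_binomial <= p_c + 1e-15

    def test_direction_flips_when_sets_swapped(self, rng):
        fs = rng.normal(1, 1, 100)
        bs = rng.normal(0, 1, 100)
        assert optimal_cutoff_binomial(fs, bs).direction == "over"
        assert optimal_cutoff_binomial(bs, fs).direction == "under"

    def test_perfect_separation_closed_form(self):
        fs = np.full(10, 5.0)
        bs = np.full(20, 1.0)
        res = optimal_cutoff_binomial(fs, bs)
        # f=F=10, b=0 at cutoff 5; rate clamps to 1/(2B)=1/40
        assert res.fg_hits == 10 and res.bg_hits == 0
        assert res.p_binomial == pytest.approx((1 / 40) ** 10, rel=1e-9)

    def test_identical_scores_degenerate(self):
        with pytest.warns(UserWarning):
            res = optimal_cutoff_binomial(np.ones(5), np.ones(5))
        assert res.p_binomial == 1.0

    def test_no_signal_flagged_by_calibration(self, rng):
        scores = rng.normal(size=200)
        p = calibrate_by_label_permutation(scores, scores.copy(), n_perm=100, seed=1)
        assert p > 0.05


class TestCalibration:
    def test_strong_signal_hits_permutation_floor(self, ebox_pwm):
        spec = MotifSimSpec(pwm=ebox_pwm, seed=5)
        fg, bg, _ = simulate_sequences(spec)
        fs = np.array([scan_best(ebox_pwm, s)[0] for s in fg.values()])
        bs = np.array([scan_best(ebox_pwm, s)[0] for s in bg.values()])
        p = calibrate_by_label_permutation(fs, bs, n_perm=100, seed=0)
        assert p <= 2 / 101

    def test_formula_floor(self, rng):
        # even an unbeatable observed statistic cannot go below 1/(n_perm+1)
        fs = rng.normal(10, 0.1, 50)
        bs = rng.normal(-10, 0.1, 50)
        p = calibrate_by_label_permutation(fs, bs, n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            calibrate_by_label_permutation(rng.normal(size=10),
                                           rng.normal(size=10), n_perm=50)


class TestMatchedRandomRegions:
    GENOME = [("chr1", 50_000), ("chr2", 30_000)]

    def test_count_and_length_multiset_preserved(self, rng):
        regions = [GenomicInterval("chrZ", 0, int(L))
                   for L in rng.integers(50, 400, size=10)]
        out = matched_random_regions(regions, self.GENOME, seed=3)
        assert len(out) == 10
        assert sorted(iv.length for iv in out) == sorted(iv.length for iv in regions)

    def test_exclusion_respected_with_814_regions(self):
        # the historical foreground size: 814 open-chromatin regions
        regions = [GenomicInterval("chrZ", 0, 100) for _ in range(814)]
        exclude = [GenomicInterval("chr1", 0, 25_000)]
        genome = [("chr1", 50_000), ("chr2", 100_000), ("chr3", 100_000)]
        out = matched_random_regions(regions, genome, seed=7, exclude=exclude)
        assert len(out) == 814
        assert all(not iv.overlaps(e) for iv in out for e in exclude)

    def test_single_slot_deterministic(self):
        regions = [GenomicInterval("chrZ", 0, 100)]
        genome = [("chr1", 300)]
        exclude = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        out = matched_random_regions(regions, genome, seed=11, exclude=exclude)
        assert out[0].start == 100 and out[0].end == 200

    def test_capacity_error(self):
        regions = [GenomicInterval("chrZ", 0, 1000)]
        with pytest.raises(ValueError):
            matched_random_regions(regions, [("chr1", 500)], seed=0)
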