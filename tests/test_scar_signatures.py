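import numpy as np
import pytest

from hrdscape.reference_io import ASCNSegment
from hrdscape.scar_signatures import (
    ScarParams,
    ScarScores,
    count_loh,
    count_lst,
    count_tai,
    score_sample,
    smooth_segments,
)

from .conftest import random_mini_profile
from .oracles import oracle_loh, oracle_lst, oracle_tai

MB = 1_000_000


def seg(chrom, start, end, nmaj, nmin, sample="S1"):
    return ASCNSegment(sample, chrom, start, end, nmaj, nmin)


def diploid(genome, sample="S1"):
    return [
        seg(c, 1, length, 1, 1, sample) for c, length in genome.chromosomes
    ]


class TestLOH:
    def test_heterozygous_diploid_has_none(self, toy_genome):
        assert count_loh(diploid(toy_genome), toy_genome) == 0

    def test_interstitial_20mb_loh_counts(self, toy_genome):
        profile = [
            seg("chr1", 1, 10 * MB - 1, 1, 1),
            seg("chr1", 10 * MB, 30 * MB, 1, 0),
            seg("chr1", 30 * MB + 1, 100 * MB, 1, 1),
        ]
        assert count_loh(profile, toy_genome) == 1

    def test_whole_chromosome_loh_excluded(self, toy_genome):
        profile = [seg("chr2", 1, 100 * MB, 2, 0)]
        assert count_loh(profile, toy_genome) == 0

    def test_length_at_threshold_excluded(self, toy_genome):
        profile = [
            seg("chr1", 1, 10 * MB - 1, 1, 1),
            seg("chr1", 10 * MB, 25 * MB - 1, 1, 0),  # exactly 15 Mb
            seg("chr1", 25 * MB, 100 * MB, 1, 1),
        ]
        assert count_loh(profile, toy_genome) == 0

    def test_homozygous_deletion_breaks_run(self, toy_genome):
        # two 10 Mb LOH pieces separated by a (0,0) segment: neither passes
        profile = [
            seg("chr1", 1, 20 * MB, 1, 1),
            seg("chr1", 20 * MB + 1, 30 * MB, 1, 0),
            seg("chr1", 30 * MB + 1, 32 * MB, 0, 0),
            seg("chr1", 32 * MB + 1, 42 * MB, 1, 0),
            seg("chr1", 42 * MB + 1, 100 * MB, 1, 1),
        ]
        assert count_loh(profile, toy_genome) == 0


class TestSmoothing:
    def test_profile_without_short_segments_is_fixpoint(self, toy_genome):
        profile = [
            seg("chr1", 1, 50 * MB, 1, 1),
            seg("chr1", 50 * MB + 1, 100 * MB, 2, 1),
        ]
        assert smooth_segments(profile, 3 * MB) == profile

    def test_short_segment_between_identical_neighbors_merges(self):
        profile = [
            seg("chr1", 1, 12 * MB, 1, 1),
            seg("chr1", 12 * MB + 1, 14 * MB, 2, 1),
            seg("chr1", 14 * MB + 1, 26 * MB, 1, 1),
        ]
        assert smooth_segments(profile, 3 * MB) == [
            seg("chr1", 1, 26 * MB, 1, 1)
        ]

    def test_short_segment_between_different_neighbors_splits_at_midpoint(self):
        profile = [
            seg("chr1", 1, 12 * MB, 1, 1),
            seg("chr1", 12 * MB + 1, 14 * MB, 2, 1),
            seg("chr1", 14 * MB + 1, 26 * MB, 2, 2),
        ]
        assert smooth_segments(profile, 3 * MB) == [
            seg("chr1", 1, 13 * MB, 1, 1),
            seg("chr1", 13 * MB + 1, 26 * MB, 2, 2),
        ]

    def test_covered_span_conserved(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            profile = random_mini_profile(rng)
            before = sum(s.length for s in profile)
            after = smooth_segments(profile, 3)
            assert sum(s.length for s in after) == before


class TestLST:
    def test_single_segment_per_arm_has_no_breaks(self, toy_genome):
        assert count_lst(diploid(toy_genome), toy_genome) == 0

    def test_p_arm_break_between_large_segments(self, toy_genome):
        profile = [
            seg("chr1", 1, 20 * MB, 1, 1),
            seg("chr1", 20 * MB + 1, 45 * MB, 2, 1),
        ]
        assert count_lst(profile, toy_genome) == 1

    def test_small_second_segment_does_not_count(self, toy_genome):
        profile = [
            seg("chr1", 1, 20 * MB, 1, 1),
            seg("chr1", 20 * MB + 1, 28 * MB, 2, 1),  # 8 Mb < 10 Mb
        ]
        assert count_lst(profile, toy_genome) == 0

    def test_break_across_centromere_midpoint_not_counted(self, toy_genome):
        # transition at 50 Mb sits exactly on the arm boundary
        profile = [
            seg("chr1", 1, 50 * MB, 1, 1),
            seg("chr1", 50 * MB + 1, 100 * MB, 2, 1),
        ]
        assert count_lst(profile, toy_genome) == 0


class TestTAI:
    def test_balanced_profile_has_none(self, toy_genome):
        assert count_tai(diploid(toy_genome), toy_genome) == 0

    def test_telomeric_imbalance_counts(self, toy_genome):
        profile = [
            seg("chr1", 1, 25 * MB, 2, 1),
            seg("chr1", 25 * MB + 1, 100 * MB, 1, 1),
        ]
        assert count_tai(profile, toy_genome) == 1

    def test_interstitial_centromere_crossing_excluded(self, toy_genome):
        profile = [
            seg("chr1", 1, 40 * MB - 1, 1, 1),
            seg("chr1", 40 * MB, 60 * MB, 2, 1),
            seg("chr1", 60 * MB + 1, 100 * MB, 1, 1),
        ]
        assert count_tai(profile, toy_genome) == 0

    def test_whole_chromosome_imbalance_excluded(self, toy_genome):
        assert count_tai([seg("chr3", 1, 100 * MB, 2, 1)], toy_genome) == 0


class TestScoreSample:
    def test_hrd_is_sum_of_scars(self, toy_genome):
        profile = diploid(toy_genome)
        scores = score_sample(profile, toy_genome)
        assert scores == ScarScores("S1", 0, 0, 0, 0)

    def test_scar_scores_reject_inconsistent_sum(self):
        with pytest.raises(ValueError, match="hrd"):
            ScarScores("S1", 2, 3, 1, 7)

    def test_row_order_does_not_matter(self, mini_genome, mini_params):
        rng = np.random.default_rng(17)
        for _ in range(20):
            profile = random_mini_profile(rng)
            if not profile:
                continue
            shuffled = [profile[i] for i in rng.permutation(len(profile))]
            assert score_sample(profile, mini_genome, mini_params) == \
                score_sample(shuffled, mini_genome, mini_params)


class TestOracleEquivalence:
    """Fast scorers vs literal per-base re-implementations of each rule."""

    def test_random_profiles_match_brute_force(self, mini_genome, mini_params):
        rng = np.random.default_rng(101)
        for i in range(300):
            profile = random_mini_profile(rng)
            if not profile:
                continue
            assert count_loh(profile, mini_genome, mini_params) == \
                oracle_loh(profile, mini_genome, mini_params), i
            assert count_tai(profile, mini_genome, mini_params) == \
                oracle_tai(profile, mini_genome, mini_params), i
            assert count_lst(profile, mini_genome, mini_params) == \
                oracle_lst(profile, mini_genome, mini_params), i

    def test_raising_thresholds_never_raises_counts(self, mini_genome):
        rng = np.random.default_rng(55)
        for _ in range(50):
            profile = random_mini_profile(rng)
            if not profile:
                continue
            base = ScarParams(loh_min_len=10, lst_min_segment=8,
                              lst_smooth_len=2)
            stricter = ScarParams(loh_min_len=20, lst_min_segment=12,
                                  lst_smooth_len=2)
            assert count_loh(profile, mini_genome, stricter) <= \
                count_loh(profile, mini_genome, base)
            assert count_lst(profile, mini_genome, stricter) <= \
                count_lst(profile, mini_genome, base)
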