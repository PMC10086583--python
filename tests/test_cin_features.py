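import numpy as np
import pytest

from hrdscape.cin_features import (
    CINParams,
    aneuploidy_events,
    chromosome_cin,
    cin_profile,
    classify_segments,
    cytoband_cin,
    fraction_genome_altered,
    hrr_cin_score,
    merge_call_runs,
)
from hrdscape.reference_io import ASCNSegment, GeneLocus, L2RSegment

MB = 1_000_000


def l2r(chrom, start, end, value, sample="S1"):
    return L2RSegment(sample, chrom, start, end, value)


def ascn(chrom, start, end, nmaj, nmin, sample="S1"):
    return ASCNSegment(sample, chrom, start, end, nmaj, nmin)


class TestClassification:
    @pytest.mark.parametrize(
        "value,call,high",
        [
            (0.1, "neutral", "none"),  # boundary is strict
            (0.11, "gain", "none"),
            (-0.1, "neutral", "none"),
            (-0.3, "loss", "none"),
            (0.8, "gain", "amplification"),
            (-0.8, "loss", "deep_deletion"),
            (0.0, "neutral", "none"),
        ],
    )
    def test_l2r_thresholds(self, value, call, high):
        [c] = classify_segments([l2r("chr1", 1, MB, value)])
        assert (c.call, c.high_level) == (call, high)

    @pytest.mark.parametrize(
        "total,call", [((1, 1), "neutral"), ((2, 1), "gain"), ((1, 0), "loss")]
    )
    def test_ascn_total_copy_number(self, total, call):
        [c] = classify_segments([ascn("chr1", 1, MB, *total)])
        assert c.call == call

    def test_mixed_segment_types_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            classify_segments([l2r("chr1", 1, MB, 0.5),
                               ascn("chr1", MB + 1, 2 * MB, 2, 1)])


class TestChromosomeCIN:
    def test_neutral_profile_all_zero(self, toy_genome):
        segs = classify_segments(
            [l2r(c, 1, l, 0.0) for c, l in toy_genome.chromosomes]
        )
        counts = chromosome_cin(segs, toy_genome)
        assert (counts[["gains", "losses", "total"]].to_numpy() == 0).all()

    def test_segment_counts_per_chromosome(self, toy_genome):
        segs = classify_segments([
            l2r("chr1", 1, 10 * MB, 0.5),
            l2r("chr1", 30 * MB, 40 * MB, 0.5),
            l2r("chr1", 60 * MB, 80 * MB, -0.5),
        ])
        row = chromosome_cin(segs, toy_genome).set_index("chrom").loc["chr1"]
        assert (row.gains, row.losses, row.total) == (2, 1, 3)

    def test_merged_runs_collapse_abutting_same_call(self, toy_genome):
        segs = classify_segments([
            l2r("chr1", 1, 10 * MB, 0.5),
            l2r("chr1", 10 * MB + 1, 20 * MB, 0.4),
        ])
        merged = chromosome_cin(segs, toy_genome, merge_runs=True)
        raw = chromosome_cin(segs, toy_genome, merge_runs=False)
        assert merged.set_index("chrom").loc["chr1", "gains"] == 1
        assert raw.set_index("chrom").loc["chr1", "gains"] == 2


class TestFGA:
    def test_single_30mb_gain_is_tenth_of_toy_genome(self, toy_genome):
        segs = classify_segments([l2r("chr1", 1, 30 * MB, 0.5)])
        fga_gain, fga_loss, fga_total, _ = fraction_genome_altered(
            segs, toy_genome
        )
        assert fga_gain == pytest.approx(0.1)
        assert fga_loss == 0.0
        assert fga_total == pytest.approx(0.1)

    def test_whole_chromosome_loss(self, toy_genome):
        segs = classify_segments([l2r("chr1", 1, 100 * MB, -0.5)])
        _, fga_loss, _, per_chrom = fraction_genome_altered(segs, toy_genome)
        assert fga_loss == pytest.approx(1 / 3)
        assert per_chrom.set_index("chrom").loc["chr1", "frac_loss"] == 1.0

    def test_gain_plus_loss_fractions_sum(self, toy_genome):
        rng = np.random.default_rng(3)
        segs = classify_segments([
            l2r("chr1", 1, 20 * MB, 0.5),
            l2r("chr1", 30 * MB, 50 * MB, -0.5),
            l2r("chr2", 1, 10 * MB, rng.uniform(-1, 1)),
        ])
        g, l, t, _ = fraction_genome_altered(segs, toy_genome)
        assert t == pytest.approx(g + l)


class TestAneuploidy:
    @pytest.mark.parametrize("span,flagged", [(95, True), (80, False)])
    def test_gained_fraction_threshold(self, toy_genome, span, flagged):
        segs = classify_segments([l2r("chr1", 1, span * MB, 0.5)])
        count, flags = aneuploidy_events(segs, toy_genome)
        assert count == int(flagged)
        assert flags.set_index("chrom").loc["chr1", "aneuploid"] == flagged

    def test_half_gained_half_lost_not_flagged(self, toy_genome):
        segs = classify_segments([
            l2r("chr1", 1, 50 * MB, 0.5),
            l2r("chr1", 50 * MB + 1, 100 * MB, -0.5),
        ])
        count, _ = aneuploidy_events(segs, toy_genome)
        assert count == 0


class TestCytobandCIN:
    def test_neutral_profile_zero_everywhere(self, toy_genome):
        segs = classify_segments([l2r("chr1", 1, 100 * MB, 0.0)])
        bands = cytoband_cin(segs, toy_genome)
        assert (bands["total"] == 0).all()

    def test_gain_spanning_two_bands_counts_in_both(self, toy_genome):
        segs = classify_segments([l2r("chr1", 20 * MB, 30 * MB, 0.5)])
        bands = cytoband_cin(segs, toy_genome).set_index(["chrom", "band"])
        assert bands.loc[("chr1", "p2"), "gains"] == 1
        assert bands.loc[("chr1", "p1"), "gains"] == 1

    def test_gain_ending_on_band_boundary_stays_in_one_band(self, toy_genome):
        segs = classify_segments([l2r("chr1", 1, 25 * MB, 0.5)])
        bands = cytoband_cin(segs, toy_genome).set_index(["chrom", "band"])
        assert bands.loc[("chr1", "p2"), "gains"] == 1
        assert bands.loc[("chr1", "p1"), "gains"] == 0

    def test_counts_match_per_base_oracle(self, mini_genome):
        from .conftest import random_mini_profile
        from .oracles import oracle_interval_hits

        rng = np.random.default_rng(31)
        for _ in range(20):
            segs = classify_segments(random_mini_profile(rng))
            bands = cytoband_cin(segs, mini_genome)
            intervals = [
                (r.chrom, r.start, r.end) for r in bands.itertuples()
            ]
            expected = oracle_interval_hits(segs, intervals)
            assert list(zip(bands["gains"], bands["losses"])) == expected


class TestHRRCIN:
    def test_neutral_profile_scores_zero(self, toy_genome):
        from hrdscape.reference_io import hrr_gene_catalog

        catalog = hrr_gene_catalog(toy_genome)
        segs = classify_segments([l2r("chr1", 1, 100 * MB, 0.0)])
        assert hrr_cin_score(segs, catalog) == 0

    def test_lost_region_counts_each_covered_gene_once(self, toy_genome):
        from hrdscape.reference_io import hrr_gene_catalog

        catalog = hrr_gene_catalog(toy_genome)  # 4 genes on chr1
        segs = classify_segments([l2r("chr1", 1, 100 * MB, -0.5)])
        assert hrr_cin_score(segs, catalog) == 4

    def test_gene_hit_by_gain_and_loss_contributes_two(self):
        catalog = [GeneLocus("G1", "chr1", 10 * MB, 11 * MB)]
        segs = classify_segments([
            l2r("chr1", 1, 10 * MB + MB // 2, 0.5),
            l2r("chr1", 10 * MB + MB // 2 + 1, 12 * MB, -0.5),
        ])
        assert hrr_cin_score(segs, catalog) == 2

    def test_score_bounded_by_twice_catalog(self, mini_genome):
        from .conftest import random_mini_profile

        catalog = [
            GeneLocus(f"G{i}", "chr1", 10 * i + 1, 10 * i + 5)
            for i in range(5)
        ]
        rng = np.random.default_rng(8)
        for _ in range(20):
            segs = classify_segments(random_mini_profile(rng))
            assert 0 <= hrr_cin_score(segs, catalog) <= 10


class TestProfile:
    def test_full_profile_summary(self, toy_genome):
        from hrdscape.reference_io import hrr_gene_catalog

        segs = [
            l2r("chr1", 1, 95 * MB, 0.5),
            l2r("chr2", 1, 40 * MB, -0.5),
        ]
        prof = cin_profile(
            segs, toy_genome, catalog=hrr_gene_catalog(toy_genome)
        )
        assert prof.sample == "S1"
        assert prof.aneuploidy_count == 1
        assert prof.fga_total == pytest.approx(135 / 300)
        assert prof.hrr_cin > 0
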