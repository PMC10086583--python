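import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdscape.reference_io import (
    ASCNSegment,
    GenomeBuild,
    hrr_gene_catalog,
    load_genome_build,
    read_ascn_segments,
    read_maf_minimal,
    write_ascn_segments,
)


class TestGenomeBuild:
    def test_toy_build_layout(self, toy_genome):
        assert toy_genome.chrom_names == ("chr1", "chr2", "chr3")
        assert all(l == 100_000_000 for _, l in toy_genome.chromosomes)
        assert toy_genome.centromere("chr1") == (45_000_000, 55_000_000)

    def test_hg38_build_covers_autosomes_and_x(self, hg38_genome):
        assert len(hg38_genome.chromosomes) == 23
        assert "chrY" not in hg38_genome.chrom_names
        assert hg38_genome.chrom_length("chr1") == 248_956_422

    def test_overlapping_cytobands_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            GenomeBuild(
                "bad",
                (("chr1", 100),),
                {"chr1": (40, 60)},
                {"chr1": (("p", 1, 60), ("q", 50, 100))},
            )

    def test_centromere_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="centromere"):
            GenomeBuild(
                "bad",
                (("chr1", 100),),
                {"chr1": (90, 120)},
                {"chr1": (("p", 1, 100),)},
            )

    def test_ucsc_cytoband_file_parsed(self, tmp_path):
        path = tmp_path / "cytoBand.txt"
        rows = [
            ("chr1", 0, 40, "p11", "gneg"),
            ("chr1", 40, 60, "cen", "acen"),
            ("chr1", 60, 100, "q11", "gneg"),
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        build = load_genome_build(str(path))
        assert build.chrom_length("chr1") == 100
        assert build.centromere("chr1") == (41, 60)
        assert len(build.cytobands["chr1"]) == 3

    def test_unknown_build_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            load_genome_build("hg17")


class TestHRRCatalog:
    def test_hg38_catalog_has_70_genes(self, hg38_genome):
        catalog = hrr_gene_catalog(hg38_genome)
        assert len(catalog) == 70
        symbols = {g.symbol for g in catalog}
        assert {"BRCA1", "BRCA2", "RAD51", "FANCA"} <= symbols

    def test_toy_catalog_has_10_loci(self, toy_genome):
        assert len(hrr_gene_catalog(toy_genome)) == 10


class TestASCNReader:
    def test_valid_file_round_trips(self, tmp_path):
        path = tmp_path / "ascn.tsv"
        segs = [
            ASCNSegment("S1", "chr1", 1, 50, 1, 1),
            ASCNSegment("S1", "chr1", 51, 100, 2, 0),
        ]
        write_ascn_segments(segs, path)
        assert read_ascn_segments(path) == segs

    @pytest.mark.parametrize(
        "row,err",
        [
            (("S1", "chr1", 10, 5, 1, 1), "start > end"),
            (("S1", "chr1", 1, 10, 1, 2), "n_minor > n_major"),
            (("S1", "chr1", -3, 10, 1, 1), "coordinate"),
        ],
    )
    def test_invariant_violations_rejected(self, tmp_path, row, err):
        path = tmp_path / "bad.tsv"
        pd.DataFrame(
            [row],
            columns=["sample", "chrom", "start", "end", "n_major", "n_minor"],
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match=err):
            read_ascn_segments(path)

    def test_overlapping_segments_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame(
            [("S1", "chr1", 1, 60, 1, 1), ("S1", "chr1", 50, 100, 2, 1)],
            columns=["sample", "chrom", "start", "end", "n_major", "n_minor"],
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="overlap"):
            read_ascn_segments(path)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        pd.DataFrame(
            columns=["sample", "chrom", "start", "end", "n_major", "n_minor"]
        ).to_csv(path, sep="\t", index=False)
        assert read_ascn_segments(path) == []

    def test_chry_dropped_and_chr_prefix_added(self, tmp_path):
        path = tmp_path / "ascn.tsv"
        pd.DataFrame(
            [("S1", "1", 1, 10, 1, 1), ("S1", "chrY", 1, 10, 1, 0)],
            columns=["sample", "chrom", "start", "end", "n_major", "n_minor"],
        ).to_csv(path, sep="\t", index=False)
        segs = read_ascn_segments(path)
        assert [s.chrom for s in segs] == ["chr1"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_round_trip_identity(self, tmp_path_factory, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        from .conftest import random_mini_profile

        segs = random_mini_profile(rng)
        path = tmp_path_factory.mktemp("rt") / "segs.tsv"
        write_ascn_segments(segs, path)
        assert read_ascn_segments(path) == sorted(
            segs, key=lambda s: (s.sample, s.chrom, s.start)
        )


class TestMAFReader:
    def _write(self, tmp_path):
        path = tmp_path / "variants.maf"
        pd.DataFrame(
            [
                ("BRCA1", "S1", "Missense_Mutation", "PASS"),
                ("BRCA2", "S1", "Nonsense_Mutation", "artifact"),
                ("RAD51", "S2", "Splice_Site", "PASS"),
            ],
            columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                     "Variant_Classification", "FILTER"],
        ).to_csv(path, sep="\t", index=False)
        return path

    def test_pass_filter_applied(self, tmp_path):
        variants = read_maf_minimal(self._write(tmp_path), require_pass=True)
        assert len(variants) == 2
        assert all(v.filter_status == "PASS" for v in variants)

    def test_filter_disabled_keeps_all(self, tmp_path):
        assert len(read_maf_minimal(self._write(tmp_path), require_pass=False)) == 3

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.maf"
        pd.DataFrame(
            [("BRCA1", "S1", "PASS")],
            columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "FILTER"],
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="Variant_Classification"):
            read_maf_minimal(path)
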