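"""Gene models: coordinate mapping, region classification, annotation IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_model, random_model, region_oracle, spliced_positions
from posclip.transcriptome import (
    REGIONS,
    classify_position,
    classify_positions,
    genomic_to_transcript,
    load_annotation,
    region_lengths,
    transcript_to_genomic,
    utr_length_stats,
)


class TestCoordinateMapping:
    def test_roundtrip_matches_bruteforce_enumeration(self):
        """Every exonic base maps to its spliced offset and back, on both
        strands, matching a literal spliced-sequence enumeration."""
        rng = np.random.default_rng(1)
        for i in range(60):
            m = random_model(rng, f"g{i}")
            expected = spliced_positions(m)
            for tx, g in enumerate(expected):
                assert genomic_to_transcript(m, g) == tx
                assert transcript_to_genomic(m, tx) == g

    def test_intronic_and_outside_positions_are_none(self):
        m = make_model(50, 150, 50, n_exons=3)
        exonic = set(spliced_positions(m))
        span = range(m.exons[0][0] - 5, m.exons[-1][1] + 5)
        for g in span:
            if g not in exonic:
                assert genomic_to_transcript(m, g) is None

    @pytest.mark.parametrize("strand,genomic,expected", [
        ("+", 1000, 0),      # first base of a single exon
        ("-", 0, 99),        # minus strand: genomic 0 is the 3' end
    ])
    def test_strand_conventions(self, strand, genomic, expected):
        if strand == "+":
            m = make_model(10, 80, 10, strand="+", start=1000)
        else:
            m = make_model(10, 80, 10, strand="-", start=0)
        assert genomic_to_transcript(m, genomic) == expected

    def test_two_exon_spliced_offset(self):
        """Exons [0,100) and [200,300): genomic 250 is spliced offset 150."""
        from posclip.transcriptome import TranscriptModel
        m = TranscriptModel("g", "t", "chr1", "+", ((0, 100), (200, 300)), 50, 150)
        assert genomic_to_transcript(m, 250) == 150

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        m = random_model(rng)
        g = np.array(spliced_positions(m))
        tx = genomic_to_transcript(m, g)
        assert np.array_equal(tx, np.arange(m.length))


class TestRegionClassification:
    def test_matches_interval_oracle_including_edge_geometries(self):
        """Labels agree with a materialized-interval oracle and partition
        the transcript, including short-5'UTR and short-CDS models."""
        rng = np.random.default_rng(3)
        geometries = [random_model(rng, f"g{i}") for i in range(30)]
        geometries += [
            make_model(10, 300, 400),     # 5'UTR shorter than the window
            make_model(200, 60, 400),     # CDS shorter than 100: windows overlap
            make_model(5, 40, 8),         # everything short
            make_model(200, 3, 400),      # minimal CDS
        ]
        for m in geometries:
            got = [REGIONS[c] for c in classify_positions(m, np.arange(m.length))]
            assert got == region_oracle(m)
            lens = region_lengths(m)
            assert lens.sum() == m.length
            assert np.array_equal(
                lens, np.bincount(classify_positions(m, np.arange(m.length)),
                                  minlength=5))

    @pytest.mark.parametrize("pos,label", [
        (100, "five_prime_utr"), (160, "start"), (300, "cds"),
        (470, "stop"), (600, "three_prime_utr"),
    ])
    def test_reference_model_labels(self, pos, label):
        m = make_model(200, 300, 400)
        assert classify_position(m, pos) == label

    def test_reference_model_region_lengths(self):
        assert list(region_lengths(make_model(200, 300, 400))) == \
            [150, 100, 200, 100, 350]

    def test_short_utr5_truncates_start_window(self):
        lens = region_lengths(make_model(10, 300, 540))
        assert lens[0] == 0 and lens[1] == 60

    def test_out_of_range_position_raises(self):
        m = make_model(50, 150, 50)
        with pytest.raises(ValueError):
            classify_position(m, m.length)

    @given(st.integers(0, 500), st.integers(3, 900), st.integers(0, 500),
           st.integers(1, 4), st.integers(1, 4))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_region_lengths_ignore_exon_structure(self, u5, cds, u3, n1, n2):
        """Region lengths depend only on UTR/CDS lengths, never on how the
        transcript is split into exons."""
        u5, u3 = u5 + 1, u3 + 1
        n_max = max(1, min(4, u5 + cds + u3))
        m1 = make_model(u5, cds, u3, n_exons=min(n1, n_max))
        m2 = make_model(u5, cds, u3, n_exons=min(n2, n_max), strand="-")
        assert np.array_equal(region_lengths(m1), region_lengths(m2))


def _gtf_line(chrom, feat, start0, end0, strand, gene, tx):
    return (f"{chrom}\tsrc\t{feat}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";')


class TestLoadAnnotation:
    def _write(self, tmp_path, lines):
        p = tmp_path / "ann.gtf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_longest_coding_transcript_kept(self, tmp_path):
        lines = [
            _gtf_line("chr1", "exon", 0, 900, "+", "g1", "t_short"),
            _gtf_line("chr1", "CDS", 100, 700, "+", "g1", "t_short"),
            _gtf_line("chr1", "exon", 0, 1400, "+", "g1", "t_long"),
            _gtf_line("chr1", "CDS", 100, 700, "+", "g1", "t_long"),
        ]
        models, n_excluded = load_annotation(self._write(tmp_path, lines))
        assert models["g1"].transcript_id == "t_long"
        assert models["g1"].length == 1400
        assert n_excluded == 0

    def test_noncoding_gene_excluded_and_counted(self, tmp_path):
        lines = [
            _gtf_line("chr1", "exon", 0, 500, "+", "g_nc", "t_nc"),
            _gtf_line("chr1", "exon", 1000, 1900, "+", "g_c", "t_c"),
            _gtf_line("chr1", "CDS", 1100, 1500, "+", "g_c", "t_c"),
        ]
        models, n_excluded = load_annotation(self._write(tmp_path, lines))
        assert set(models) == {"g_c"}
        assert n_excluded == 1

    def test_spliced_length_and_cds_in_transcript_coordinates(self, tmp_path):
        lines = [
            _gtf_line("chr1", "exon", 100, 200, "+", "g", "t"),
            _gtf_line("chr1", "exon", 300, 400, "+", "g", "t"),
            _gtf_line("chr1", "CDS", 150, 200, "+", "g", "t"),
            _gtf_line("chr1", "CDS", 300, 350, "+", "g", "t"),
        ]
        models, _ = load_annotation(self._write(tmp_path, lines))
        m = models["g"]
        assert m.length == 200
        assert (m.cds_start_tx, m.cds_end_tx) == (50, 150)

    def test_cds_outside_exons_rejected(self, tmp_path):
        lines = [
            _gtf_line("chr1", "exon", 0, 100, "+", "g", "t"),
            _gtf_line("chr1", "CDS", 150, 250, "+", "g", "t"),
        ]
        models, n_excluded = load_annotation(self._write(tmp_path, lines))
        assert models == {} and n_excluded == 1

    def test_bed12_thick_region_is_cds(self, tmp_path):
        p = tmp_path / "ann.bed"
        # two blocks of 100 nt; thick region spans 150-350 genomic
        p.write_text("chr1\t100\t400\tg|t\t0\t+\t150\t350\t0\t2\t100,100\t0,200\n")
        models, _ = load_annotation(p, dialect="bed12")
        m = models["g"]
        assert m.length == 200
        assert (m.cds_start_tx, m.cds_end_tx) == (50, 150)


class TestUtrLengthStats:
    def test_per_cluster_summaries_and_errors(self, toy_models):
        assign = pd.DataFrame({
            "gene_id": ["gA", "gB", "gC"],
            "label": ["x", "x", "y"],
        })
        out = utr_length_stats(toy_models, assign).set_index("label")
        assert out.loc["x", "utr5_median"] == np.median([200, 10])
        assert out.loc["y", "utr3_median"] == 200
        with pytest.raises(KeyError):
            utr_length_stats(toy_models, pd.DataFrame(
                {"gene_id": ["nope"], "label": ["x"]}))

    def test_empty_assignment_is_empty_summary(self, toy_models):
        out = utr_length_stats(
            toy_models, pd.DataFrame({"gene_id": [], "label": []}))
        assert len(out) == 0
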