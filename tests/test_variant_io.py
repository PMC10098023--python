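"""Interval handling, variant classification, decomposition and file I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipivar as lv
from lipivar.variant_io import MISSING, GenomicInterval


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestIntervals:
    @pytest.mark.parametrize(
        "intervals, flank, expected",
        [
            ([("chr1", 1000, 2000)], 300, [("chr1", 700, 2300)]),
            ([("chr1", 700, 1000), ("chr1", 900, 1200)], 0, [("chr1", 700, 1200)]),
            ([("chr1", 100, 200)], 0, [("chr1", 100, 200)]),
            # adjacent (book-ended) intervals merge
            ([("1", 1, 10), ("1", 11, 20)], 0, [("1", 1, 20)]),
            # different chromosomes never merge
            ([("1", 1, 10), ("2", 1, 10)], 0, [("1", 1, 10), ("2", 1, 10)]),
            # extension clipped at position 1
            ([("1", 100, 200)], 300, [("1", 1, 500)]),
        ],
    )
    def test_extend_and_merge(self, intervals, flank, expected):
        out = lv.extend_and_merge_intervals([iv(*t) for t in intervals], flank)
        assert [(o.chrom, o.start, o.end) for o in out] == expected

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="chr1:50"):
            iv("chr1", 50, 40)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["1", "2"]),
                st.integers(1, 500),
                st.integers(0, 100),
            ),
            min_size=1,
            max_size=12,
        ),
        st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_merge_properties(self, raw, flank):
        """Merged output is sorted and disjoint; flank-0 is idempotent;
        covered length is monotone non-decreasing in flank."""
        intervals = [iv(c, s, s + d) for c, s, d in raw]
        merged = lv.extend_and_merge_intervals(intervals, flank)
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert b.start > a.end + 1
        assert lv.extend_and_merge_intervals(merged, 0) == merged
        covered = lambda ivs: sum(len(i) for i in ivs)  # noqa: E731
        assert covered(merged) >= covered(
            lv.extend_and_merge_intervals(intervals, 0)
        )


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref, alts, expected",
        [
            ("A", ["G"], ("SNV", "biallelic")),
            ("A", ["AT"], ("indel", "biallelic")),
            ("C", ["T", "G"], ("SNV", "multiallelic")),
            ("AT", ["A"], ("indel", "biallelic")),
            ("C", ["T", "CA"], ("mixed", "multiallelic")),
        ],
    )
    def test_examples(self, ref, alts, expected):
        assert lv.classify_variant(ref, alts) == expected

    @pytest.mark.parametrize("ref, alts", [("A", ["<DEL>"]), ("N", ["A"]), ("A", ["A"])])
    def test_rejects_bad_alleles(self, ref, alts):
        with pytest.raises(ValueError):
            lv.classify_variant(ref, alts)


class TestDecompose:
    def test_multiallelic_het_both_alts(self):
        site = lv.VariantSite("1", 10, "C", ("T", "G"))
        children = lv.decompose_multiallelic(site, [(1, 2)])
        assert [c.alts for c, _ in children] == [("T",), ("G",)]
        assert [int(codes[0]) for _, codes in children] == [1, 1]

    def test_biallelic_hom_alt(self):
        site = lv.VariantSite("1", 10, "C", ("T",))
        (_, codes), = lv.decompose_multiallelic(site, [(1, 1)])
        assert int(codes[0]) == 2

    def test_missing_propagates_to_all_children(self):
        site = lv.VariantSite("1", 10, "C", ("T", "G"))
        children = lv.decompose_multiallelic(site, [None])
        assert all(int(codes[0]) == MISSING for _, codes in children)

    @given(
        st.lists(
            st.one_of(
                st.none(),
                st.tuples(st.integers(0, 3), st.integers(0, 3)),
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_alt_copy_conservation(self, pairs):
        """Sum of child codes equals total alt copies in the parent."""
        site = lv.VariantSite("1", 10, "A", ("C", "G", "T"))
        children = lv.decompose_multiallelic(site, pairs)
        for i, pair in enumerate(pairs):
            child_codes = [int(codes[i]) for _, codes in children]
            if pair is None:
                assert child_codes == [MISSING] * 3
            else:
                assert sum(child_codes) == sum(1 for a in pair if a > 0)


class TestVcfRoundTrip:
    def test_round_trip_exact(self, tmp_path, small_cohort):
        matrix = small_cohort.matrix
        path = tmp_path / "cohort.vcf"
        lv.write_cohort_vcf(path, matrix)
        _, back = lv.read_cohort_vcf(path)
        order = sorted(
            range(matrix.n_sites),
            key=lambda j: (matrix.sites[j].chrom, matrix.sites[j].pos),
        )
        assert [matrix.sites[j] for j in order] == back.sites
        assert [matrix.sites[j].rsid for j in order] == [s.rsid for s in back.sites]
        assert np.array_equal(matrix.codes[:, order], back.codes)

    def test_panel_subsetting_and_dialect(self, tmp_path):
        """Sites outside the panel are dropped; 'chr' prefixes reconcile."""
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "chr1\t1500\trs10\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\n"
            "chr1\t1600\t.\tC\tT\t.\t.\t.\tGT\t0/0\t./1\n"
            "chr1\t99999\trs11\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\n"
        )
        panel = lv.GenePanel([("G", [GenomicInterval("1", 1000, 2000)])], flank=0)
        sites, matrix = lv.read_cohort_vcf(vcf, panel)
        assert [s.pos for s in sites] == [1500, 1600]
        assert sites[0].rsid == "rs10" and sites[1].rsid is None
        # phasing ignored; half-call ./1 is missing
        assert matrix.codes.tolist() == [[1, 0], [2, MISSING]]

    def test_filter_column_respected(self, tmp_path):
        vcf = tmp_path / "f.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FILTER=<ID=VQSRTrancheSNP,Description="failed">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "1\t200\t.\tC\tT\t.\tVQSRTrancheSNP\t.\tGT\t0/1\n"
        )
        sites, _ = lv.read_cohort_vcf(vcf)
        assert [s.pos for s in sites] == [100]
        sites, _ = lv.read_cohort_vcf(vcf, keep_filtered=True)
        assert [s.pos for s in sites] == [100, 200]

    def test_multiallelic_becomes_two_records(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\trs5\tC\tT,G\t.\t.\t.\tGT\t1/2\n"
        )
        sites, matrix = lv.read_cohort_vcf(vcf)
        assert [s.alts for s in sites] == [("T",), ("G",)]
        assert matrix.codes.tolist() == [[1, 1]]


class TestReferenceFrequencies:
    def test_reads_entries(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "rsid\tpopulation\talt_freq\tn_diploid\n"
            "rs328\tAMR\t0.06340\t347\n"
            "rs328\tALL\t0.09245\t2504\n"
        )
        panel = lv.read_reference_frequencies(path)
        assert panel.freq("AMR", "rs328") == pytest.approx(0.06340)
        assert panel.n_diploid("AMR") == 347

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("rsid\tpopulation\talt_freq\tn_diploid\n")
        with pytest.warns(UserWarning):
            panel = lv.read_reference_frequencies(path)
        assert panel.names == []

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "rsid\tpopulation\talt_freq\tn_diploid\n"
            "rs1\tAMR\t0.1\t347\nrs1\tAMR\t0.2\t347\n"
        )
        with pytest.raises(ValueError, match="rs1"):
            lv.read_reference_frequencies(path)

    def test_out_of_range_frequency_rejected(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text(
            "rsid\tpopulation\talt_freq\tn_diploid\nrs1\tAMR\t1.2\t347\n"
        )
        with pytest.raises(ValueError, match="rs1"):
            lv.read_reference_frequencies(path)


class TestFixtures:
    @pytest.mark.parametrize(
        "name, n_rows", [("table3", 8), ("table5", 18), ("table6", 8)]
    )
    def test_fixture_row_counts(self, name, n_rows):
        assert len(lv.load_paper_fixtures(name)) == n_rows

    def test_unknown_fixture_lists_valid_names(self):
        with pytest.raises(ValueError, match="table5"):
            lv.load_paper_fixtures("table9")

    def test_panel_gene_list(self):
        genes = lv.load_panel_gene_symbols()
        assert len(genes) == 69
        assert "LPL" in genes and "APOB" in genes

    def test_missing_cells_are_nan(self):
        t3 = lv.load_paper_fixtures("table3")
        assert pd.isna(
            t3.loc[t3.rsid == "rs144009925", "freq_1kgp_all"]
        ).all()


class TestPanelReaders:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr1\t999\t2000\tLPL\n")
        panel = lv.read_panel(bed)
        (gene, (interval,)), = panel.genes
        assert gene == "LPL"
        assert (interval.start, interval.end) == (1000, 2000)

    def test_tsv_is_one_based(self, tmp_path):
        tsv = tmp_path / "p.tsv"
        tsv.write_text("gene\tchrom\tstart\tend\nLPL\t8\t19901717\t19967259\n")
        panel = lv.read_panel(tsv, flank=300)
        ext = panel.extended()
        assert (ext[0].start, ext[0].end) == (19901417, 19967559)
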