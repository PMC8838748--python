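"""Data model and file-format round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from poolsweep import io as pio
from poolsweep.model import (
    BASES,
    ORF,
    SampleMeta,
    Treatment,
    VariantSite,
    VariantTable,
)

from conftest import make_samples, table_from_counts


# ---------------------------------------------------------------------------
# model invariants
# ---------------------------------------------------------------------------


class TestModel:
    def test_af_missing_below_min_depth(self):
        samples = make_samples(n_replicates=1, days=(12,))
        t = table_from_counts([[3]], [[7]], samples, min_depth=10)
        assert np.isnan(t.af[0, 0])
        t2 = table_from_counts([[3]], [[10]], samples, min_depth=10)
        assert t2.af[0, 0] == pytest.approx(0.3)

    def test_two_alts_at_one_position_are_distinct_sites(self):
        a = VariantSite("c", 5, "A", "G")
        b = VariantSite("c", 5, "A", "T")
        assert a.key != b.key

    def test_invalid_sites_rejected(self):
        with pytest.raises(ValueError):
            VariantSite("c", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantSite("c", 1, "A", "A")
        with pytest.raises(ValueError):
            VariantSite("c", 1, "N", "G")

    def test_ancestor_needs_no_day_but_evolved_does(self):
        SampleMeta("anc", "A0", Treatment.ANCESTOR)
        with pytest.raises(ValueError):
            SampleMeta("s1", "R1", Treatment.WEAK_DEMOGRAPHY)

    def test_orf_length_and_frame_flag(self):
        orf = ORF("x", ((1, 9), (20, 28)), "+")
        assert orf.length == 18 and orf.frame_ok
        assert not ORF("y", ((1, 10),), "+").frame_ok

    def test_minus_strand_positions_run_backwards(self):
        orf = ORF("x", ((1, 3), (7, 9)), "-")
        assert orf.genomic_positions() == [9, 8, 7, 3, 2, 1]


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------


class TestSampleSheet:
    def write(self, tmp_path, rows):
        path = tmp_path / "sheet.tsv"
        header = "sample_id\treplicate_id\ttreatment\tday\tbatch_id\n"
        path.write_text(header + "".join(r + "\n" for r in rows))
        return str(path)

    def test_full_experiment_sheet(self, tmp_path):
        rows = []
        # six replicates x (5 or 6) time points + ancestors = 35 populations
        days = {r: [12, 26, 40, 50, 64] for r in range(6)}
        days[0].append(58)
        for r, ds in days.items():
            treat = "weak_demography" if r < 3 else "strong_demography"
            batch = "novaseq" if r < 3 else "nextseq"
            for d in ds:
                rows.append(f"R{r}_d{d}\tR{r}\t{treat}\t{d}\t{batch}")
        for i in range(4):
            rows.append(f"anc{i}\tanc\tancestor\t\tnextseq")
        samples = pio.read_sample_sheet(self.write(tmp_path, rows))
        assert len(samples) == 35
        assert sum(s.is_ancestor for s in samples) == 4

    def test_header_only_gives_empty_list(self, tmp_path):
        assert pio.read_sample_sheet(self.write(tmp_path, [])) == []

    @pytest.mark.parametrize(
        "row",
        [
            "s1\tR1\tweak_demography\tabc\tb1",  # non-integer day
            "s1\tR1\tmedium_demography\t12\tb1",  # unknown treatment
        ],
    )
    def test_bad_rows_rejected(self, tmp_path, row):
        with pytest.raises(ValueError):
            pio.read_sample_sheet(self.write(tmp_path, [row]))

    def test_duplicate_sample_id_rejected(self, tmp_path):
        row = "s1\tR1\tweak_demography\t12\tb1"
        with pytest.raises(ValueError, match="duplicate"):
            pio.read_sample_sheet(self.write(tmp_path, [row, row]))

    def test_sheet_round_trip(self, tmp_path):
        samples = make_samples(n_replicates=3, days=(12, 40, 64))
        path = tmp_path / "out.tsv"
        pio.write_sample_sheet(samples, str(path))
        assert pio.read_sample_sheet(str(path)) == samples


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="ref obs">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="alt obs">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tR1_d12\tR1_d64
"""


class TestVcf:
    def _read(self, tmp_path, records, **kw):
        path = tmp_path / "in.vcf"
        path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
        samples = make_samples(n_replicates=1, days=(12, 64))
        return pio.read_variant_table(str(path), samples, **kw)

    def test_qual_threshold_is_inclusive(self, tmp_path):
        recs = [
            "chr1\t100\t.\tA\tG\t19.9\t.\t.\tRO:AO\t90:10\t80:20",
            "chr1\t200\t.\tA\tG\t20.0\t.\t.\tRO:AO\t90:10\t80:20",
        ]
        t = self._read(tmp_path, recs)
        assert [s.pos for s in t.sites] == [200]

    def test_low_coverage_frequency_is_missing(self, tmp_path):
        recs = ["chr1\t100\t.\tA\tG\t100\t.\t.\tRO:AO\t4:3\t500:500"]
        t = self._read(tmp_path, recs)
        assert np.isnan(t.af[0, 0]) and t.af[0, 1] == pytest.approx(0.5)
        # counts kept even where the frequency is undefined
        assert t.alt_counts[0, 0] == 3

    def test_multiallelic_decomposed_with_residual_to_ref(self, tmp_path):
        recs = ["chr1\t100\t.\tA\tG,T\t100\t.\t.\tRO:AO\t90:6,4\t80:15,5"]
        t = self._read(tmp_path, recs)
        assert [(s.pos, s.alt_base) for s in t.sites] == [(100, "G"), (100, "T")]
        # focal alt keeps its own reads; the other alt's reads count as ref
        assert t.alt_counts[0, 0] == 6 and t.ref_counts[0, 0] == 94
        assert t.alt_counts[1, 0] == 4 and t.ref_counts[1, 0] == 96
        assert t.depth[0, 0] == t.depth[1, 0] == 100

    def test_indels_skipped(self, tmp_path):
        recs = [
            "chr1\t100\t.\tA\tAG\t100\t.\t.\tRO:AO\t90:10\t80:20",
            "chr1\t200\t.\tAT\tA\t100\t.\t.\tRO:AO\t90:10\t80:20",
            "chr1\t300\t.\tA\tC\t100\t.\t.\tRO:AO\t90:10\t80:20",
        ]
        t = self._read(tmp_path, recs)
        assert [s.pos for s in t.sites] == [300]

    def test_ad_format_supported(self, tmp_path):
        path = tmp_path / "ad.vcf"
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="ref obs">\n'
            '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="alt obs">\n',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">\n',
        )
        path.write_text(header + "chr1\t100\t.\tA\tG,T\t50\t.\t.\tAD\t90,6,4\t80,15,5\n")
        samples = make_samples(n_replicates=1, days=(12, 64))
        t = pio.read_variant_table(str(path), samples)
        assert t.alt_counts[0, 1] == 15 and t.ref_counts[0, 1] == 85

    def test_sheet_sample_missing_from_vcf_errors(self, tmp_path):
        path = tmp_path / "in.vcf"
        path.write_text(VCF_HEADER)
        samples = make_samples(n_replicates=2, days=(12, 64))
        with pytest.raises(ValueError, match="not present"):
            pio.read_variant_table(str(path), samples)


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

counts_strategy = hst.integers(min_value=0, max_value=2000)


@given(
    data=hst.data(),
    n_sites=hst.integers(1, 8),
    n_samples=hst.integers(1, 6),
    fmt=hst.sampled_from(["tsv", "vcf"]),
)
def test_round_trip_identity(tmp_path_factory, data, n_sites, n_samples, fmt):
    """Write->read reproduces counts, quals and missingness exactly."""
    tmp = tmp_path_factory.mktemp("rt")
    days = [12 + 10 * j for j in range(n_samples)]
    samples = make_samples(n_replicates=1, days=tuple(days))
    alt = np.array(
        data.draw(
            hst.lists(
                hst.lists(counts_strategy, min_size=n_samples, max_size=n_samples),
                min_size=n_sites,
                max_size=n_sites,
            )
        )
    )
    extra = np.array(
        data.draw(
            hst.lists(
                hst.lists(counts_strategy, min_size=n_samples, max_size=n_samples),
                min_size=n_sites,
                max_size=n_sites,
            )
        )
    )
    quals = data.draw(
        hst.lists(
            hst.floats(20.0, 3000.0, allow_nan=False), min_size=n_sites, max_size=n_sites
        )
    )
    table = table_from_counts(alt, alt + extra, samples, quals=quals)
    path = tmp / f"t.{fmt}"
    pio.write_variant_table(table, str(path), format=fmt)
    back = pio.read_variant_table(str(path), samples)
    assert [s.key for s in back.sites] == [s.key for s in table.sites]
    assert [s.qual for s in back.sites] == pytest.approx(
        [s.qual for s in table.sites]
    )
    np.testing.assert_array_equal(back.ref_counts, table.ref_counts)
    np.testing.assert_array_equal(back.alt_counts, table.alt_counts)
    np.testing.assert_array_equal(
        np.isnan(back.af), np.isnan(table.af)
    )


def test_empty_table_round_trip(tmp_path):
    samples = make_samples(n_replicates=1, days=(12,))
    table = table_from_counts(
        np.zeros((0, 1)), np.zeros((0, 1)), samples
    )
    path = tmp_path / "empty.tsv"
    pio.write_variant_table(table, str(path))
    back = pio.read_variant_table(str(path), samples)
    assert back.n_sites == 0


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


class TestAnnotation:
    def test_tsv_with_explicit_strand(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "name\tstart\tend\tstrand\nA540L\t257089\t260859\t−\n"
        )
        ann = pio.read_annotation(str(path), genome_length=330_611)
        (orf,) = ann.orfs
        assert orf.length == 3771 and orf.strand == "-"

    def test_tsv_strand_inferred_from_name_suffix(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("name\tstart\tend\nA078R\t42007\t42183\n")
        ann = pio.read_annotation(str(path), genome_length=330_611)
        (orf,) = ann.orfs
        assert orf.strand == "+" and orf.length == 177

    def test_two_segment_orf_assembled(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "name\tstart\tend\tstrand\nx001R\t1\t9\t+\nx001R\t20\t28\t+\n"
        )
        ann = pio.read_annotation(str(path), genome_length=50)
        (orf,) = ann.orfs
        assert orf.segments == ((1, 9), (20, 28)) and orf.length == 18

    def test_segment_outside_contig_errors(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("name\tstart\tend\tstrand\nx001R\t5\t40\t+\n")
        with pytest.raises(ValueError, match="outside"):
            pio.read_annotation(str(path), genome_length=30)

    def test_out_of_frame_orf_flagged_not_dropped(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("name\tstart\tend\tstrand\nx001R\t1\t10\t+\n")
        ann = pio.read_annotation(str(path), genome_length=30)
        assert len(ann.orfs) == 1 and not ann.orfs[0].frame_ok

    def test_gff3_cds_grouped_by_parent(self, tmp_path):
        path = tmp_path / "ann.gff3"
        path.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 100\n"
            "chr1\tsrc\tgene\t1\t28\t.\t+\t.\tID=gene1\n"
            "chr1\tsrc\tmRNA\t1\t28\t.\t+\t.\tID=rna1;Parent=gene1\n"
            "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=cds1;Parent=rna1;gene=g1\n"
            "chr1\tsrc\tCDS\t20\t28\t.\t+\t0\tID=cds1;Parent=rna1;gene=g1\n"
            "chr1\tsrc\tCDS\t40\t60\t.\t-\t0\tID=cds2;Parent=rna2;gene=g2\n"
        )
        ann = pio.read_annotation(str(path))
        assert ann.genome_length == 100
        by_name = {o.name: o for o in ann.orfs}
        assert by_name["g1"].segments == ((1, 9), (20, 28))
        assert by_name["g2"].strand == "-" and by_name["g2"].length == 21

    def test_fasta_round_trip(self, tmp_path):
        path = tmp_path / "g.fa"
        pio.write_fasta("toy1", "ATGAAATAA", str(path))
        name, seq = pio.read_fasta(str(path))
        assert name == "toy1" and seq == "ATGAAATAA"
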