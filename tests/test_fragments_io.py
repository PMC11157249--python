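"""Fragment table I/O, UMI-consensus dedup, and size selection."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbbnipt.fragments_io import (
    SPANNING_DEL,
    SPANNING_REF,
    FragmentFormatError,
    FragmentTable,
    PanelSite,
    count_alleles,
    dedup_umi,
    read_fragments,
    size_select,
    write_fragments,
)

from conftest import make_table


class TestPanelSite:
    def test_ref_must_differ_from_alts(self):
        with pytest.raises(ValueError):
            PanelSite("chr11", 5248155, "C", ("C",))

    def test_positive_position_required(self):
        with pytest.raises(ValueError):
            PanelSite("chr11", 0, "C", ("G",))


class TestReadFragments:
    def test_tsv_row_count_preserved(self, tmp_path):
        path = tmp_path / "frags.tsv"
        path.write_text(
            "read_id\tchrom\tpos\tallele\tfrag_len\tumi\n"
            "r1\tchr11\t100\tA\t150\tU1\n"
            "r2\tchr11\t100\tT\t140\tU2\n"
            "r3\tchr11\t200\tG\t160\tU3\n"
        )
        table = read_fragments(path)
        assert len(table) == 3
        assert len(set(zip(table.df["chrom"], table.df["pos"]))) == 2

    def test_tsv_round_trip(self, tmp_path):
        table = make_table([("r1", "chr11", 100, "A", 150, "U1")])
        out = tmp_path / "out.tsv"
        write_fragments(table, out)
        again = read_fragments(out)
        pd.testing.assert_frame_equal(
            table.df[["read_id", "chrom", "pos", "allele", "frag_len", "umi"]],
            again.df[["read_id", "chrom", "pos", "allele", "frag_len", "umi"]],
        )

    def test_malformed_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("not\ta\tfragment\tfile\n")
        with pytest.raises(FragmentFormatError):
            read_fragments(path)

    def test_off_panel_rows_skipped_with_counter(self, tmp_path):
        path = tmp_path / "frags.tsv"
        path.write_text(
            "read_id\tchrom\tpos\tallele\tfrag_len\tumi\n"
            "r1\tchr11\t100\tA\t150\tU1\n"
            "r2\tchr11\t999\tT\t140\tU2\n"
        )
        panel = [PanelSite("chr11", 100, "A", ("T",))]
        table = read_fragments(path, panel=panel)
        assert len(table) == 1
        assert table.n_skipped == 1


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr11\tLN:6000000\n"


class TestSamIngestion:
    def _panel(self):
        return [PanelSite("chr11", 5248155, "C", ("G",))]

    def test_negative_template_length_absolute(self, tmp_path):
        sam = tmp_path / "in.sam"
        sam.write_text(
            SAM_HEADER
            + "r1\t99\tchr11\t5248150\t60\t10M\t=\t5248300\t-160\t"
            + "AAAAACAAAA\tIIIIIIIIII\tRX:Z:ACGT\n"
        )
        table = read_fragments(sam, format="sam_bam", panel=self._panel())
        assert len(table) == 1
        row = table.df.iloc[0]
        assert row["frag_len"] == 160
        assert row["allele"] == "C"  # 6th base covers pos 5248155
        assert row["umi"] == "ACGT"

    def test_read_outside_panel_counted_not_error(self, tmp_path):
        sam = tmp_path / "in.sam"
        sam.write_text(
            SAM_HEADER
            + "r1\t0\tchr11\t100\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        table = read_fragments(sam, format="sam_bam", panel=self._panel())
        assert len(table) == 0
        assert table.n_skipped == 1

    def test_deletion_region_classification(self, tmp_path):
        panel = [PanelSite("chr11", 5246486, "REF", ("DEL619",))]
        sam = tmp_path / "in.sam"
        # one read with a 622 bp deletion over the region, one continuous read
        sam.write_text(
            SAM_HEADER
            + "rdel\t0\tchr11\t5246466\t60\t20M622D20M\t*\t0\t0\t"
            + "A" * 40 + "\t" + "I" * 40 + "\tRX:Z:U1\n"
            + "rref\t0\tchr11\t5246476\t60\t40M\t*\t0\t0\t"
            + "A" * 40 + "\t" + "I" * 40 + "\tRX:Z:U2\n"
        )
        table = read_fragments(sam, format="sam_bam", panel=panel)
        alleles = dict(zip(table.df["read_id"], table.df["allele"]))
        assert alleles == {"rdel": SPANNING_DEL, "rref": SPANNING_REF}


class TestDedup:
    def test_majority_allele_and_longest_length(self):
        table = make_table(
            [
                ("r1", "chr11", 100, "G", 150, "ACGT"),
                ("r2", "chr11", 100, "G", 150, "ACGT"),
                ("r3", "chr11", 100, "T", 162, "ACGT"),
            ]
        )
        out = dedup_umi(table)
        assert len(out) == 1
        assert out.df.iloc[0]["allele"] == "G"
        assert out.df.iloc[0]["frag_len"] == 162
        assert out.deduped

    def test_distinct_umis_not_grouped(self):
        table = make_table(
            [
                ("r1", "chr11", 100, "G", 150, "AAAA"),
                ("r2", "chr11", 100, "G", 150, "CCCC"),
            ]
        )
        assert len(dedup_umi(table)) == 2

    def test_tie_breaks_lexicographic(self):
        table = make_table(
            [
                ("r1", "chr11", 100, "T", 150, "AAAA"),
                ("r2", "chr11", 100, "G", 150, "AAAA"),
            ]
        )
        assert dedup_umi(table).df.iloc[0]["allele"] == "G"

    def test_idempotent(self):
        table = make_table([("r1", "chr11", 100, "G", 150, "AAAA")])
        once = dedup_umi(table)
        twice = dedup_umi(once)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_empty_table_passes_through(self):
        out = dedup_umi(make_table([]))
        assert len(out) == 0 and out.deduped

    def test_consensus_reduces_error_rate_on_simulation(self):
        from hbbnipt.simulator import PlasmaSimConfig, simulate_plasma

        config = PlasmaSimConfig(
            ff_true=0.1, n_genomic_snps=5, depth_mean=200,
            duplication_rate=3.0, error_rate=0.02, seed=11,
        )
        table, truth = simulate_plasma(config)
        raw_err = float(np.mean(table.df["allele"].to_numpy() != truth.molecule_allele))
        out = dedup_umi(table)
        # map consensus rows back to molecule truth via their UMI index
        mol = out.df["umi"].str.lstrip("U").astype(int).to_numpy()
        first_row = {}
        for i, m in enumerate(table.df["umi"].str.lstrip("U").astype(int)):
            first_row.setdefault(m, i)
        true_alleles = truth.molecule_allele[[first_row[m] for m in mol]]
        dedup_err = float(np.mean(out.df["allele"].to_numpy() != true_alleles))
        assert len(out) == config.n_genomic_snps * config.depth_mean
        assert dedup_err < raw_err


class TestSizeSelect:
    def test_identity_when_cutoff_above_all(self):
        table = make_table([("r1", "chr11", 100, "A", 150, "U1")])
        out = size_select(table, 1000)
        assert len(out) == 1 and out.length_cutoff == 1000

    def test_inclusive_boundary(self):
        rows = [("r%d" % L, "chr11", 100, "A", L, "U%d" % L) for L in (120, 140, 160)]
        out = size_select(make_table(rows), 140)
        assert sorted(out.df["frag_len"]) == [120, 140]

    @given(
        a=st.integers(min_value=50, max_value=250),
        b=st.integers(min_value=50, max_value=250),
    )
    @settings(max_examples=30, deadline=None)
    def test_composition_equals_smaller_cutoff(self, a, b):
        rows = [
            ("r%d" % L, "chr11", 100, "A", L, "U%d" % L)
            for L in range(40, 260, 7)
        ]
        table = make_table(rows)
        lo, hi = min(a, b), max(a, b)
        twice = size_select(size_select(table, hi), lo)
        once = size_select(table, lo)
        assert list(twice.df["frag_len"]) == list(once.df["frag_len"])

    def test_enriches_fetal_fragments_in_mixture(self):
        from hbbnipt.simulator import PlasmaSimConfig, simulate_plasma

        config = PlasmaSimConfig(
            ff_true=0.1, n_genomic_snps=10, depth_mean=2000, seed=3
        )
        table, truth = simulate_plasma(config)
        base = truth.fetal_origin.mean()
        keep = table.df["frag_len"].to_numpy() <= 150
        assert truth.fetal_origin[keep].mean() > base


class TestCountAlleles:
    def test_counts_and_depth(self, tiny_counts_table):
        counts = tiny_counts_table.counts_at("chr11", 5248219)
        assert counts == {"G": 6, "T": 4}
        assert tiny_counts_table.depth_at("chr11", 5248219) == 10

    def test_empty_table_zero_counts_with_panel(self):
        panel = [PanelSite("chr11", 100, "A", ("T",))]
        counts = count_alleles(make_table([]), panel=panel)
        assert counts.counts_at("chr11", 100) == {"A": 0, "T": 0}

    def test_totals_match_row_counts_per_site(self):
        rng = np.random.default_rng(5)
        rows = [
            ("r%d" % i, "chr11", int(rng.choice([100, 200, 300])),
             str(rng.choice(list("ACGT"))), 150, "U%d" % i)
            for i in range(200)
        ]
        table = make_table(rows)
        counts = count_alleles(table)
        per_site = table.df.groupby("pos").size()
        for pos, n in per_site.items():
            assert counts.depth_at("chr11", int(pos)) == n

    def test_printed_ratio_recovered_from_fragments(self):
        # 59%/41% at a maternal mutation site, as in the printed "59C/41G"
        rows = [
            ("r%d" % i, "chr11", 5248155, "C" if i < 59 else "G", 150, "U%d" % i)
            for i in range(100)
        ]
        counts = count_alleles(make_table(rows)).counts_at("chr11", 5248155)
        depth = sum(counts.values())
        assert round(100 * counts["C"] / depth) == 59
        assert round(100 * counts["G"] / depth) == 41
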