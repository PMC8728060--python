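"""Reference binning, read counting, and GC-bias correction."""

import numpy as np
import pandas as pd
import pytest

from knncnv.preprocess import (
    correct_gc_bias,
    count_reads_per_bin,
    load_reference_bins,
    read_bin_table,
    reference_bins_from_sequence,
    write_bin_table,
)
from tests.conftest import write_bam, write_fasta


class TestReferenceBins:
    def test_gc_fraction_simple(self):
        # bins "ACGTA" and "CGTAC": 2/5 and 3/5 G+C
        _, bins = reference_bins_from_sequence("ACGTACGTAC", "c", bin_size=5)
        assert len(bins) == 2
        assert bins["gc"].tolist() == [0.4, 0.6]
        assert bins["valid"].all()

    def test_all_n_bin_invalid(self):
        _, bins = reference_bins_from_sequence("NNNNN" + "GGGGG", "c", bin_size=5)
        assert not bins["valid"].iloc[0]
        assert bins["valid"].iloc[1]
        assert bins["gc"].iloc[1] == 1.0

    def test_gc_matches_per_window_recount(self):
        # independent brute-force recount per window
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), size=100_000, p=[0.3, 0.2, 0.2, 0.25, 0.05]))
        _, bins = reference_bins_from_sequence(seq, "c", bin_size=1000)
        assert len(bins) == 100
        for row in bins.itertuples(index=False):
            window = seq[row.start : row.end]
            n_valid = sum(b in "ACGT" for b in window)
            if n_valid == 0:
                assert not row.valid
            else:
                expected = sum(b in "GC" for b in window) / n_valid
                assert row.gc == pytest.approx(expected, abs=1e-12)

    def test_bins_tile_chromosome(self):
        _, bins = reference_bins_from_sequence("ACGT" * 700, "c", bin_size=1000)
        assert bins["start"].iloc[0] == 0
        assert (bins["start"].iloc[1:].to_numpy() == bins["end"].iloc[:-1].to_numpy()).all()
        assert bins["end"].iloc[-1] == 2800

    def test_missing_chromosome_fatal(self, tmp_path):
        fasta = write_fasta(tmp_path / "ref.fa", {"chr1": "ACGT" * 300})
        with pytest.raises(KeyError, match="chr1"):
            load_reference_bins(fasta, "chrX")

    def test_load_from_fasta(self, tmp_path):
        fasta = write_fasta(tmp_path / "ref.fa", {"chr1": "ACGTACGTAC"})
        track, bins = load_reference_bins(fasta, "chr1", bin_size=5)
        assert track.length == 10
        assert bins["gc"].tolist() == [0.4, 0.6]


class TestReadCounting:
    def test_single_read_coverage(self, tmp_path):
        _, bins = reference_bins_from_sequence("A" * 2000, "chr1", bin_size=1000)
        bam = write_bam(tmp_path / "r.bam", "chr1", 2000, [(100, 100)])
        out = count_reads_per_bin(bam, bins)
        assert out["rd_raw"].iloc[0] == pytest.approx(0.1)
        assert out["rd_raw"].iloc[1] == 0.0

    def test_no_reads_zero_fill(self, tmp_path):
        _, bins = reference_bins_from_sequence("A" * 3000, "chr1", bin_size=1000)
        bam = write_bam(tmp_path / "r.bam", "chr1", 3000, [])
        out = count_reads_per_bin(bam, bins)
        assert (out["rd_raw"] == 0).all()

    def test_matches_per_base_pileup_oracle(self, tmp_path):
        rng = np.random.default_rng(1)
        length = 10_000
        reads = [(int(s), int(l)) for s, l in zip(
            rng.integers(0, length - 150, 500), rng.integers(50, 150, 500)
        )]
        _, bins = reference_bins_from_sequence("A" * length, "chr1", bin_size=1000)
        bam = write_bam(tmp_path / "r.bam", "chr1", length, reads)
        out = count_reads_per_bin(bam, bins)
        # dense per-base pileup computed independently
        depth = np.zeros(length)
        for s, l in reads:
            depth[s : s + l] += 1
        for row in out.itertuples(index=False):
            assert row.rd_raw == pytest.approx(depth[row.start : row.end].mean(), abs=1e-12)

    def test_contig_mismatch_fatal(self, tmp_path):
        _, bins = reference_bins_from_sequence("A" * 2000, "chrZ", bin_size=1000)
        bam = write_bam(tmp_path / "r.bam", "chr1", 2000, [(0, 100)])
        with pytest.raises(KeyError, match="chrZ"):
            count_reads_per_bin(bam, bins)


def _bin_frame(rd, gc, valid=None):
    n = len(rd)
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "gc": gc,
            "rd_raw": rd,
            "rd_corrected": rd,
            "valid": np.ones(n, bool) if valid is None else valid,
        }
    )


class TestGCCorrection:
    def test_single_stratum_identity(self):
        bins = _bin_frame(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 0.5))
        out = correct_gc_bias(bins)
        np.testing.assert_allclose(out["rd_corrected"], bins["rd_raw"])

    def test_two_strata_scaling(self):
        rd = np.array([10.0, 10.0, 20.0, 20.0])
        gc = np.array([0.3, 0.3, 0.6, 0.6])
        out = correct_gc_bias(_bin_frame(rd, gc))
        np.testing.assert_allclose(out["rd_corrected"], [15, 15, 15, 15])

    def test_sinusoidal_bias_slope_shrinks(self):
        rng = np.random.default_rng(2)
        n = 5000
        gc = np.clip(rng.normal(0.45, 0.07, n), 0.2, 0.7)
        bias = 1 + 0.4 * np.sin(2 * np.pi * (gc - 0.2) / 0.5)
        rd = 10 * bias * rng.gamma(50, 1 / 50, n)
        out = correct_gc_bias(_bin_frame(rd, gc))
        slope_before = np.polyfit(gc, rd, 1)[0]
        slope_after = np.polyfit(gc, out["rd_corrected"], 1)[0]
        assert abs(slope_after) <= 0.1 * abs(slope_before)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(3)
        rd = rng.gamma(20, 0.5, 2000)
        gc = np.clip(rng.normal(0.45, 0.05, 2000), 0.2, 0.7)
        out = correct_gc_bias(_bin_frame(rd, gc))
        assert out["rd_corrected"].mean() == pytest.approx(rd.mean(), rel=0.01)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        rd = rng.gamma(20, 0.5, 1000)
        gc = np.clip(rng.normal(0.45, 0.05, 1000), 0.2, 0.7)
        once = correct_gc_bias(_bin_frame(rd, gc))
        once["rd_raw"] = once["rd_corrected"]
        twice = correct_gc_bias(once)
        np.testing.assert_allclose(
            twice["rd_corrected"], once["rd_corrected"], rtol=1e-6
        )

    def test_all_invalid_fatal(self):
        bins = _bin_frame(np.ones(3), np.full(3, 0.5), valid=np.zeros(3, bool))
        with pytest.raises(ValueError, match="invalid"):
            correct_gc_bias(bins)

    def test_zero_signal_fatal(self):
        bins = _bin_frame(np.zeros(3), np.full(3, 0.5))
        with pytest.raises(ValueError, match="signal"):
            correct_gc_bias(bins)


def test_bin_table_round_trip(tmp_path):
    _, bins = reference_bins_from_sequence("ACGTNNNNGGCC" * 100, "c", bin_size=100)
    path = tmp_path / "bins.tsv"
    write_bin_table(bins, path)
    back = read_bin_table(path)
    pd.testing.assert_frame_equal(back, bins, check_dtype=False)
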