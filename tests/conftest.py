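"""Shared fixtures: tiny FASTA/BAM builders and a small simulated profile."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from knncnv import simulate
from knncnv.preprocess import correct_gc_bias


def write_fasta(path, sequences: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return str(path)


def write_bam(path, chrom: str, chrom_length: int, reads: list[tuple[int, int]]) -> str:
    """Write a sorted, indexed BAM of perfect-match reads (start, length)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_length}],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (start, length) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read{i}"
            a.query_sequence = "A" * length
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{length}M"
            a.flag = 0
            bam.write(a)
    pysam.index(path)
    return path


@pytest.fixture(scope="session")
def small_benchmark():
    """A 4-Mb simulated profile with four planted events, GC-corrected."""
    events = [
        simulate.CNVEvent(400_000, 520_000, 0),
        simulate.CNVEvent(1_200_000, 1_330_000, 1),
        simulate.CNVEvent(2_100_000, 2_250_000, 3),
        simulate.CNVEvent(3_000_000, 3_180_000, 4),
    ]
    config = simulate.SimulationConfig(
        purity=0.3,
        coverage=6.0,
        chrom_length=4_000_000,
        events=events,
        seed=11,
    )
    bins, truth = simulate.simulate_rd_profile(config)
    bins = correct_gc_bias(bins)
    return config, bins, truth
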