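"""Binned read-depth profile construction: reference masking, per-bin read
counting from BAM, and GC-bias correction.

The bin table is a pandas DataFrame with one row per fixed-width bin and
columns ``chrom, start, end, gc, rd_raw, rd_corrected, valid``.  Coordinates
are 0-based half-open throughout.  Bins consisting entirely of 'N' bases are
flagged invalid and excluded from every downstream vector; regions of the
genome untouched by reads simply get zero coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1000

BIN_COLUMNS = ["chrom", "start", "end", "gc", "rd_raw", "rd_corrected", "valid"]


@dataclass
class ReferenceTrack:
    """Per-base validity mask and per-bin GC fractions for one chromosome.

    ``valid_mask[i]`` is False where the reference base is 'N' (or any
    non-ACGT ambiguity code).  ``gc`` is G+C count over valid bases per bin,
    NaN for bins with no valid base.
    """

    chrom: str
    length: int
    valid_mask: np.ndarray  # bool, length == sequence length
    gc: np.ndarray  # float per bin

    def __post_init__(self) -> None:
        if len(self.valid_mask) != self.length:
            raise ValueError("validity mask length must equal sequence length")


def _bin_edges(length: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, length)
    return starts, ends


def load_reference_bins(
    fasta_path: str, chrom: str, bin_size: int = DEFAULT_BIN_SIZE
) -> tuple[ReferenceTrack, pd.DataFrame]:
    """Lay out fixed-width bins over one chromosome of a FASTA reference.

    Returns the reference track (base-level validity, per-bin GC) and a
    skeleton bin table with ``rd_raw``/``rd_corrected`` set to 0.  Bins whose
    bases are all 'N' are marked invalid.  The terminal bin may be shorter
    than ``bin_size``; it keeps its true width.
    """
    fa = Fasta(fasta_path, rebuild=False)
    if chrom not in fa:
        raise KeyError(
            f"chromosome {chrom!r} not found in {fasta_path}; "
            f"available: {', '.join(fa.keys())}"
        )
    seq = str(fa[chrom][:]).upper()
    if len(seq) == 0:
        raise ValueError(f"chromosome {chrom!r} has empty sequence")
    return reference_bins_from_sequence(seq, chrom, bin_size)


def reference_bins_from_sequence(
    seq: str, chrom: str, bin_size: int = DEFAULT_BIN_SIZE
) -> tuple[ReferenceTrack, pd.DataFrame]:
    """Same as :func:`load_reference_bins` but from an in-memory sequence."""
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    length = len(arr)
    if length == 0:
        raise ValueError("empty sequence")
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    is_gc = np.isin(arr, [b"G", b"C"])

    starts, ends = _bin_edges(length, bin_size)
    n_bins = len(starts)
    # per-bin sums via cumulative sums over the base-level masks
    cv = np.concatenate([[0], np.cumsum(valid)])
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    n_valid = cv[ends] - cv[starts]
    n_gc = cg[ends] - cg[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(n_valid > 0, n_gc / np.maximum(n_valid, 1), np.nan)

    track = ReferenceTrack(chrom=chrom, length=length, valid_mask=valid, gc=gc)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "gc": gc,
            "rd_raw": np.zeros(n_bins),
            "rd_corrected": np.zeros(n_bins),
            "valid": n_valid > 0,
        }
    )
    return track, bins


def count_reads_per_bin(
    bam_path: str,
    bins: pd.DataFrame,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Fill ``rd_raw`` with the mean per-base read coverage of each bin.

    Unmapped, secondary, supplementary and duplicate-flagged reads are
    excluded; reads below ``min_mapq`` are skipped (default keeps all mapped
    reads).  Bins untouched by any read get 0.  Coverage is accumulated from
    aligned blocks, so spliced/clipped portions do not count.
    """
    chrom = bins["chrom"].iloc[0]
    length = int(bins["end"].iloc[-1])
    bam = pysam.AlignmentFile(bam_path, "rb")
    try:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{bam_path} has no index; run 'samtools index' first"
            )
        if chrom not in bam.references:
            raise KeyError(
                f"contig {chrom!r} absent from {bam_path}; "
                f"BAM contigs: {', '.join(bam.references)}"
            )
        depth = np.zeros(length, dtype=np.int64)
        for read in bam.fetch(chrom):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            for bstart, bend in read.get_blocks():
                s = max(bstart, 0)
                e = min(bend, length)
                if e > s:
                    depth[s] += 1
                    if e < length:
                        depth[e] -= 1
        # difference-array trick: prefix sum yields per-base depth
        depth = np.cumsum(depth)
    finally:
        bam.close()

    out = bins.copy()
    cs = np.concatenate([[0], np.cumsum(depth)])
    starts = out["start"].to_numpy()
    ends = out["end"].to_numpy()
    widths = ends - starts
    out["rd_raw"] = (cs[ends] - cs[starts]) / widths
    out["rd_corrected"] = out["rd_raw"]
    return out


def correct_gc_bias(bins: pd.DataFrame, min_stratum_size: int = 2) -> pd.DataFrame:
    """Remove GC-dependent coverage bias by per-GC-percent mean scaling.

    Each valid bin's raw read depth is scaled by (global mean RD) / (mean RD
    of bins whose GC fraction rounds to the same integer percent).  Strata
    with fewer than ``min_stratum_size`` bins, or zero stratum mean, fall
    back to a factor of 1.  The global mean is preserved up to stratum
    fallback effects.
    """
    valid = bins["valid"].to_numpy()
    if not valid.any():
        raise ValueError("all bins are invalid; nothing to correct")
    rd = bins["rd_raw"].to_numpy(dtype=float)
    if rd[valid].mean() == 0:
        raise ValueError("zero global mean read depth; no signal to correct")

    gc_pct = np.full(len(bins), -1, dtype=int)
    gc_pct[valid] = np.rint(bins["gc"].to_numpy()[valid] * 100).astype(int)

    # strata too small (or empty of signal) fall back to a factor of 1; the
    # scaling target is the mean over correctable bins only, which makes the
    # correction idempotent
    strata = []
    correctable = np.zeros(len(bins), dtype=bool)
    for pct in np.unique(gc_pct[valid]):
        members = (gc_pct == pct) & valid
        stratum_mean = rd[members].mean()
        if int(members.sum()) < min_stratum_size or stratum_mean == 0:
            continue
        strata.append((members, stratum_mean))
        correctable |= members

    corrected = rd.copy()
    if correctable.any():
        global_mean = rd[correctable].mean()
        for members, stratum_mean in strata:
            corrected[members] = rd[members] * (global_mean / stratum_mean)

    out = bins.copy()
    out["rd_corrected"] = np.where(valid, np.maximum(corrected, 0.0), 0.0)
    return out


def write_bin_table(bins: pd.DataFrame, path: str) -> None:
    """Serialize a bin table as TSV with the canonical column order."""
    bins.to_csv(path, sep="\t", index=False, columns=BIN_COLUMNS)


def read_bin_table(path: str) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t")
    missing = set(BIN_COLUMNS) - set(bins.columns)
    if missing:
        raise ValueError(f"bin table {path} missing columns: {sorted(missing)}")
    bins["valid"] = bins["valid"].astype(bool)
    return bins
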