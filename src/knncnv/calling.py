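"""Assembling flagged segments into genomic CNV calls.

Maximal runs of genomically adjacent flagged segments merge into single
calls (merge gap 0 bp by default); each call is typed gain or loss by
comparing its bin-weighted mean read depth to the baseline, the median
corrected read depth of the unflagged segments.  Calls serialize as BED5+
(chrom, start, end, gain|loss, score scaled 0-1000, mean_rd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BED_HEADER = "#chrom\tstart\tend\tname\tscore\tmean_rd"


@dataclass
class CNVCall:
    chrom: str
    start: int
    end: int
    type: str  # "gain" | "loss" | "" before typing
    mean_rd: float
    mean_score: float
    n_segments: int


def merge_flagged_segments(
    segments: pd.DataFrame,
    labels,
    scores: np.ndarray | None = None,
    merge_gap: int = 0,
    groups: np.ndarray | None = None,
) -> list[CNVCall]:
    """Merge runs of flagged segments separated by at most ``merge_gap`` bp.

    Per-call mean RD is the bin-count-weighted mean over member segments;
    mean score is likewise weighted.  Returns calls in coordinate order
    (untyped); an empty flag set yields an empty list.  When ``groups`` is
    given, a run additionally breaks wherever the group value changes
    (used to keep gain-direction and loss-direction segments in separate
    calls).
    """
    flags = np.asarray(getattr(labels, "is_cnv", labels), dtype=bool)
    if len(flags) != len(segments):
        raise ValueError("labels not aligned to segments")
    if scores is None:
        scores = np.zeros(len(segments))
    else:
        scores = np.asarray(getattr(scores, "scores", scores), dtype=float)

    chroms = segments["chrom"].to_numpy()
    starts = segments["start"].to_numpy()
    ends = segments["end"].to_numpy()
    nbins = segments["n_bins"].to_numpy()
    rd = segments["mean_rd"].to_numpy()

    calls: list[CNVCall] = []
    run: list[int] = []

    def close_run() -> None:
        if not run:
            return
        w = nbins[run]
        calls.append(
            CNVCall(
                chrom=str(chroms[run[0]]),
                start=int(starts[run[0]]),
                end=int(ends[run[-1]]),
                type="",
                mean_rd=float(np.average(rd[run], weights=w)),
                mean_score=float(np.average(scores[run], weights=w)),
                n_segments=len(run),
            )
        )
        run.clear()

    for i in np.flatnonzero(flags):
        if run and (
            chroms[i] != chroms[run[-1]]
            or starts[i] - ends[run[-1]] > merge_gap
            or (groups is not None and groups[i] != groups[run[-1]])
        ):
            close_run()
        run.append(int(i))
    close_run()
    return calls


def classify_gain_loss(call: CNVCall, baseline_rd: float) -> CNVCall:
    """Type a call as gain or loss against the diploid baseline read depth.

    RD above baseline means extra copies (gain); below, lost copies (loss).
    Exact equality is typed loss with a warning (an RD exactly at baseline
    should not have been flagged).
    """
    if baseline_rd <= 0:
        raise ValueError("baseline read depth must be positive (no normal segments?)")
    if call.mean_rd == baseline_rd:
        log.warning(
            "call %s:%d-%d mean RD equals baseline; typing as loss",
            call.chrom,
            call.start,
            call.end,
        )
    call.type = "gain" if call.mean_rd > baseline_rd else "loss"
    return call


def baseline_read_depth(segments: pd.DataFrame, labels) -> float:
    """Median corrected RD over unflagged segments, the diploid reference level."""
    flags = np.asarray(getattr(labels, "is_cnv", labels), dtype=bool)
    normal = segments["mean_rd"].to_numpy()[~flags]
    if len(normal) == 0:
        raise ValueError("every segment is flagged; no baseline available")
    return float(np.median(normal))


def call_cnvs(
    segments: pd.DataFrame, labels, scores=None, merge_gap: int = 0
) -> list[CNVCall]:
    """Merge flagged segments direction-aware and type each call gain/loss.

    Adjacent flagged segments whose read depths deviate from the baseline
    in opposite directions stay in separate calls, so an amplification can
    never be fused with a neighboring deletion.
    """
    flags = np.asarray(getattr(labels, "is_cnv", labels), dtype=bool)
    if not flags.any():
        return []
    baseline = baseline_read_depth(segments, labels)
    direction = segments["mean_rd"].to_numpy() > baseline
    calls = merge_flagged_segments(segments, labels, scores, merge_gap, direction)
    return [classify_gain_loss(c, baseline) for c in calls]


def write_calls(calls: list[CNVCall], path: str) -> None:
    """Write calls as BED5+ with a header comment; deterministic byte output.

    The BED score column rescales mean outlier scores to 0-1000 over the
    written calls.
    """
    smax = max((c.mean_score for c in calls), default=0.0)
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for c in calls:
            bed_score = int(round(1000 * c.mean_score / smax)) if smax > 0 else 0
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{bed_score}\t"
                f"{c.mean_rd:.6g}\n"
            )


def read_calls(path: str) -> pd.DataFrame:
    """Read a BED of calls (ours or a truth set) into a DataFrame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
                "name": parts[3] if len(parts) > 3 else "",
            }
            if row["end"] <= row["start"]:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if len(parts) > 4:
                row["score"] = float(parts[4])
            if len(parts) > 5:
                row["mean_rd"] = float(parts[5])
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "mean_rd"])
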