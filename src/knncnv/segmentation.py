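"""Region partitioning and per-region circular binary segmentation (CBS).

The chromosome is cut into fixed 50-kb regions; within each region the
bin-level corrected read depth is segmented by CBS: the circular split
(i, j) maximizing the pooled two-sample t-statistic between the arc and its
complement is accepted when a permutation p-value falls below ``alpha``, and
the procedure recurses on the resulting pieces.  Segments never span region
boundaries.  The result is the column vector R = [r1..rN]' of per-segment
mean read depths consumed by the kNN scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REGION_SIZE = 50_000
DEFAULT_CBS_ALPHA = 0.01
DEFAULT_CBS_PERMUTATIONS = 1000
DEFAULT_CBS_MIN_WIDTH = 2

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_bins", "mean_rd"]


@dataclass
class Region:
    index: int
    chrom: str
    start: int
    end: int
    bin_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def partition_regions(bins: pd.DataFrame, region_size: int = DEFAULT_REGION_SIZE) -> list[Region]:
    """Assign every valid bin to one fixed-width genomic region.

    Regions tile [0, chromosome end); a region left empty by 'N' masking is
    dropped.  Fatal if the region size is smaller than the bin size.
    """
    if len(bins) == 0:
        raise ValueError("empty bin table")
    bin_size = int((bins["end"] - bins["start"]).max())
    if region_size < bin_size:
        raise ValueError(
            f"region size {region_size} smaller than bin size {bin_size}"
        )
    chrom = bins["chrom"].iloc[0]
    chrom_end = int(bins["end"].iloc[-1])
    valid_idx = np.flatnonzero(bins["valid"].to_numpy())
    starts = bins["start"].to_numpy()

    regions: list[Region] = []
    region_of_bin = starts[valid_idx] // region_size
    for ridx in np.unique(region_of_bin):
        members = valid_idx[region_of_bin == ridx]
        rstart = int(ridx) * region_size
        rend = min(rstart + region_size, chrom_end)
        regions.append(
            Region(
                index=int(ridx),
                chrom=chrom,
                start=rstart,
                end=rend,
                bin_indices=members,
            )
        )
    return regions


def _max_arc_tstat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximum |t| over circular arcs of one vector; returns (tmax, i, j)."""
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    q = np.concatenate([[0.0], np.cumsum(x * x)])
    tot, totq = c[-1], q[-1]
    best_t, best_i, best_j = -1.0, 0, n
    for k in range(min_width, n - min_width + 1):
        arcsum = c[k:] - c[:-k]
        arcsq = q[k:] - q[:-k]
        t = _arc_t(arcsum, arcsq, tot, totq, k, n)
        imax = int(np.argmax(t))
        if t[imax] > best_t:
            best_t, best_i, best_j = float(t[imax]), imax, imax + k
    return best_t, best_i, best_j


def _arc_t(arcsum, arcsq, tot, totq, k, n):
    """|t| of arc vs complement, pooled variance; vectorized over arc starts."""
    m1 = arcsum / k
    m2 = (tot - arcsum) / (n - k)
    ss = (arcsq - arcsum * m1) + (totq - arcsq) - (tot - arcsum) * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ss / (n - 2)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / k + 1.0 / (n - k)))
    diff = np.abs(m1 - m2)
    t = np.where(sp2 <= 0, np.where(diff > 0, np.inf, 0.0), t)
    return t


def _perm_max_tstats(x: np.ndarray, n_perm: int, min_width: int, rng: np.random.Generator) -> np.ndarray:
    """Max arc |t| for ``n_perm`` row-wise permutations of x."""
    n = len(x)
    perms = np.tile(x, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    c = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    q = np.concatenate(
        [np.zeros((n_perm, 1)), np.cumsum(perms * perms, axis=1)], axis=1
    )
    tot = c[:, -1:]
    totq = q[:, -1:]
    best = np.zeros(n_perm)
    for k in range(min_width, n - min_width + 1):
        arcsum = c[:, k:] - c[:, :-k]
        arcsq = q[:, k:] - q[:, :-k]
        t = _arc_t(arcsum, arcsq, tot, totq, k, n)
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _split_significant(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    block: int = 100,
) -> tuple[bool, int, int]:
    """Find the best circular split and decide significance by permutation.

    Permutations are drawn in blocks; once the exceedance count reaches
    ``alpha * n_perm`` the final p-value is guaranteed >= alpha, so the scan
    stops early with the identical accept/reject decision.
    """
    n = len(x)
    if n < 2 * min_width:
        return False, 0, n
    tmax, i, j = _max_arc_tstat(x, min_width)
    if tmax <= 0:
        return False, i, j
    threshold = alpha * n_perm
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        stats = _perm_max_tstats(x, b, min_width, rng)
        # strict inequality: permutations that merely tie the observed
        # maximum (e.g. perfect two-level separations) do not count
        exceed += int(np.sum(stats > tmax))
        done += b
        if exceed >= threshold:
            return False, i, j
    return (exceed / n_perm) < alpha, i, j


def cbs_segment_region(
    rd: np.ndarray,
    alpha: float = DEFAULT_CBS_ALPHA,
    n_permutations: int = DEFAULT_CBS_PERMUTATIONS,
    min_width: int = DEFAULT_CBS_MIN_WIDTH,
    seed: int | np.random.Generator = 0,
) -> list[int]:
    """Segment one region's read-depth vector; returns sorted breakpoints.

    Breakpoints are bin offsets strictly inside (0, len(rd)); a constant or
    unsplittable vector yields no breakpoints.  Deterministic for a fixed
    seed.  NaN input is fatal.
    """
    rd = np.asarray(rd, dtype=float)
    if rd.ndim != 1 or len(rd) < 1:
        raise ValueError("rd must be a non-empty 1-D vector")
    if np.isnan(rd).any():
        raise ValueError("NaN in read-depth vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        ok, i, j = _split_significant(
            rd[lo:hi], alpha, n_permutations, min_width, rng
        )
        if not ok:
            return
        cuts = _validate_cuts(rd, lo, hi, lo + i, lo + j, alpha)
        if not cuts:
            return
        breakpoints.extend(cuts)
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(rd))
    return sorted(breakpoints)


def _edge_pvalue(left: np.ndarray, right: np.ndarray) -> float:
    """Two-sided pooled t-test p-value between the pieces flanking a cut."""
    n1, n2 = len(left), len(right)
    df = n1 + n2 - 2
    if df < 1:
        return 1.0
    ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
    sp2 = ss / df
    if sp2 <= 0:
        return 0.0 if left.mean() != right.mean() else 1.0
    t = abs(left.mean() - right.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * float(stats.t.sf(t, df))


def _validate_cuts(
    rd: np.ndarray, lo: int, hi: int, i: int, j: int, alpha: float
) -> list[int]:
    """Re-test each change-point of an accepted circular arc individually.

    A two-cut arc split can owe its significance to one edge alone, leaving
    the other edge a noise artifact; each cut is therefore re-tested
    against its flanking pieces and pruned when not significant on its own.
    If the arc was significant but neither edge survives, the stronger edge
    is kept.
    """
    cuts = [c for c in (i, j) if lo < c < hi]
    if len(cuts) < 2:
        return cuts
    p_left = _edge_pvalue(rd[lo:i], rd[i:j])
    p_right = _edge_pvalue(rd[i:j], rd[j:hi])
    kept = [c for c, p in zip((i, j), (p_left, p_right)) if p < alpha]
    if not kept:
        kept = [i if p_left <= p_right else j]
    return kept


def build_rd_vector(
    bins: pd.DataFrame,
    regions: list[Region],
    breakpoints: dict[int, list[int]] | list[list[int]],
) -> pd.DataFrame:
    """Materialize segments with genomic extents and mean corrected RD.

    ``breakpoints`` maps each region (by list position or region index) to
    the bin offsets returned by :func:`cbs_segment_region`.  The output is
    the segment table in coordinate order; its ``mean_rd`` column is the
    vector R.
    """
    if not regions:
        raise ValueError("empty region list")
    if isinstance(breakpoints, dict):
        bp_of = lambda pos, region: breakpoints.get(region.index, [])
    else:
        bp_of = lambda pos, region: breakpoints[pos]

    rd = bins["rd_corrected"].to_numpy(dtype=float)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()

    rows = []
    member_lists = []
    for pos, region in enumerate(regions):
        idx = region.bin_indices
        cuts = [0] + sorted(bp_of(pos, region)) + [len(idx)]
        for a, b in zip(cuts[:-1], cuts[1:]):
            members = idx[a:b]
            if len(members) == 0:
                continue
            rows.append(
                (
                    region.chrom,
                    int(starts[members[0]]),
                    int(ends[members[-1]]),
                    len(members),
                    float(rd[members].mean()),
                )
            )
            member_lists.append(members)
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    segments["bin_indices"] = member_lists
    return segments


def segment_bins(
    bins: pd.DataFrame,
    region_size: int = DEFAULT_REGION_SIZE,
    alpha: float = DEFAULT_CBS_ALPHA,
    n_permutations: int = DEFAULT_CBS_PERMUTATIONS,
    min_width: int = DEFAULT_CBS_MIN_WIDTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Full segmentation stage: partition into regions, CBS each, build R."""
    regions = partition_regions(bins, region_size)
    rng = np.random.default_rng(seed)
    rd = bins["rd_corrected"].to_numpy(dtype=float)
    bps = [
        cbs_segment_region(
            rd[region.bin_indices], alpha, n_permutations, min_width, rng
        )
        for region in regions
    ]
    return build_rd_vector(bins, regions, bps)


def write_segments(segments: pd.DataFrame, path: str) -> None:
    segments.to_csv(path, sep="\t", index=False, columns=SEGMENT_COLUMNS)


def read_segments(path: str) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"segment table {path} missing columns: {sorted(missing)}")
    return seg
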