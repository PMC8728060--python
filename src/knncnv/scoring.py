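"""kNN outlier scores for genome segments.

Each segment's score is a summary (mean by default; max or median as
variants) of its first k nearest-neighbor Euclidean distances within the
per-segment read-depth vector R.  CNV segments sit far from the bulk of
normal read depths, so their neighbor distances — and scores — are large.
k itself is drawn uniformly at random from the integers of
[floor(0.2 N), floor(0.35 N)], which the average scheme is insensitive to.

Queries go through a KD-tree (exact search); ``brute_force_scores`` is the
O(N^2) reference implementation kept as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KDTree

SCHEMES = ("average", "largest", "median")

K_FRACTION_LOW = 0.2
K_FRACTION_HIGH = 0.35


@dataclass
class ScoreVector:
    """Outlier scores S = [s1..sN]' with the k and scheme that produced them."""

    scores: np.ndarray
    k: int
    scheme: str
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.scores)


def choose_k(n: int, seed: int | np.random.Generator = 0) -> int:
    """Draw k uniformly from the integers of [floor(0.2 n), floor(0.35 n)].

    Clamped to [1, n-1] so a neighbor always exists; reproducible for a
    fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 segments to have neighbors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = int(np.floor(K_FRACTION_LOW * n))
    hi = int(np.floor(K_FRACTION_HIGH * n))
    k = int(rng.integers(lo, hi + 1))
    return min(max(k, 1), n - 1)


def _as_matrix(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise ValueError("NaN in segment read-depth vector")
    if r.ndim == 1:
        r = r[:, None]
    return r


def k_nearest_distances(r: np.ndarray, query_index: int, k: int) -> np.ndarray:
    """The k smallest distances from one segment to all others, ascending.

    Self is excluded; ties are resolved by ascending segment index, and the
    neighborhood is capped at exactly k members.
    """
    x = _as_matrix(r)
    n = len(x)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    d = np.linalg.norm(x - x[query_index], axis=1)
    order = np.argsort(np.delete(d, query_index), kind="stable")
    return np.delete(d, query_index)[order][:k]


def _summarize(dists: np.ndarray, scheme: str) -> np.ndarray:
    """Collapse each row of sorted neighbor distances into one score."""
    if scheme == "average":
        return dists.mean(axis=1)
    if scheme == "largest":
        return dists[:, -1]
    if scheme == "median":
        # lower median for even k
        return dists[:, (dists.shape[1] - 1) // 2]
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def _neighbor_distance_rows(r: np.ndarray, k: int) -> np.ndarray:
    """N x k matrix of each point's first k neighbor distances (KD-tree)."""
    x = _as_matrix(r)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 segments")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    tree = KDTree(x)
    # query k+1 and drop the self column (distance 0 at the front)
    dist, idx = tree.query(x, k=k + 1)
    rows = np.arange(n)
    keep = idx != rows[:, None]
    # exactly one self match per row; when duplicates exist the tree may
    # place self later, so drop the first non-kept ... ensure k columns
    out = np.empty((n, k))
    for i in range(n):
        di = dist[i][keep[i]]
        if len(di) > k:  # self not among the k+1 (all-duplicate corner)
            di = di[:k]
        out[i] = di
    return out


def outlier_scores(
    r: np.ndarray, k: int, scheme: str = "average"
) -> ScoreVector:
    """Score every segment by its first k nearest-neighbor distances.

    ``scheme`` selects the summary: mean (default), largest, or median
    (lower median for even k).  Exact KD-tree search; scores are finite and
    nonnegative.
    """
    rows = _neighbor_distance_rows(r, k)
    return ScoreVector(scores=_summarize(rows, scheme), k=k, scheme=scheme)


def outlier_score_profile(
    r: np.ndarray, ks: list[int] | np.ndarray, scheme: str = "average"
) -> dict[int, np.ndarray]:
    """Scores for many k values from a single KD-tree query at max(ks).

    Equivalent to calling :func:`outlier_scores` per k, but the sorted
    neighbor-distance rows are computed once and summarized per k with
    prefix operations.
    """
    ks = sorted(set(int(k) for k in ks))
    rows = _neighbor_distance_rows(r, max(ks))
    csum = np.cumsum(rows, axis=1)
    out: dict[int, np.ndarray] = {}
    for k in ks:
        if scheme == "average":
            out[k] = csum[:, k - 1] / k
        else:
            out[k] = _summarize(rows[:, :k], scheme)
    return out


def brute_force_scores(
    r: np.ndarray, k: int, scheme: str = "average"
) -> ScoreVector:
    """Reference O(N^2) implementation over the full pairwise distance matrix."""
    x = _as_matrix(r)
    n = len(x)
    if n > 10_000:
        raise ValueError("brute-force oracle limited to N <= 10000")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)  # exclude self
    rows = np.sort(d, axis=1)[:, :k]
    return ScoreVector(scores=_summarize(rows, scheme), k=k, scheme=scheme)
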