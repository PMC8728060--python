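"""Benchmarking CNV calls against a truth set.

Precision, sensitivity and F1 are computed at base-pair granularity:
TP is the number of genomic positions shared between the declared and
confirmed CNV interval unions, PP the positions declared, P the positions
confirmed.  The overlapping density score ODS = m_cnv * m'_cnv ranks
callers when no truth set exists; its two density factors are defined in
prior work and injected through a hook.

``ablation_harness`` sweeps score schemes, k fractions and labeling
strategies over a simulated profile and tabulates F1 per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from knncnv.calling import call_cnvs
from knncnv.labeling import assign_labels, baseline_labelers, fit_vbgmm
from knncnv.scoring import outlier_scores
from knncnv.segmentation import segment_bins

DEFAULT_K_FRACTIONS = tuple(np.arange(1, 21) * 0.05)  # 0.05N .. 1.00N
DEFAULT_TOP_N_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class MetricsReport:
    tp: int
    pp: int
    p: int
    precision: float
    sensitivity: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "pp": self.pp,
            "p": self.p,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
        }


def _validate(intervals: pd.DataFrame | Iterable) -> pd.DataFrame:
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.DataFrame(
            list(intervals), columns=["chrom", "start", "end"]
        )
    for lineno, row in enumerate(intervals.itertuples(index=False), 1):
        if row.end <= row.start:
            raise ValueError(f"interval {lineno}: end <= start ({row})")
    return intervals


def _union(intervals: np.ndarray) -> np.ndarray:
    """Collapse (start, end) rows into a sorted disjoint union."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    merged = [list(intervals[order[0]])]
    for s, e in intervals[order[1:]]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _intersection_length(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap between two disjoint sorted interval sets (sweep)."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            total += e - s
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def overlap_metrics(declared, truth) -> MetricsReport:
    """Base-pair precision/sensitivity/F1 of declared vs confirmed CNVs.

    Self-overlaps within either set are collapsed before counting; the
    intersection is taken per chromosome.  F1 of an empty-vs-empty
    comparison is 0 by convention.
    """
    declared = _validate(declared)
    truth = _validate(truth)
    tp = pp = p = 0
    chroms = set(declared["chrom"]) | set(truth["chrom"])
    for chrom in chroms:
        d = _union(
            declared.loc[declared["chrom"] == chrom, ["start", "end"]].to_numpy()
        )
        t = _union(truth.loc[truth["chrom"] == chrom, ["start", "end"]].to_numpy())
        pp += int((d[:, 1] - d[:, 0]).sum()) if len(d) else 0
        p += int((t[:, 1] - t[:, 0]).sum()) if len(t) else 0
        tp += _intersection_length(d, t)
    precision = tp / pp if pp else 0.0
    sensitivity = tp / p if p else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    return MetricsReport(tp, pp, p, precision, sensitivity, f1)


def ods(
    m_cnv: float | None = None,
    m_prime_cnv: float | None = None,
    declared=None,
    factor_hook: Callable[..., tuple[float, float]] | None = None,
    **hook_kwargs,
) -> float:
    """Overlapping density score: the product of its two density factors.

    The factors' definitions live in the prior work that introduced them;
    supply them directly or through ``factor_hook(declared, **kwargs)``
    returning ``(m_cnv, m_prime_cnv)``.  Negative factors are rejected.
    """
    if factor_hook is not None:
        m_cnv, m_prime_cnv = factor_hook(declared, **hook_kwargs)
    if m_cnv is None or m_prime_cnv is None:
        raise ValueError("provide both factors or a factor_hook")
    if m_cnv < 0 or m_prime_cnv < 0:
        raise ValueError("ODS factors must be nonnegative")
    return float(m_cnv) * float(m_prime_cnv)


def _label_with(strategy: str, scores, seed: int, top_n_frac: float | None):
    if strategy == "vbgmm":
        fit = fit_vbgmm(scores, seed=seed)
        return assign_labels(fit, scores)
    if strategy == "top_n":
        return baseline_labelers(scores, "top_n", frac=top_n_frac or 0.10, seed=seed)
    return baseline_labelers(scores, strategy, seed=seed)


def evaluate_labels(segments: pd.DataFrame, labels, scores, truth) -> MetricsReport:
    """Call CNVs from labeled segments and score them against truth."""
    calls = call_cnvs(segments, labels, scores)
    declared = pd.DataFrame(
        [(c.chrom, c.start, c.end) for c in calls], columns=["chrom", "start", "end"]
    )
    return overlap_metrics(declared, truth[["chrom", "start", "end"]])


def ablation_harness(
    bins: pd.DataFrame,
    truth: pd.DataFrame,
    schemes: Sequence[str] = ("average",),
    labelers: Sequence[str] = ("vbgmm",),
    k_fractions: Sequence[float] = DEFAULT_K_FRACTIONS,
    top_n_fractions: Sequence[float] = DEFAULT_TOP_N_FRACTIONS,
    seeds: Sequence[int] = (0,),
    segments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """F1 over a grid of score schemes x k fractions x labeling strategies.

    The profile is segmented once per seed (pass ``segments`` to reuse an
    existing segmentation across calls); each grid cell rescores and
    relabels.  k per cell is floor(fraction * N), clamped to [1, N-1].
    Returns a tidy table with one row per (scheme, k_fraction, labeler,
    top_n_frac, seed) and the resulting F1.
    """
    if not schemes or not labelers or not len(k_fractions) or not len(seeds):
        raise ValueError("empty ablation grid")
    rows = []
    for seed in seeds:
        seg = segments if segments is not None else segment_bins(bins, seed=seed)
        n = len(seg)
        for scheme in schemes:
            for kf in k_fractions:
                k = min(max(int(np.floor(kf * n)), 1), n - 1)
                sv = outlier_scores(seg["mean_rd"].to_numpy(), k, scheme)
                for labeler in labelers:
                    fracs = top_n_fractions if labeler == "top_n" else (None,)
                    for tf in fracs:
                        labels = _label_with(labeler, sv, seed, tf)
                        report = evaluate_labels(seg, labels, sv, truth)
                        rows.append(
                            (scheme, kf, k, labeler, tf, seed, report.f1)
                        )
    return pd.DataFrame(
        rows,
        columns=["scheme", "k_fraction", "k", "labeler", "top_n_frac", "seed", "f1"],
    )
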