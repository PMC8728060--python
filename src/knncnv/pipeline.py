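"""End-to-end orchestration: preprocess -> segment -> score -> label -> call.

Accepts either a BAM + reference FASTA (the real-data path) or a
precomputed bin-table TSV (which skips alignment handling entirely), runs
the stages with a single seed, and writes a BED of calls, an optional JSON
report with the VBGMM fit summary, and metrics when a truth BED is given.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from knncnv import calling, evaluation, labeling, preprocess, scoring, segmentation
from knncnv.simulate import read_truth_bed

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # inputs: either bam+ref, or bins (TSV path) / bin_table (DataFrame)
    bam: str | None = None
    ref: str | None = None
    bins: str | None = None
    bin_table: pd.DataFrame | None = field(default=None, repr=False)
    chrom: str | None = None
    # stage parameters (defaults are the published constants)
    bin_size: int = preprocess.DEFAULT_BIN_SIZE
    region_size: int = segmentation.DEFAULT_REGION_SIZE
    cbs_alpha: float = segmentation.DEFAULT_CBS_ALPHA
    cbs_permutations: int = segmentation.DEFAULT_CBS_PERMUTATIONS
    cbs_min_width: int = segmentation.DEFAULT_CBS_MIN_WIDTH
    scheme: str = "average"
    k: int | None = None
    labeler: str = "vbgmm"
    top_n_frac: float = 0.10
    merge_gap: int = 0
    seed: int = 0
    # outputs
    out_bed: str | None = None
    truth_bed: str | None = None
    report_json: str | None = None


def _load_bins(config: RunConfig) -> pd.DataFrame:
    if config.bin_table is not None:
        return config.bin_table
    if config.bins is not None:
        return preprocess.read_bin_table(config.bins)
    if config.bam is None or config.ref is None or config.chrom is None:
        raise ValueError("provide either a bin table or BAM + reference + chromosome")
    _, bins = preprocess.load_reference_bins(config.ref, config.chrom, config.bin_size)
    bins = preprocess.count_reads_per_bin(config.bam, bins)
    return preprocess.correct_gc_bias(bins)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a result dict and writes configured outputs.

    Result keys: ``segments`` (DataFrame), ``scores`` (ScoreVector),
    ``labels`` (LabelVector), ``calls`` (list of CNVCall), ``fit`` (VBGMMFit
    or None), ``metrics`` (MetricsReport or None), ``report`` (JSON-ready
    dict).
    """
    bins = _load_bins(config)
    log.info("bins: %d (%d valid)", len(bins), int(bins["valid"].sum()))

    segments = segmentation.segment_bins(
        bins,
        region_size=config.region_size,
        alpha=config.cbs_alpha,
        n_permutations=config.cbs_permutations,
        min_width=config.cbs_min_width,
        seed=config.seed,
    )
    n = len(segments)
    r = segments["mean_rd"].to_numpy()
    k = config.k if config.k is not None else scoring.choose_k(n, config.seed)
    sv = scoring.outlier_scores(r, k, config.scheme)
    sv.seed = config.seed
    log.info("segments: N=%d, k=%d, scheme=%s", n, k, config.scheme)

    fit = None
    if config.labeler == "vbgmm":
        fit = labeling.fit_vbgmm(sv, seed=config.seed)
        labels = labeling.assign_labels(fit, sv)
    else:
        labels = labeling.baseline_labelers(
            sv, config.labeler, frac=config.top_n_frac, seed=config.seed
        )
    calls = calling.call_cnvs(segments, labels, sv, config.merge_gap)
    log.info("flagged %d segments -> %d calls", int(labels.is_cnv.sum()), len(calls))

    metrics = None
    if config.truth_bed is not None:
        truth = read_truth_bed(config.truth_bed)
        declared = pd.DataFrame(
            [(c.chrom, c.start, c.end) for c in calls],
            columns=["chrom", "start", "end"],
        )
        metrics = evaluation.overlap_metrics(declared, truth[["chrom", "start", "end"]])

    report = {
        "n_bins": int(len(bins)),
        "n_segments": int(n),
        "k": int(k),
        "scheme": config.scheme,
        "labeler": config.labeler,
        "seed": int(config.seed),
        "n_flagged": int(labels.is_cnv.sum()),
        "n_calls": len(calls),
    }
    if fit is not None:
        report["vbgmm"] = {
            "alphas": [float(a) for a in fit.alphas],
            "means": [float(m) for m in fit.means],
            "variances": [float(v) for v in fit.variances],
            "elbo_final": float(fit.elbo_trace[-1]),
            "n_iterations": int(fit.n_iter),
            "converged": bool(fit.converged),
            "cnv_component": int(labels.cnv_component),
        }
    if metrics is not None:
        report["metrics"] = metrics.as_dict()

    if config.out_bed is not None:
        calling.write_calls(calls, config.out_bed)
    if config.report_json is not None:
        with open(config.report_json, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return {
        "bins": bins,
        "segments": segments,
        "scores": sv,
        "labels": labels,
        "calls": calls,
        "fit": fit,
        "metrics": metrics,
        "report": report,
    }
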