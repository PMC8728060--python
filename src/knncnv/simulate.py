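"""Synthetic read-depth profiles with planted CNVs.

The generator emulates a tumor-sample whole-genome sequencing experiment at
the bin level: a diploid baseline at a chosen coverage, planted gain/loss
intervals whose read-depth shift is attenuated by tumor purity p via

    E[RD] = coverage * ((1 - p) * 2 + p * c) / 2,

with copy number c = 2 outside events, a smooth GC-dependent coverage bias,
and overdispersed (gamma-Poisson) read counts.  Profiles are reproducible
given a seed, and the planted events are emitted as a BED truth set so
every pipeline stage can be validated without external data.

A lighter generator, :func:`simulate_scores`, produces half-normal score
vectors with a shifted outlier fraction for exercising the VBGMM labeler
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CHROM = "chr21"
DEFAULT_CHROM_LENGTH = 20_000_000
DEFAULT_READ_LENGTH = 100


@dataclass
class CNVEvent:
    start: int
    end: int
    copy_number: int

    @property
    def type(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    ``purity`` and ``coverage`` mirror the (p, cov) grid of tumor purity
    {0.2, 0.3, 0.4} and coverage depth {4x, 6x}; ``dispersion`` is the
    negative-binomial shape for per-bin read counts (larger = closer to
    Poisson); ``gc_amplitude`` scales the smooth GC-coverage bias.
    """

    purity: float = 0.3
    coverage: float = 6.0
    chrom: str = DEFAULT_CHROM
    chrom_length: int = DEFAULT_CHROM_LENGTH
    bin_size: int = 1000
    events: list[CNVEvent] = field(default_factory=list)
    gc_amplitude: float = 0.1
    dispersion: float = 100.0
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        ev = sorted(self.events, key=lambda e: e.start)
        for a, b in zip(ev[:-1], ev[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping events [{a.start},{a.end}) and [{b.start},{b.end})"
                )


def default_events(
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    n_events: int = 14,
    size_range: tuple[int, int] = (10_000, 200_000),
    copy_numbers: tuple[int, ...] = (0, 1, 3, 4),
    min_gap: int = 300_000,
    seed: int | np.random.Generator = 0,
) -> list[CNVEvent]:
    """Plant disjoint gain/loss events of 10-200 kb across the chromosome.

    Event sizes are uniform over ``size_range``; copy numbers cycle through
    ``copy_numbers`` so every state is represented; events keep ``min_gap``
    bp apart so each produces a distinct call.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_events)
    # spread event anchors evenly, then jitter inside each slot
    slot = chrom_length // n_events
    if slot < size_range[1] + min_gap:
        raise ValueError("chromosome too short for the requested events")
    events = []
    for i in range(n_events):
        lo = i * slot + min_gap // 2
        hi = (i + 1) * slot - min_gap // 2 - int(sizes[i])
        start = int(rng.integers(lo, max(hi, lo + 1)))
        events.append(
            CNVEvent(
                start=start,
                end=start + int(sizes[i]),
                copy_number=int(copy_numbers[i % len(copy_numbers)]),
            )
        )
    return events


def _bin_copy_numbers(config: SimulationConfig, starts, ends) -> np.ndarray:
    """Per-bin mean copy number (events may cover bins partially)."""
    c = np.full(len(starts), 2.0)
    for ev in config.events:
        ov = np.minimum(ends, ev.end) - np.maximum(starts, ev.start)
        inside = ov > 0
        widths = ends[inside] - starts[inside]
        frac = ov[inside] / widths
        c[inside] = 2.0 * (1 - frac) + ev.copy_number * frac
    return c


def _smooth_gc_track(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying GC fractions around 0.45, as in mammalian isochores."""
    base = 0.45 + 0.08 * np.sin(2 * np.pi * np.arange(n_bins) / 3000.0)
    noise = rng.normal(0, 1, n_bins)
    kernel = np.ones(51) / 51.0
    smooth = np.convolve(noise, kernel, mode="same")
    return np.clip(base + 0.02 * smooth, 0.25, 0.75)


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth multiplicative coverage bias as a function of GC fraction."""
    return 1.0 + amplitude * np.sin(2 * np.pi * (gc - 0.30) / 0.60)


def simulate_rd_profile(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a binned read-depth profile and its ground-truth events.

    Returns a bin table (same schema as the preprocessing stage, with
    ``rd_corrected`` initialized to the raw values) and a truth table with
    columns ``chrom, start, end, type, copy_number``.
    """
    rng = np.random.default_rng(config.seed)
    n_bins = int(np.ceil(config.chrom_length / config.bin_size))
    starts = np.arange(n_bins, dtype=np.int64) * config.bin_size
    ends = np.minimum(starts + config.bin_size, config.chrom_length)

    c = _bin_copy_numbers(config, starts, ends)
    expected_rd = config.coverage * ((1 - config.purity) * 2 + config.purity * c) / 2.0
    gc = _smooth_gc_track(n_bins, rng)
    mean_rd = expected_rd * gc_bias_factor(gc, config.gc_amplitude)

    # gamma-Poisson (negative binomial) read counts per bin
    widths = ends - starts
    mean_reads = mean_rd * widths / config.read_length
    theta = config.dispersion
    lam = rng.gamma(shape=theta, scale=np.maximum(mean_reads, 1e-12) / theta)
    reads = rng.poisson(lam)
    rd_raw = reads * config.read_length / widths

    bins = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "gc": gc,
            "rd_raw": rd_raw.astype(float),
            "rd_corrected": rd_raw.astype(float),
            "valid": True,
        }
    )
    truth = pd.DataFrame(
        [
            (config.chrom, ev.start, ev.end, ev.type, ev.copy_number)
            for ev in sorted(config.events, key=lambda e: e.start)
        ],
        columns=["chrom", "start", "end", "type", "copy_number"],
    )
    return bins, truth


def simulate_scores(
    n_normal: int,
    n_outliers: int,
    shift: float,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-normal score vector with a shifted outlier fraction.

    Returns (scores, labels) with ``labels`` True for planted outliers;
    normals come first.  All scores are nonnegative.
    """
    if n_normal < 2:
        raise ValueError("need at least 2 normal scores")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    normal = np.abs(rng.normal(0, sigma, n_normal))
    outliers = np.abs(rng.normal(0, sigma, n_outliers)) + shift
    scores = np.concatenate([normal, outliers])
    labels = np.concatenate(
        [np.zeros(n_normal, dtype=bool), np.ones(n_outliers, dtype=bool)]
    )
    return scores, labels


def write_truth_bed(truth: pd.DataFrame, path: str) -> None:
    """Ground-truth events as BED5 (name = gain|loss, score = copy number)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttype\tcopy_number\n")
        for row in truth.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.type}\t{row.copy_number}\n"
            )


def read_truth_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "type": parts[3] if len(parts) > 3 else "",
                    "copy_number": int(float(parts[4])) if len(parts) > 4 else -1,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "copy_number"])
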