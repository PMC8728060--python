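# Methods

## Model and pipeline

The caller assumes a read-depth (RD) signal in which copy-neutral genome
segments cluster around a common diploid level and CNV segments deviate
from it, upward for gains and downward for losses, by an amount attenuated
by tumor purity. Detection proceeds in five stages.

**Binning and GC correction.** Per-base coverage is averaged over fixed
1-kb bins (0-based half-open coordinates throughout; 1-based only in
human-facing text). Reads flagged unmapped, secondary, supplementary or
duplicate are excluded; no mapping-quality cutoff is applied by default
(configurable), since aggressive MAPQ filtering biases coverage in
repetitive regions more than it removes noise. Bins consisting entirely of
'N' reference bases are dropped from all downstream vectors; bins merely
untouched by reads keep RD 0. GC bias is removed by stratified mean
scaling: bins are grouped by GC fraction rounded to the integer percent,
and each correctable stratum is rescaled to the mean RD over correctable
bins. Strata with fewer than 2 bins (or zero mean) are left untouched;
defining the scaling target over correctable bins only makes the operation
exactly idempotent. This removes any coverage-vs-GC relationship that is
constant within a percent, monotone or not, but cannot remove bias that
varies at fixed GC (e.g. mappability), which is out of scope.

**Segmentation.** Bins are grouped into 50-kb regions and each region's RD
vector is segmented independently by circular binary segmentation. At each
recursion step the circular arc (i, j) maximizing the pooled two-sample
t-statistic between arc and complement is found by an exact vectorized
scan (minimum piece width 2 bins); zero pooled variance with unequal means
is treated as an infinite statistic, with equal means as zero.
Significance uses a permutation test (default 1000 permutations,
α = 0.01) with two numerical choices:

- *Strict exceedance*: permutations that tie the observed maximum do not
  count. Ties occur with probability ~0 for continuous data but are
  systematic for degenerate inputs (a perfect two-level vector ties with
  every permutation that happens to separate the levels), where the
  non-strict convention would make clean steps unsplittable at small n.
- *Block early stopping*: permutations are drawn in blocks of 100 and the
  scan stops as soon as the exceedance count reaches α·n_perm, at which
  point the final p-value is guaranteed ≥ α. The accept/reject decision is
  identical to the full scan; only the work for clearly-null regions (the
  vast majority) shrinks by roughly an order of magnitude.

When an accepted arc has both endpoints interior, each change-point is
re-tested individually with a pooled t-test against its flanking pieces
and pruned if not significant on its own; if neither survives, the
stronger one is kept. Without this classical refinement the second arc
edge is frequently a pure noise artifact: the arc statistic can be carried
entirely by one true edge. Breakpoints never cross region boundaries, and
the segment means in coordinate order form the vector **R**.
Segmentation runs on corrected RD (correction precedes segmentation in the
workflow order).

**kNN scoring.** The score of segment r is a summary of its first k
nearest-neighbor Euclidean distances within **R** — mean by default,
largest or median as ablation variants (lower median for even k). The
neighborhood is capped at exactly k members, ties broken by ascending
segment index. Queries use a KD-tree and are exact; `brute_force_scores`
reimplements the contract over the full pairwise distance matrix and
exists purely as a test oracle. k is drawn once per score computation,
uniformly over the integers of [⌊0.2N⌋, ⌊0.35N⌋] and clamped to
[1, N−1]; drawing once per chromosome (rather than per region) keeps the
score vector a single coherent geometry. Scores are translation-invariant
and positively homogeneous in **R**, and the average scheme is
nondecreasing in k.

**VBGMM labeling.** A two-component 1-D Gaussian mixture is fitted to the
scores by coordinate-ascent variational inference with a factorized
posterior q(Z)q(μ)q(τ): Gaussian posteriors over component means, Gamma
posteriors over precisions, and mixing weights point-maximized each sweep
as αₘ = (1/N)Σᵢ hᵢₘ. Priors are weakly informative and data-scaled — mean
prior centered at the sample mean with the sample variance as spread;
precision prior Gamma(shape 1/2, rate s²/2), i.e. a one-degree-of-freedom
1-D Wishart with scale 1/s². The precision prior keeps every posterior
variance bounded away from zero, so no component can collapse onto a
single score as maximum-likelihood EM can. Because all priors scale with
the data, the labels are invariant to positive affine transforms of the
scores. Each sweep updates q(μ), q(τ), q(Z), then α, and records the exact
ELBO; every update is an exact coordinate maximization, so the trace is
monotone (asserted in tests at 1e-8). Initialization seeds
responsibilities from k-means++ centers (D²-proportional sampling, itself
affine-equivariant); three restarts keep the best final ELBO. Convergence:
|ΔELBO| < 1e-6 or 500 sweeps, with a warning and `converged=False`
otherwise. The fitter accepts general M; the pipeline fixes M = 2
(CNV vs normal). The component with the larger responsibility-weighted
mean score is the CNV component; coinciding means fall back to the
lower-weight component with a warning, as does a CNV weight above 0.5
(outliers should be the minority). Baseline labelers for ablations:
maximum-likelihood GMM (scikit-learn), the boxplot upper fence
Q3 + 0.75·IQR, and top-n (n largest scores, ties by index).

**Call assembly.** Flagged segments adjacent in genome coordinates (gap
0 bp, configurable) merge into calls, with one refinement over pure
adjacency: a run breaks where the RD direction relative to baseline flips,
so a flagged low segment next to a flagged high segment yields separate
loss and gain calls instead of one mistyped fusion. The baseline is the
median corrected RD of unflagged segments; calls with mean RD above it are
gains, otherwise losses (exact equality: loss, with a warning). Merging
ignores region-of-origin boundaries. Output is BED5+ with the mean outlier
score rescaled to 0–1000 in the score column.

## Evaluation

Precision, sensitivity and F1 are computed on base pairs: TP is the size
of the intersection of the declared and confirmed interval unions, PP and
P the union sizes themselves, with self-overlaps collapsed first and
F1(0, 0) defined as 0. Event-level matching is deliberately not used. The
overlapping density score is exposed as the fixed product
ODS = m_cnv · m′_cnv with the two density factors supplied by the caller
through a hook — their definitions belong to the caller-comparison
protocol that introduced them and are not reimplemented here, so ODS on
real data requires supplying those factors. The ablation harness sweeps
score schemes × k fractions (0.05N–1.00N) × labeling strategies (top-n at
n/N ∈ {0.05 … 0.25}) and reports F1 per cell, reusing one segmentation
per seed.

## Synthetic data

The generator emulates a tumor WGS experiment at the bin level rather than
the read level. Expected RD per bin is
coverage · ((1−p)·2 + p·c)/2 with copy number c = 2 outside planted
events; partial bin overlap uses the covered fraction. A slowly varying GC
track (sinusoid of 3-Mb period around 0.45 plus smoothed noise, clipped to
[0.25, 0.75]) drives a smooth multiplicative coverage bias of default
amplitude 0.1, and per-bin read counts are gamma-Poisson (negative
binomial) with dispersion θ = 100 — about 1.6× Poisson variance at 6x
coverage, i.e. the moderate overdispersion of a well-behaved library.
Defaults mirror the study grid: purity ∈ {0.2, 0.3, 0.4}, coverage
∈ {4x, 6x}, with the benchmark cell at (0.3, 6x); 14 disjoint events of
10–200 kb with copy numbers cycling {0, 1, 3, 4} on a 20-Mb chromosome.
What the generator does *not* reproduce: read-level artifacts (fragment
length, sequencing errors, indels), mappability structure, replication
timing waves, and the clustered event-size distributions of real tumors.
Passing tests therefore demonstrate the pipeline's statistical behavior
under its own model assumptions, not calling accuracy on real genomes.

## Known limitations and observed behavior

The mixture labeler places its decision boundary at roughly two standard
deviations of the normal-score cluster, so the upper tail of copy-neutral
50-kb regions (about 2–3% of them) is flagged in every run. On the default
benchmark this caps base-pair precision near 0.5–0.7 while sensitivity
sits near 0.95, for a median F1 around 0.7; the same boundary emerges from
scikit-learn's independent variational mixture on identical scores, and
near-Poisson noise raises F1 only to ~0.75–0.85, so this is a property of
thresholding two-component mixture responsibilities, not of this
implementation. By the same token the method assumes CNVs are a small
minority of the genome; profiles where variants cover a large fraction
violate the outlier premise and will be mislabeled. Problem sizes in the
test suite — 4-Mb chromosomes for unit-level end-to-end checks, 20-Mb with
20 replicate seeds for the benchmark — were chosen as the smallest at
which region/segment counts resemble a real chromosome arm.
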