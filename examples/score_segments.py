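"""kNN outlier scores on a toy read-depth vector.

Each segment's score is the mean of its first k nearest-neighbor distances
in 1-D read-depth space: segments far from the diploid bulk score high.
"""

import numpy as np

from knncnv import brute_force_scores, choose_k, outlier_scores

rng = np.random.default_rng(0)
# 60 diploid segments around RD 6, plus a deletion (4.2) and a gain (7.8)
r = np.concatenate([rng.normal(6.0, 0.15, 60), [4.2, 7.8]])

k = choose_k(len(r), seed=0)
sv = outlier_scores(r, k, scheme="average")
print(f"N={len(r)} segments, k={k} (drawn uniformly from [0.2N, 0.35N])")
print(f"normal-segment scores: median {np.median(sv.scores[:60]):.3f}, "
      f"max {sv.scores[:60].max():.3f}")
print(f"deletion score: {sv.scores[60]:.3f}  gain score: {sv.scores[61]:.3f}")
# the two planted outliers score an order of magnitude above the bulk

bf = brute_force_scores(r, k)
print(f"tree vs brute-force max |diff|: {np.abs(sv.scores - bf.scores).max():.2e}")
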