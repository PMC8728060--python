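"""Base-pair overlap metrics between declared and confirmed CNVs.

TP/PP/P count genomic positions: shared, declared, and confirmed; precision
and sensitivity are their ratios and F1 the harmonic mean.
"""

import pandas as pd

from knncnv import ods, overlap_metrics

declared = pd.DataFrame(
    [("chr21", 100_000, 200_000), ("chr21", 500_000, 560_000)],
    columns=["chrom", "start", "end"],
)
truth = pd.DataFrame(
    [("chr21", 150_000, 250_000), ("chr21", 500_000, 540_000)],
    columns=["chrom", "start", "end"],
)

report = overlap_metrics(declared, truth)
print(f"TP={report.tp} PP={report.pp} P={report.p}")
print(f"precision={report.precision:.3f} sensitivity={report.sensitivity:.3f} "
      f"F1={report.f1:.3f}")
# 50 kb of the first call and all 40 kb of the second overlap the truth

# without a truth set, callers are ranked by the overlapping density score,
# the product of two density factors supplied by the caller comparison
print(f"ODS example: {ods(1.2, 0.9):.3f}")
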