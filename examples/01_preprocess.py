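"""Preprocessing walk-through: binning, z-scoring, labelling, gene filter.

Builds a toy per-bp coverage track and a small dataset by hand, then runs
each preprocessing stage and prints what it computes.
"""

import numpy as np

from transferchrome import (
    BinningScheme,
    CellLineDataset,
    GeneSample,
    TSS,
    assign_labels,
    bin_signals,
    compute_stats,
    filter_genes,
    zscore_normalize,
)

# ---- binning: 10 kb of per-bp coverage around a TSS -> 100 bins of 100 bp
scheme = BinningScheme()
coverage = np.zeros(scheme.window_bp)
coverage[4900:5100] = 2.0  # a 200-bp peak straddling the TSS
bins = bin_signals(coverage, scheme)
print(f"peak coverage lands in bins 49-50: bin49={bins[49]:.0f}, bin50={bins[50]:.0f}")

# ---- z-score normalization per mark, pooled over all genes of a cell line
rng = np.random.default_rng(0)
genes = [
    GeneSample(f"g{i}", rng.gamma(2.0, 1.5, size=(5, 100))) for i in range(50)
]
dataset = CellLineDataset("toy", genes)
stats = compute_stats(dataset)
normalized = zscore_normalize(dataset, stats)
check = compute_stats(normalized)
print(
    "after z-scoring, pooled per-mark mean/sd:",
    np.round(check.mean, 12),
    np.round(check.sd, 12),
)

# ---- median-split labelling (>= median -> 1)
expressions = np.array([0.0, 1.5, 3.0, 3.0, 8.0])
labels, threshold = assign_labels(expressions)
print(f"expressions {expressions.tolist()} -> threshold t={threshold}, labels {labels.tolist()}")

# ---- TSS-proximity filter: drop genes within 5 kb downstream of a kept gene
table = [
    ("geneA", TSS("chr1", 10_000)),
    ("geneB", TSS("chr1", 12_500)),   # 2.5 kb downstream of kept geneA: dropped
    ("geneC", TSS("chr1", 16_000)),   # 6 kb downstream of geneA: kept
    ("geneD", TSS("chr2", 1_000)),    # other chromosome: kept
]
print("kept after proximity filter:", filter_genes(table))
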