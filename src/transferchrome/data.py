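"""Data model and preprocessing for binned histone-modification signals.

A gene is represented by an ``n_marks x n_bins`` matrix of nonnegative signal
values covering a fixed window centred on its transcription start site (TSS):
by default five core marks (H3K4me3, H3K4me1, H3K36me3, H3K27me3, H3K9me3)
over 100 bins of 100 bp, i.e. TSS +/- 5 kb.  Preprocessing comprises

* aggregating bp-level coverage into bins,
* per-cell-line z-score normalization of each mark (pooled over all bins of
  all genes of that mark),
* binary labelling by the median expression value (>= median -> 1), and
* a TSS-proximity filter that drops genes starting within 5 kb downstream of
  an already kept gene, to avoid overlapping signal windows.

Datasets are exchanged as long-format CSV: one row per (gene, bin) with one
column per mark, the DeepChrome-style layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_MARK_NAMES = ("H3K4me3", "H3K4me1", "H3K36me3", "H3K27me3", "H3K9me3")

FILTER_DISTANCE_BP = 5000


class FormatError(ValueError):
    """A dataset file violates the expected CSV dialect."""


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width binning of a TSS-centred window."""

    window_bp: int = 10_000
    n_bins: int = 100

    def __post_init__(self):
        if self.window_bp <= 0 or self.n_bins <= 0:
            raise ValueError("window_bp and n_bins must be positive")
        if self.window_bp % self.n_bins != 0:
            raise ValueError("window_bp must be divisible by n_bins")

    @property
    def bin_width_bp(self) -> int:
        return self.window_bp // self.n_bins


@dataclass(frozen=True)
class TSS:
    """A transcription start site (0-based position)."""

    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GeneSample:
    """One gene: signal matrix plus optional expression/label/domain/TSS."""

    gene_id: str
    signal: np.ndarray  # (n_marks, n_bins)
    expression: float | None = None
    label: int | None = None
    domain: int | None = None
    tss: TSS | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError(f"gene {self.gene_id}: signal must be 2-D (marks x bins)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"gene {self.gene_id}: signal contains non-finite values")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"gene {self.gene_id}: label must be 0 or 1")
        if self.domain is not None and self.domain not in (0, 1):
            raise ValueError(f"gene {self.gene_id}: domain must be 0 or 1")


@dataclass(frozen=True)
class NormalizationStats:
    """Per-mark pooled mean and standard deviation."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=np.float64))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be nonnegative")

    @property
    def n_marks(self) -> int:
        return self.mean.shape[0]


@dataclass
class CellLineDataset:
    """Ordered genes of one cell line with shared shape and mark order."""

    cell_line_id: str
    samples: list[GeneSample]
    mark_names: tuple[str, ...] = DEFAULT_MARK_NAMES
    stats: NormalizationStats | None = None
    threshold: float | None = None

    def __post_init__(self):
        self.mark_names = tuple(self.mark_names)
        shapes = {s.signal.shape for s in self.samples}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent signal shapes in dataset: {shapes}")
        for s in self.samples:
            if s.signal.shape[0] != len(self.mark_names):
                raise ValueError(
                    f"gene {s.gene_id}: {s.signal.shape[0]} marks but "
                    f"{len(self.mark_names)} mark names"
                )
        ids = [s.gene_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in dataset")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    @property
    def n_bins(self) -> int:
        if not self.samples:
            raise ValueError("empty dataset has no bin count")
        return self.samples[0].signal.shape[1]

    def signals(self) -> np.ndarray:
        """Stacked (n_genes, n_marks, n_bins) array."""
        return np.stack([s.signal for s in self.samples])

    def labels(self) -> np.ndarray:
        if any(s.label is None for s in self.samples):
            raise ValueError(f"dataset {self.cell_line_id} has unlabeled genes")
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def expressions(self) -> np.ndarray:
        if any(s.expression is None for s in self.samples):
            raise ValueError(f"dataset {self.cell_line_id} has genes without expression")
        return np.array([s.expression for s in self.samples], dtype=np.float64)

    def subset(self, indices, suffix: str = "") -> "CellLineDataset":
        return CellLineDataset(
            cell_line_id=self.cell_line_id + suffix,
            samples=[self.samples[i] for i in indices],
            mark_names=self.mark_names,
            stats=self.stats,
            threshold=self.threshold,
        )


def bin_signals(
    per_bp_signal: np.ndarray,
    scheme: BinningScheme = BinningScheme(),
    aggregate: str = "sum",
) -> np.ndarray:
    """Aggregate bp-resolution coverage over a TSS-centred window into bins.

    Bin j covers the half-open bp slice [j*w, (j+1)*w) of the window, w being
    the bin width; the default aggregate is the sum (coverage-style), with
    ``aggregate="mean"`` available.
    """
    sig = np.asarray(per_bp_signal, dtype=np.float64)
    if sig.ndim != 1 or sig.shape[0] != scheme.window_bp:
        raise ValueError(
            f"per-bp signal must have length {scheme.window_bp}, got {sig.shape}"
        )
    binned = sig.reshape(scheme.n_bins, scheme.bin_width_bp)
    if aggregate == "sum":
        return binned.sum(axis=1)
    if aggregate == "mean":
        return binned.mean(axis=1)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def compute_stats(dataset: CellLineDataset, ddof: int = 0) -> NormalizationStats:
    """Per-mark mean/sd pooled over every bin of every gene of the cell line.

    The default is the population standard deviation (ddof=0); pass ddof=1
    for the sample convention.
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute statistics of an empty dataset")
    x = dataset.signals()  # (genes, marks, bins)
    pooled = x.transpose(1, 0, 2).reshape(dataset.n_marks, -1)
    return NormalizationStats(
        mean=pooled.mean(axis=1), sd=pooled.std(axis=1, ddof=ddof)
    )


def zscore_normalize(
    dataset: CellLineDataset, stats: NormalizationStats | None = None
) -> CellLineDataset:
    """Standardize every mark to zero pooled mean and unit pooled sd.

    A zero-variance mark is mapped to all zeros: after centring, a constant
    mark carries no information, so dividing by zero is replaced by the zero
    signal.  The returned dataset records the stats used.
    """
    if stats is None:
        stats = compute_stats(dataset)
    if stats.n_marks != dataset.n_marks:
        raise ValueError(
            f"stats cover {stats.n_marks} marks, dataset has {dataset.n_marks}"
        )
    safe_sd = np.where(stats.sd > 0, stats.sd, 1.0)
    samples = []
    for s in dataset.samples:
        z = (s.signal - stats.mean[:, None]) / safe_sd[:, None]
        z[stats.sd == 0, :] = 0.0
        samples.append(replace(s, signal=z))
    return CellLineDataset(
        cell_line_id=dataset.cell_line_id,
        samples=samples,
        mark_names=dataset.mark_names,
        stats=stats,
        threshold=dataset.threshold,
    )


def assign_labels(expressions: np.ndarray) -> tuple[np.ndarray, float]:
    """Median-split labelling: expression >= median -> 1, else 0."""
    expr = np.asarray(expressions, dtype=np.float64)
    if expr.size == 0:
        raise ValueError("cannot label an empty expression vector")
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression values must be finite")
    threshold = float(np.median(expr))
    labels = (expr >= threshold).astype(np.int64)
    return labels, threshold


def label_dataset(dataset: CellLineDataset) -> CellLineDataset:
    """Apply the median-split rule to a dataset's expression values."""
    labels, t = assign_labels(dataset.expressions())
    samples = [
        replace(s, label=int(l)) for s, l in zip(dataset.samples, labels)
    ]
    return CellLineDataset(
        cell_line_id=dataset.cell_line_id,
        samples=samples,
        mark_names=dataset.mark_names,
        stats=dataset.stats,
        threshold=t,
    )


def filter_genes(
    genes: list[tuple[str, TSS]],
    distance_bp: int = FILTER_DISTANCE_BP,
    strand_aware: bool = False,
) -> list[str]:
    """Drop genes whose TSS lies within ``distance_bp`` downstream of the
    most recently kept gene's TSS on the same chromosome.

    "Downstream" is measured along the + direction (increasing coordinates)
    by default; with ``strand_aware`` the direction follows the kept gene's
    strand.  The scan proceeds in ascending coordinate order per chromosome;
    the returned ids preserve the input order of the survivors.  A gene at
    exactly the same position as a kept gene (distance 0) is kept.
    """
    for gid, tss in genes:
        if tss is None:
            raise ValueError(f"gene {gid} has no TSS coordinate")

    by_chrom: dict[str, list[tuple[int, str, TSS]]] = {}
    for idx, (gid, tss) in enumerate(genes):
        by_chrom.setdefault(tss.chrom, []).append((idx, gid, tss))

    kept_idx: set[int] = set()
    for entries in by_chrom.values():
        entries = sorted(entries, key=lambda e: e[2].position)
        kept: list[TSS] = []
        for idx, gid, tss in entries:
            drop = False
            if kept:
                prev = kept[-1]
                delta = tss.position - prev.position
                if strand_aware and prev.strand == "-":
                    delta = -delta
                if 0 < delta <= distance_bp:
                    drop = True
            if not drop:
                kept.append(tss)
                kept_idx.add(idx)
    return [gid for idx, (gid, _) in enumerate(genes) if idx in kept_idx]


def read_tss_table(path) -> list[tuple[str, TSS]]:
    """Read a BED-like TSV: chrom, 0-based position, gene_id, strand."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, pos, gid, strand = parts
            out.append((gid, TSS(chrom=chrom, position=int(pos), strand=strand)))
    return out


def _csv_header(mark_names) -> list[str]:
    return ["gene_id", "bin_id", *mark_names, "label"]


def read_dataset(
    path, cell_line_id: str | None = None, expected_bins: int | None = None
) -> CellLineDataset:
    """Read a per-cell-line dataset CSV.

    Layout: header ``gene_id,bin_id,<mark...>,label``; one row per
    (gene, bin); bin_id ascending 0..n_bins-1 within each gene; the label is
    repeated on every row of a gene and may be empty for unlabeled
    (target-domain) data.  ``expected_bins`` additionally pins the bin count
    (otherwise the first gene defines it).
    """
    try:
        df = pd.read_csv(path, dtype={"gene_id": str}, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "gene_id" or cols[1] != "bin_id" or cols[-1] != "label":
        raise FormatError(
            f"{path}: header must be gene_id,bin_id,<marks...>,label; got {cols}"
        )
    mark_names = tuple(cols[2:-1])
    if df.empty:
        return CellLineDataset(
            cell_line_id=cell_line_id or str(path), samples=[], mark_names=mark_names
        )
    if df["bin_id"].isna().any() or df[list(mark_names)].isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise FormatError(f"{path}: line {bad}: missing value")

    n_bins = expected_bins
    samples = []
    # preserve file order of genes
    for gene_id, grp in df.groupby("gene_id", sort=False):
        bins = grp["bin_id"].to_numpy()
        if len(np.unique(bins)) != len(bins):
            line = int(grp.index[np.argmax(np.diff(np.sort(bins)) == 0)]) + 2
            raise FormatError(f"{path}: line {line}: duplicate (gene, bin) row for {gene_id}")
        if not np.array_equal(bins, np.arange(len(bins))):
            line = int(grp.index[0]) + 2
            raise FormatError(
                f"{path}: line {line}: gene {gene_id} bins must be 0..{len(bins)-1} ascending"
            )
        if n_bins is None:
            n_bins = len(bins)
        elif len(bins) != n_bins:
            line = int(grp.index[0]) + 2
            raise FormatError(
                f"{path}: line {line}: gene {gene_id} has {len(bins)} bins, expected {n_bins}"
            )
        signal = grp[list(mark_names)].to_numpy(dtype=np.float64).T
        label_vals = grp["label"]
        if label_vals.isna().all():
            label = None
        else:
            uniq = label_vals.dropna().unique()
            if label_vals.isna().any() or len(uniq) != 1:
                line = int(grp.index[0]) + 2
                raise FormatError(
                    f"{path}: line {line}: gene {gene_id} label must be constant per gene"
                )
            label = int(uniq[0])
        samples.append(GeneSample(gene_id=str(gene_id), signal=signal, label=label))
    return CellLineDataset(
        cell_line_id=cell_line_id or str(path), samples=samples, mark_names=mark_names
    )


def write_dataset(dataset: CellLineDataset, path) -> None:
    """Write the CSV dialect of :func:`read_dataset` (deterministic order)."""
    buf = io.StringIO()
    buf.write(",".join(_csv_header(dataset.mark_names)) + "\n")
    for s in dataset.samples:
        label = "" if s.label is None else str(int(s.label))
        for j in range(s.signal.shape[1]):
            vals = ",".join(repr(float(v)) for v in s.signal[:, j])
            buf.write(f"{s.gene_id},{j},{vals},{label}\n")
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def split_dataset(
    dataset: CellLineDataset,
    fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> tuple[CellLineDataset, CellLineDataset, CellLineDataset]:
    """Random disjoint train/validation/test partition of the genes.

    Fractions must be positive and sum to 1; the permutation is driven only
    by ``seed`` so equal seeds give identical partitions.
    """
    f = np.asarray(fractions, dtype=np.float64)
    if f.shape != (3,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 positive values summing to 1, got {fractions}")
    n = len(dataset)
    perm = np.random.default_rng(seed).permutation(n)
    b1 = int(round(n * f[0]))
    b2 = int(round(n * (f[0] + f[1])))
    return (
        dataset.subset(perm[:b1]),
        dataset.subset(perm[b1:b2]),
        dataset.subset(perm[b2:]),
    )
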