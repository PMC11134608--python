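"""Sample scale-factor estimation by adaptive-bin median-ratio.

Sequencing-depth differences cannot be removed by total-count scaling when
a large share of reads sits in peaks whose occupancy itself differs between
samples.  The estimator here therefore (1) tabulates fragments in small
fixed-width bins, (2) greedily merges neighboring bins whose pooled per-bp
densities are similar — long runs of similar density are background, while
sharp density changes (peak edges) break merging, so the merge step
implicitly separates background from peak bins while growing per-bin
information — and (3) applies median-of-ratios estimation over the merged
bins: per-bin pseudo-references are geometric means across samples and a
sample's factor is the median of its ratios to the reference.

Factors are normalized to geometric mean 1; normalized signal is defined
as raw signal divided by the factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals_io import FragmentSet, GenomeLayout

log = logging.getLogger(__name__)

__all__ = [
    "BinTable",
    "MergedBinTable",
    "ScaleFactors",
    "bin_counts",
    "merge_bins",
    "median_ratio_factors",
    "estimate_scale_factors",
]


@dataclass
class BinTable:
    """Fixed-width genomic bins with per-sample fragment counts.

    Bins tile each chromosome left to right; the last bin of a chromosome
    may be shorter than ``width``.  ``counts[chrom]`` is an
    (n_bins, n_samples) int64 array.
    """

    layout: GenomeLayout
    width: int
    samples: list[str]
    counts: dict[str, np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return -(-self.layout.lengths[chrom] // self.width)

    def bin_lengths(self, chrom: str) -> np.ndarray:
        n = self.n_bins(chrom)
        lengths = np.full(n, self.width, dtype=np.int64)
        rem = self.layout.lengths[chrom] % self.width
        if rem:
            lengths[-1] = rem
        return lengths

    def total_counts(self) -> np.ndarray:
        return sum(c.sum(axis=0) for c in self.counts.values())


@dataclass
class MergedBinTable:
    """Variable-length bins (unions of adjacent fixed bins) with summed
    per-sample counts, as a DataFrame with columns
    ``chrom, start, end, length`` plus one count column per sample."""

    samples: list[str]
    table: pd.DataFrame

    def length_normalized(self) -> pd.DataFrame:
        """Per-sample count densities (count / bin length, per bp)."""
        return self.table[self.samples].div(self.table["length"], axis=0)

    def pooled_density(self) -> pd.Series:
        return self.table[self.samples].sum(axis=1) / self.table["length"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ScaleFactors:
    """Positive per-sample factors with geometric mean 1."""

    factors: dict[str, float]
    n_bins_used: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("scale factors must be positive")
        logs = np.log([self.factors[s] for s in self.factors])
        if abs(logs.mean()) > 1e-9:
            raise ValueError("factors must have geometric mean 1")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tfactor\n")
            for s, f in self.factors.items():
                fh.write(f"{s}\t{f:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScaleFactors":
        df = pd.read_csv(path, sep="\t")
        return cls({r["sample"]: float(r["factor"]) for _, r in df.iterrows()})


def bin_counts(
    samples: Sequence[FragmentSet],
    layout: GenomeLayout,
    width: int = 75,
    mode: str = "overlap",
) -> BinTable:
    """Count fragments per fixed-width bin for each sample.

    In ``overlap`` mode (default) a fragment is tabulated in every bin it
    falls within, i.e. overlaps by at least one base.  Because adjacent
    bins then share most of their fragments, neighboring bin densities are
    strongly correlated, which is what lets the 33%-change merge step grow
    long, information-rich background bins at ordinary sequencing depth.

    In ``midpoint`` mode a fragment belongs to exactly one bin — the one
    containing its midpoint ``floor((start + end) / 2)`` — so per-sample
    bin totals equal fragment counts exactly (a partition of the sample).
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown counting mode {mode!r}")
    names = [s.sample_id for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("sample ids must be unique")
    counts: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        n = -(-layout.lengths[chrom] // width)
        mat = np.zeros((n, len(samples)), dtype=np.int64)
        for j, fs in enumerate(samples):
            arr = fs.data.get(chrom)
            if arr is None or len(arr) == 0:
                continue
            if mode == "midpoint":
                mids = (arr[:, 0] + arr[:, 1]) // 2
                mat[:, j] = np.bincount(mids // width, minlength=n)
            else:
                lo = arr[:, 0] // width
                hi = np.minimum((arr[:, 1] - 1) // width + 1, n)
                d = np.zeros(n + 1, dtype=np.int64)
                np.add.at(d, lo, 1)
                np.add.at(d, hi, -1)
                mat[:, j] = np.cumsum(d[:-1])
        counts[chrom] = mat
    return BinTable(layout, width, names, counts)


def merge_bins(bins: BinTable, change_threshold: float = 0.33) -> MergedBinTable:
    """Greedy left-to-right merge of neighboring bins with similar pooled
    per-bp density.

    The current merged bin absorbs the next fixed bin iff the relative
    change ``|a - b| / max(a, b)`` between its pooled density ``a``
    (recomputed after each absorption) and the candidate's density ``b``
    is below ``change_threshold``; two zero densities count as no change.
    Merging never crosses a chromosome boundary.  Pooled (summed across
    samples) densities drive merging so that all samples share the merged
    boundaries, which per-bin cross-sample ratios require.
    """
    if not (0 < change_threshold < 1):
        raise ValueError("change_threshold must be in (0, 1)")
    rows = []
    for chrom in bins.layout.names:
        mat = bins.counts[chrom]
        lengths = bins.bin_lengths(chrom)
        pooled = mat.sum(axis=1)
        n = len(lengths)
        if n == 0:
            continue
        cur_start = 0
        cur_len = int(lengths[0])
        cur_pool = int(pooled[0])
        cur_counts = mat[0].copy()
        for i in range(1, n):
            a = cur_pool / cur_len
            b = pooled[i] / lengths[i]
            hi = max(a, b)
            change = 0.0 if hi == 0 else abs(a - b) / hi
            if change < change_threshold:
                cur_len += int(lengths[i])
                cur_pool += int(pooled[i])
                cur_counts += mat[i]
            else:
                rows.append((chrom, cur_start * bins.width, cur_start * bins.width + cur_len, cur_len, *cur_counts))
                cur_start = i
                cur_len = int(lengths[i])
                cur_pool = int(pooled[i])
                cur_counts = mat[i].copy()
        rows.append((chrom, cur_start * bins.width, cur_start * bins.width + cur_len, cur_len, *cur_counts))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length", *bins.samples])
    return MergedBinTable(bins.samples, df)


def median_ratio_factors(
    merged: MergedBinTable,
    min_pooled_density: float = 0.0,
    min_merged_length: int = 0,
) -> ScaleFactors:
    """Median-of-ratios scale factors over merged background bins.

    Bins where any sample has a zero count (undefined geometric mean) or
    whose pooled per-bp density is at or below ``min_pooled_density`` are
    dropped; ``min_merged_length`` optionally restricts to long,
    background-like bins (off by default).  Per retained bin the
    pseudo-reference is the geometric mean across samples of per-bp
    densities; a sample's factor is the median of its density/reference
    ratios, and factors are rescaled to geometric mean 1.
    """
    if len(merged.samples) < 2:
        raise ValueError("median-ratio estimation requires >= 2 samples")
    dens = merged.length_normalized().to_numpy()
    keep = (dens > 0).all(axis=1)
    keep &= merged.pooled_density().to_numpy() > min_pooled_density
    if min_merged_length > 0:
        keep &= merged.table["length"].to_numpy() >= min_merged_length
    dens = dens[keep]
    if len(dens) < 2:
        raise ValueError("insufficient background bins for factor estimation")
    ref = np.exp(np.log(dens).mean(axis=1))  # per-bin geometric mean
    raw = np.median(dens / ref[:, None], axis=0)
    factors = raw / np.exp(np.log(raw).mean())  # rescale to geometric mean 1
    log.info("median_ratio_factors: %d/%d bins retained", len(dens), len(keep))
    return ScaleFactors(dict(zip(merged.samples, factors)), n_bins_used=len(dens))


def estimate_scale_factors(
    samples: Sequence[FragmentSet],
    layout: GenomeLayout,
    width: int = 75,
    change_threshold: float = 0.33,
    min_pooled_density: float = 0.0,
) -> ScaleFactors:
    """Convenience: bin, merge, and estimate in one call."""
    return median_ratio_factors(
        merge_bins(bin_counts(samples, layout, width), change_threshold),
        min_pooled_density=min_pooled_density,
    )
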