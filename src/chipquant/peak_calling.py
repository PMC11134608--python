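"""Poisson scoring of ChIP signal against the noise track and peak calling.

Every base is scored with the Poisson upper tail
``p = P(X >= round(chip) | X ~ Poisson(noise))`` — the probability of
seeing at least the observed (normalized) fragment depth under the local
background rate.  P-values are converted to q-values by Benjamini–Hochberg
applied over the whole genome with each constant interval weighted by its
width in bases (a base is the unit hypothesis; constant intervals just
carry many identical copies).  Bases at q <= q_cutoff form candidate peaks,
nearby candidates are bridged across small gaps, and short remnants are
dropped.  Peaks called per condition are pooled and union-merged into
consensus peaks for cross-condition testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup import StepTrack

__all__ = [
    "ScoreTrack",
    "PeakCallParams",
    "PeakSet",
    "ConsensusPeakSet",
    "poisson_pvalue_track",
    "qvalue_track",
    "call_peaks",
    "merge_condition_peaks",
]


def poisson_pvalue_track(
    chip: StepTrack, noise: StepTrack, continuous: bool = False
) -> StepTrack:
    """Per-base Poisson upper-tail p-values of chip signal given noise.

    The chip value is rounded half-up to an integer count k and
    ``p = P(X >= k)`` with ``X ~ Poisson(noise)``; ``k = 0`` gives p = 1.
    With ``continuous=True`` the discrete tail is replaced by the
    regularized upper incomplete gamma function at the unrounded value.
    """
    layout = chip.layout
    out = {}
    for chrom in layout.names:
        starts, (cv, nv) = StepTrack.align([chip, noise], chrom)
        if (nv <= 0).any():
            raise ValueError(f"noise track not strictly positive on {chrom}")
        if continuous:
            # P(X >= k) = gammainc(k, lam) extends smoothly to real k > 0
            from scipy.special import gammainc
            x = np.maximum(cv, 0.0)
            p = np.where(x <= 0, 1.0, gammainc(np.maximum(x, 1e-12), nv))
        else:
            k = np.floor(cv + 0.5)
            p = stats.poisson.sf(k - 1, nv)
        out[chrom] = (starts, p)
    return StepTrack(layout, out)


@dataclass
class ScoreTrack:
    """Genome-wide significance: q-values with the raw p-value companion."""

    q: StepTrack
    p: StepTrack

    @property
    def neglog10q(self) -> StepTrack:
        return self.q.with_values(lambda v: -np.log10(np.maximum(v, 1e-300)))


def qvalue_track(p_track: StepTrack) -> ScoreTrack:
    """Base-pair-weighted Benjamini–Hochberg q-values over the genome.

    Each constant interval of the p-value track represents ``width``
    identical per-base hypotheses, so classical BH over all bases reduces
    to: sort unique p ascending, use cumulative covered bases as the
    effective rank, q(p_i) = min_{p_j >= p_i} p_j * total_bp / cum_bp_j,
    capped at 1.  This equals per-base-expanded BH exactly.
    """
    layout = p_track.layout
    ps, ws = [], []
    for chrom in layout.names:
        starts, ends, values = p_track.segments(chrom)
        if ((values <= 0) | (values > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        ps.append(values)
        ws.append(ends - starts)
    p = np.concatenate(ps)
    w = np.concatenate(ws).astype(np.float64)
    uniq, inv = np.unique(p, return_inverse=True)
    cum_bp = np.cumsum(np.bincount(inv, weights=w))
    total_bp = cum_bp[-1]
    raw = uniq * total_bp / cum_bp
    q_uniq = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = {}
    for chrom in layout.names:
        starts, values = p_track.chrom_arrays(chrom)
        idx = np.searchsorted(uniq, values)
        out[chrom] = (starts.copy(), q_uniq[idx])
    return ScoreTrack(q=StepTrack(layout, out), p=p_track)


@dataclass
class PeakCallParams:
    """Thresholds of peak formation.

    ``q_cutoff`` is the per-base significance threshold; candidate regions
    separated by gaps of at most ``max_gap`` bp are bridged; peaks shorter
    than ``min_length`` bp (conventionally the fragment length d) are
    discarded.
    """

    q_cutoff: float = 0.01
    min_length: int = 200
    max_gap: int = 75

    def __post_init__(self):
        if not (0 < self.q_cutoff < 1):
            raise ValueError("q_cutoff must be in (0, 1)")
        if self.min_length < 1 or self.max_gap < 0:
            raise ValueError("min_length >= 1 and max_gap >= 0 required")


@dataclass
class PeakSet:
    """Called peaks: disjoint intervals with summit and score annotations.

    ``df`` columns: chrom, start, end, summit (absolute bp), score
    (max -log10 q in peak), signal (max signal value in peak),
    summit_neglog10p, summit_neglog10q.
    """

    df: pd.DataFrame

    COLUMNS = [
        "chrom", "start", "end", "summit", "score", "signal",
        "summit_neglog10p", "summit_neglog10q",
    ]

    def __len__(self) -> int:
        return len(self.df)

    def total_length(self) -> int:
        if len(self.df) == 0:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def intervals(self) -> pd.DataFrame:
        return self.df[["chrom", "start", "end"]]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")

    def to_narrowpeak(self, path: str | Path, name_prefix: str = "peak") -> None:
        """ENCODE narrowPeak: score col 5, signalValue col 7, -log10 p
        col 8, -log10 q col 9, summit offset col 10."""
        with open(path, "w") as fh:
            for i, r in enumerate(self.df.itertuples(index=False), 1):
                score = int(min(1000, round(10 * r.score)))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name_prefix}_{i}\t{score}\t."
                    f"\t{r.signal:.6g}\t{r.summit_neglog10p:.6g}"
                    f"\t{r.summit_neglog10q:.6g}\t{r.summit - r.start}\n"
                )

    @classmethod
    def from_narrowpeak(cls, path: str | Path) -> "PeakSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                s = line.rstrip("\n")
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                f = s.split("\t")
                start = int(f[1])
                rows.append(
                    (f[0], start, int(f[2]), start + int(f[9]), float(f[4]) / 10,
                     float(f[6]), float(f[7]), float(f[8]))
                )
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def call_peaks(
    score: ScoreTrack,
    params: PeakCallParams,
    chip: StepTrack | None = None,
) -> PeakSet:
    """Threshold the q-value track and form peaks.

    Bases at q <= q_cutoff form candidates; candidates separated by gaps
    <= max_gap are bridged; intervals shorter than min_length are dropped.
    The summit is the leftmost base attaining the maximum chip signal
    within the peak (the score track itself if no chip track is given).
    """
    signal = chip if chip is not None else score.neglog10q
    nlq = score.neglog10q
    nlp = score.p.with_values(lambda v: -np.log10(np.maximum(v, 1e-300)))
    rows = []
    for chrom in score.q.layout.names:
        starts, ends, qv = score.q.segments(chrom)
        sig = qv <= params.q_cutoff
        if not sig.any():
            continue
        cand = _runs(starts, ends, sig)
        merged = _bridge(cand, params.max_gap)
        seg_s, seg_e, seg_v = signal.segments(chrom)
        q_s, q_e, q_v = nlq.segments(chrom)
        for s, e in merged:
            if e - s < params.min_length:
                continue
            lo = np.searchsorted(seg_e, s, side="right")
            hi = np.searchsorted(seg_s, e, side="left")
            vals = seg_v[lo:hi]
            best = int(np.argmax(vals))
            summit = int(max(seg_s[lo + best], s))
            peak_sig = float(vals[best])
            qlo = np.searchsorted(q_e, s, side="right")
            qhi = np.searchsorted(q_s, e, side="left")
            peak_score = float(q_v[qlo:qhi].max())
            rows.append(
                (chrom, int(s), int(e), summit, peak_score, peak_sig,
                 float(nlp.values_at(chrom, np.array([summit]))[0]),
                 float(nlq.values_at(chrom, np.array([summit]))[0]))
            )
    return PeakSet(pd.DataFrame(rows, columns=PeakSet.COLUMNS))


def _runs(starts: np.ndarray, ends: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Merge consecutive True segments into maximal intervals."""
    out: list[tuple[int, int]] = []
    for s, e, m in zip(starts, ends, mask):
        if not m:
            continue
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], int(e))
        else:
            out.append((int(s), int(e)))
    return out


def _bridge(intervals: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Bridge gaps of at most max_gap bp between successive intervals."""
    if not intervals:
        return []
    out = [intervals[0]]
    for s, e in intervals[1:]:
        if s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


@dataclass
class ConsensusPeakSet:
    """Union-merged peaks pooled across conditions.

    ``df`` columns: chrom, start, end, conditions (comma-joined sorted
    labels of the conditions whose peaks contributed).
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> pd.DataFrame:
        return self.df[["chrom", "start", "end"]]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.conditions}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "ConsensusPeakSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                s = line.rstrip("\n")
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                f = s.split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "conditions"]))


def merge_condition_peaks(
    peaksets: Mapping[str, PeakSet] | Sequence[PeakSet],
) -> ConsensusPeakSet:
    """Pool peaks across conditions and union-merge overlapping intervals.

    Only strictly overlapping intervals merge; abutting half-open
    intervals stay separate.  Each consensus peak records the sorted set
    of conditions that contributed.
    """
    if isinstance(peaksets, Mapping):
        labeled = list(peaksets.items())
    else:
        labeled = [(str(i), ps) for i, ps in enumerate(peaksets)]
    recs = []
    for label, ps in labeled:
        for r in ps.df.itertuples(index=False):
            recs.append((r.chrom, int(r.start), int(r.end), label))
    recs.sort(key=lambda t: (t[0], t[1], t[2]))
    rows = []
    cur = None
    for chrom, s, e, label in recs:
        if cur is not None and chrom == cur[0] and s < cur[2]:
            cur = (chrom, cur[1], max(cur[2], e), cur[3] | {label})
        else:
            if cur is not None:
                rows.append((cur[0], cur[1], cur[2], ",".join(sorted(cur[3]))))
            cur = (chrom, s, e, {label})
    if cur is not None:
        rows.append((cur[0], cur[1], cur[2], ",".join(sorted(cur[3]))))
    return ConsensusPeakSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "conditions"])
    )
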