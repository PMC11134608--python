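"""Piecewise-constant genome tracks and pileup construction.

A :class:`StepTrack` is a nonnegative step function over the genome,
equivalent to a BedGraph: per chromosome an ascending array of breakpoints
(always beginning at 0) and the value that holds from each breakpoint to the
next.  Pileups, noise estimates, p-value and score tracks are all
StepTracks, built by exact sweep-line accumulation over integer event
positions so that conservation identities hold in integer arithmetic.

Three pileup flavors are provided:

* ``paired_pileup`` — each fragment adds +1 over its own interval; the
  per-base value is the number of fragments covering that base.
* ``extended_start_pileup`` — each fragment contributes its two read starts
  (both endpoints); every read start adds ``scale`` over a window of
  ``ext`` bp centered on it.  With ``scale = 0.5`` and ``ext`` equal to the
  median fragment length this approximates the paired pileup from read
  starts alone while correcting for double-counting of paired-end data.
* ``build_noise_track`` — the multiscale Input background: the pointwise
  maximum of fragment-scale, small-local (±500 bp) and large-local
  (±5,000 bp) pileups and a global rate, scale-normalized, then floored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

from .intervals_io import FragmentSet, GenomeLayout

__all__ = [
    "StepTrack",
    "NoiseParams",
    "median_fragment_length",
    "paired_pileup",
    "extended_start_pileup",
    "build_noise_track",
    "normalize_track",
]


def _coalesce(starts: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) <= 1:
        return starts, values
    keep = np.empty(len(starts), dtype=bool)
    keep[0] = True
    keep[1:] = values[1:] != values[:-1]
    return starts[keep], values[keep]


_ZERO = (np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.float64))


class StepTrack:
    """Piecewise-constant function over a :class:`GenomeLayout`.

    ``data`` maps chromosome name to ``(starts, values)`` where ``starts``
    is ascending int64 with ``starts[0] == 0`` and ``values[i]`` holds on
    ``[starts[i], starts[i+1])`` (the last segment runs to the chromosome
    end).  Chromosomes absent from ``data`` are implicitly zero.
    """

    __slots__ = ("layout", "_data")

    def __init__(self, layout: GenomeLayout, data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self.layout = layout
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, values) in (data or {}).items():
            if chrom not in layout:
                raise ValueError(f"chromosome {chrom!r} absent from layout")
            starts = np.asarray(starts, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if len(starts) != len(values) or len(starts) == 0:
                raise ValueError("starts and values must be equal-length, non-empty")
            if starts[0] != 0 or (np.diff(starts) <= 0).any():
                raise ValueError("breakpoints must be ascending and begin at 0")
            if starts[-1] >= layout.lengths[chrom]:
                raise ValueError("breakpoint beyond chromosome end")
            self._data[chrom] = _coalesce(starts, values)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_deltas(
        cls,
        layout: GenomeLayout,
        events: dict[str, tuple[np.ndarray, np.ndarray]],
        scale: float = 1.0,
    ) -> "StepTrack":
        """Build a track from ±delta events by exact sweep-line cumsum.

        ``events[chrom] = (positions, deltas)``; positions are clipped to
        ``[0, chrom length]``.  Deltas are accumulated in their native
        (typically integer) dtype before the optional ``scale`` multiply,
        keeping integer pileups exact.
        """
        data = {}
        for chrom, (pos, delta) in events.items():
            if len(pos) == 0:
                continue
            L = layout.lengths[chrom]
            pos = np.clip(np.asarray(pos, dtype=np.int64), 0, L)
            delta = np.asarray(delta)
            order = np.argsort(pos, kind="stable")
            pos, delta = pos[order], delta[order]
            cum = np.cumsum(delta)
            uniq, first = np.unique(pos, return_index=True)
            last = np.append(first[1:], len(pos)) - 1
            vals = cum[last].astype(np.float64)
            if scale != 1.0:
                vals = vals * scale
            if len(uniq) == 0 or uniq[0] != 0:
                uniq = np.concatenate(([0], uniq))
                vals = np.concatenate(([0.0], vals))
            keep = uniq < L
            data[chrom] = (uniq[keep], vals[keep])
        return cls(layout, data)

    @classmethod
    def constant(cls, layout: GenomeLayout, value: float) -> "StepTrack":
        return cls(layout, {c: (np.zeros(1, np.int64), np.full(1, value)) for c in layout.names})

    # -- accessors ------------------------------------------------------

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._data.get(chrom, _ZERO)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (starts, ends, values) covering [0, chrom length)."""
        starts, values = self.chrom_arrays(chrom)
        ends = np.append(starts[1:], self.layout.lengths[chrom])
        return starts, ends, values

    def iter_segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.layout.names:
            starts, ends, values = self.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        starts, values = self.chrom_arrays(chrom)
        idx = np.searchsorted(starts, positions, side="right") - 1
        return values[idx]

    def integral(self) -> float:
        tot = 0.0
        for chrom in self.layout.names:
            starts, ends, values = self.segments(chrom)
            tot += float(((ends - starts) * values).sum())
        return tot

    def min_value(self) -> float:
        vals = [self.chrom_arrays(c)[1].min() for c in self.layout.names]
        return float(min(vals))

    def max_value(self) -> float:
        vals = [self.chrom_arrays(c)[1].max() for c in self.layout.names]
        return float(max(vals))

    def equals(self, other: "StepTrack") -> bool:
        if self.layout.lengths != other.layout.lengths:
            return False
        for chrom in self.layout.names:
            s1, v1 = self.chrom_arrays(chrom)
            s2, v2 = other.chrom_arrays(chrom)
            if len(s1) != len(s2) or (s1 != s2).any() or (v1 != v2).any():
                return False
        return True

    # -- transformations ------------------------------------------------

    def with_values(self, fn: Callable[[np.ndarray], np.ndarray]) -> "StepTrack":
        """Apply an elementwise function to segment values (piecewise
        constancy is preserved by construction)."""
        out = {}
        for chrom in self.layout.names:
            starts, values = self.chrom_arrays(chrom)
            out[chrom] = (starts.copy(), np.asarray(fn(values), dtype=np.float64))
        return StepTrack(self.layout, out)

    def scale(self, factor: float) -> "StepTrack":
        return self.with_values(lambda v: v * factor)

    def clip_min(self, floor: float) -> "StepTrack":
        return self.with_values(lambda v: np.maximum(v, floor))

    @staticmethod
    def maximum(tracks: Sequence["StepTrack"], constant: float | None = None) -> "StepTrack":
        """Pointwise maximum of step tracks (and an optional constant)."""
        if not tracks:
            raise ValueError("need at least one track")
        layout = tracks[0].layout
        out = {}
        for chrom in layout.names:
            all_starts = np.unique(
                np.concatenate([t.chrom_arrays(chrom)[0] for t in tracks])
            )
            vals = np.maximum.reduce([t.values_at(chrom, all_starts) for t in tracks])
            if constant is not None:
                vals = np.maximum(vals, constant)
            out[chrom] = _coalesce(all_starts, vals)
        return StepTrack(layout, out)

    @staticmethod
    def align(tracks: Sequence["StepTrack"], chrom: str) -> tuple[np.ndarray, list[np.ndarray]]:
        """Union breakpoints of several tracks on one chromosome and each
        track's values sampled on them."""
        all_starts = np.unique(
            np.concatenate([t.chrom_arrays(chrom)[0] for t in tracks])
        )
        return all_starts, [t.values_at(chrom, all_starts) for t in tracks]

    # -- I/O -------------------------------------------------------------

    def to_bedgraph(self, path: str | Path, include_zero: bool = False) -> None:
        """Write 4-column BedGraph; zero segments are omitted by default."""
        with open(path, "w") as fh:
            for chrom, s, e, v in self.iter_segments():
                if v == 0 and not include_zero:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, layout: GenomeLayout) -> "StepTrack":
        """Read a BedGraph; gaps become zero-valued segments."""
        acc: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lno, line in enumerate(fh, 1):
                s = line.rstrip("\n")
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                parts = s.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lno}: expected 4 BedGraph columns")
                acc.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
        data = {}
        for chrom, rows in acc.items():
            rows.sort()
            starts, values = [0], [0.0]
            cursor = 0
            for s, e, v in rows:
                if s < cursor:
                    raise ValueError(f"{path}: overlapping BedGraph records on {chrom}")
                if s > cursor:
                    if values[-1] != 0.0:
                        starts.append(cursor)
                        values.append(0.0)
                if s == 0:
                    starts, values = [0], [v]
                elif v != values[-1]:
                    starts.append(s)
                    values.append(v)
                cursor = e
            L = layout.lengths[chrom]
            if cursor < L and values[-1] != 0.0:
                starts.append(cursor)
                values.append(0.0)
            data[chrom] = (np.array(starts, np.int64), np.array(values))
        return cls(layout, data)


@dataclass
class NoiseParams:
    """Parameters of the multiscale Input background model.

    ``d`` is the median paired-end fragment length in bp; ``ext_small`` and
    ``ext_large`` are the half-widths (bp) of the two local windows; the
    global rate is total read mass over ``effective_genome_size``; the
    post-normalization noise is raised to at least ``floor`` so that called
    peaks must clear a meaningful absolute signal, not just a relative one.
    """

    d: int
    effective_genome_size: int
    ext_small: int = 500
    ext_large: int = 5000
    floor: float = 2.0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("fragment length d must be >= 1")
        if self.ext_small >= self.ext_large:
            raise ValueError("ext_small must be < ext_large")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.effective_genome_size <= 0:
            raise ValueError("effective_genome_size must be positive")


def median_fragment_length(frags: FragmentSet) -> int:
    """Median fragment length in bp, rounded half-up to an integer.

    For an even number of fragments the mean of the two central order
    statistics is taken before rounding.
    """
    lengths = frags.lengths()
    if len(lengths) == 0:
        raise ValueError("cannot take median of an empty fragment set")
    return int(math.floor(float(np.median(lengths)) + 0.5))


def paired_pileup(frags: FragmentSet) -> StepTrack:
    """Fragment-interval pileup: value at a base = number of fragments
    covering it.  Integral equals the exact sum of fragment lengths."""
    events = {}
    for chrom, arr in frags.iter_chroms():
        pos = np.concatenate([arr[:, 0], arr[:, 1]])
        delta = np.concatenate(
            [np.ones(len(arr), np.int64), -np.ones(len(arr), np.int64)]
        )
        events[chrom] = (pos, delta)
    return StepTrack.from_deltas(frags.layout, events)


def extended_start_pileup(frags: FragmentSet, ext: int, scale: float = 1.0) -> StepTrack:
    """Pileup of read starts extended to ``ext`` bp centered windows.

    Each fragment contributes both of its endpoints as read starts; a read
    start at r covers [r - ext//2, r + ext - ext//2), clipped to the
    chromosome, with weight ``scale``.
    """
    if ext < 1:
        raise ValueError("ext must be >= 1")
    left = ext // 2
    right = ext - left
    events = {}
    for chrom, arr in frags.iter_chroms():
        starts = np.concatenate([arr[:, 0], arr[:, 1]])
        pos = np.concatenate([starts - left, starts + right])
        delta = np.concatenate(
            [np.ones(len(starts), np.int64), -np.ones(len(starts), np.int64)]
        )
        events[chrom] = (pos, delta)
    return StepTrack.from_deltas(frags.layout, events, scale=scale)


def build_noise_track(
    input_frags: FragmentSet,
    p: NoiseParams,
    input_scale_factor: float = 1.0,
) -> tuple[StepTrack, float]:
    """Multiscale Poisson background estimate from an Input sample.

    Combines, by pointwise maximum, (1) the fragment-scale extended-start
    pileup (ext = d, halved for paired-end double counting), (2) the small
    local pileup (±ext_small, rescaled by d / (2·ext_small)), (3) the large
    local pileup (±ext_large, rescaled by d / (2·ext_large)), and (4) the
    global background rate λ_bg = n_reads · d / effective_genome_size.
    The merged track is divided by ``input_scale_factor`` and raised to at
    least ``floor``.  Returns (track, λ_bg).
    """
    if input_frags.n_fragments == 0:
        raise ValueError("cannot build a noise track from zero fragments")
    if input_scale_factor <= 0:
        raise ValueError("input_scale_factor must be positive")
    d = p.d
    t_frag = extended_start_pileup(input_frags, ext=d, scale=0.5)
    t_small = extended_start_pileup(
        input_frags, ext=2 * p.ext_small, scale=0.5 * d / (2 * p.ext_small)
    )
    t_large = extended_start_pileup(
        input_frags, ext=2 * p.ext_large, scale=0.5 * d / (2 * p.ext_large)
    )
    lambda_bg = input_frags.n_reads * d / p.effective_genome_size
    merged = StepTrack.maximum([t_frag, t_small, t_large], constant=lambda_bg)
    normalized = merged.with_values(lambda v: v / input_scale_factor)
    return normalized.clip_min(p.floor), lambda_bg


def normalize_track(t: StepTrack, factor: float) -> StepTrack:
    """Divide every value by a positive sample-specific scale factor."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return t.with_values(lambda v: v / factor)
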