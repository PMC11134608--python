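"""Fragment and region I/O, quality filtering, and replicate merging.

All coordinates are 0-based half-open (BED convention).  The unit of
evidence throughout the package is the *fragment*: the genomic interval
spanned by one sequenced paired-end molecule.  Fragments arrive either as
3+-column fragment BED or as BEDPE (the fragment is the span from the
leftmost mate start to the rightmost mate end on a single chromosome).

Quality filtering mirrors standard post-alignment ChIP-seq practice:
fragments fully contained in an exclusion (blacklist) region are dropped,
exact positional duplicates are collapsed to a single copy, and fragments
longer than 1,000 bp are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "FragmentSet",
    "RegionSet",
    "FilterStats",
    "read_fragments",
    "write_fragments",
    "write_bedpe",
    "filter_fragments",
    "downsample_merge",
    "write_regions",
]


class GenomeLayout:
    """Ordered chromosome names, lengths, and the effective genome size.

    The effective genome size is the mappable length used to convert total
    read mass into a global background rate; it defaults to the full summed
    length, which is exact for synthetic genomes.
    """

    def __init__(
        self,
        lengths: Mapping[str, int] | Sequence[tuple[str, int]],
        effective_genome_size: int | None = None,
    ):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        names = [str(n) for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        self.names: tuple[str, ...] = tuple(names)
        self.lengths: dict[str, int] = {str(n): int(L) for n, L in items}
        for n, L in self.lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {L}")
        total = sum(self.lengths.values())
        egs = total if effective_genome_size is None else int(effective_genome_size)
        if not (0 < egs <= total):
            raise ValueError(
                f"effective_genome_size must be in (0, {total}], got {egs}"
            )
        self.effective_genome_size: int = egs

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeLayout)
            and self.names == other.names
            and self.lengths == other.lengths
            and self.effective_genome_size == other.effective_genome_size
        )

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self.names)} chromosomes, {self.total_length} bp)"

    @classmethod
    def from_chrom_sizes(
        cls, path: str | Path, effective_genome_size: int | None = None
    ) -> "GenomeLayout":
        """Read a two-column ``name<TAB>length`` chromosome-sizes table."""
        pairs = []
        with open(path) as fh:
            for lno, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lno}: expected 'name<TAB>length'")
                try:
                    pairs.append((parts[0], int(parts[1])))
                except ValueError as e:
                    raise ValueError(f"{path}:{lno}: bad length {parts[1]!r}") from e
        return cls(pairs, effective_genome_size)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n in self.names:
                fh.write(f"{n}\t{self.lengths[n]}\n")


def _empty_intervals() -> np.ndarray:
    return np.empty((0, 2), dtype=np.int64)


def _sort_rows(arr: np.ndarray) -> np.ndarray:
    """Sort (n,2) interval rows by (start, end)."""
    if len(arr) == 0:
        return arr
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


@dataclass
class FragmentSet:
    """A sample's paired-end fragments as a multiset of genomic intervals.

    ``data`` maps chromosome name to an (n, 2) int64 array of sorted
    [start, end) rows; duplicate rows are permitted (multiset semantics).
    """

    sample_id: str
    role: str  # "ChIP" | "Input"
    condition: str
    layout: GenomeLayout
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("ChIP", "Input"):
            raise ValueError(f"role must be 'ChIP' or 'Input', got {self.role!r}")
        clean = {}
        for chrom, arr in self.data.items():
            if chrom not in self.layout:
                raise ValueError(f"chromosome {chrom!r} absent from layout")
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr):
                L = self.layout.lengths[chrom]
                if (arr[:, 0] < 0).any() or (arr[:, 1] > L).any():
                    raise ValueError(f"fragment out of bounds on {chrom}")
                if (arr[:, 0] >= arr[:, 1]).any():
                    raise ValueError(f"fragment with start >= end on {chrom}")
                clean[chrom] = _sort_rows(arr)
        self.data = clean

    @property
    def n_fragments(self) -> int:
        return sum(len(a) for a in self.data.values())

    @property
    def n_reads(self) -> int:
        """Paired-end: every fragment was sequenced as two reads."""
        return 2 * self.n_fragments

    def lengths(self) -> np.ndarray:
        if not self.data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for a in self.chrom_arrays()])

    def chrom_arrays(self) -> Iterator[np.ndarray]:
        for chrom in self.layout.names:
            if chrom in self.data:
                yield self.data[chrom]

    def iter_chroms(self) -> Iterator[tuple[str, np.ndarray]]:
        for chrom in self.layout.names:
            yield chrom, self.data.get(chrom, _empty_intervals())

    def replace(self, **kw) -> "FragmentSet":
        d = dict(sample_id=self.sample_id, role=self.role, condition=self.condition,
                 layout=self.layout, data=self.data)
        d.update(kw)
        return FragmentSet(**d)

    def as_multiset(self) -> set[tuple[str, int, int, int]]:
        """Multiset of (chrom, start, end, copy-index) for equality tests."""
        out = set()
        for chrom, arr in self.iter_chroms():
            seen: dict[tuple[int, int], int] = {}
            for s, e in arr:
                k = (int(s), int(e))
                seen[k] = seen.get(k, 0) + 1
                out.add((chrom, k[0], k[1], seen[k]))
        return out


@dataclass
class RegionSet:
    """A set of genomic intervals (exclusion lists, peak ranges)."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr):
                if (arr[:, 0] >= arr[:, 1]).any():
                    raise ValueError(f"region with start >= end on {chrom}")
                clean[chrom] = _sort_rows(arr)
        self.data = clean

    def __len__(self) -> int:
        return sum(len(a) for a in self.data.values())

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.data.values()))

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.data):
            for s, e in self.data[chrom]:
                yield chrom, int(s), int(e)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        acc: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            acc.setdefault(chrom, []).append((s, e))
        return cls({c: np.array(v, dtype=np.int64) for c, v in acc.items()})

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for lno, line in enumerate(fh, 1):
                s = line.rstrip("\n")
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                parts = s.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lno}: expected >=3 BED columns")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as e:
                    raise ValueError(f"{path}:{lno}: bad coordinates") from e
        return cls.from_intervals(rows)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals():
                fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class FilterStats:
    """Per-rule removal counts reported by :func:`filter_fragments`."""

    n_input: int
    n_excluded: int
    n_too_long: int
    n_duplicate: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_excluded - self.n_too_long - self.n_duplicate


def read_fragments(
    path: str | Path,
    layout: GenomeLayout,
    *,
    sample_id: str | None = None,
    role: str = "ChIP",
    condition: str = "",
    fmt: str = "auto",
    interchrom: str = "skip",
) -> FragmentSet:
    """Read fragments from a fragment BED (3+ cols) or a BEDPE file.

    BEDPE records contribute the span from the leftmost mate start to the
    rightmost mate end; inter-chromosomal records are skipped with a logged
    count (``interchrom="error"`` hard-fails instead).
    """
    if fmt not in ("auto", "bed", "bedpe"):
        raise ValueError(f"unknown format {fmt!r}")
    rows: list[list[str]] = []
    lnos: list[int] = []
    with open(path) as fh:
        for lno, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if not s or s.startswith(("#", "track", "browser")):
                continue
            rows.append(s.split("\t"))
            lnos.append(lno)
    sid = sample_id if sample_id is not None else Path(path).stem
    if not rows:
        return FragmentSet(sid, role, condition, layout, {})

    if fmt == "auto":
        first = rows[0]
        is_bedpe = (
            len(first) >= 6
            and first[3] in layout
            and _is_int(first[4])
            and _is_int(first[5])
        )
        fmt = "bedpe" if is_bedpe else "bed"

    acc: dict[str, list[tuple[int, int]]] = {}
    n_inter = 0
    for parts, lno in zip(rows, lnos):
        if fmt == "bed":
            if len(parts) < 3 or not (_is_int(parts[1]) and _is_int(parts[2])):
                raise ValueError(f"{path}:{lno}: malformed BED record")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
        else:
            if len(parts) < 6 or not all(_is_int(parts[i]) for i in (1, 2, 4, 5)):
                raise ValueError(f"{path}:{lno}: malformed BEDPE record")
            c1, s1, e1, c2, s2, e2 = (
                parts[0], int(parts[1]), int(parts[2]),
                parts[3], int(parts[4]), int(parts[5]),
            )
            if c1 != c2:
                if interchrom == "error":
                    raise ValueError(f"{path}:{lno}: inter-chromosomal BEDPE record")
                n_inter += 1
                continue
            chrom, s, e = c1, min(s1, s2), max(e1, e2)
        if chrom not in layout:
            raise ValueError(f"{path}:{lno}: chromosome {chrom!r} absent from layout")
        L = layout.lengths[chrom]
        if not (0 <= s < e <= L):
            raise ValueError(
                f"{path}:{lno}: interval [{s},{e}) outside [0,{L}) on {chrom}"
            )
        acc.setdefault(chrom, []).append((s, e))
    if n_inter:
        log.info("%s: skipped %d inter-chromosomal BEDPE records", path, n_inter)
    data = {c: np.array(v, dtype=np.int64) for c, v in acc.items()}
    return FragmentSet(sid, role, condition, layout, data)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    """Write fragments as a sorted 3-column BED file."""
    with open(path, "w") as fh:
        for chrom, arr in frags.iter_chroms():
            for s, e in arr:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_bedpe(frags: FragmentSet, path: str | Path, read_length: int = 36) -> None:
    """Write fragments as BEDPE, synthesizing mate intervals of
    ``read_length`` bp (capped at the fragment length) at either end."""
    with open(path, "w") as fh:
        for chrom, arr in frags.iter_chroms():
            for s, e in arr:
                rl = min(read_length, int(e - s))
                fh.write(
                    f"{chrom}\t{s}\t{s + rl}\t{chrom}\t{e - rl}\t{e}\t.\t0\t+\t-\n"
                )


def filter_fragments(
    frags: FragmentSet,
    exclusion: RegionSet | None = None,
    max_length: int = 1000,
    dedupe: bool = True,
) -> tuple[FragmentSet, FilterStats]:
    """Apply the three post-alignment quality filters.

    Removes fragments (i) fully contained in any exclusion interval,
    (ii) strictly longer than ``max_length`` bp, and (iii) exact positional
    duplicates beyond the first copy.  The result is independent of rule
    order: the first two rules are evaluated on the raw input and
    deduplication collapses identical survivors (identical coordinates
    share their fate under the other rules).
    """
    n_excluded = n_too_long = n_dup = 0
    out: dict[str, np.ndarray] = {}
    for chrom, arr in frags.iter_chroms():
        if len(arr) == 0:
            continue
        keep = np.ones(len(arr), dtype=bool)
        if exclusion is not None and chrom in exclusion.data:
            excl = exclusion.data[chrom]
            # fragment fully contained in SOME single exclusion interval:
            # among intervals with start <= frag.start, does any end >= frag.end?
            starts = excl[:, 0]
            prefix_max_end = np.maximum.accumulate(excl[:, 1])
            idx = np.searchsorted(starts, arr[:, 0], side="right") - 1
            contained = (idx >= 0) & (
                prefix_max_end[np.clip(idx, 0, None)] >= arr[:, 1]
            )
            n_excluded += int(contained.sum())
            keep &= ~contained
        too_long = (arr[:, 1] - arr[:, 0]) > max_length
        n_too_long += int((too_long & keep).sum())
        keep &= ~too_long
        surv = arr[keep]
        if dedupe and len(surv):
            uniq = np.unique(surv, axis=0)
            n_dup += len(surv) - len(uniq)
            surv = uniq
        if len(surv):
            out[chrom] = surv
    stats = FilterStats(frags.n_fragments, n_excluded, n_too_long, n_dup)
    log.info(
        "filter %s: excluded=%d too_long=%d duplicate=%d kept=%d",
        frags.sample_id, stats.n_excluded, stats.n_too_long,
        stats.n_duplicate, stats.n_kept,
    )
    return frags.replace(data=out), stats


def downsample_merge(replicates: Sequence[FragmentSet], seed: int) -> FragmentSet:
    """Equalize replicate depths by seeded subsampling, then concatenate.

    Every replicate with more fragments than the smallest one is randomly
    down-sampled (without replacement) to the minimum count, so no single
    deep replicate dominates the pooled evidence used for peak discovery.
    """
    if len(replicates) == 0:
        raise ValueError("no replicates given")
    if len(replicates) == 1:
        log.info("downsample_merge: single replicate, identity")
        return replicates[0]
    roles = {r.role for r in replicates}
    conds = {r.condition for r in replicates}
    if len(roles) != 1 or len(conds) != 1:
        raise ValueError("replicates must share role and condition")
    sizes = [r.n_fragments for r in replicates]
    if min(sizes) == 0:
        raise ValueError("empty replicate cannot be down-sampled")
    n_min = min(sizes)
    rng = np.random.default_rng(seed)
    merged: dict[str, list[np.ndarray]] = {}
    for rep in replicates:
        chroms = [c for c, _ in rep.iter_chroms()]
        arrs = [a for _, a in rep.iter_chroms()]
        n = rep.n_fragments
        if n > n_min:
            pick = np.sort(rng.choice(n, size=n_min, replace=False))
            offsets = np.cumsum([0] + [len(a) for a in arrs])
            for ci, (chrom, arr) in enumerate(zip(chroms, arrs)):
                lo, hi = offsets[ci], offsets[ci + 1]
                local = pick[(pick >= lo) & (pick < hi)] - lo
                if len(local):
                    merged.setdefault(chrom, []).append(arr[local])
        else:
            for chrom, arr in zip(chroms, arrs):
                if len(arr):
                    merged.setdefault(chrom, []).append(arr)
    data = {c: np.concatenate(v) for c, v in merged.items()}
    first = replicates[0]
    sid = "+".join(r.sample_id for r in replicates)
    return FragmentSet(sid, first.role, first.condition, first.layout, data)


def write_regions(regions, path: str | Path, fmt: str = "bed") -> None:
    """Write a RegionSet (BED) or a PeakSet (BED or narrowPeak)."""
    if fmt == "bed":
        if hasattr(regions, "to_bed"):
            regions.to_bed(path)
        else:
            raise TypeError(f"cannot write {type(regions).__name__} as BED")
    elif fmt == "narrowpeak":
        if hasattr(regions, "to_narrowpeak"):
            regions.to_narrowpeak(path)
        else:
            raise TypeError(
                f"{type(regions).__name__} has no summit data for narrowPeak"
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
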