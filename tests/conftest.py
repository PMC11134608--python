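import numpy as np
import pytest

from chipquant import FragmentSet, GenomeLayout


@pytest.fixture
def layout():
    """Toy two-chromosome genome."""
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def make_frags(layout):
    """Factory for FragmentSets from (chrom, start, end) triples."""

    def _make(intervals, sample_id="s1", role="ChIP", condition="A", lay=None):
        lay = lay or layout
        acc = {}
        for chrom, s, e in intervals:
            acc.setdefault(chrom, []).append((s, e))
        data = {c: np.array(v, dtype=np.int64) for c, v in acc.items()}
        return FragmentSet(sample_id, role, condition, lay, data)

    return _make


@pytest.fixture
def random_frags(layout):
    """Factory for random FragmentSets on the toy genome."""

    def _make(n, seed=0, sample_id="r1", role="ChIP", condition="A", lay=None):
        lay = lay or layout
        rng = np.random.default_rng(seed)
        data = {}
        for chrom, L in lay.lengths.items():
            k = n // len(lay.lengths)
            start = rng.integers(0, L - 1, size=k)
            length = rng.integers(1, min(400, L // 4), size=k)
            end = np.minimum(start + length, L)
            data[chrom] = np.stack([start, end], axis=1)
        return FragmentSet(sample_id, role, condition, lay, data)

    return _make


def per_base(track, chrom):
    """Expand a StepTrack chromosome to one value per base."""
    L = track.layout.lengths[chrom]
    return track.values_at(chrom, np.arange(L))
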