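import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipquant import (
    GenomeLayout,
    NoiseParams,
    StepTrack,
    build_noise_track,
    extended_start_pileup,
    median_fragment_length,
    normalize_track,
    paired_pileup,
)
from conftest import per_base


def brute_force_paired(frags, chrom):
    L = frags.layout.lengths[chrom]
    acc = np.zeros(L)
    for s, e in frags.data.get(chrom, []):
        acc[s:e] += 1
    return acc


def brute_force_extended(frags, chrom, ext, scale):
    L = frags.layout.lengths[chrom]
    acc = np.zeros(L)
    left, right = ext // 2, ext - ext // 2
    for s, e in frags.data.get(chrom, []):
        for r in (s, e):
            acc[max(0, r - left):min(L, r + right)] += scale
    return acc


class TestStepTrack:
    def test_segments_cover_chromosome(self, layout):
        t = StepTrack(layout, {"chr1": (np.array([0, 100]), np.array([1.0, 3.0]))})
        starts, ends, values = t.segments("chr1")
        assert starts[0] == 0 and ends[-1] == layout.lengths["chr1"]
        assert values.tolist() == [1.0, 3.0]
        # absent chromosome is implicitly zero
        assert t.values_at("chr2", np.array([0, 4999])).tolist() == [0.0, 0.0]

    def test_adjacent_equal_values_coalesce(self, layout):
        t = StepTrack(layout, {"chr1": (np.array([0, 50, 100]), np.array([2.0, 2.0, 1.0]))})
        starts, _ = t.chrom_arrays("chr1")
        assert starts.tolist() == [0, 100]

    def test_invalid_breakpoints_rejected(self, layout):
        with pytest.raises(ValueError):
            StepTrack(layout, {"chr1": (np.array([10]), np.array([1.0]))})
        with pytest.raises(ValueError):
            StepTrack(layout, {"chr1": (np.array([0, 0]), np.array([1.0, 2.0]))})

    def test_bedgraph_round_trip(self, layout, tmp_path):
        t = StepTrack(
            layout,
            {
                "chr1": (np.array([0, 100, 300, 600]), np.array([0.0, 2.5, 0.0, 7.0])),
                "chr2": (np.array([0]), np.array([1.25])),
            },
        )
        p = tmp_path / "t.bedgraph"
        t.to_bedgraph(p)
        assert StepTrack.from_bedgraph(p, layout).equals(t)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_maximum_matches_per_base_oracle(self, seed):
        lay = GenomeLayout({"c": 400})
        rng = np.random.default_rng(seed)
        tracks = []
        for _ in range(3):
            k = rng.integers(1, 8)
            starts = np.concatenate(([0], np.sort(rng.choice(np.arange(1, 400), size=k, replace=False))))
            vals = rng.integers(0, 5, size=k + 1).astype(float)
            tracks.append(StepTrack(lay, {"c": (starts, vals)}))
        got = StepTrack.maximum(tracks, constant=1.5)
        expect = np.maximum.reduce([per_base(t, "c") for t in tracks])
        expect = np.maximum(expect, 1.5)
        assert np.array_equal(per_base(got, "c"), expect)

    def test_maximum_associative_commutative(self):
        lay = GenomeLayout({"c": 300})
        rng = np.random.default_rng(1)
        ts = []
        for _ in range(3):
            starts = np.concatenate(([0], np.sort(rng.choice(np.arange(1, 300), 5, replace=False))))
            ts.append(StepTrack(lay, {"c": (starts, rng.uniform(0, 4, 6))}))
        a, b, c = ts
        left = StepTrack.maximum([StepTrack.maximum([a, b]), c])
        right = StepTrack.maximum([a, StepTrack.maximum([b, c])])
        swapped = StepTrack.maximum([c, a, b])
        assert left.equals(right) and left.equals(swapped)


class TestMedianFragmentLength:
    @pytest.mark.parametrize(
        "lengths,expect",
        [((180, 200, 220), 200), ((180, 200), 190), ((150, 150, 150), 150),
         ((100, 101), 101)],  # 100.5 rounds half-up
    )
    def test_median_conventions(self, make_frags, lengths, expect):
        fs = make_frags([("chr1", i * 500, i * 500 + l) for i, l in enumerate(lengths)])
        assert median_fragment_length(fs) == expect

    def test_empty_error(self, make_frags):
        with pytest.raises(ValueError):
            median_fragment_length(make_frags([]))


class TestPairedPileup:
    def test_single_fragment(self, make_frags):
        t = paired_pileup(make_frags([("chr1", 100, 300)]))
        starts, ends, values = t.segments("chr1")
        nz = [(int(s), int(e), v) for s, e, v in zip(starts, ends, values) if v]
        assert nz == [(100, 300, 1.0)]

    def test_two_overlapping(self, make_frags):
        t = paired_pileup(make_frags([("chr1", 100, 300), ("chr1", 200, 400)]))
        assert t.values_at("chr1", np.array([150, 250, 350])).tolist() == [1, 2, 1]

    def test_conservation(self, random_frags):
        fs = random_frags(300, seed=9)
        assert int(paired_pileup(fs).integral()) == int(fs.lengths().sum())

    def test_matches_per_base_oracle(self, random_frags):
        fs = random_frags(120, seed=4)
        t = paired_pileup(fs)
        for chrom in fs.layout.names:
            assert np.array_equal(per_base(t, chrom), brute_force_paired(fs, chrom))


class TestExtendedStartPileup:
    def test_centered_windows(self, make_frags):
        fs = make_frags([("chr1", 1000, 1300)])
        t = extended_start_pileup(fs, ext=200, scale=0.5)
        starts, ends, values = t.segments("chr1")
        nz = [(int(s), int(e), v) for s, e, v in zip(starts, ends, values) if v]
        assert nz == [(900, 1100, 0.5), (1200, 1400, 0.5)]

    def test_clipping_at_chromosome_start(self, make_frags):
        fs = make_frags([("chr1", 20, 2000)])
        t = extended_start_pileup(fs, ext=200, scale=1.0)
        starts, ends, values = t.segments("chr1")
        assert starts[0] == 0 and values[0] == 1.0 and ends[0] == 120

    def test_integral_accounts_for_clipping(self, random_frags):
        fs = random_frags(150, seed=6)
        ext, scale = 300, 0.25
        t = extended_start_pileup(fs, ext, scale)
        expect = sum(
            brute_force_extended(fs, c, ext, scale).sum() for c in fs.layout.names
        )
        assert t.integral() == pytest.approx(expect, rel=1e-12)

    def test_matches_per_base_oracle(self, random_frags):
        fs = random_frags(80, seed=5)
        t = extended_start_pileup(fs, ext=101, scale=0.5)
        for chrom in fs.layout.names:
            assert np.allclose(
                per_base(t, chrom), brute_force_extended(fs, chrom, 101, 0.5)
            )


class TestNoiseTrack:
    def test_lambda_bg_formula(self, random_frags):
        fs = random_frags(200, seed=2, role="Input")
        p = NoiseParams(d=150, effective_genome_size=10_000)
        _, lambda_bg = build_noise_track(fs, p)
        assert lambda_bg == pytest.approx(2 * fs.n_fragments * 150 / 10_000)

    def test_matches_per_base_composition_oracle(self, random_frags):
        fs = random_frags(100, seed=8, role="Input")
        d = median_fragment_length(fs)
        factor = 1.3
        p = NoiseParams(d=d, effective_genome_size=fs.layout.effective_genome_size,
                        ext_small=50, ext_large=500, floor=2.0)
        track, lambda_bg = build_noise_track(fs, p, factor)
        for chrom in fs.layout.names:
            t1 = brute_force_extended(fs, chrom, d, 0.5)
            t2 = brute_force_extended(fs, chrom, 100, 0.5 * d / 100)
            t3 = brute_force_extended(fs, chrom, 1000, 0.5 * d / 1000)
            merged = np.maximum.reduce([t1, t2, t3, np.full_like(t1, lambda_bg)])
            expect = np.maximum(merged / factor, 2.0)
            assert np.allclose(per_base(track, chrom), expect, rtol=1e-12)

    def test_floor_and_global_bound(self, random_frags):
        fs = random_frags(60, seed=3, role="Input")
        p = NoiseParams(d=100, effective_genome_size=fs.layout.effective_genome_size)
        track, lambda_bg = build_noise_track(fs, p, input_scale_factor=2.0)
        bound = max(p.floor, lambda_bg / 2.0)
        for chrom in fs.layout.names:
            assert (track.chrom_arrays(chrom)[1] >= bound).all()

    def test_errors(self, make_frags, random_frags):
        p = NoiseParams(d=100, effective_genome_size=1000)
        with pytest.raises(ValueError):
            build_noise_track(make_frags([]), p)
        with pytest.raises(ValueError):
            build_noise_track(random_frags(10, seed=0), p, input_scale_factor=0.0)
        with pytest.raises(ValueError):
            NoiseParams(d=100, effective_genome_size=0)


class TestNormalizeTrack:
    def test_divides_values(self, make_frags):
        t = paired_pileup(make_frags([("chr1", 0, 100)] * 4))
        # dedupe not applied here: 4 identical fragments stack to 4
        out = normalize_track(t, 2.0)
        assert out.values_at("chr1", np.array([50]))[0] == 2.0

    def test_identity_and_composition(self, random_frags):
        t = paired_pileup(random_frags(50, seed=1))
        assert normalize_track(t, 1.0).equals(t)
        ab = normalize_track(normalize_track(t, 2.0), 3.0)
        direct = normalize_track(t, 6.0)
        for chrom in t.layout.names:
            assert np.allclose(ab.chrom_arrays(chrom)[1], direct.chrom_arrays(chrom)[1])

    def test_nonpositive_factor_rejected(self, random_frags):
        t = paired_pileup(random_frags(10, seed=1))
        with pytest.raises(ValueError):
            normalize_track(t, 0.0)
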