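import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipquant import (
    GenomeLayout,
    PeakCallParams,
    PeakSet,
    StepTrack,
    call_peaks,
    merge_condition_peaks,
    poisson_pvalue_track,
    qvalue_track,
)
from conftest import per_base


def poisson_tail_oracle(k, lam):
    """Direct pmf summation for P(X >= k), X ~ Poisson(lam)."""
    if k <= 0:
        return 1.0
    terms = []
    j = int(k)
    while True:
        logp = j * math.log(lam) - lam - math.lgamma(j + 1)
        t = math.exp(logp)
        terms.append(t)
        if t < 1e-30 and j > lam + k:
            break
        j += 1
    return math.fsum(sorted(terms))


def expanded_bh_oracle(p_per_base):
    """Classical BH applied to every base individually (same arithmetic
    order as the weighted implementation: p * N / rank)."""
    p = np.asarray(p_per_base, dtype=float)
    n = float(len(p))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1, dtype=float)
    raw = p[order] * n / ranks
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    # within a tie group every base gets the group's (last-rank) q
    q = np.empty_like(p)
    q[order] = q_sorted
    uniq = np.unique(p)
    for u in uniq:
        m = p == u
        q[m] = q[m].min()
    return q


def track_from_values(lay, chrom, values):
    values = np.asarray(values, dtype=float)
    change = np.concatenate(([True], values[1:] != values[:-1]))
    starts = np.flatnonzero(change)
    return StepTrack(lay, {chrom: (starts.astype(np.int64), values[starts])})


class TestPoissonPvalueTrack:
    def test_hand_value(self, layout):
        chip = StepTrack.constant(layout, 5.0)
        noise = StepTrack.constant(layout, 2.0)
        p = poisson_pvalue_track(chip, noise)
        assert p.values_at("chr1", np.array([0]))[0] == pytest.approx(0.05265, abs=5e-6)

    def test_zero_chip_gives_one(self, layout):
        p = poisson_pvalue_track(
            StepTrack.constant(layout, 0.0), StepTrack.constant(layout, 3.0)
        )
        assert p.values_at("chr1", np.array([0]))[0] == 1.0

    def test_monotone_in_chip(self, layout):
        noise = StepTrack.constant(layout, 4.0)
        ps = [
            poisson_pvalue_track(StepTrack.constant(layout, c), noise)
            .values_at("chr1", np.array([0]))[0]
            for c in (0, 1, 3, 7, 15, 40)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_against_summation_oracle_grid(self, layout):
        chips = np.arange(0, 51)
        noises = np.array([0.5, 2.0, 7.3, 20.0, 49.5])
        for lam in noises:
            noise = StepTrack.constant(layout, float(lam))
            for k in chips:
                p = poisson_pvalue_track(StepTrack.constant(layout, float(k)), noise)
                got = p.values_at("chr1", np.array([0]))[0]
                expect = poisson_tail_oracle(int(k), float(lam))
                assert got == pytest.approx(expect, abs=1e-12, rel=1e-9)

    def test_rounding_half_up(self, layout):
        noise = StepTrack.constant(layout, 2.0)
        p_half = poisson_pvalue_track(StepTrack.constant(layout, 4.5), noise)
        p_five = poisson_pvalue_track(StepTrack.constant(layout, 5.0), noise)
        assert p_half.values_at("chr1", np.array([0]))[0] == p_five.values_at(
            "chr1", np.array([0])
        )[0]

    def test_nonpositive_noise_rejected(self, layout):
        with pytest.raises(ValueError):
            poisson_pvalue_track(
                StepTrack.constant(layout, 1.0), StepTrack.constant(layout, 0.0)
            )


class TestQvalueTrack:
    def test_two_interval_hand_example(self):
        lay = GenomeLayout({"c": 400})
        p = StepTrack(lay, {"c": (np.array([0, 100]), np.array([0.01, 0.04]))})
        score = qvalue_track(p)
        qs = score.q.values_at("c", np.array([0, 100]))
        assert qs[0] == qs[1] == pytest.approx(0.04, rel=1e-12)

    def test_uniform_p_is_identity(self, layout):
        score = qvalue_track(StepTrack.constant(layout, 0.37))
        assert score.q.values_at("chr1", np.array([0]))[0] == 0.37

    def test_monotone_in_p(self):
        lay = GenomeLayout({"c": 1000})
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.001, 1.0, size=20)
        t = track_from_values(lay, "c", np.repeat(vals, 50))
        score = qvalue_track(t)
        pv = per_base(t, "c")
        qv = per_base(score.q, "c")
        order = np.argsort(pv)
        assert (np.diff(qv[order]) >= -1e-15).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_exactly_equals_expanded_bh(self, seed):
        lay = GenomeLayout({"c": 2000})
        rng = np.random.default_rng(seed)
        n_seg = rng.integers(2, 30)
        cuts = np.sort(rng.choice(np.arange(1, 2000), size=n_seg - 1, replace=False))
        starts = np.concatenate(([0], cuts))
        vals = rng.uniform(1e-6, 1.0, size=n_seg)
        t = StepTrack(lay, {"c": (starts, vals)})
        score = qvalue_track(t)
        expect = expanded_bh_oracle(per_base(t, "c"))
        assert np.array_equal(per_base(score.q, "c"), expect)

    def test_invalid_p_rejected(self, layout):
        with pytest.raises(ValueError):
            qvalue_track(StepTrack.constant(layout, 0.0))


def make_score(lay, chrom, qvals):
    """ScoreTrack stand-in from per-segment q values (p = q for tests)."""
    from chipquant.peak_calling import ScoreTrack

    t = track_from_values(lay, chrom, qvals)
    return ScoreTrack(q=t, p=t)


class TestCallPeaks:
    def test_gap_bridging(self):
        lay = GenomeLayout({"c": 2000})
        q = np.ones(2000)
        q[1000:1150] = 0.001
        q[1190:1400] = 0.001
        peaks = call_peaks(make_score(lay, "c", q), PeakCallParams(min_length=100, max_gap=75))
        assert len(peaks) == 1
        r = peaks.df.iloc[0]
        assert (r["start"], r["end"]) == (1000, 1400)

    def test_wide_gap_not_bridged(self):
        lay = GenomeLayout({"c": 2000})
        q = np.ones(2000)
        q[100:400] = 0.001
        q[500:800] = 0.001
        peaks = call_peaks(make_score(lay, "c", q), PeakCallParams(min_length=100, max_gap=75))
        assert len(peaks) == 2

    def test_min_length_filter(self):
        lay = GenomeLayout({"c": 2000})
        q = np.ones(2000)
        q[100:220] = 0.001  # 120 bp
        peaks = call_peaks(make_score(lay, "c", q), PeakCallParams(min_length=200, max_gap=75))
        assert len(peaks) == 0

    def test_summit_leftmost_max_of_chip(self):
        lay = GenomeLayout({"c": 1000})
        q = np.ones(1000)
        q[100:500] = 0.001
        chip = np.ones(1000)
        chip[200:250] = 9.0
        chip[300:350] = 9.0  # tie: leftmost wins
        score = make_score(lay, "c", q)
        peaks = call_peaks(score, PeakCallParams(min_length=100, max_gap=75),
                           chip=track_from_values(lay, "c", chip))
        assert peaks.df.iloc[0]["summit"] == 200
        assert peaks.df.iloc[0]["signal"] == 9.0

    def test_cutoff_monotone_coverage(self):
        lay = GenomeLayout({"c": 5000})
        rng = np.random.default_rng(5)
        q = np.repeat(rng.uniform(0.0001, 1.0, size=100), 50)
        loose = call_peaks(make_score(lay, "c", q), PeakCallParams(q_cutoff=0.05, min_length=10, max_gap=0))
        strict = call_peaks(make_score(lay, "c", q), PeakCallParams(q_cutoff=0.01, min_length=10, max_gap=0))

        def covered(ps):
            bases = set()
            for r in ps.df.itertuples(index=False):
                bases.update(range(r.start, r.end))
            return bases

        assert covered(strict) <= covered(loose)

    def test_narrowpeak_round_trip(self, tmp_path):
        lay = GenomeLayout({"c": 1000})
        q = np.ones(1000)
        q[100:500] = 1e-5
        score = make_score(lay, "c", q)
        peaks = call_peaks(score, PeakCallParams(min_length=100, max_gap=75))
        p = tmp_path / "p.narrowPeak"
        peaks.to_narrowpeak(p)
        back = PeakSet.from_narrowpeak(p)
        assert back.df[["chrom", "start", "end", "summit"]].equals(
            peaks.df[["chrom", "start", "end", "summit"]]
        )


class TestMergeConditionPeaks:
    def _ps(self, intervals):
        import pandas as pd

        rows = [
            (c, s, e, s, 1.0, 1.0, 1.0, 1.0) for c, s, e in intervals
        ]
        return PeakSet(pd.DataFrame(rows, columns=PeakSet.COLUMNS))

    def test_overlapping_merge(self):
        cons = merge_condition_peaks(
            {"A": self._ps([("c", 100, 200)]), "B": self._ps([("c", 150, 300)])}
        )
        assert cons.df[["start", "end"]].values.tolist() == [[100, 300]]
        assert cons.df.iloc[0]["conditions"] == "A,B"

    def test_abutting_stay_separate(self):
        cons = merge_condition_peaks(
            {"A": self._ps([("c", 100, 200)]), "B": self._ps([("c", 200, 300)])}
        )
        assert len(cons) == 2

    def test_single_input_identity(self):
        ps = self._ps([("c", 10, 50), ("c", 100, 160)])
        cons = merge_condition_peaks({"A": ps})
        assert cons.df[["start", "end"]].values.tolist() == [[10, 50], [100, 160]]
        assert set(cons.df["conditions"]) == {"A"}

    def test_chain_of_overlaps_collapses(self):
        cons = merge_condition_peaks(
            {
                "A": self._ps([("c", 0, 100), ("c", 150, 260)]),
                "B": self._ps([("c", 90, 160)]),
            }
        )
        assert cons.df[["start", "end"]].values.tolist() == [[0, 260]]
        assert cons.df.iloc[0]["conditions"] == "A,B"
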