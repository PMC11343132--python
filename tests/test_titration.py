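"""Novelty classification, score binning, paired scatters and slope fits."""

import numpy as np
import pytest

from crosspeak.intervals import GenomicInterval, Peak, PeakSet, merge_master_probes
from crosspeak.titration import (
    ConditionSeries,
    PairedScores,
    bin_by_score,
    classify_novelty,
    fit_slope,
    paired_scores,
)
from oracles import ols_normal_equations


def peak(chrom, start, end, pid, score=10.0):
    return Peak(GenomicInterval(chrom, start, end), pid, score, 0.001)


def series_from(levels):
    sets = [
        PeakSet(f"level{i}", peaks, level=i, level_value=float(i))
        for i, peaks in enumerate(levels)
    ]
    return ConditionSeries("test", sets)


class TestNovelty:
    def test_requires_two_levels_and_increasing_values(self):
        with pytest.raises(ValueError):
            ConditionSeries("t", [PeakSet("a", [])])
        with pytest.raises(ValueError):
            ConditionSeries(
                "t",
                [PeakSet("a", [], level_value=1.0), PeakSet("b", [], level_value=1.0)],
            )

    def test_level0_all_new(self):
        s = series_from([[peak("c", 0, 100, "a"), peak("c", 500, 600, "b")], []])
        calls = classify_novelty(s)
        assert all(c.label == "new" for c in calls if c.level == 0)

    def test_probe_occupied_earlier_makes_later_peak_previous(self):
        # probe occupied at levels 1 and 2 only: new at 1, previous at 2
        s = series_from(
            [
                [peak("c", 5000, 5100, "l0")],
                [peak("c", 0, 100, "l1")],
                [peak("c", 50, 160, "l2"), peak("c", 9000, 9100, "l2b")],
            ]
        )
        labels = {(c.level, c.peak_id): c.label for c in classify_novelty(s)}
        assert labels[(1, "l1")] == "new"
        assert labels[(2, "l2")] == "previous"
        assert labels[(2, "l2b")] == "new"

    def test_adjacent_mode_only_consults_previous_level(self):
        # occupied at level 0, absent at level 1, back at level 2
        s = series_from(
            [[peak("c", 0, 100, "l0")], [peak("c", 5000, 5100, "l1")], [peak("c", 20, 120, "l2")]]
        )
        all_lower = {(c.level, c.peak_id): c.label for c in classify_novelty(s)}
        adjacent = {
            (c.level, c.peak_id): c.label for c in classify_novelty(s, against="adjacent")
        }
        assert all_lower[(2, "l2")] == "previous"
        assert adjacent[(2, "l2")] == "new"

    def test_matches_generator_first_appearance_exactly(self, small_bundle):
        series = ConditionSeries("titration", list(small_bundle.level_sets))
        calls = classify_novelty(series)
        truth = small_bundle.truth_peaks.set_index("peak_id")["first_level"].to_dict()
        for c in calls:
            expected = "new" if truth[c.peak_id] == c.level else "previous"
            assert c.label == expected

    def test_novelty_monotone_and_counts_sum(self, small_bundle):
        series = ConditionSeries("titration", list(small_bundle.level_sets))
        calls = classify_novelty(series)
        per_level = {ps.level: [c for c in calls if c.level == ps.level] for ps in series.sets}
        for ps in series.sets:
            n_new = sum(1 for c in per_level[ps.level] if c.label == "new")
            n_prev = sum(1 for c in per_level[ps.level] if c.label == "previous")
            assert n_new + n_prev == len(ps)
        # once occupied, always previous afterwards
        probes = merge_master_probes(series.sets)
        first = {}
        for c in calls:
            idx = probes.probe_index_of(f"level{c.level}", c.peak_id)
            if c.label == "new":
                first.setdefault(idx, c.level)
        for c in calls:
            idx = probes.probe_index_of(f"level{c.level}", c.peak_id)
            if c.level > first.get(idx, c.level):
                assert c.label == "previous"


class TestBinning:
    def _fake_set(self, n, rng):
        peaks = [
            peak("c", 1000 * i, 1000 * i + 100, f"p{i}", score=float(rng.uniform(1, 100)))
            for i in range(n)
        ]
        return PeakSet("level0", peaks, level=0)

    def test_chunk_sizes(self):
        rng = np.random.default_rng(0)
        ps = self._fake_set(2500, rng)
        bins = bin_by_score(ps, [], bin_size=1000)
        assert [b.n for b in bins] == [1000, 1000, 500]

    def test_all_new_gives_fraction_one(self):
        rng = np.random.default_rng(1)
        ps = self._fake_set(10, rng)
        from crosspeak.titration import NoveltyCall

        calls = [NoveltyCall(pid, 0, "new") for pid in ps.ids]
        assert all(b.fraction_new == 1.0 for b in bin_by_score(ps, calls, bin_size=3))

    def test_fraction_matches_independent_recount(self):
        rng = np.random.default_rng(2)
        ps = self._fake_set(137, rng)
        from crosspeak.titration import NoveltyCall

        labels = {pid: ("new" if rng.random() < 0.4 else "previous") for pid in ps.ids}
        calls = [NoveltyCall(pid, 0, lab) for pid, lab in labels.items()]
        bins = bin_by_score(ps, calls, bin_size=25)
        for b in bins:
            recount = sum(1 for pid in b.peak_ids if labels[pid] == "new") / len(b.peak_ids)
            assert b.fraction_new == pytest.approx(recount)

    def test_bins_are_score_sorted(self):
        rng = np.random.default_rng(3)
        ps = self._fake_set(50, rng)
        bins = bin_by_score(ps, [], bin_size=10)
        by_id = ps.by_id()
        lows = [min(by_id[i].score for i in b.peak_ids) for b in bins]
        highs = [max(by_id[i].score for i in b.peak_ids) for b in bins]
        assert all(h <= l for l, h in zip(lows, highs[1:]))


class TestPairedScores:
    def test_identical_levels_give_equal_scores_and_unit_slope(self):
        peaks = [peak("c", 100 * i, 100 * i + 50, f"p{i}", score=10.0 + i) for i in range(10)]
        s = series_from([peaks, [Peak(p.interval, f"q{i}", p.score, 0.001) for i, p in enumerate(peaks)]])
        pairs = paired_scores(s, 0, 1)
        assert all(lo == hi for _, lo, hi in pairs.rows)
        slope, intercept, r = fit_slope(pairs)
        assert slope == pytest.approx(1.0)

    def test_new_peak_appears_as_vertical_line_row(self):
        s = series_from([[peak("c", 0, 100, "a", 30.0)], [peak("c", 5000, 5100, "b", 40.0)]])
        pairs = paired_scores(s, 0, 1)
        rows = {(lo, hi) for _, lo, hi in pairs.rows}
        assert rows == {(30.0, 0.0), (0.0, 40.0)}

    def test_matches_bruteforce_per_probe_max(self, small_bundle):
        series = ConditionSeries("titration", list(small_bundle.level_sets))
        lo, hi = 1, 2
        pairs = paired_scores(series, lo, hi)
        lo_set, hi_set = series.sets[lo], series.sets[hi]
        probes = merge_master_probes([lo_set, hi_set])
        expected = []
        for probe in probes:
            s_lo = max(
                (p.score for p in lo_set if p.interval.overlaps(probe.interval)), default=0.0
            )
            s_hi = max(
                (p.score for p in hi_set if p.interval.overlaps(probe.interval)), default=0.0
            )
            if s_lo or s_hi:
                expected.append((s_lo, s_hi))
        assert sorted((lo_, hi_) for _, lo_, hi_ in pairs.rows) == sorted(expected)


class TestFitSlope:
    def test_exact_doubling(self):
        rows = [(f"r{i}", float(x), 2.0 * x) for i, x in enumerate([1, 2, 5, 9, 20])]
        slope, intercept, r = fit_slope(PairedScores((0, 1), rows))
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 50, size=200)
        y = 1.7 * x + rng.normal(0, 3, size=200)
        rows = [(f"r{i}", float(a), float(b)) for i, (a, b) in enumerate(zip(x, y))]
        got = fit_slope(PairedScores((0, 1), rows))
        expected = ols_normal_equations(x, y)
        assert got == pytest.approx(expected)

    def test_include_new_changes_row_count(self):
        rows = [("a", 0.0, 10.0), ("b", 5.0, 11.0), ("c", 7.0, 15.0)]
        with_new = fit_slope(PairedScores((0, 1), rows), include_new=True)
        without = fit_slope(PairedScores((0, 1), rows), include_new=False)
        assert with_new != without

    def test_degenerate_constant_x_raises(self):
        rows = [("a", 3.0, 1.0), ("b", 3.0, 2.0)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_slope(PairedScores((0, 1), rows))
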