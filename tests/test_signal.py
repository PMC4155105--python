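"""Quantile normalization, median smoothing and the maxfour statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tilemark as tm
from tilemark.model import ProbeTrack, PromoterWindow, TilemarkError
from tilemark.signal import maxfour_table, MaxfourResult

from test_peaks import line_layout, track_of


class TestQuantileNormalize:
    def test_identical_tracks_are_a_fixed_point(self):
        layout = line_layout(5)
        v = [1.0, -2.0, 0.5, 3.0, 0.0]
        out = tm.quantile_normalize([track_of(layout, v), track_of(layout, v)])
        for t in out:
            assert np.allclose(t.values, v)

    def test_mean_order_statistics_by_hand(self):
        layout = line_layout(3)
        a, b = track_of(layout, [1, 2, 3]), track_of(layout, [4, 5, 6])
        na, nb = tm.quantile_normalize([a, b])
        assert np.allclose(na.values, [2.5, 3.5, 4.5])
        assert np.allclose(nb.values, [2.5, 3.5, 4.5])

    def test_unsorted_tracks_map_through_ranks(self):
        layout = line_layout(3)
        a, b = track_of(layout, [3, 1, 2]), track_of(layout, [40, 60, 50])
        na, nb = tm.quantile_normalize([a, b])
        ref = np.mean([np.sort(a.values), np.sort(b.values)], axis=0)
        assert np.allclose(na.values, [ref[2], ref[0], ref[1]])
        assert np.allclose(nb.values, [ref[0], ref[2], ref[1]])

    def test_ties_stay_tied_midrank(self):
        layout = line_layout(4)
        a = track_of(layout, [0.0, 0.0, 1.0, 2.0])
        b = track_of(layout, [5.0, 6.0, 7.0, 8.0])
        na, _ = tm.quantile_normalize([a, b])
        assert na.values[0] == na.values[1]  # tie preserved
        ref = np.mean([np.sort(a.values), np.sort(b.values)], axis=0)
        assert na.values[0] == pytest.approx(ref[:2].mean())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sorted_vectors_identical_and_ranks_preserved(self, seed):
        rng = np.random.default_rng(seed)
        layout = line_layout(40)
        tracks = [track_of(layout, rng.normal(0, 1, 40)) for _ in range(3)]
        out = tm.quantile_normalize(tracks)
        sorted_vecs = [np.sort(t.values) for t in out]
        for v in sorted_vecs[1:]:
            assert np.allclose(v, sorted_vecs[0])
        for before, after in zip(tracks, out):
            # strict order relations are preserved
            i = np.argsort(before.values, kind="stable")
            assert np.all(np.diff(after.values[i]) >= 0)

    def test_single_track_rejected(self):
        layout = line_layout(3)
        with pytest.raises(TilemarkError):
            tm.quantile_normalize([track_of(layout, [1, 2, 3])])


class TestMedianSmooth:
    @pytest.mark.parametrize(
        "before, after",
        [
            ([1.0] * 5, [1.0] * 5),
            ([0, 10, 0], [0, 0, 0]),
            ([1, 2, 9, 2, 1], [1, 2, 2, 2, 1]),
        ],
    )
    def test_hand_evaluations(self, before, after):
        layout = line_layout(len(before))
        out = tm.median_smooth(track_of(layout, before))
        assert np.allclose(out.values, after)

    def test_tiles_never_smoothed_across_each_other(self, tiny_layout):
        # a spike at the last probe of a tile must survive: it is a tile
        # endpoint even though interior probes of the concatenated array
        # surround it
        v = np.zeros(tiny_layout.n_probes)
        tiles = tiny_layout.tile_ids()
        last_of_first_tile = np.flatnonzero(tiles == tiles[0])[-1]
        v[last_of_first_tile] = 7.0
        out = tm.median_smooth(tm.ProbeTrack("c", "m", v, tiny_layout))
        assert out.values[last_of_first_tile] == 7.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_input_extremes(self, seed):
        rng = np.random.default_rng(seed)
        layout = line_layout(30)
        t = track_of(layout, rng.normal(0, 1, 30))
        out = tm.median_smooth(t)
        assert out.values.max() <= t.values.max()
        assert out.values.min() >= t.values.min()


class TestMaxfour:
    def make(self, values, n_per_window=None):
        layout = line_layout(len(values), chrom="chr1")
        win = PromoterWindow("p1", "g1", "chr1", "+",
                             tss=3500, start=0, end=4250)
        return win, track_of(layout, values), layout

    def test_enumerated_example(self):
        win, t, layout = self.make([0.5, 1.2, 1.3, 1.1, 1.4, 0.2])
        r = tm.maxfour(win, t, layout)
        assert r.value == pytest.approx(1.25)  # run (1.2, 1.3, 1.1, 1.4)
        assert not r.underpowered

    def test_all_zero(self):
        win, t, layout = self.make([0.0] * 6)
        assert tm.maxfour(win, t, layout).value == 0.0

    def test_underpowered_window(self):
        win, t, layout = self.make([1.0, 3.0])
        r = tm.maxfour(win, t, layout)
        assert r.underpowered and r.value == pytest.approx(2.0) and r.n_probes == 2

    def test_probe_free_window_is_missing_not_zero(self, tiny_layout):
        win = PromoterWindow.from_tss("orphan", "chrZ", "+", 10_000)
        t = tm.ProbeTrack("c", "m", np.zeros(tiny_layout.n_probes), tiny_layout)
        r = tm.maxfour(win, t, tiny_layout)
        assert math.isnan(r.value) and r.n_probes == 0

    def test_matches_brute_force_on_random_promoters(self, default_noisy_study):
        # exact agreement with enumeration over all length-4 windows for
        # 1000 promoters
        study = default_noisy_study
        track = study.tracks[("BTSC3", "H3K4me3")]
        table = maxfour_table(study.promoters[:1000], track, study.layout)
        starts, _ = study.layout._arrays()
        for w in study.promoters[:1000]:
            idx = study.layout.probe_indices_in(w.chrom, w.start, w.end)
            v = track.values[idx]
            brute = max(v[i:i + 4].mean() for i in range(len(v) - 3))
            assert table.loc[w.promoter_id, "maxfour"] == pytest.approx(brute, abs=0)


class TestTopRankSet:
    def test_basic_and_full_population(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert tm.top_rank_set(scores, 2) == {"a", "b"}
        assert tm.top_rank_set(scores, 3) == {"a", "b", "c"}

    def test_boundary_tie_broken_lexicographically(self):
        scores = {"z": 5.0, "b": 1.0, "a": 1.0, "c": 1.0}
        got = tm.top_rank_set(scores, 2)
        assert got == {"z", "a"} and len(got) == 2

    def test_oversized_k_rejected(self):
        with pytest.raises(TilemarkError):
            tm.top_rank_set({"a": 1.0}, 2)
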