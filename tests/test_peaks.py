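"""Peak caller: cutoff ladder, window fallbacks, merging, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.model import ArrayLayout, Peak, ProbeTrack, TilemarkError
from tilemark.peaks import PeakCallerParams, cutoff_fdr_table


def line_layout(n, spacing=100, probe_len=50, chrom="chr1"):
    """A single run of n probes on one chromosome."""
    starts = np.arange(n) * spacing
    probes = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": chrom,
        "start": starts,
        "end": starts + probe_len,
        "tile": "T1",
    })
    return ArrayLayout(
        probes=probes,
        promoter_tiles=pd.DataFrame(columns=["promoter_id", "chrom", "strand", "tss"]),
        long_regions=pd.DataFrame(columns=["region_id", "chrom", "start", "end"]),
        spacing=spacing,
    )


def track_of(layout, values):
    return ProbeTrack("c", "m", np.asarray(values, float), layout)


class TestTheoreticalMaximum:
    def test_all_zero_track(self):
        layout = line_layout(10)
        assert tm.theoretical_maximum(track_of(layout, np.zeros(10))) == 0.0

    def test_matches_two_pass_oracle(self):
        layout = line_layout(1000)
        v = np.random.default_rng(3).normal(0.1, 0.5, 1000)
        # independent two-pass computation
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        got = tm.theoretical_maximum(track_of(layout, v))
        assert got == pytest.approx(mean + 6 * sd, abs=1e-12)

    def test_empty_track_rejected(self):
        layout = line_layout(2)
        t = track_of(layout, [0, 0])
        t.values = np.empty(0)
        with pytest.raises(TilemarkError):
            tm.theoretical_maximum(t)


class TestCallPeaks:
    def test_flat_zero_track_yields_no_peaks(self):
        layout = line_layout(1000)
        assert tm.call_peaks(track_of(layout, np.zeros(1000)), layout) == []

    def test_negative_ceiling_yields_no_peaks(self):
        # mean so negative that mean + 6 SD <= 0: cutoffs would invert sign
        layout = line_layout(100)
        v = np.full(100, -5.0)
        v[::2] = -5.001
        assert tm.call_peaks(track_of(layout, v), layout) == []

    def test_six_planted_probes_on_zero_background(self):
        # hand evaluation: only the 6 probes at +10 exceed any cutoff of the
        # ceiling; every 500 bp window over them holds >=4 qualifying probes,
        # so one peak spanning exactly probes 500..505 results
        layout = line_layout(1000)
        v = np.zeros(1000)
        v[500:506] = 10.0
        peaks = tm.call_peaks(track_of(layout, v), layout)
        assert len(peaks) == 1
        (p,) = peaks
        assert (p.start, p.end) == (500 * 100, 505 * 100 + 50)
        assert p.n_probes == 6
        assert p.score == pytest.approx(10.0)
        assert p.best_cutoff == 0.90  # 0.9 * ceiling < 10 here

    def test_fallback_to_three_probes_in_sparse_window(self):
        # at 200 bp spacing a 500 bp window holds only 3 probes, so the
        # primary requirement of 4 cannot be met and the first fallback (3)
        # applies; 3 hot probes still become a peak
        layout = line_layout(500, spacing=200)
        v = np.zeros(500)
        v[250:253] = 10.0
        peaks = tm.call_peaks(track_of(layout, v), layout)
        assert len(peaks) == 1
        assert peaks[0].n_probes == 3

    def test_two_hot_probes_too_sparse_for_any_window(self):
        # 600 bp spacing: a 500 bp window holds a single probe; no fallback
        # can be satisfied (minimum is 2), so nothing is called
        layout = line_layout(200, spacing=600)
        v = np.zeros(200)
        v[100:102] = 10.0
        assert tm.call_peaks(track_of(layout, v), layout) == []

    def test_lowering_the_cutoff_only_adds_qualifying_probes(self, default_noisy_study):
        # monotonicity: at a higher cutoff every qualifying probe also
        # qualifies at any lower cutoff, so window counts can only shrink
        # as the cutoff rises
        study = default_noisy_study
        track = study.tracks[("BTSC1", "H3K27me3")]
        tmax = tm.theoretical_maximum(track)
        from tilemark.peaks import _Geometry

        geom = _Geometry(study.layout, PeakCallerParams())
        prev = None
        for c in PeakCallerParams().cutoff_fractions:  # decreasing
            mask = geom.qualifying_mask(track.values, c * tmax)
            if prev is not None:
                assert np.all(mask[prev])
            prev = mask

    def test_peak_calling_invariant_to_input_file_order(self, tmp_path, tiny_layout):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.3, tiny_layout.n_probes)
        v[10:16] += 3.0
        track = ProbeTrack("c", "m", v, tiny_layout)
        from tilemark.io import read_probe_track, write_probe_track

        path = tmp_path / "t.tsv"
        write_probe_track(track, path)
        lines = path.read_text().splitlines()
        head, body = lines[:2], lines[2:]
        rng.shuffle(body)
        path.write_text("\n".join(head + body) + "\n")
        shuffled = read_probe_track(path, tiny_layout)
        a = tm.call_peaks(track, tiny_layout)
        b = tm.call_peaks(shuffled, tiny_layout)
        assert [(p.start, p.end, p.best_cutoff) for p in a] == \
            [(p.start, p.end, p.best_cutoff) for p in b]


class TestFdr:
    def test_identity_permutation_gives_fdr_one(self):
        layout = line_layout(1000)
        v = np.zeros(1000)
        v[500:506] = 10.0
        params = PeakCallerParams(n_randomizations=1)
        peaks = tm.estimate_fdr(track_of(layout, v), layout, params,
                                permutations=[np.arange(1000)])
        assert all(p.fdr == 1.0 for p in peaks)

    def test_strong_planted_peak_has_zero_fdr(self):
        # permutations scatter the 6 hot probes; 4 of them landing within
        # one 500 bp window is vanishingly unlikely, so randomized counts
        # are 0 and the peak's FDR is 0
        layout = line_layout(1000)
        v = np.zeros(1000)
        v[500:506] = 10.0
        peaks = tm.estimate_fdr(track_of(layout, v), layout, PeakCallerParams(seed=1))
        assert len(peaks) == 1 and peaks[0].fdr == 0.0

    def test_fdr_reproducible_with_fixed_seed(self, default_noisy_study):
        study = default_noisy_study
        track = study.tracks[("BTSC2", "H3K9me3")]
        params = PeakCallerParams(seed=9, n_randomizations=5)
        a = tm.estimate_fdr(track, study.layout, params)
        b = tm.estimate_fdr(track, study.layout, params)
        assert [(p.start, p.fdr) for p in a] == [(p.start, p.fdr) for p in b]

    def test_cutoff_table_shapes_and_undefined_levels(self):
        layout = line_layout(1000)
        v = np.zeros(1000)
        v[500:506] = 10.0
        table = cutoff_fdr_table(track_of(layout, v), layout, PeakCallerParams(seed=0))
        assert list(table["cutoff"]) == list(PeakCallerParams().cutoff_fractions)
        assert (table["n_observed"] == 1).all()  # one planted peak at every level
        assert (table["fdr"] == 0.0).all()


class TestFilterStringent:
    def test_threshold_is_strict(self):
        peaks = [Peak("c", i * 1000, i * 1000 + 500, 0.9, 1.0, 4, fdr=f)
                 for i, f in enumerate([0.0, 0.19, 0.2, 0.9])]
        kept = tm.filter_stringent(peaks, 0.2)
        assert [p.fdr for p in kept] == [0.0, 0.19]

    def test_empty_input_and_permissive_threshold(self):
        assert tm.filter_stringent([], 0.2) == []
        peaks = [Peak("c", 0, 500, 0.9, 1.0, 4, fdr=1.0)]
        assert tm.filter_stringent(peaks, 1.01) == peaks

    def test_stringent_subset_of_generous(self, default_noisy_study):
        study = default_noisy_study
        track = study.tracks[("fNSC", "meC")]
        peaks = tm.estimate_fdr(track, study.layout, PeakCallerParams(seed=2))
        stringent = tm.filter_stringent(peaks)
        ids = {(p.chrom, p.start, p.end) for p in peaks}
        assert all((p.chrom, p.start, p.end) in ids for p in stringent)
        assert len(stringent) <= len(peaks)
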