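"""Layout geometry, planted-signal simulation and truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.model import TilemarkError
from tilemark.synthetic import NoiseModel, TruthTable, TRUTH_COLUMNS, _TruthBuilder


def _truth_rows(rows):
    b = _TruthBuilder()
    for r in rows:
        b.add(*r)
    return b.table()


class TestBuildLayout:
    def test_single_promoter_tile_has_101_probes(self):
        layout = tm.build_layout(1, 0, spacing=100)
        assert layout.n_probes == 101
        span = layout.probes["start"].max() - layout.probes["start"].min()
        assert span == 10_000

    def test_megabase_long_region_probe_count(self):
        layout = tm.build_layout(0, 1, long_region_length=1_000_000, spacing=100)
        assert layout.n_probes == 10_001

    def test_promoter_tiles_pairwise_disjoint(self):
        layout = tm.build_layout(2000, 0)
        g = layout.probes.groupby("tile")
        tiles = pd.DataFrame({
            "chrom": g["chrom"].first(),
            "start": g["start"].min(),
            "end": g["end"].max(),
        })
        # exhaustive pairwise interval check within each chromosome
        for _, sub in tiles.groupby("chrom"):
            s = sub["start"].to_numpy()[:, None]
            e = sub["end"].to_numpy()[:, None]
            overlap = (s < e.T) & (s.T < e)
            np.fill_diagonal(overlap, False)
            assert not overlap.any()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_promoters=-1), dict(n_promoters=1, spacing=0),
         dict(n_promoters=1, spacing=-100), dict(n_promoters=1, spacing=300)],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(TilemarkError):
            tm.build_layout(**{"n_promoters": 1, **kwargs})

    def test_promoter_free_layout_allowed(self):
        layout = tm.build_layout(0, 1, 100_000)
        assert len(layout.promoter_tiles) == 0 and layout.n_probes == 1001


class TestSimulateTracks:
    def test_zero_noise_amplitudes_are_exact(self, tiny_layout):
        win = tm.promoter_windows(tiny_layout)[0]
        s, e = win.tss - 1000, win.tss - 400  # 6 probes at 100 bp spacing
        truth = _truth_rows([("focal_peak", "c1", "H3K4me3", win.chrom, s, e, 2.0, win.promoter_id)])
        tracks = tm.simulate_tracks(tiny_layout, truth, NoiseModel(sigma=0.0, baseline=0.1),
                                    ["c1"], ["H3K4me3"])
        v = tracks[("c1", "H3K4me3")].values
        covered = tiny_layout.probe_indices_in(win.chrom, s, e)
        assert covered.size == 6
        assert np.allclose(v[covered], 2.1)
        mask = np.ones(v.size, bool)
        mask[covered] = False
        assert np.allclose(v[mask], 0.1)

    def test_same_seed_is_bit_identical_distinct_seeds_differ(self, tiny_layout):
        noise = NoiseModel(sigma=0.3, seed=42)
        a = tm.simulate_tracks(tiny_layout, TruthTable.empty(), noise, ["c1"], ["m"])
        b = tm.simulate_tracks(tiny_layout, TruthTable.empty(), noise, ["c1"], ["m"])
        c = tm.simulate_tracks(tiny_layout, TruthTable.empty(),
                               NoiseModel(sigma=0.3, seed=43), ["c1"], ["m"])
        assert np.array_equal(a[("c1", "m")].values, b[("c1", "m")].values)
        assert not np.array_equal(a[("c1", "m")].values, c[("c1", "m")].values)

    def test_background_sample_sd_matches_noise_model(self):
        # chi-square bounds: for n=500 draws at sigma=0.3 the sample SD lies
        # in [0.25, 0.35] except with negligible probability
        layout = tm.build_layout(5, 0)  # 505 probes
        tracks = tm.simulate_tracks(layout, TruthTable.empty(),
                                    NoiseModel(sigma=0.3, baseline=0.0, seed=7),
                                    ["c1"], ["m"])
        sd = np.std(tracks[("c1", "m")].values[:500], ddof=1)
        assert 0.25 <= sd <= 0.35

    def test_feature_outside_tiled_space_names_feature(self, tiny_layout):
        truth = _truth_rows([("focal_peak", "c1", "m", "chr1", 10**7, 10**7 + 600, 2.0, "P00000")])
        with pytest.raises(TilemarkError, match="F000001"):
            tm.simulate_tracks(tiny_layout, truth, NoiseModel(sigma=0.0), ["c1"], ["m"])

    def test_undeclared_cell_type_rejected(self, tiny_layout):
        win = tm.promoter_windows(tiny_layout)[0]
        truth = _truth_rows([("focal_peak", "ghost", "m", win.chrom,
                              win.tss, win.tss + 600, 2.0, win.promoter_id)])
        with pytest.raises(TilemarkError, match="ghost"):
            tm.simulate_tracks(tiny_layout, truth, NoiseModel(sigma=0.0), ["c1"], ["m"])


class TestStudyDesign:
    def test_default_design_matches_stated_conditions(self):
        d = tm.StudyDesign()
        assert d.n_promoters == 2000
        assert d.n_long_regions == 4 and d.long_region_length == 500_000
        assert len(d.cell_types) == 5 and len(d.marks) == 4
        assert d.sigma == 0.3 and d.focal_amplitude == 2.0

    def test_h3k9me3_prevalence_reduced_in_one_cell(self, small_zero_study):
        truth = small_zero_study.truth
        low = len(truth.positive_promoters("BTSC2", "H3K9me3"))
        others = [len(truth.positive_promoters(c, "H3K9me3"))
                  for c in ("fNSC", "BTSC1", "BTSC3", "BTSC4")]
        assert low < 0.55 * min(others)

    def test_truth_bivalent_morphologies_planted(self, small_zero_study):
        truth = small_zero_study.truth
        ref = truth.bivalent_truth("fNSC", ("H3K4me3", "H3K27me3"))
        kinds = set(ref.values())
        assert kinds == {"bivalent_overlapping", "bivalent_adjacent"}

    def test_broad_domains_exceed_50kb(self, small_zero_study):
        f = small_zero_study.truth.features
        broad = f[f["feature_kind"] == "broad_domain"]
        assert len(broad) > 0
        assert ((broad["end"] - broad["start"]) > 50_000).all()
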