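"""Bivalent promoter calling, overlap morphology and resolution."""

import numpy as np
import pandas as pd
import pytest

import tilemark as tm
from tilemark.bivalent import (
    call_bivalent,
    classify_overlap,
    resolve_vs_reference,
)
from tilemark.model import Peak, PromoterWindow, TilemarkError
from tilemark.promoters import MarkCallMatrix


WIN = PromoterWindow("p1", "g1", "chr1", "+", 10_000, 6500, 10_750)


def peak(start, end, chrom="chr1"):
    return Peak(chrom, start, end, 0.9, 1.5, 4)


def make_matrix(states, cells, marks=("K4", "K27")):
    """states: {(pid, cell, mark): (n_peaks, maxfour)}"""
    pids = sorted({p for p, _, _ in states})
    rows = []
    for p in pids:
        for c in cells:
            for m in marks:
                n, mf = states.get((p, c, m), (0, 0.0))
                rows.append((p, c, m, n >= 1, n, mf, "generous"))
    entries = pd.DataFrame(
        rows, columns=["promoter_id", "cell_type", "mark", "positive",
                       "n_peaks", "maxfour", "peak_set_kind"],
    ).set_index(["promoter_id", "cell_type", "mark"]).sort_index()
    return MarkCallMatrix(entries, tuple(cells), tuple(marks), tuple(pids))


class TestCallBivalent:
    def test_both_arms_required(self):
        m = make_matrix({
            ("p1", "A", "K4"): (1, 1.8), ("p1", "A", "K27"): (1, 1.2),  # bivalent
            ("p2", "A", "K4"): (1, 1.8), ("p2", "A", "K27"): (1, 0.9),  # maxfour fails
            ("p3", "A", "K4"): (1, 1.8), ("p3", "A", "K27"): (0, 1.5),  # no peak
            ("p4", "A", "K4"): (1, 1.0), ("p4", "A", "K27"): (1, 1.5),  # 1.0 is not > 1.0
        }, cells=["A"])
        calls = call_bivalent(m, ("K4", "K27"), "A")
        assert {c.promoter_id for c in calls} == {"p1"}

    def test_missing_maxfour_skipped_with_warning(self):
        m = make_matrix({
            ("p1", "A", "K4"): (1, np.nan), ("p1", "A", "K27"): (1, 1.5),
        }, cells=["A"])
        with pytest.warns(UserWarning, match="under-powered|missing maxfour"):
            assert call_bivalent(m, ("K4", "K27"), "A") == []


class TestClassifyOverlap:
    def test_separate_peaks_inside_window(self):
        a = [peak(6600, 6700)]
        b = [peak(6800, 6900)]
        assert classify_overlap(WIN, a, b) == "non_overlapping"

    def test_overlapping_peaks(self):
        a = [peak(6600, 6750)]
        b = [peak(6700, 6900)]
        assert classify_overlap(WIN, a, b) == "overlapping"

    def test_peak_past_window_edge_not_assessable(self):
        a = [peak(6400, 6700)]  # starts before the window
        b = [peak(6800, 6900)]
        assert classify_overlap(WIN, a, b) == "not_assessable"

    def test_abutting_peaks_do_not_overlap(self):
        a = [peak(6600, 6700)]
        b = [peak(6700, 6800)]
        assert classify_overlap(WIN, a, b) == "non_overlapping"

    def test_peaks_outside_window_are_not_contributing(self):
        a = [peak(6600, 6700), peak(20_000, 20_500)]  # second never touches
        b = [peak(6800, 6900)]
        assert classify_overlap(WIN, a, b) == "non_overlapping"

    def test_empty_mark_contradicts_precondition(self):
        with pytest.raises(TilemarkError):
            classify_overlap(WIN, [peak(6600, 6700)], [])


class TestResolution:
    CELLS = ["R", "B1", "B2", "B3", "B4"]

    def full_states(self, fates):
        """fates: pid -> per-group-cell (k4_pos, k27_pos, maxfours ok)."""
        states = {}
        for pid, per_cell in fates.items():
            states[(pid, "R", "K4")] = (1, 1.8)
            states[(pid, "R", "K27")] = (1, 1.8)
            for c, (k4, k27) in zip(self.CELLS[1:], per_cell):
                states[(pid, c, "K4")] = (1 if k4 else 0, 1.8 if k4 else 0.0)
                states[(pid, c, "K27")] = (1 if k27 else 0, 1.8 if k27 else 0.0)
        return states

    def test_categories_assigned_and_disjoint(self):
        B = (True, True)
        A = (True, False)
        P = (False, True)
        L = (False, False)
        fates = {
            "biv": [B, B, B, B],
            "act": [A, A, A, A],
            "rep": [P, P, P, P],
            "gone": [L, L, L, L],
            "mixed": [A, A, A, B],   # 3 cells resolved, 1 still bivalent
            "mixed2": [A, P, L, B],
        }
        m = make_matrix(self.full_states(fates), cells=self.CELLS)
        ref = {c.promoter_id for c in call_bivalent(m, ("K4", "K27"), "R")}
        assert ref == set(fates)
        rep = resolve_vs_reference(ref, m, ("K4", "K27"), self.CELLS[1:])
        assert rep.bivalent_in_all == {"biv"}
        assert rep.to_active_only_in_all == {"act"}
        assert rep.to_repressive_only_in_all == {"rep"}
        assert rep.lost_both_in_all == {"gone"}
        assert rep.other == {"mixed", "mixed2"}
        cats = [rep.bivalent_in_all, rep.to_active_only_in_all,
                rep.to_repressive_only_in_all, rep.lost_both_in_all, rep.other]
        assert sum(len(c) for c in cats) == len(set().union(*cats)) == len(ref)

    def test_brute_force_category_oracle(self):
        rng = np.random.default_rng(5)
        fates = {
            f"p{i:02d}": [tuple(rng.random(2) < 0.5) for _ in range(4)]
            for i in range(40)
        }
        m = make_matrix(self.full_states(fates), cells=self.CELLS)
        ref = set(fates)
        rep = resolve_vs_reference(ref, m, ("K4", "K27"), self.CELLS[1:])
        for pid, per_cell in fates.items():
            if all(k4 and k27 for k4, k27 in per_cell):
                assert pid in rep.bivalent_in_all
            elif all(k4 and not k27 for k4, k27 in per_cell):
                assert pid in rep.to_active_only_in_all
            elif all(k27 and not k4 for k4, k27 in per_cell):
                assert pid in rep.to_repressive_only_in_all
            elif all(not k4 and not k27 for k4, k27 in per_cell):
                assert pid in rep.lost_both_in_all
            else:
                assert pid in rep.other


class TestZeroNoiseMorphology:
    def test_planted_morphologies_recovered_exactly(self, small_zero_study):
        """Adjacent-mark promoters classify non_overlapping, overlapping
        promoters overlapping — 100% agreement with the planted truth."""
        study = small_zero_study
        params = tm.PeakCallerParams(seed=0, n_randomizations=1)
        windows = {w.promoter_id: w for w in study.promoters}
        for pair in [("H3K4me3", "H3K27me3"), ("H3K4me3", "H3K9me3")]:
            for cell in ("fNSC", "BTSC3"):
                truth = study.truth.bivalent_truth(cell, pair)
                if not truth:
                    continue
                pa = tm.call_peaks(study.tracks[(cell, pair[0])], study.layout, params)
                pb = tm.call_peaks(study.tracks[(cell, pair[1])], study.layout, params)
                for pid, kind in truth.items():
                    got = classify_overlap(windows[pid], pa, pb)
                    expected = ("overlapping" if kind == "bivalent_overlapping"
                                else "non_overlapping")
                    assert got == expected, (pid, kind, got)
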