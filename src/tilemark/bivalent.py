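"""Conservative bivalent-promoter calling and overlap morphology.

A promoter is bivalent for a mark pair (active H3K4me3 plus a repressive
mark) only under two independent lines of evidence for *each* mark: at
least one called peak overlaps the promoter window AND the maxfour score
exceeds the positivity threshold.  Bivalent promoters are then classified
by peak morphology — overlapping marks vs marks occupying separate parts of
the window — and tracked across cell types relative to a reference cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .model import Peak, PromoterWindow, TilemarkError, overlaps
from .promoters import MarkCallMatrix
from .signal import ScoreParams

__all__ = [
    "BivalentCall",
    "ResolutionReport",
    "call_bivalent",
    "classify_overlap",
    "classify_calls",
    "resolve_vs_reference",
]

OVERLAP_CLASSES = ("overlapping", "non_overlapping", "not_assessable")


@dataclass
class BivalentCall:
    promoter_id: str
    mark_pair: tuple[str, str]
    cell_type: str
    overlap_class: str | None = None


def call_bivalent(
    matrix: MarkCallMatrix,
    mark_pair: tuple[str, str],
    cell_type: str,
    params: ScoreParams | None = None,
) -> list[BivalentCall]:
    """Promoters peak-positive AND maxfour-positive for both marks.

    Promoters with a missing maxfour for either mark (under-powered windows)
    are skipped with a warning.
    """
    params = params or ScoreParams()
    a, b = mark_pair
    mf_a = matrix.maxfour_series(cell_type, a)
    mf_b = matrix.maxfour_series(cell_type, b)
    pos_a = matrix.positives(cell_type, a)
    pos_b = matrix.positives(cell_type, b)
    skipped = 0
    calls = []
    for pid in matrix.promoter_ids:
        va, vb = mf_a[pid], mf_b[pid]
        if math.isnan(va) or math.isnan(vb):
            if pid in pos_a and pid in pos_b:
                skipped += 1
            continue
        if (
            pid in pos_a
            and pid in pos_b
            and va > params.positive_threshold
            and vb > params.positive_threshold
        ):
            calls.append(BivalentCall(pid, tuple(mark_pair), cell_type))
    if skipped:
        warnings.warn(
            f"{skipped} peak-positive promoters skipped in bivalent calling "
            "(missing maxfour)",
            stacklevel=2,
        )
    return calls


def _window_peaks(promoter: PromoterWindow, peaks: Sequence[Peak]) -> list[Peak]:
    return [
        p
        for p in peaks
        if p.chrom == promoter.chrom and overlaps(p.start, p.end, promoter.start, promoter.end)
    ]


def classify_overlap(
    promoter: PromoterWindow,
    peaks_mark_a: Sequence[Peak],
    peaks_mark_b: Sequence[Peak],
) -> str:
    """Overlap morphology of the two marks' peaks inside one promoter.

    Only promoters whose contributing peaks lie entirely within the window
    are assessable; otherwise the apparent morphology could be an artifact
    of peak mass outside the window.
    """
    in_a = _window_peaks(promoter, peaks_mark_a)
    in_b = _window_peaks(promoter, peaks_mark_b)
    if not in_a or not in_b:
        raise TilemarkError(
            f"{promoter.promoter_id}: both marks must contribute at least one "
            "overlapping peak (bivalent precondition)"
        )
    for p in in_a + in_b:
        if p.start < promoter.start or p.end > promoter.end:
            return "not_assessable"
    for pa in in_a:
        for pb in in_b:
            if overlaps(pa.start, pa.end, pb.start, pb.end):
                return "overlapping"
    return "non_overlapping"


def classify_calls(
    calls: Sequence[BivalentCall],
    promoters_by_id: Mapping[str, PromoterWindow],
    peaks_mark_a: Sequence[Peak],
    peaks_mark_b: Sequence[Peak],
) -> list[BivalentCall]:
    """Fill ``overlap_class`` for every call, in place."""
    for c in calls:
        c.overlap_class = classify_overlap(
            promoters_by_id[c.promoter_id], peaks_mark_a, peaks_mark_b
        )
    return list(calls)


@dataclass(frozen=True)
class ResolutionReport:
    """Fates of reference-bivalent promoters across a group of cell types.

    Categories are pairwise disjoint and cover the reference set: still
    bivalent everywhere, resolved to the active mark only (poised for
    activation), resolved to the repressive mark only, both marks lost
    everywhere, or mixed outcomes ("other").  Mark positivity here is
    peak-positivity; the maxfour arm applies only to the bivalent
    definition itself.
    """

    mark_pair: tuple[str, str]
    reference_bivalent: frozenset[str]
    bivalent_in_all: frozenset[str]
    to_active_only_in_all: frozenset[str]
    to_repressive_only_in_all: frozenset[str]
    lost_both_in_all: frozenset[str]
    other: frozenset[str]

    def __post_init__(self) -> None:
        cats = [
            self.bivalent_in_all,
            self.to_active_only_in_all,
            self.to_repressive_only_in_all,
            self.lost_both_in_all,
            self.other,
        ]
        total = sum(len(c) for c in cats)
        union = frozenset().union(*cats)
        if total != len(union) or not union <= self.reference_bivalent:
            raise TilemarkError("resolution categories must partition the reference set")

    def counts(self) -> dict[str, int]:
        return {
            "reference_bivalent": len(self.reference_bivalent),
            "bivalent_in_all": len(self.bivalent_in_all),
            "to_active_only_in_all": len(self.to_active_only_in_all),
            "to_repressive_only_in_all": len(self.to_repressive_only_in_all),
            "lost_both_in_all": len(self.lost_both_in_all),
            "other": len(self.other),
        }


def resolve_vs_reference(
    reference_bivalent: set[str],
    matrix: MarkCallMatrix,
    mark_pair: tuple[str, str],
    group_cell_types: Sequence[str],
    params: ScoreParams | None = None,
) -> ResolutionReport:
    """Categorize each reference-bivalent promoter across the group cells."""
    params = params or ScoreParams()
    a, b = mark_pair
    biv_by_cell = {
        c: {call.promoter_id for call in call_bivalent(matrix, mark_pair, c, params)}
        for c in group_cell_types
    }
    pos_a = {c: matrix.positives(c, a) for c in group_cell_types}
    pos_b = {c: matrix.positives(c, b) for c in group_cell_types}

    cats: dict[str, set[str]] = {
        "bivalent_in_all": set(),
        "to_active_only_in_all": set(),
        "to_repressive_only_in_all": set(),
        "lost_both_in_all": set(),
        "other": set(),
    }
    for pid in reference_bivalent:
        if all(pid in biv_by_cell[c] for c in group_cell_types):
            cats["bivalent_in_all"].add(pid)
        elif all(pid in pos_a[c] and pid not in pos_b[c] for c in group_cell_types):
            cats["to_active_only_in_all"].add(pid)
        elif all(pid in pos_b[c] and pid not in pos_a[c] for c in group_cell_types):
            cats["to_repressive_only_in_all"].add(pid)
        elif all(pid not in pos_a[c] and pid not in pos_b[c] for c in group_cell_types):
            cats["lost_both_in_all"].add(pid)
        else:
            cats["other"].add(pid)
    return ResolutionReport(
        mark_pair=tuple(mark_pair),
        reference_bivalent=frozenset(reference_bivalent),
        bivalent_in_all=frozenset(cats["bivalent_in_all"]),
        to_active_only_in_all=frozenset(cats["to_active_only_in_all"]),
        to_repressive_only_in_all=frozenset(cats["to_repressive_only_in_all"]),
        lost_both_in_all=frozenset(cats["lost_both_in_all"]),
        other=frozenset(cats["other"]),
    )
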