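"""Broad-modification domains (> 50 kb) in long tiled regions.

Broad domains — continuously modified stretches of chromosomal space — are
mechanistically distinct from focal peaks and are detected here with an
explicit, reproducible rule: within each long tiled region, probes are
binarized against an occupancy threshold, runs of positive probes with
gaps up to a tolerance are merged, and merged spans strictly longer than
the minimum length are reported.  Cross-cell-type differential calls flag
regions whose broad domain in one cell is mostly uncovered in another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ArrayLayout, BroadRegion, ProbeTrack, TilemarkError
from .peaks import DEFAULT_CUTOFFS, theoretical_maximum

__all__ = ["BroadParams", "segment_broad", "differential_broad", "differential_summary"]


@dataclass(frozen=True)
class BroadParams:
    min_length: int = 50_000          # strict >
    gap_tolerance: int = 5_000        # bp bridged between positive probes
    #: absolute log2 threshold; None ties it to the peak caller's most
    #: generous cutoff (lowest ladder fraction x theoretical maximum)
    occupancy_threshold: float | None = None
    occupancy_fraction: float = min(DEFAULT_CUTOFFS)
    #: minimum fraction of positive probes across a merged span; enforces
    #: "continuously modified" — without it, sparse noise probes chained by
    #: the gap tolerance would masquerade as domains
    min_occupancy: float = 0.5
    differential_coverage_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise TilemarkError("min_length must be positive")
        if self.gap_tolerance < 0:
            raise TilemarkError("gap_tolerance must be >= 0")
        if not (0 < self.differential_coverage_fraction <= 1):
            raise TilemarkError("differential_coverage_fraction must be in (0, 1]")
        if not (0 <= self.min_occupancy <= 1):
            raise TilemarkError("min_occupancy must be in [0, 1]")

    def threshold_for(self, track: ProbeTrack) -> float:
        if self.occupancy_threshold is not None:
            return self.occupancy_threshold
        return self.occupancy_fraction * theoretical_maximum(track)


def segment_broad(
    track: ProbeTrack, layout: ArrayLayout, params: BroadParams | None = None
) -> list[BroadRegion]:
    """Detect broad domains of one track inside the layout's long regions."""
    params = params or BroadParams()
    if len(layout.long_regions) == 0:
        warnings.warn("layout declares no long regions; nothing to segment", stacklevel=2)
        return []
    thr = params.threshold_for(track)
    starts, ends = layout._arrays()
    out: list[BroadRegion] = []
    for r in layout.long_regions.itertuples():
        idx = layout.probe_indices_in(r.chrom, int(r.start), int(r.end))
        if idx.size == 0:
            continue
        v = track.values[idx]
        pos = np.flatnonzero(v > thr)
        if pos.size == 0:
            continue
        gidx = idx[pos]
        gaps = starts[gidx[1:]] - ends[gidx[:-1]]
        run_break = np.flatnonzero(gaps > params.gap_tolerance) + 1
        for run in np.split(np.arange(pos.size), run_break):
            first, last = gidx[run[0]], gidx[run[-1]]
            span_start, span_end = int(starts[first]), int(ends[last])
            if span_end - span_start <= params.min_length:
                continue
            span_probes = np.arange(first, last + 1)
            if run.size / span_probes.size < params.min_occupancy:
                continue
            out.append(
                BroadRegion(
                    region_id=str(r.region_id),
                    chrom=str(r.chrom),
                    start=span_start,
                    end=span_end,
                    mark=track.mark,
                    cell_type=track.cell_type,
                    mean_signal=float(track.values[span_probes].mean()),
                    fraction_probes_positive=float(run.size / span_probes.size),
                    n_probes=int(span_probes.size),
                )
            )
    return out


def _covered_fraction(region: BroadRegion, others: Sequence[BroadRegion]) -> float:
    covered = 0
    for o in others:
        if o.chrom != region.chrom:
            continue
        covered += max(0, min(region.end, o.end) - max(region.start, o.start))
    return covered / region.length


@dataclass(frozen=True)
class DifferentialCall:
    region: BroadRegion
    cell_present: str
    cell_absent: str
    coverage_fraction: float


def differential_broad(
    regions_by_cell: Mapping[str, Sequence[BroadRegion]],
    params: BroadParams | None = None,
) -> list[DifferentialCall]:
    """Pairwise cross-cell differential calls on broad domains.

    A domain of cell A is differential against cell B when B's same-mark
    broad domains cover less than ``differential_coverage_fraction`` of it.
    """
    params = params or BroadParams()
    if len(regions_by_cell) < 2:
        raise TilemarkError("differential analysis needs at least 2 cell types")
    calls = []
    for cell_a, regions in regions_by_cell.items():
        for region in regions:
            for cell_b, others in regions_by_cell.items():
                if cell_b == cell_a:
                    continue
                same_mark = [o for o in others if o.mark == region.mark]
                frac = _covered_fraction(region, same_mark)
                if frac < params.differential_coverage_fraction:
                    calls.append(DifferentialCall(region, cell_a, cell_b, frac))
    return calls


def differential_summary(
    regions_by_cell: Mapping[str, Sequence[BroadRegion]],
    layout: ArrayLayout,
    marks: Sequence[str],
    params: BroadParams | None = None,
) -> pd.DataFrame:
    """Per-(long region, mark): does any cell pair differ?

    Mirrors an "N of M surveyed regions differ" tally, with one row per
    (declared long region, mark).
    """
    calls = differential_broad(regions_by_cell, params) if len(regions_by_cell) >= 2 else []
    flagged = {(c.region.region_id, c.region.mark) for c in calls}
    rows = []
    for r in layout.long_regions.itertuples():
        for m in marks:
            rows.append(
                {
                    "region_id": r.region_id,
                    "mark": m,
                    "differential": (r.region_id, m) in flagged,
                }
            )
    return pd.DataFrame(rows, columns=["region_id", "mark", "differential"])
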