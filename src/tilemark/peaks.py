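"""Sliding-window peak calling with a cutoff ladder and permutation FDR.

The procedure mirrors the classic tiling-array workflow: a per-track
"theoretical maximum" is set at the track mean plus six standard deviations;
candidate windows of fixed genomic width must contain at least 4 probes
above a cutoff (falling back to 3, then 2, when the window holds fewer
probes); the cutoff is stepped down a ladder of fractions of the theoretical
maximum (90% ... 15%), and the union over the ladder is the "generous" peak
set.  A per-cutoff false discovery rate is estimated by permuting the probe
values across the whole track and re-counting peaks; filtering at
FDR < 0.2 yields the "stringent" set.

Design notes
------------
* SD is the sample standard deviation (n-1 denominator).
* If the theoretical maximum is <= 0 (possible with a sufficiently negative
  track mean) no peaks are called: a non-positive ceiling would invert the
  sign of the cutoff ladder.
* A probe qualifies on strict inequality (value > cutoff * maximum).
* Windows are anchored at each probe start; qualifying probes from all
  qualifying windows are unioned and maximal runs with inter-probe gaps
  <= the window width merge into one peak, whose bounds run from the first
  qualifying probe start to the last qualifying probe end.
* Randomization permutes values over the whole track.  The permutation does
  not change the mean or SD, so the cutoff ladder is identical for observed
  and randomized data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import ArrayLayout, Peak, ProbeTrack, TilemarkError

__all__ = [
    "PeakCallerParams",
    "theoretical_maximum",
    "call_peaks",
    "estimate_fdr",
    "cutoff_fdr_table",
    "filter_stringent",
]

DEFAULT_CUTOFFS = (0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30, 0.25, 0.20, 0.15)


@dataclass(frozen=True)
class PeakCallerParams:
    window_bp: int = 500
    min_probes_primary: int = 4
    min_probes_fallbacks: tuple[int, ...] = (3, 2)
    cutoff_fractions: tuple[float, ...] = DEFAULT_CUTOFFS
    n_randomizations: int = 20
    fdr_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise TilemarkError("window_bp must be positive")
        if self.n_randomizations < 1:
            raise TilemarkError("n_randomizations must be >= 1")
        cf = self.cutoff_fractions
        if not cf or any(not (0 < c <= 1) for c in cf):
            raise TilemarkError("cutoff fractions must lie in (0, 1]")
        if any(b >= a for a, b in zip(cf, cf[1:])):
            raise TilemarkError("cutoff fractions must be strictly decreasing")
        if self.min_probes_primary < 2:
            raise TilemarkError("min_probes_primary must be >= 2")
        if any(f >= self.min_probes_primary or f < 2 for f in self.min_probes_fallbacks):
            raise TilemarkError("fallbacks must be in [2, min_probes_primary)")


def theoretical_maximum(track: ProbeTrack) -> float:
    """Track mean plus six sample standard deviations."""
    v = track.values
    if v.size == 0:
        raise TilemarkError("cannot compute a theoretical maximum of an empty track")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)) + 6.0 * sd


class _Geometry:
    """Window geometry of a layout, independent of probe values.

    Precomputes, for the window anchored at every probe, the half-open probe
    index range it covers and the number of above-cutoff probes it requires
    (primary count or the first applicable fallback).  Windows never cross
    chromosomes.
    """

    def __init__(self, layout: ArrayLayout, params: PeakCallerParams) -> None:
        self.layout = layout
        self.window_bp = params.window_bp
        n = layout.n_probes
        self.starts, self.ends = layout._arrays()
        self.hi = np.empty(n, dtype=np.int64)
        self.chrom_code = np.empty(n, dtype=np.int32)
        for code, (chrom, sl) in enumerate(layout.chrom_slices().items()):
            s = self.starts[sl]
            self.hi[sl] = sl.start + np.searchsorted(s, s + params.window_bp, side="left")
            self.chrom_code[sl] = code
        n_in = self.hi - np.arange(n)
        ladder = (params.min_probes_primary, *params.min_probes_fallbacks)
        req = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
        for r in ladder:  # primary first, then fallbacks in declared order
            unset = req == np.iinfo(np.int64).max
            req[unset & (n_in >= r)] = r
        self.req = req

    def qualifying_mask(self, values: np.ndarray, threshold: float) -> np.ndarray:
        """Probes that are above threshold and inside a qualifying window."""
        above = values > threshold
        cum = np.concatenate(([0], np.cumsum(above)))
        n = values.size
        n_above = cum[self.hi] - cum[:n]
        qual_win = np.flatnonzero(n_above >= self.req)
        delta = np.zeros(n + 1, dtype=np.int32)
        delta[qual_win] += 1
        np.subtract.at(delta, self.hi[qual_win], 1)
        covered = np.cumsum(delta[:n]) > 0
        return above & covered

    def runs(self, mask: np.ndarray) -> list[np.ndarray]:
        """Maximal runs of masked probes with inter-probe gap <= window width."""
        j = np.flatnonzero(mask)
        if j.size == 0:
            return []
        new = np.ones(j.size, dtype=bool)
        new[1:] = (self.chrom_code[j[1:]] != self.chrom_code[j[:-1]]) | (
            self.starts[j[1:]] - self.ends[j[:-1]] > self.window_bp
        )
        return np.split(j, np.flatnonzero(new)[1:])

    def count_runs(self, mask: np.ndarray) -> int:
        j = np.flatnonzero(mask)
        if j.size == 0:
            return 0
        breaks = (self.chrom_code[j[1:]] != self.chrom_code[j[:-1]]) | (
            self.starts[j[1:]] - self.ends[j[:-1]] > self.window_bp
        )
        return int(breaks.sum()) + 1


def _check_track(track: ProbeTrack, layout: ArrayLayout) -> None:
    if track.layout is not layout and track.values.size != layout.n_probes:
        raise TilemarkError("track does not match layout")


def _assemble_peaks(
    geom: _Geometry,
    values: np.ndarray,
    masks: Sequence[np.ndarray],
    cutoffs: Sequence[float],
) -> list[Peak]:
    n = values.size
    # highest ladder level (lowest index) at which each probe qualifies
    best_level = np.full(n, -1, dtype=np.int32)
    union = np.zeros(n, dtype=bool)
    for i, m in enumerate(masks):
        best_level[(best_level == -1) & m] = i
        union |= m
    chroms = geom.layout.probes["chrom"].to_numpy()
    peaks = []
    for members in geom.runs(union):
        level = int(best_level[members].min())
        peaks.append(
            Peak(
                chrom=str(chroms[members[0]]),
                start=int(geom.starts[members[0]]),
                end=int(geom.ends[members[-1]]),
                best_cutoff=float(cutoffs[level]),
                score=float(values[members].mean()),
                n_probes=int(members.size),
            )
        )
    return peaks


def call_peaks(
    track: ProbeTrack, layout: ArrayLayout, params: PeakCallerParams | None = None
) -> list[Peak]:
    """Call the generous peak set (union over the whole cutoff ladder)."""
    params = params or PeakCallerParams()
    _check_track(track, layout)
    tmax = theoretical_maximum(track)
    if tmax <= 0:
        return []
    geom = _Geometry(layout, params)
    masks = [geom.qualifying_mask(track.values, c * tmax) for c in params.cutoff_fractions]
    return _assemble_peaks(geom, track.values, masks, params.cutoff_fractions)


def _fdr_internal(
    track: ProbeTrack,
    layout: ArrayLayout,
    params: PeakCallerParams,
    permutations: Sequence[np.ndarray] | None,
) -> tuple[list[Peak], pd.DataFrame]:
    _check_track(track, layout)
    cutoffs = params.cutoff_fractions
    empty_table = pd.DataFrame(
        {"cutoff": list(cutoffs), "n_observed": 0, "mean_randomized": np.nan, "fdr": np.nan}
    )
    tmax = theoretical_maximum(track)
    if tmax <= 0:
        return [], empty_table
    geom = _Geometry(layout, params)
    thresholds = [c * tmax for c in cutoffs]
    masks = [geom.qualifying_mask(track.values, t) for t in thresholds]
    obs_counts = np.array([geom.count_runs(m) for m in masks], dtype=np.float64)
    peaks = _assemble_peaks(geom, track.values, masks, cutoffs)

    if permutations is None:
        perms: Iterable[np.ndarray] = (
            np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(r,)))
            .permutation(track.values.size)
            for r in range(params.n_randomizations)
        )
    else:
        perms = permutations
    rand_counts = []
    for perm in perms:
        shuffled = track.values[np.asarray(perm)]
        rand_counts.append(
            [geom.count_runs(geom.qualifying_mask(shuffled, t)) for t in thresholds]
        )
    mean_rand = np.asarray(rand_counts, dtype=np.float64).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.minimum(1.0, mean_rand / obs_counts)
    fdr[obs_counts == 0] = np.nan  # undefined: no observed peaks at that level

    level_of = {c: i for i, c in enumerate(cutoffs)}
    for p in peaks:
        p.fdr = float(fdr[level_of[p.best_cutoff]])
    table = pd.DataFrame(
        {
            "cutoff": list(cutoffs),
            "n_observed": obs_counts.astype(int),
            "mean_randomized": mean_rand,
            "fdr": fdr,
        }
    )
    return peaks, table


def estimate_fdr(
    track: ProbeTrack,
    layout: ArrayLayout,
    params: PeakCallerParams | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> list[Peak]:
    """Call generous peaks and annotate each with its permutation FDR.

    The FDR of a cutoff level is min(1, mean randomized peak count /
    observed peak count) over ``n_randomizations`` seeded whole-track
    permutations; each peak inherits the FDR of its best cutoff.
    ``permutations`` may supply explicit permutation index arrays (testing).
    """
    params = params or PeakCallerParams()
    return _fdr_internal(track, layout, params, permutations)[0]


def cutoff_fdr_table(
    track: ProbeTrack,
    layout: ArrayLayout,
    params: PeakCallerParams | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-cutoff observed/randomized peak counts and FDR."""
    params = params or PeakCallerParams()
    return _fdr_internal(track, layout, params, permutations)[1]


def filter_stringent(peaks: Sequence[Peak], fdr_threshold: float = 0.2) -> list[Peak]:
    """Peaks with FDR strictly below the threshold, order preserved."""
    return [p for p in peaks if p.fdr < fdr_threshold]
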