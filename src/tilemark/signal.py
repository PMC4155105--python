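"""Track preprocessing and promoter scoring.

Quantile normalization (across same-mark arrays), a three-point median
smooth confined to contiguous tiles, and the maxfour promoter statistic:
the largest mean over four consecutive in-window probes, with > 1.0 log2
(i.e. > 2-fold) scoring the promoter "maxfour positive".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ArrayLayout, ProbeTrack, PromoterWindow, TilemarkError

__all__ = [
    "ScoreParams",
    "quantile_normalize",
    "median_smooth",
    "maxfour",
    "maxfour_table",
    "top_rank_set",
    "MaxfourResult",
]


@dataclass(frozen=True)
class ScoreParams:
    maxfour_window: int = 4          # consecutive probes in the scan
    positive_threshold: float = 1.0  # log2 units; strict >
    smooth_width: int = 3
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.positive_threshold):
            raise TilemarkError("positive_threshold must be finite")
        if self.top_k is not None and self.top_k <= 0:
            raise TilemarkError("top_k must be positive")


def quantile_normalize(tracks: Sequence[ProbeTrack]) -> list[ProbeTrack]:
    """Quantile-normalize tracks of one mark onto their mean distribution.

    Every output track has the same sorted value vector: the mean of the
    input order statistics.  Within-track rank order is preserved; tied
    input values receive the mean of the reference values their rank block
    spans (midrank method), so ties stay tied.
    """
    if len(tracks) < 2:
        raise TilemarkError("quantile normalization requires at least 2 tracks")
    n = tracks[0].values.size
    if any(t.values.size != n or t.layout is not tracks[0].layout for t in tracks[1:]):
        raise TilemarkError("all tracks must share one layout")
    reference = np.mean([np.sort(t.values) for t in tracks], axis=0)
    out = []
    for t in tracks:
        order = np.argsort(t.values, kind="stable")
        mapped = np.empty(n, dtype=np.float64)
        # midrank tie handling: average the reference values inside each
        # block of tied input values
        sv = t.values[order]
        block_id = np.cumsum(np.concatenate(([True], sv[1:] != sv[:-1]))) - 1
        sums = np.bincount(block_id, weights=reference)
        counts = np.bincount(block_id)
        tied_mean = (sums / counts)[block_id]
        mapped[order] = tied_mean
        out.append(t.with_values(mapped))
    return out


def median_smooth(track: ProbeTrack) -> ProbeTrack:
    """Three-point median smooth within each contiguous tile.

    The first and last probe of every tile are copied unchanged; tiles
    (promoter tiles, long regions) are never smoothed across each other.
    """
    v = track.values
    out = v.copy()
    tiles = track.layout.tile_ids()
    n = v.size
    if n == 0:
        return track.with_values(out)
    same_prev = np.concatenate(([False], tiles[1:] == tiles[:-1]))
    same_next = np.concatenate((tiles[:-1] == tiles[1:], [False]))
    interior = same_prev & same_next
    idx = np.flatnonzero(interior)
    if idx.size:
        out[idx] = np.median(np.stack([v[idx - 1], v[idx], v[idx + 1]]), axis=0)
    return track.with_values(out)


@dataclass(frozen=True)
class MaxfourResult:
    value: float          # NaN when the window holds no probe
    n_probes: int
    underpowered: bool    # fewer probes than the scan width


def _maxfour_from_values(v: np.ndarray, window: int) -> MaxfourResult:
    if v.size == 0:
        return MaxfourResult(math.nan, 0, True)
    if v.size < window:
        return MaxfourResult(float(v.mean()), int(v.size), True)
    # left-to-right window sums: bit-identical to summing each window directly
    sums = np.zeros(v.size - window + 1)
    for k in range(window):
        sums += v[k:v.size - window + 1 + k]
    return MaxfourResult(float(sums.max() / window), int(v.size), False)


def maxfour(
    promoter: PromoterWindow,
    track: ProbeTrack,
    layout: ArrayLayout,
    window: int = 4,
) -> MaxfourResult:
    """Largest mean of ``window`` consecutive probes inside the promoter.

    Promoters holding fewer than ``window`` probes return the mean of what
    they have, flagged under-powered; promoters with no probes return a
    missing value (never silently 0).
    """
    idx = layout.probe_indices_in(promoter.chrom, promoter.start, promoter.end)
    return _maxfour_from_values(track.values[idx], window)


def maxfour_table(
    promoters: Sequence[PromoterWindow],
    track: ProbeTrack,
    layout: ArrayLayout,
    window: int = 4,
) -> pd.DataFrame:
    """maxfour for every promoter; indexed by promoter_id."""
    rows = {}
    for p in promoters:
        r = maxfour(p, track, layout, window)
        rows[p.promoter_id] = (r.value, r.n_probes, r.underpowered)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["maxfour", "n_probes", "underpowered"]
    )
    df.index.name = "promoter_id"
    return df


def top_rank_set(scores: Mapping[str, float], k: int) -> set[str]:
    """The ``k`` highest-scoring promoter ids.

    Boundary ties are broken by lexicographic promoter id so the result is
    deterministic and has exactly ``k`` members.
    """
    if k > len(scores):
        raise TilemarkError(f"k={k} exceeds the {len(scores)} scored promoters")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {pid for pid, _ in ranked[:k]}
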