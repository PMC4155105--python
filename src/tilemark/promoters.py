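"""Mapping peaks onto proximal promoters and the call matrix.

A promoter is positive for a (cell type, mark) when one or more peaks share
at least one base with its window (half-open semantics; abutment is not
overlap).  The matrix is complete: every promoter appears for every
(cell type, mark) analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Peak, PromoterWindow, TilemarkError

__all__ = ["MarkCallMatrix", "map_peaks_to_promoters", "build_call_matrix"]


def map_peaks_to_promoters(
    peaks: Sequence[Peak], promoters: Sequence[PromoterWindow]
) -> pd.DataFrame:
    """Count overlapping peaks per promoter for one (cell type, mark).

    Returns a frame indexed by promoter_id with columns ``n_peaks`` and
    ``positive``.  A peak overlapping several promoters counts for each;
    peaks on chromosomes absent from the promoter file are ignored with a
    warning.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    prom_chroms = {w.chrom for w in promoters}
    orphans = sorted(set(by_chrom) - prom_chroms)
    if orphans:
        warnings.warn(
            f"peaks on chromosomes without promoters ignored: {orphans[:10]}",
            stacklevel=2,
        )
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ps in by_chrom.items():
        starts = np.sort(np.array([p.start for p in ps], dtype=np.int64))
        ends = np.sort(np.array([p.end for p in ps], dtype=np.int64))
        arrays[chrom] = (starts, ends)

    counts = {}
    for w in promoters:
        got = arrays.get(w.chrom)
        if got is None:
            counts[w.promoter_id] = 0
            continue
        starts, ends = got
        # overlap <=> peak.start < win.end and peak.end > win.start;
        # the two exclusion conditions (start >= win.end, end <= win.start)
        # are mutually exclusive, so counting on the independently sorted
        # start and end arrays is exact for any peak set
        n_start_ok = int(np.searchsorted(starts, w.end, side="left"))
        n_end_low = int(np.searchsorted(ends, w.start, side="right"))
        counts[w.promoter_id] = n_start_ok - n_end_low
    df = pd.DataFrame({"n_peaks": pd.Series(counts, dtype=np.int64)})
    df["positive"] = df["n_peaks"] >= 1
    df.index.name = "promoter_id"
    return df


@dataclass
class MarkCallMatrix:
    """Promoter x cell type x mark call table.

    ``entries`` is a long-format frame indexed by (promoter_id, cell_type,
    mark) with columns ``positive, n_peaks, maxfour, peak_set_kind``.
    """

    entries: pd.DataFrame
    cell_types: tuple[str, ...]
    marks: tuple[str, ...]
    promoter_ids: tuple[str, ...]
    peak_set_kind: str = "generous"

    def __post_init__(self) -> None:
        expected = len(self.promoter_ids) * len(self.cell_types) * len(self.marks)
        if len(self.entries) != expected:
            raise TilemarkError(
                f"matrix has {len(self.entries)} entries, expected {expected} "
                "(one per promoter x cell type x mark)"
            )

    def positives(self, cell_type: str, mark: str) -> set[str]:
        self._check(cell_type, mark)
        sub = self.entries.xs((cell_type, mark), level=("cell_type", "mark"))
        return set(sub.index[sub["positive"]])

    def n_peaks(self, promoter_id: str, cell_type: str, mark: str) -> int:
        return int(self.entries.loc[(promoter_id, cell_type, mark), "n_peaks"])

    def maxfour_value(self, promoter_id: str, cell_type: str, mark: str) -> float:
        return float(self.entries.loc[(promoter_id, cell_type, mark), "maxfour"])

    def maxfour_series(self, cell_type: str, mark: str) -> pd.Series:
        self._check(cell_type, mark)
        return self.entries.xs((cell_type, mark), level=("cell_type", "mark"))["maxfour"]

    def _check(self, cell_type: str, mark: str) -> None:
        if cell_type not in self.cell_types:
            raise TilemarkError(f"unknown cell type {cell_type!r}")
        if mark not in self.marks:
            raise TilemarkError(f"unknown mark {mark!r}")

    def summary_table(self) -> pd.DataFrame:
        """Positive-promoter counts per (cell type, mark)."""
        rows = [
            {
                "cell_type": c,
                "mark": m,
                "n_positive": len(self.positives(c, m)),
                "peak_set_kind": self.peak_set_kind,
            }
            for c in self.cell_types
            for m in self.marks
        ]
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        return self.entries.reset_index()


def build_call_matrix(
    peak_sets: Mapping[tuple[str, str], Sequence[Peak]],
    promoters: Sequence[PromoterWindow],
    maxfour_scores: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
    peak_set_kind: str = "generous",
    cell_types: Sequence[str] | None = None,
    marks: Sequence[str] | None = None,
) -> MarkCallMatrix:
    """Assemble the complete call matrix from per-(cell, mark) peak sets."""
    if cell_types is None:
        cell_types = sorted({c for c, _ in peak_sets})
    if marks is None:
        marks = sorted({m for _, m in peak_sets})
    missing = [(c, m) for c in cell_types for m in marks if (c, m) not in peak_sets]
    if missing:
        raise TilemarkError(f"missing peak sets for combinations: {missing}")
    pids = [w.promoter_id for w in promoters]
    frames = []
    for c in cell_types:
        for m in marks:
            df = map_peaks_to_promoters(peak_sets[(c, m)], promoters)
            df = df.reindex(pids)
            df["cell_type"] = c
            df["mark"] = m
            if maxfour_scores is not None and (c, m) in maxfour_scores:
                mf = maxfour_scores[(c, m)]
                df["maxfour"] = [mf.get(p, np.nan) for p in pids]
            else:
                df["maxfour"] = np.nan
            frames.append(df.reset_index())
    entries = (
        pd.concat(frames, ignore_index=True)
        .set_index(["promoter_id", "cell_type", "mark"])
        .sort_index()
    )
    entries["peak_set_kind"] = peak_set_kind
    return MarkCallMatrix(
        entries=entries[["positive", "n_peaks", "maxfour", "peak_set_kind"]],
        cell_types=tuple(cell_types),
        marks=tuple(marks),
        promoter_ids=tuple(pids),
        peak_set_kind=peak_set_kind,
    )
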