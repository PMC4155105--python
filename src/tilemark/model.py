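"""Core data containers shared across the pipeline.

All genomic coordinates are 0-based half-open ``[start, end)``. "Overlap"
always means sharing at least one base under those semantics; abutting
intervals do not overlap. GFF3 files are converted to/from 1-based inclusive
at the I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TilemarkError",
    "ArrayLayout",
    "ProbeTrack",
    "PromoterWindow",
    "Peak",
    "BroadRegion",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
]

#: proximal-promoter window extent around the TSS, in transcription orientation
PROMOTER_UPSTREAM = 3500
PROMOTER_DOWNSTREAM = 750


class TilemarkError(ValueError):
    """Base class for tilemark domain errors."""


@dataclass(frozen=True)
class ArrayLayout:
    """Fixed probe geometry of a tiling array.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id, chrom, start, end, tile``; sorted
        by (chrom, start), non-overlapping within a chromosome.  ``tile``
        names the contiguous tiled unit the probe belongs to (a promoter tile
        or a long region); smoothing and window scans never cross tiles.
    promoter_tiles
        DataFrame ``promoter_id, chrom, strand, tss`` describing the 10 kb
        tiles (7 kb upstream, 3 kb downstream of the TSS in transcription
        orientation) around each promoter.
    long_regions
        DataFrame ``region_id, chrom, start, end`` of long contiguously
        tiled regions.
    """

    probes: pd.DataFrame
    promoter_tiles: pd.DataFrame
    long_regions: pd.DataFrame
    spacing: int = 100

    def __post_init__(self) -> None:
        req = {"probe_id", "chrom", "start", "end", "tile"}
        if not req.issubset(self.probes.columns):
            raise TilemarkError(f"probe table must have columns {sorted(req)}")
        starts = self.probes["start"].to_numpy()
        ends = self.probes["end"].to_numpy()
        if np.any(ends <= starts):
            raise TilemarkError("probe end must exceed start")
        for _, sl in self.chrom_slices().items():
            s, e = starts[sl], ends[sl]
            if np.any(np.diff(s) <= 0):
                raise TilemarkError("probes must be sorted by start within chromosome")
            if np.any(e[:-1] > s[1:]):
                raise TilemarkError("probes overlap within a chromosome")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        cached = self.__dict__.get("_coord_arrays")
        if cached is None:
            cached = (
                self.probes["start"].to_numpy(dtype=np.int64),
                self.probes["end"].to_numpy(dtype=np.int64),
            )
            object.__setattr__(self, "_coord_arrays", cached)
        return cached

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice of the probe table per chromosome."""
        cached = self.__dict__.get("_chrom_slices")
        if cached is not None:
            return cached
        chroms = self.probes["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chroms):
            change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
            bounds = np.concatenate([[0], change, [len(chroms)]])
            for i in range(len(bounds) - 1):
                c = chroms[bounds[i]]
                if c in out:
                    raise TilemarkError(f"probe table not grouped by chromosome: {c}")
                out[c] = slice(int(bounds[i]), int(bounds[i + 1]))
        object.__setattr__(self, "_chrom_slices", out)
        return out

    def probe_indices_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of probes overlapping ``chrom:[start, end)``, in layout order."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return np.empty(0, dtype=np.intp)
        starts, ends = self._arrays()
        s, e = starts[sl], ends[sl]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.intp)

    def tile_ids(self) -> np.ndarray:
        return self.probes["tile"].to_numpy()


@dataclass
class ProbeTrack:
    """Probe-level log2(ChIP/input) measurements for one (cell type, mark).

    ``values`` is aligned to the layout's probe order, one finite value per
    probe, in log2 enrichment units.
    """

    cell_type: str
    mark: str
    values: np.ndarray
    layout: ArrayLayout = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.layout.n_probes,):
            raise TilemarkError(
                f"track has {self.values.size} values for "
                f"{self.layout.n_probes} layout probes"
            )
        if not np.all(np.isfinite(self.values)):
            raise TilemarkError("track values must be finite")

    def with_values(self, values: np.ndarray) -> "ProbeTrack":
        return ProbeTrack(self.cell_type, self.mark, values, self.layout)


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware proximal-promoter interval anchored at a TSS.

    The window spans 3.5 kb upstream to 750 bp downstream of the TSS in
    transcription orientation; on the minus strand the genomic interval is
    mirrored.
    """

    promoter_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TilemarkError(f"{self.promoter_id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise TilemarkError(f"{self.promoter_id}: end <= start")
        if self.strand == "+":
            ok = self.start == self.tss - PROMOTER_UPSTREAM and self.end == self.tss + PROMOTER_DOWNSTREAM
        else:
            ok = self.start == self.tss - PROMOTER_DOWNSTREAM and self.end == self.tss + PROMOTER_UPSTREAM
        if not ok:
            raise TilemarkError(
                f"{self.promoter_id}: window [{self.start},{self.end}) inconsistent "
                f"with tss={self.tss} strand={self.strand}"
            )

    @classmethod
    def from_tss(
        cls, promoter_id: str, chrom: str, strand: str, tss: int, gene_symbol: str = ""
    ) -> "PromoterWindow":
        if strand == "+":
            start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        elif strand == "-":
            start, end = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
        else:
            raise TilemarkError(f"{promoter_id}: strand must be + or -, got {strand!r}")
        return cls(promoter_id, gene_symbol or promoter_id, chrom, strand, tss, start, end)

    def genomic(self, offset: int) -> int:
        """Genomic coordinate of a TSS-relative offset (negative = upstream)."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


@dataclass
class Peak:
    """A contiguous enriched interval called on one track.

    ``best_cutoff`` is the highest cutoff fraction (of the theoretical
    maximum) at which the peak was detected; ``score`` the mean log2 ratio of
    member probes; ``fdr`` the permutation FDR of its best cutoff level
    (NaN until estimated).
    """

    chrom: str
    start: int
    end: int
    best_cutoff: float
    score: float
    n_probes: int
    fdr: float = math.nan

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise TilemarkError("peak end must exceed start")
        if self.n_probes < 2:
            raise TilemarkError("a peak requires at least 2 probes")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BroadRegion:
    """A continuously modified domain (> min_length) inside one long region."""

    region_id: str
    chrom: str
    start: int
    end: int
    mark: str
    cell_type: str
    mean_signal: float
    fraction_probes_positive: float
    n_probes: int

    @property
    def length(self) -> int:
        return self.end - self.start


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap: at least one shared base."""
    return a_start < b_end and b_start < a_end
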