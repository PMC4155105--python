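"""Synthetic tiled-array studies with planted epigenetic features.

The generator emulates a promoter-centric tiling design: 10 kb promoter
tiles (7 kb upstream / 3 kb downstream of the TSS, 100 bp probe spacing)
plus a handful of long contiguously tiled regions standing in for large
genomic survey regions.  Signal is simulated directly at the log2(ChIP/input)
level: per-probe value = baseline + sum of planted feature amplitudes
covering the probe + i.i.d. Gaussian noise.  Every planted feature is
recorded in a machine-readable truth table so downstream calls can be scored
against known truth.

All randomness flows from one integer seed through counter-based
substreams (``numpy.random.SeedSequence`` spawn keys), one per
(cell type, mark), so adding a track never perturbs another track's noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ArrayLayout, ProbeTrack, PromoterWindow, TilemarkError

__all__ = [
    "NoiseModel",
    "TruthTable",
    "StudyDesign",
    "SimulatedStudy",
    "build_layout",
    "promoter_windows",
    "build_truth",
    "simulate_tracks",
    "simulate_study",
    "default_design",
]

TILE_UPSTREAM = 7000     # bp upstream of TSS covered by a promoter tile
TILE_DOWNSTREAM = 3000   # bp downstream
TILE_LENGTH = TILE_UPSTREAM + TILE_DOWNSTREAM
_SLOT = 25_000           # genomic pitch between promoter tiles
_PROMOTERS_PER_CHROM = 500

FOCAL_KINDS = ("focal_peak", "bivalent_overlapping", "bivalent_adjacent")

TRUTH_COLUMNS = [
    "feature_id",
    "feature_kind",
    "cell_type",
    "mark",
    "chrom",
    "start",
    "end",
    "amplitude",
    "promoter_id",
]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian probe-noise model on the log2-ratio scale.

    ``baseline`` is the background mean.  The default is slightly negative:
    after the global centering applied to two-channel ratio data, enriched
    probes pull the distribution mean up, leaving unenriched background a
    little below zero.
    """

    sigma: float = 0.3
    baseline: float = -0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise TilemarkError("sigma must be >= 0")


@dataclass
class TruthTable:
    """Planted-feature registry for a simulated study.

    One row per (feature, cell type, mark); bivalent promoters contribute
    one row per mark, tagged ``bivalent_overlapping``/``bivalent_adjacent``
    in cell types where both marks are planted and ``focal_peak`` where only
    one survives.
    """

    features: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - set(self.features.columns)
        if missing:
            raise TilemarkError(f"truth table missing columns {sorted(missing)}")
        self.features = self.features[TRUTH_COLUMNS].reset_index(drop=True)

    @classmethod
    def empty(cls) -> "TruthTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            TRUTH_COLUMNS,
            [str, str, str, str, str, np.int64, np.int64, np.float64, str],
        )}))

    def __len__(self) -> int:
        return len(self.features)

    def for_track(self, cell_type: str, mark: str) -> pd.DataFrame:
        f = self.features
        return f[(f["cell_type"] == cell_type) & (f["mark"] == mark)]

    def positive_promoters(self, cell_type: str, mark: str) -> set[str]:
        """Promoters with a planted focal feature for (cell, mark)."""
        f = self.for_track(cell_type, mark)
        f = f[f["feature_kind"].isin(FOCAL_KINDS) & (f["promoter_id"] != "")]
        return set(f["promoter_id"])

    def bivalent_truth(self, cell_type: str, mark_pair: tuple[str, str]) -> dict[str, str]:
        """promoter_id -> morphology for promoters planted bivalent in this cell."""
        a, b = mark_pair
        fa = self.for_track(cell_type, a)
        fb = self.for_track(cell_type, b)
        out: dict[str, str] = {}
        for kind in ("bivalent_overlapping", "bivalent_adjacent"):
            pa = set(fa.loc[fa["feature_kind"] == kind, "promoter_id"])
            pb = set(fb.loc[fb["feature_kind"] == kind, "promoter_id"])
            for p in pa & pb:
                out[p] = kind
        return out

    def broad_domains(self, cell_type: str, mark: str) -> pd.DataFrame:
        f = self.for_track(cell_type, mark)
        return f[f["feature_kind"] == "broad_domain"]

    def expected_bivalent_classes(
        self, layout: ArrayLayout, cell_type: str, mark_pair: tuple[str, str]
    ) -> dict[str, str]:
        """Expected bivalent promoters and morphology at zero noise.

        Any promoter with a planted focal feature for both marks is expected
        bivalent; the expected class follows from whether the probe spans
        covered by the two planted intervals share a base (called peak
        bounds run from the first to the last covered probe).
        """
        starts, ends = layout._arrays()

        def span(row) -> tuple[int, int] | None:
            idx = layout.probe_indices_in(row.chrom, int(row.start), int(row.end))
            if idx.size == 0:
                return None
            return int(starts[idx[0]]), int(ends[idx[-1]])

        a_mark, b_mark = mark_pair
        fa = self.for_track(cell_type, a_mark)
        fb = self.for_track(cell_type, b_mark)
        fa = fa[fa["feature_kind"].isin(FOCAL_KINDS) & (fa["promoter_id"] != "")]
        fb = fb[fb["feature_kind"].isin(FOCAL_KINDS) & (fb["promoter_id"] != "")]
        spans_a = {r.promoter_id: span(r) for r in fa.itertuples()}
        spans_b = {r.promoter_id: span(r) for r in fb.itertuples()}
        out = {}
        for pid in set(spans_a) & set(spans_b):
            sa, sb = spans_a[pid], spans_b[pid]
            if sa is None or sb is None:
                continue
            hit = sa[0] < sb[1] and sb[0] < sa[1]
            out[pid] = "overlapping" if hit else "non_overlapping"
        return out


def build_layout(
    n_promoters: int,
    n_long_regions: int = 0,
    long_region_length: int = 500_000,
    spacing: int = 100,
) -> ArrayLayout:
    """Build a synthetic array layout.

    Promoter tiles span TSS-7000..TSS+3000 in transcription orientation with
    one probe every ``spacing`` bp (``TILE_LENGTH/spacing + 1`` probes);
    long regions are tiled at the same spacing with
    ``long_region_length/spacing + 1`` probes.  Strands alternate +/- so
    both promoter-window orientations are exercised.
    """
    if spacing <= 0:
        raise TilemarkError("spacing must be positive")
    if n_promoters < 0 or n_long_regions < 0:
        raise TilemarkError("counts must be non-negative")
    if TILE_LENGTH % spacing:
        raise TilemarkError(f"spacing must divide the {TILE_LENGTH} bp tile length")
    if n_long_regions and long_region_length % spacing:
        raise TilemarkError("spacing must divide long_region_length")
    probe_len = min(50, spacing)

    records: list[tuple[str, str, int, int, str]] = []
    prom_records = []
    for i in range(n_promoters):
        pid = f"P{i:05d}"
        chrom = f"chr{i // _PROMOTERS_PER_CHROM + 1}"
        slot = (i % _PROMOTERS_PER_CHROM) * _SLOT
        tss = slot + TILE_UPSTREAM
        strand = "+" if i % 2 == 0 else "-"
        first = tss - (TILE_UPSTREAM if strand == "+" else TILE_DOWNSTREAM)
        n = TILE_LENGTH // spacing + 1
        for k in range(n):
            s = first + k * spacing
            records.append((f"{pid}_p{k:04d}", chrom, s, s + probe_len, pid))
        prom_records.append((pid, chrom, strand, tss))

    long_records = []
    for j in range(n_long_regions):
        rid = f"ENC{j + 1:02d}"
        chrom = f"chrL{j + 1}"
        start = 10_000
        n = long_region_length // spacing + 1
        for k in range(n):
            s = start + k * spacing
            records.append((f"{rid}_p{k:06d}", chrom, s, s + probe_len, rid))
        long_records.append((rid, chrom, start, start + long_region_length + probe_len))

    probes = pd.DataFrame(records, columns=["probe_id", "chrom", "start", "end", "tile"])
    promoters = pd.DataFrame(prom_records, columns=["promoter_id", "chrom", "strand", "tss"])
    regions = pd.DataFrame(long_records, columns=["region_id", "chrom", "start", "end"])
    return ArrayLayout(probes=probes, promoter_tiles=promoters, long_regions=regions, spacing=spacing)


def promoter_windows(layout: ArrayLayout) -> list[PromoterWindow]:
    """Proximal-promoter windows (TSS-3500..TSS+750) for every layout promoter."""
    return [
        PromoterWindow.from_tss(r.promoter_id, r.chrom, r.strand, int(r.tss),
                                gene_symbol=f"GENE_{r.promoter_id}")
        for r in layout.promoter_tiles.itertuples()
    ]


def _tile_spans(layout: ArrayLayout) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    g = layout.probes.groupby("tile", sort=False)
    starts = g["start"].min()
    ends = g["end"].max()
    chroms = g["chrom"].first()
    for tile in starts.index:
        spans.setdefault(chroms[tile], []).append((int(starts[tile]), int(ends[tile])))
    for c in spans:
        spans[c].sort()
    return spans


def simulate_tracks(
    layout: ArrayLayout,
    truth: TruthTable,
    noise: NoiseModel,
    cell_types: Sequence[str],
    marks: Sequence[str],
) -> dict[tuple[str, str], ProbeTrack]:
    """Simulate one probe track per (cell type, mark).

    Each probe reads ``baseline + sum(amplitudes of covering features)
    + N(0, sigma)``; identical seeds reproduce identical tracks.  Every truth
    feature must fall inside a tiled portion of the layout and reference a
    declared cell type and mark.
    """
    declared = {(c, m) for c in cell_types for m in marks}
    extra = set(zip(truth.features["cell_type"], truth.features["mark"])) - declared
    if extra:
        raise TilemarkError(f"truth references undeclared (cell, mark) combinations: {sorted(extra)}")

    spans = _tile_spans(layout)
    for row in truth.features.itertuples():
        ok = any(s <= row.start and row.end <= e for s, e in spans.get(row.chrom, ()))
        if not ok:
            raise TilemarkError(
                f"feature {row.feature_id} ({row.chrom}:{row.start}-{row.end}) "
                "lies outside the tiled portion of the layout"
            )

    out: dict[tuple[str, str], ProbeTrack] = {}
    for ci, cell in enumerate(cell_types):
        for mi, mark in enumerate(marks):
            values = np.full(layout.n_probes, noise.baseline, dtype=np.float64)
            for row in truth.for_track(cell, mark).itertuples():
                idx = layout.probe_indices_in(row.chrom, int(row.start), int(row.end))
                values[idx] += row.amplitude
            if noise.sigma > 0:
                ss = np.random.SeedSequence(noise.seed, spawn_key=(1, ci, mi))
                values += np.random.default_rng(ss).normal(0.0, noise.sigma, layout.n_probes)
            out[(cell, mark)] = ProbeTrack(cell, mark, values, layout)
    return out


# ---------------------------------------------------------------------------
# Full study designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BivalentPlan:
    """Planted bivalent promoters for one mark pair, in the reference cell.

    ``fates`` maps each resolution category to the number of
    reference-bivalent promoters following it across the group cell types.
    ``fraction_overlapping`` of each category is planted with overlapping
    peak morphology, the rest with adjacent (same-window, >=1 probe apart)
    morphology.
    """

    mark_pair: tuple[str, str]
    fates: Mapping[str, int]
    fraction_overlapping: float = 0.6

    @property
    def total(self) -> int:
        return int(sum(self.fates.values()))


@dataclass(frozen=True)
class BroadPlanEntry:
    region_index: int
    mark: str
    cell_types: tuple[str, ...]
    rel_start: int
    length: int


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a simulated multi-cell-type epigenome survey."""

    n_promoters: int = 2000
    n_long_regions: int = 4
    long_region_length: int = 500_000
    spacing: int = 100
    cell_types: tuple[str, ...] = ("fNSC", "BTSC1", "BTSC2", "BTSC3", "BTSC4")
    reference_cell_type: str = "fNSC"
    marks: tuple[str, ...] = ("H3K4me3", "H3K27me3", "H3K9me3", "meC")
    #: per-cell fraction of promoters carrying a focal peak, by mark
    focal_prevalence: Mapping[str, float] = field(default_factory=lambda: {
        "H3K4me3": 0.45, "H3K27me3": 0.22, "H3K9me3": 0.12, "meC": 0.30,
    })
    #: multiplicative per-(cell, mark) prevalence overrides; models the
    #: strongly reduced H3K9me3 system activity of one tumor line
    prevalence_scale: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        ("BTSC2", "H3K9me3"): 0.3,
    })
    core_fraction: float = 0.55       # of the smallest per-cell positive count
    gained_fraction: float = 0.02     # positive in every group cell, not reference
    reference_only_fraction: float = 0.04
    focal_width_probes: int = 6
    focal_amplitude: float = 2.0
    broad_amplitude: float = 1.5
    sigma: float = 0.3
    baseline: float = -0.25
    bivalent_plans: tuple[BivalentPlan, ...] = (
        BivalentPlan(("H3K4me3", "H3K27me3"), {
            "bivalent_in_all": 25, "to_active_only_in_all": 30,
            "to_repressive_only_in_all": 25, "lost_both_in_all": 10, "other": 60,
        }),
        BivalentPlan(("H3K4me3", "H3K9me3"), {
            "bivalent_in_all": 12, "to_active_only_in_all": 16,
            "to_repressive_only_in_all": 8, "lost_both_in_all": 4, "other": 40,
        }),
    )
    broad_plan: tuple[BroadPlanEntry, ...] = (
        BroadPlanEntry(0, "H3K27me3", ("fNSC", "BTSC1", "BTSC2", "BTSC3", "BTSC4"), 100_000, 80_000),
        BroadPlanEntry(1, "H3K27me3", ("fNSC", "BTSC1", "BTSC3"), 50_000, 100_000),
        BroadPlanEntry(2, "H3K27me3", ("BTSC2", "BTSC4"), 200_000, 90_000),
        BroadPlanEntry(3, "H3K27me3", ("fNSC",), 300_000, 100_000),
        BroadPlanEntry(3, "H3K9me3", ("BTSC3",), 50_000, 80_000),
    )

    @property
    def group_cell_types(self) -> tuple[str, ...]:
        return tuple(c for c in self.cell_types if c != self.reference_cell_type)

    def with_sigma(self, sigma: float) -> "StudyDesign":
        return dataclasses.replace(self, sigma=sigma)

    def scaled(self, n_promoters: int, n_long_regions: int | None = None) -> "StudyDesign":
        """A smaller (or larger) design with planted counts scaled along.

        Bivalent fate counts scale proportionally with the promoter count;
        broad-plan entries referencing dropped long regions are removed.
        Useful for quick desk-scale runs and tests.
        """
        f = n_promoters / self.n_promoters
        plans = tuple(
            BivalentPlan(
                p.mark_pair,
                {k: int(round(v * f)) for k, v in p.fates.items()},
                p.fraction_overlapping,
            )
            for p in self.bivalent_plans
        )
        n_regions = self.n_long_regions if n_long_regions is None else n_long_regions
        broad = tuple(e for e in self.broad_plan if e.region_index < n_regions)
        return dataclasses.replace(
            self,
            n_promoters=n_promoters,
            n_long_regions=n_regions,
            bivalent_plans=plans,
            broad_plan=broad,
        )


def default_design() -> StudyDesign:
    return StudyDesign()


@dataclass
class SimulatedStudy:
    design: StudyDesign
    layout: ArrayLayout
    truth: TruthTable
    tracks: dict[tuple[str, str], ProbeTrack]
    promoters: list[PromoterWindow]


def _planted_interval(win: PromoterWindow, rel_start: int, width_bp: int) -> tuple[int, int]:
    """Genomic interval of a planted feature given its TSS-relative 5' start."""
    if win.strand == "+":
        return win.tss + rel_start, win.tss + rel_start + width_bp
    return win.tss - rel_start - width_bp, win.tss - rel_start


class _TruthBuilder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self._n = 0

    def add(self, kind: str, cell: str, mark: str, chrom: str, start: int, end: int,
            amplitude: float, promoter_id: str = "") -> None:
        self._n += 1
        self.rows.append((f"F{self._n:06d}", kind, cell, mark, chrom,
                          int(start), int(end), float(amplitude), promoter_id))

    def table(self) -> TruthTable:
        return TruthTable(pd.DataFrame(self.rows, columns=TRUTH_COLUMNS))


def _plan_bivalent(builder: _TruthBuilder, design: StudyDesign, plan: BivalentPlan,
                   windows: dict[str, PromoterWindow], promoter_ids: list[str],
                   rng: np.random.Generator) -> None:
    a_mark, b_mark = plan.mark_pair
    amp = design.focal_amplitude
    w = design.focal_width_probes * design.spacing
    # morphologies: A always at -2000; overlapping B shares two thirds of the
    # span, adjacent B sits 750 bp downstream in the same window
    rel_a, rel_b_over, rel_b_adj = -2000, -1800, -700
    i = 0
    for fate, count in plan.fates.items():
        for j in range(count):
            pid = promoter_ids[i]
            i += 1
            win = windows[pid]
            overlapping = rng.random() < plan.fraction_overlapping
            kind = "bivalent_overlapping" if overlapping else "bivalent_adjacent"
            a0, a1 = _planted_interval(win, rel_a, w)
            b0, b1 = _planted_interval(win, rel_b_over if overlapping else rel_b_adj, w)

            def put(cell: str, with_a: bool, with_b: bool) -> None:
                both = with_a and with_b
                if with_a:
                    builder.add(kind if both else "focal_peak", cell, a_mark,
                                win.chrom, a0, a1, amp, pid)
                if with_b:
                    builder.add(kind if both else "focal_peak", cell, b_mark,
                                win.chrom, b0, b1, amp, pid)

            put(design.reference_cell_type, True, True)
            group = design.group_cell_types
            if fate == "bivalent_in_all":
                for c in group:
                    put(c, True, True)
            elif fate == "to_active_only_in_all":
                for c in group:
                    put(c, True, False)
            elif fate == "to_repressive_only_in_all":
                for c in group:
                    put(c, False, True)
            elif fate == "lost_both_in_all":
                pass
            elif fate == "other":
                for k, c in enumerate(group):
                    put(c, True, k % 2 == 0)  # mixed outcome across group cells
            else:
                raise TilemarkError(f"unknown bivalent fate {fate!r}")


def build_truth(design: StudyDesign, seed: int) -> tuple[ArrayLayout, TruthTable, list[PromoterWindow]]:
    """Build the layout and planted-feature truth table for a study design."""
    layout = build_layout(design.n_promoters, design.n_long_regions,
                          design.long_region_length, design.spacing)
    windows = {w.promoter_id: w for w in promoter_windows(layout)}
    all_ids = sorted(windows)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    builder = _TruthBuilder()

    # --- bivalent promoters first; they are excluded from generic planting
    #     of their own marks
    n_biv = sum(p.total for p in design.bivalent_plans)
    if n_biv > len(all_ids):
        raise TilemarkError("more planted bivalent promoters than promoters")
    biv_ids = list(rng.choice(all_ids, size=n_biv, replace=False))
    reserved: dict[str, set[str]] = {m: set() for m in design.marks}
    pos = 0
    for plan in design.bivalent_plans:
        ids = biv_ids[pos:pos + plan.total]
        pos += plan.total
        for m in plan.mark_pair:
            reserved[m].update(ids)
        _plan_bivalent(builder, design, plan, windows, ids, rng)

    # --- generic focal planting per mark with core / gained / reference-only
    #     / cell-variable structure
    w = design.focal_width_probes * design.spacing
    group = design.group_cell_types
    ref = design.reference_cell_type
    lo = -(3400 // design.spacing)
    hi = (750 - w - 50) // design.spacing
    for mark in design.marks:
        prev = design.focal_prevalence.get(mark, 0.0)
        if prev <= 0:
            continue
        n_pos = {
            c: int(round(prev * design.prevalence_scale.get((c, mark), 1.0) * design.n_promoters))
            for c in design.cell_types
        }
        avail = [p for p in all_ids if p not in reserved[mark]]
        avail = list(rng.permutation(avail))
        n_shared = int(round(design.core_fraction * min(n_pos.values())))
        n_gained = int(round(design.gained_fraction * design.n_promoters))
        n_ref_only = int(round(design.reference_only_fraction * design.n_promoters))
        if n_shared + n_gained + n_ref_only > len(avail):
            raise TilemarkError(f"not enough promoters for mark {mark}")
        shared = avail[:n_shared]
        gained = avail[n_shared:n_shared + n_gained]
        ref_only = avail[n_shared + n_gained:n_shared + n_gained + n_ref_only]
        pool = np.array(avail[n_shared + n_gained + n_ref_only:])

        offsets = {p: int(rng.integers(lo, hi + 1)) * design.spacing for p in avail}
        positives: dict[str, set[str]] = {}
        for c in design.cell_types:
            base = set(shared) | (set(gained) if c in group else set())
            if c == ref:
                base |= set(ref_only)
            n_extra = max(0, n_pos[c] - len(base))
            if n_extra > len(pool):
                raise TilemarkError(f"not enough promoters for extras of {mark}/{c}")
            extras = rng.choice(pool, size=n_extra, replace=False) if n_extra else []
            positives[c] = base | set(extras)
        for c in design.cell_types:
            for pid in sorted(positives[c]):
                win = windows[pid]
                s, e = _planted_interval(win, offsets[pid], w)
                builder.add("focal_peak", c, mark, win.chrom, s, e,
                            design.focal_amplitude, pid)

    # --- broad domains in long regions
    regions = layout.long_regions
    for entry in design.broad_plan:
        if entry.region_index >= len(regions):
            raise TilemarkError("broad plan references a missing long region")
        r = regions.iloc[entry.region_index]
        s = int(r["start"]) + entry.rel_start
        e = s + entry.length
        if e > int(r["end"]):
            raise TilemarkError("planted broad domain exceeds its long region")
        for c in entry.cell_types:
            builder.add("broad_domain", c, entry.mark, r["chrom"], s, e,
                        design.broad_amplitude)

    return layout, builder.table(), list(windows.values())


def simulate_study(design: StudyDesign | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate a full study: layout, truth table and all probe tracks."""
    design = design or StudyDesign()
    layout, truth, windows = build_truth(design, seed)
    noise = NoiseModel(sigma=design.sigma, baseline=design.baseline, seed=seed)
    tracks = simulate_tracks(layout, truth, noise, design.cell_types, design.marks)
    return SimulatedStudy(design, layout, truth, tracks, windows)
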