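"""On-disk formats: probe tracks (GFF3/TSV), promoters (BED), peaks
(BED6+3 with a TSV mirror), truth tables and layouts.

Conventions: all in-memory coordinates are 0-based half-open; BED is native;
GFF3 is converted to 1-based inclusive on write and back on read, losslessly.
Every writer emits a ``# tilemark`` header line carrying the schema name and
version; the genome build is an opaque label carried along in that header.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ArrayLayout, Peak, ProbeTrack, PromoterWindow, TilemarkError
from .synthetic import TRUTH_COLUMNS, TruthTable

__all__ = [
    "ParseError",
    "write_probe_track",
    "read_probe_track",
    "write_promoters",
    "read_promoters",
    "write_peaks",
    "read_peaks",
    "write_truth_table",
    "read_truth_table",
    "write_layout",
    "read_layout",
]

SCHEMA_VERSION = "v1"
_FLOAT_FMT = "{:.17g}"  # lossless for float64


class ParseError(TilemarkError):
    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _header(schema: str, **fields: str) -> str:
    extra = "".join(f" {k}={v}" for k, v in fields.items())
    return f"# tilemark {schema} {SCHEMA_VERSION}{extra}\n"


def _header_fields(line: str) -> dict[str, str]:
    return dict(tok.split("=", 1) for tok in line.split()[4:] if "=" in tok)


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------

def write_probe_track(
    track: ProbeTrack, path: str | Path, fmt: str | None = None, genome: str = "synthetic"
) -> None:
    """Write a probe track as 4-column TSV or GFF3 (chosen by ``fmt`` or suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    layout = track.layout
    probes = layout.probes
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write(_header("probe_track", cell_type=track.cell_type,
                             mark=track.mark, genome=genome))
            fh.write("probe_id\tchrom\tstart\tlog2_ratio\n")
            for pid, chrom, start, v in zip(
                probes["probe_id"], probes["chrom"], probes["start"], track.values
            ):
                fh.write(f"{pid}\t{chrom}\t{start}\t{_FLOAT_FMT.format(v)}\n")
        elif fmt == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(_header("probe_track", cell_type=track.cell_type,
                             mark=track.mark, genome=genome))
            for pid, chrom, start, end, v in zip(
                probes["probe_id"], probes["chrom"], probes["start"],
                probes["end"], track.values,
            ):
                # GFF3 is 1-based inclusive: [start, end) -> (start+1, end)
                fh.write(
                    f"{chrom}\ttilemark\tmicroarray_probe\t{start + 1}\t{end}\t"
                    f"{_FLOAT_FMT.format(v)}\t.\t.\tID={pid}\n"
                )
        else:
            raise TilemarkError(f"unknown track format {fmt!r}")


def read_probe_track(path: str | Path, layout: ArrayLayout) -> ProbeTrack:
    """Read a probe track and align it to ``layout`` by (chrom, start).

    Files missing layout probes, or containing probes the layout lacks, are
    rejected with the first offenders named.
    """
    path = Path(path)
    cell_type, mark = "", ""
    entries: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        all_lines = fh.readlines()
    is_gff = bool(all_lines) and all_lines[0].startswith("##gff-version")
    for lineno, line in enumerate(all_lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# tilemark"):
                f = _header_fields(line)
                cell_type = f.get("cell_type", cell_type)
                mark = f.get("mark", mark)
            continue
        if line.startswith("probe_id\t"):
            continue
        parts = line.split("\t")
        try:
            if is_gff:
                if len(parts) < 9:
                    raise ValueError("expected 9 GFF3 columns")
                chrom = parts[0]
                start = int(parts[3]) - 1  # back to 0-based half-open
                value = float(parts[5])
            else:
                if len(parts) != 4:
                    raise ValueError("expected 4 TSV columns")
                chrom = parts[1]
                start = int(parts[2])
                value = float(parts[3])
        except ValueError as exc:
            raise ParseError(path, lineno, f"malformed line: {exc}") from None
        key = (chrom, start)
        if key in entries:
            raise ParseError(path, lineno, f"duplicate probe at {chrom}:{start}")
        entries[key] = value

    probes = layout.probes
    keys = list(zip(probes["chrom"], probes["start"]))
    missing = [k for k in keys if k not in entries]
    if missing:
        names = [f"{c}:{s}" for c, s in missing[:10]]
        raise TilemarkError(
            f"{path}: file is missing {len(missing)} layout probes "
            f"(first offenders: {', '.join(names)})"
        )
    extra = set(entries) - set(keys)
    if extra:
        names = [f"{c}:{s}" for c, s in sorted(extra)[:10]]
        raise TilemarkError(
            f"{path}: file contains {len(extra)} probes absent from the layout "
            f"(first offenders: {', '.join(names)})"
        )
    values = np.array([entries[k] for k in keys], dtype=np.float64)
    return ProbeTrack(cell_type or "unknown", mark or "unknown", values, layout)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def write_promoters(
    promoters: Sequence[PromoterWindow], path: str | Path, genome: str = "synthetic"
) -> None:
    """Write proximal-promoter windows as extended BED6+2 (gene symbol, TSS)."""
    with open(path, "w") as fh:
        fh.write(_header("promoters", genome=genome))
        for w in promoters:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.promoter_id}\t0\t{w.strand}\t"
                f"{w.gene_symbol}\t{w.tss}\n"
            )


def read_promoters(path: str | Path) -> list[PromoterWindow]:
    """Read promoter windows from BED6 (TSS derived) or extended BED6+2."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, lineno, "expected at least 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end <= start:
                raise ParseError(path, lineno, f"end <= start for {name}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"strand must be + or -, got {strand!r}")
            gene = parts[6] if len(parts) > 6 else name
            if len(parts) > 7:
                tss = int(parts[7])
            else:
                tss = start + 3500 if strand == "+" else end - 3500
            try:
                w = PromoterWindow(name, gene, chrom, strand, tss, start, end)
            except TilemarkError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append(w)
    return out


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def write_peaks(
    peaks: Sequence[Peak],
    prefix: str | Path,
    cell_type: str = "",
    mark: str = "",
    genome: str = "synthetic",
) -> tuple[Path, Path]:
    """Write peaks as BED6+3 plus an exact TSV mirror; returns both paths.

    BED column 5 is a browser display score (1000 * min(1, score/5),
    clamped at 0); columns 7-9 carry the raw mean log2 score, best cutoff
    and FDR.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    with open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        head = _header("peaks", cell_type=cell_type or "NA", mark=mark or "NA", genome=genome)
        bed.write(head)
        tsv.write(head)
        tsv.write("name\tchrom\tstart\tend\tscore\tbest_cutoff\tfdr\tn_probes\n")
        for i, p in enumerate(peaks, start=1):
            name = f"peak_{i:06d}"
            display = int(round(1000 * min(1.0, max(0.0, p.score / 5.0))))
            fdr = "NA" if math.isnan(p.fdr) else _FLOAT_FMT.format(p.fdr)
            bed.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{display}\t.\t"
                f"{_FLOAT_FMT.format(p.score)}\t{p.best_cutoff:g}\t{fdr}\n"
            )
            tsv.write(
                f"{name}\t{p.chrom}\t{p.start}\t{p.end}\t{_FLOAT_FMT.format(p.score)}\t"
                f"{p.best_cutoff:g}\t{fdr}\t{p.n_probes}\n"
            )
    return bed_path, tsv_path


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks back from the TSV mirror written by :func:`write_peaks`."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(path, lineno, "expected 8 TSV columns")
            _, chrom, start, end, score, cutoff, fdr, n_probes = parts
            out.append(
                Peak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    score=float(score),
                    best_cutoff=float(cutoff),
                    fdr=math.nan if fdr == "NA" else float(fdr),
                    n_probes=int(n_probes),
                )
            )
    return out


# ---------------------------------------------------------------------------
# truth tables and layouts
# ---------------------------------------------------------------------------

def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header("truth_table"))
        truth.features.to_csv(fh, sep="\t", index=False)


def read_truth_table(path: str | Path) -> TruthTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False,
        dtype={c: str for c in ("feature_id", "feature_kind", "cell_type",
                                "mark", "chrom", "promoter_id")},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["amplitude"] = df["amplitude"].astype(np.float64)
    return TruthTable(df[TRUTH_COLUMNS])


def write_layout(layout: ArrayLayout, directory: str | Path) -> None:
    """Write a layout as probes.tsv + promoter_tiles.tsv + long_regions.bed."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "probes.tsv", "w") as fh:
        fh.write(_header("layout_probes", spacing=str(layout.spacing)))
        layout.probes.to_csv(fh, sep="\t", index=False)
    with open(d / "promoter_tiles.tsv", "w") as fh:
        fh.write(_header("layout_promoter_tiles"))
        layout.promoter_tiles.to_csv(fh, sep="\t", index=False)
    with open(d / "long_regions.bed", "w") as fh:
        fh.write(_header("layout_long_regions"))
        for r in layout.long_regions.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_layout(directory: str | Path) -> ArrayLayout:
    d = Path(directory)
    spacing = 100
    with open(d / "probes.tsv") as fh:
        first = fh.readline()
        if first.startswith("# tilemark"):
            spacing = int(_header_fields(first).get("spacing", spacing))
    def _read(path: Path, **kw) -> pd.DataFrame:
        try:
            return pd.read_csv(path, sep="\t", comment="#", **kw)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=kw.get("names", []))

    probes = _read(d / "probes.tsv")
    tiles = _read(d / "promoter_tiles.tsv")
    if tiles.empty:
        tiles = pd.DataFrame(columns=["promoter_id", "chrom", "strand", "tss"])
    regions = _read(
        d / "long_regions.bed", names=["chrom", "start", "end", "region_id"]
    )[["region_id", "chrom", "start", "end"]]
    return ArrayLayout(probes=probes, promoter_tiles=tiles,
                       long_regions=regions, spacing=spacing)
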