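"""End-to-end pipeline: simulate -> call peaks -> score -> sets -> bivalent
-> broad, from one config, with provenance.

Every run is deterministic under a fixed (config, seed): all outputs are
reproduced bit-identically, and every output file is stamped with the hash
of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivalent import call_bivalent, classify_calls, resolve_vs_reference
from .broad import BroadParams, differential_summary, segment_broad
from .io import write_layout, write_peaks, write_probe_track, write_promoters, write_truth_table
from .model import TilemarkError
from .peaks import PeakCallerParams, estimate_fdr, filter_stringent
from .promoters import build_call_matrix
from .sets import summarize_mark, summary_counts_table
from .signal import ScoreParams, maxfour_table, median_smooth, quantile_normalize
from .synthetic import StudyDesign, simulate_study

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

STAGES = ("simulate", "peaks", "score", "matrix", "sets", "bivalent", "broad")

BIVALENT_PAIRS = (("H3K4me3", "H3K27me3"), ("H3K4me3", "H3K9me3"))


@dataclass(frozen=True)
class RunConfig:
    out_dir: Path
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    peak_params: PeakCallerParams = field(default_factory=PeakCallerParams)
    score_params: ScoreParams = field(default_factory=ScoreParams)
    broad_params: BroadParams = field(default_factory=BroadParams)
    peak_set_kind: str = "generous"
    write_tracks: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.peak_set_kind not in ("generous", "stringent"):
            raise TilemarkError("peak_set_kind must be 'generous' or 'stringent'")
        d = self.design
        if d.reference_cell_type not in d.cell_types:
            raise TilemarkError("reference_cell_type must be one of cell_types")
        if d.reference_cell_type in d.group_cell_types:
            raise TilemarkError("reference cell type must not be in the group")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        design = StudyDesign(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in data.pop("simulate", {}).items()
        })
        if "group_cell_types" in data:
            group = tuple(data.pop("group_cell_types"))
            if design.reference_cell_type in group:
                raise TilemarkError("reference cell type must not be in the group")
        peak = PeakCallerParams(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in data.pop("peaks", {}).items()
        })
        score = ScoreParams(**data.pop("score", {}))
        broad = BroadParams(**data.pop("broad", {}))
        return cls(
            out_dir=Path(data.pop("out_dir", "tilemark_run")),
            seed=int(data.pop("seed", 0)),
            design=design,
            peak_params=peak,
            score_params=score,
            broad_params=broad,
            peak_set_kind=data.pop("peak_set_kind", "generous"),
            write_tracks=bool(data.pop("write_tracks", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def canon(o: Any) -> Any:
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: canon(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, Mapping):
                return sorted((str(k), canon(v)) for k, v in o.items())
            if isinstance(o, (list, tuple)):
                return [canon(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        blob = json.dumps(
            {f.name: canon(getattr(self, f.name)) for f in dataclasses.fields(self)
             if f.name != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    paths: dict[str, Path]
    counts: dict[str, Any]
    manifest: dict[str, Any]
    # in-memory artifacts for programmatic use
    study: Any = None
    matrix_generous: Any = None
    matrix_stringent: Any = None
    set_summaries: dict[str, Any] = field(default_factory=dict)
    bivalent_calls: dict[tuple, Any] = field(default_factory=dict)
    resolution_reports: dict[tuple, Any] = field(default_factory=dict)
    broad_regions: dict[tuple, Any] = field(default_factory=dict)


def _stamp(path: Path, config_hash: str) -> None:
    text = path.read_text()
    path.write_text(f"# tilemark run config_hash={config_hash}\n{text}")


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tilemark run config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages and write every artifact under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(config_hash=chash, paths={}, counts={}, manifest={})
    stage = "simulate"
    try:
        report = _run_stages(config, out, chash, report)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        stage = getattr(exc, "_tilemark_stage", stage)
        (out / f"failed_{stage}.marker").write_text(str(exc))
        raise TilemarkError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _run_stages(config: RunConfig, out: Path, chash: str, report: RunReport) -> RunReport:
    design = config.design
    cells, marks = design.cell_types, design.marks
    ref, group = design.reference_cell_type, design.group_cell_types
    counts: dict[str, Any] = report.counts

    def in_stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    exc._tilemark_stage = name
                return False

        return _Ctx()

    with in_stage("simulate"):
        study = simulate_study(design, config.seed)
        report.study = study
        write_layout(study.layout, out / "layout")
        write_truth_table(study.truth, out / "truth.tsv")
        write_promoters(study.promoters, out / "promoters.bed")
        for p in (out / "truth.tsv", out / "promoters.bed"):
            _stamp(p, chash)
        report.paths["truth"] = out / "truth.tsv"
        report.paths["promoters"] = out / "promoters.bed"
        if config.write_tracks:
            tdir = out / "tracks"
            tdir.mkdir(exist_ok=True)
            for (c, m), tr in study.tracks.items():
                write_probe_track(tr, tdir / f"{c}_{m}.tsv")

    with in_stage("peaks"):
        pdir = out / "peaks"
        pdir.mkdir(exist_ok=True)
        generous: dict[tuple[str, str], list] = {}
        stringent: dict[tuple[str, str], list] = {}
        for (c, m), tr in study.tracks.items():
            pk = estimate_fdr(tr, study.layout, config.peak_params)
            generous[(c, m)] = pk
            stringent[(c, m)] = filter_stringent(pk, config.peak_params.fdr_threshold)
            bed, tsv = write_peaks(pk, pdir / f"{c}_{m}_generous", cell_type=c, mark=m)
            _stamp(bed, chash)
            _stamp(tsv, chash)
        counts["peaks_generous"] = {f"{c}/{m}": len(v) for (c, m), v in generous.items()}
        counts["peaks_stringent"] = {f"{c}/{m}": len(v) for (c, m), v in stringent.items()}

    with in_stage("score"):
        # preprocessing chain for promoter scoring: quantile normalization
        # across same-mark arrays, then three-point median smoothing
        processed = {}
        for m in marks:
            per_mark = [study.tracks[(c, m)] for c in cells]
            for c, tr in zip(cells, quantile_normalize(per_mark)):
                processed[(c, m)] = median_smooth(tr)
        mf: dict[tuple[str, str], dict[str, float]] = {}
        mf_frames = []
        for (c, m), tr in processed.items():
            table = maxfour_table(study.promoters, tr, study.layout,
                                  config.score_params.maxfour_window)
            mf[(c, m)] = table["maxfour"].to_dict()
            t = table.reset_index()
            t.insert(1, "cell_type", c)
            t.insert(2, "mark", m)
            mf_frames.append(t)
        _write_tsv(pd.concat(mf_frames, ignore_index=True), out / "maxfour.tsv", chash)
        report.paths["maxfour"] = out / "maxfour.tsv"

    with in_stage("matrix"):
        matrix_g = build_call_matrix(generous, study.promoters, mf, "generous",
                                     cell_types=cells, marks=marks)
        matrix_s = build_call_matrix(stringent, study.promoters, mf, "stringent",
                                     cell_types=cells, marks=marks)
        report.matrix_generous = matrix_g
        report.matrix_stringent = matrix_s
        _write_tsv(matrix_g.to_long_frame(), out / "call_matrix_generous.tsv", chash)
        _write_tsv(matrix_g.summary_table(), out / "positive_counts_generous.tsv", chash)
        _write_tsv(matrix_s.summary_table(), out / "positive_counts_stringent.tsv", chash)
        counts["positive_promoters_generous"] = {
            f"{c}/{m}": len(matrix_g.positives(c, m)) for c in cells for m in marks
        }
        counts["positive_promoters_stringent"] = {
            f"{c}/{m}": len(matrix_s.positives(c, m)) for c in cells for m in marks
        }

    matrix = matrix_g if config.peak_set_kind == "generous" else matrix_s

    with in_stage("sets"):
        sdir = out / "sets"
        sdir.mkdir(exist_ok=True)
        summaries = {}
        for m in marks:
            s = summarize_mark(matrix, m, group, ref)
            summaries[m] = s
            rc = s.reference_comparison
            for name, ids in (
                ("core", s.core), ("universe", s.universe),
                ("gained_in_all", rc.gained_in_all),
                ("lost_in_all", rc.lost_in_all),
                ("shared_all_cell_types", rc.shared_all_cell_types),
            ):
                _write_tsv(pd.DataFrame({"promoter_id": sorted(ids)}),
                           sdir / f"{m}_{name}.tsv", chash)
        report.set_summaries = summaries
        _write_tsv(summary_counts_table(list(summaries.values())),
                   out / "set_summary.tsv", chash)
        counts["sets"] = {
            m: {"core": len(s.core), "universe": len(s.universe),
                "gained_in_all": len(s.reference_comparison.gained_in_all),
                "lost_in_all": len(s.reference_comparison.lost_in_all),
                "shared_all_cell_types": len(s.reference_comparison.shared_all_cell_types)}
            for m, s in summaries.items()
        }

    with in_stage("bivalent"):
        bdir = out / "bivalent"
        bdir.mkdir(exist_ok=True)
        windows = {w.promoter_id: w for w in study.promoters}
        pairs = [p for p in BIVALENT_PAIRS if p[0] in marks and p[1] in marks]
        biv_counts: dict[str, Any] = {}
        for pair in pairs:
            a, b = pair
            for c in cells:
                calls = call_bivalent(matrix, pair, c, config.score_params)
                classify_calls(calls, windows, generous[(c, a)], generous[(c, b)])
                report.bivalent_calls[(pair, c)] = calls
                df = pd.DataFrame(
                    [(x.promoter_id, x.overlap_class) for x in calls],
                    columns=["promoter_id", "overlap_class"],
                )
                _write_tsv(df, bdir / f"{a}_{b}_{c}.tsv", chash)
                morph = df["overlap_class"].value_counts().to_dict()
                biv_counts[f"{a}/{b}/{c}"] = {"n_bivalent": len(calls), **morph}
            ref_set = {x.promoter_id for x in report.bivalent_calls[(pair, ref)]}
            res = resolve_vs_reference(ref_set, matrix, pair, group, config.score_params)
            report.resolution_reports[pair] = res
            _write_tsv(pd.DataFrame([res.counts()]), bdir / f"{a}_{b}_resolution.tsv", chash)
            biv_counts[f"{a}/{b}/resolution"] = res.counts()
        counts["bivalent"] = biv_counts

    with in_stage("broad"):
        regions_by_cell = {
            c: [r for m in marks for r in segment_broad(
                study.tracks[(c, m)], study.layout, config.broad_params)]
            for c in cells
        }
        for c, rs in regions_by_cell.items():
            for r in rs:
                report.broad_regions.setdefault((c, r.mark), []).append(r)
        rows = [
            dataclasses.asdict(r) for c in cells for r in regions_by_cell[c]
        ]
        _write_tsv(pd.DataFrame(
            rows, columns=["region_id", "chrom", "start", "end", "mark", "cell_type",
                           "mean_signal", "fraction_probes_positive", "n_probes"]),
            out / "broad_regions.tsv", chash)
        summary = differential_summary(regions_by_cell, study.layout, marks,
                                       config.broad_params)
        _write_tsv(summary, out / "broad_differential.tsv", chash)
        counts["broad_regions"] = {
            f"{c}/{m}": len(v) for (c, m), v in sorted(report.broad_regions.items())
        }
        counts["broad_differential_regions"] = {
            m: int(summary.loc[summary["mark"] == m, "differential"].sum()) for m in marks
        }

    with in_stage("manifest"):
        manifest = {
            "config_hash": chash,
            "seed": config.seed,
            "tilemark_version": __version__,
            "stages": list(STAGES),
            "counts": counts,
            "files": {
                str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report.manifest = manifest
        report.paths["manifest"] = out / "manifest.json"

    return report
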