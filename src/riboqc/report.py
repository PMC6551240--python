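"""Pipeline orchestration, output bundle and HTML report generation.

``run_pipeline`` executes annotation -> P-site offsets -> selected QC
tools -> anomaly screening for a :class:`RunConfig`, writing every table
as TSV, plots as PNG/PDF, and a JSON manifest with a checksum for every
file so that re-runs can be verified byte-for-byte.  ``generate_report``
folds the bundle into one self-contained HTML document with the full
parameter echo and optional user notes.
"""

from __future__ import annotations

import base64
import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import anomalies as anom
from . import qc
from .alignments import AlignmentTable, annotate, load_alignments, filter_and_group
from .genome import parse_annotation
from .offsets import (
    DEFAULT_FALLBACK_OFFSET,
    DEFAULT_MIN_READS,
    DEFAULT_WINDOW,
    OffsetTable,
    build_offset_table,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "generate_report",
            "ALL_TOOLS"]

ALL_TOOLS = [
    "summary", "read_length", "gc", "feature_pct", "length_periodicity",
    "metagene", "rpkm", "anomaly",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable description of one full QC run.

    Re-running an identical config over identical inputs reproduces all
    tables bit-for-bit (all stochastic steps are governed by ``seed``).
    """

    bams: list[dict]  # each: {path, sample, exp}
    annotation: str = ""
    fasta: str = ""
    outdir: str = "riboqc_out"
    tools: list[str] = field(default_factory=lambda: list(ALL_TOOLS))
    offset_table: str | None = None  # user-supplied TSV bypasses inference
    offset_window: tuple[int, int] = DEFAULT_WINDOW
    min_reads: int = DEFAULT_MIN_READS
    fallback_offset: int = DEFAULT_FALLBACK_OFFSET
    frame_anchor: str = "start_codon"
    metagene_window: tuple[int, int] = (-50, 100)
    subsample_n: int | None = None
    seed: int = 0
    unique_mapq: int = 50
    expert_thresholds: dict | None = None
    controls: list[str] = field(default_factory=list)
    reference_path: str | None = None
    te_pseudocount: float = 0.0
    notes: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["offset_window"] = list(self.offset_window)
        d["metagene_window"] = list(self.metagene_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("offset_window", "metagene_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def validate_inputs(self) -> None:
        missing = []
        for p in [self.annotation, self.fasta, *(b["path"] for b in self.bams)]:
            if not p or not os.path.exists(p):
                missing.append(p or "<unset>")
        if self.offset_table and not os.path.exists(self.offset_table):
            missing.append(self.offset_table)
        if self.reference_path and not os.path.exists(self.reference_path):
            missing.append(self.reference_path)
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))
        unknown = [t for t in self.tools if t not in ALL_TOOLS]
        if unknown:
            raise ValueError(f"unknown tools: {unknown}; available: {ALL_TOOLS}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_plot(fig, outdir: str, name: str, files: list[str]) -> None:
    for ext in ("png", "pdf"):
        p = os.path.join(outdir, f"{name}.{ext}")
        fig.savefig(p, metadata={"CreationDate": None} if ext == "pdf" else None)
        files.append(p)
    plt.close(fig)


def _plot_length(dist: pd.DataFrame, outdir: str, files: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in dist.groupby("group"):
        ax.plot(sub["length"], sub["fraction"], marker="o", label=str(g))
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of reads")
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save_plot(fig, outdir, "read_length", files)


def _plot_gc(dist: pd.DataFrame, outdir: str, files: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in dist.groupby("group"):
        ax.plot((sub["bin_left"] + sub["bin_right"]) / 2, sub["fraction"],
                label=str(g))
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("fraction of reads")
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save_plot(fig, outdir, "gc", files)


def _plot_feature(fp: pd.DataFrame, outdir: str, files: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    piv = fp.pivot_table(index="group", columns="feature", values="pct", fill_value=0)
    piv.plot.bar(stacked=True, ax=ax)
    ax.set_ylabel("% of alignments")
    ax.legend(fontsize=6)
    fig.tight_layout()
    _save_plot(fig, outdir, "feature_pct", files)


def _plot_frames(summary: pd.DataFrame, outdir: str, files: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    summary.set_index("sample")[["frame0", "frame1", "frame2"]].plot.bar(ax=ax)
    ax.set_ylabel("fraction of CDS-mapped P-sites")
    fig.tight_layout()
    _save_plot(fig, outdir, "length_periodicity", files)


def _plot_metagene(prof_df: pd.DataFrame, anchor: str, outdir: str,
                   files: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for g, sub in prof_df.groupby("group"):
        ax.plot(sub["position"], sub["count"], label=str(g), lw=0.9)
    ax.axvline(0, color="k", ls=":", lw=0.8)
    ax.set_xlabel(f"nt relative to {anchor} codon")
    ax.set_ylabel("P-site count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    _save_plot(fig, outdir, f"metagene_{anchor}", files)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the output bundle.

    Returns the manifest dict (also written as ``manifest.json``).  On a
    stage failure a :class:`StageError` is raised after preserving the
    partial outputs and naming the failed stage in the log.
    """
    config.validate_inputs()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    files: list[str] = []
    timings: dict[str, float] = {}
    log_lines: list[str] = []
    stage = "setup"

    def log(msg: str) -> None:
        log_lines.append(msg)

    def write_log() -> None:
        with open(os.path.join(outdir, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")

    try:
        for b in config.bams:
            log(f"input {b['sample']} ({b['exp']}): {b['path']} "
                f"sha256={_sha256(b['path'])}")
        log("config: " + json.dumps(config.to_dict(), sort_keys=True))

        stage = "parse_annotation"
        t0 = time.perf_counter()
        ann = parse_annotation(config.annotation, config.fasta)
        timings[stage] = time.perf_counter() - t0
        log(f"annotation: {len(ann.genes)} genes ({ann.source_dialect})")

        stage = "load_and_annotate"
        t0 = time.perf_counter()
        fixed = (OffsetTable.from_tsv(config.offset_table,
                                      config.fallback_offset)
                 if config.offset_table else None)
        tables = []
        for b in config.bams:
            tab = load_alignments(b["path"], b["sample"], b["exp"])
            if fixed is not None:
                offs = fixed
            elif b["exp"] == "Ribo":
                offs = build_offset_table(
                    tab, ann, window=config.offset_window,
                    min_reads=config.min_reads,
                    fallback_offset=config.fallback_offset,
                )
            else:
                offs = OffsetTable.fixed(0)
            p = os.path.join(outdir, f"offsets_{b['sample']}.tsv")
            offs.to_tsv(p, os.path.join(outdir, f"offsets_{b['sample']}_diagnostics.tsv"))
            files += [p, os.path.join(outdir, f"offsets_{b['sample']}_diagnostics.tsv")]
            atab = annotate(tab, ann, offs, frame_anchor=config.frame_anchor)
            p = os.path.join(outdir, f"alignments_{b['sample']}.tsv")
            atab.to_tsv(p)
            files.append(p)
            tables.append(atab)
            log(f"annotated {b['sample']}: {len(atab)} alignments")
        merged = AlignmentTable.concat(tables)
        timings[stage] = time.perf_counter() - t0

        groups = filter_and_group(merged, group_by=["sample"])
        summary = None
        if "summary" in config.tools or "anomaly" in config.tools:
            stage = "summary"
            t0 = time.perf_counter()
            summary = qc.summary_table(tables, ann, unique_mapq=config.unique_mapq)
            if "summary" in config.tools:
                p = os.path.join(outdir, "summary.tsv")
                summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
                files.append(p)
            timings[stage] = time.perf_counter() - t0

        if "read_length" in config.tools:
            stage = "read_length"
            dist = qc.read_length_distribution(groups)
            p = os.path.join(outdir, "read_length.tsv")
            dist.to_csv(p, sep="\t", index=False, float_format="%.6g")
            files.append(p)
            _plot_length(dist, outdir, files)

        if "gc" in config.tools:
            stage = "gc"
            dist = qc.gc_distribution(groups)
            p = os.path.join(outdir, "gc.tsv")
            dist.to_csv(p, sep="\t", index=False, float_format="%.6g")
            files.append(p)
            _plot_gc(dist, outdir, files)

        if "feature_pct" in config.tools:
            stage = "feature_pct"
            fp = qc.feature_percentages(groups)
            p = os.path.join(outdir, "feature_pct.tsv")
            fp.to_csv(p, sep="\t", index=False, float_format="%.6g")
            files.append(p)
            _plot_feature(fp, outdir, files)

        if "length_periodicity" in config.tools and summary is not None:
            stage = "length_periodicity"
            _plot_frames(summary, outdir, files)

        if "metagene" in config.tools:
            stage = "metagene"
            t0 = time.perf_counter()
            sub = ((config.subsample_n, config.seed)
                   if config.subsample_n else None)
            for anchor in ("start", "stop"):
                profs = []
                for key, tab in groups:
                    prof = qc.metagene_profile(
                        tab, ann, anchor=anchor,
                        window=config.metagene_window, subsample=sub,
                    )
                    prof.group_key = key
                    profs.append(prof.to_frame())
                df = pd.concat(profs, ignore_index=True)
                p = os.path.join(outdir, f"metagene_{anchor}.tsv")
                df.to_csv(p, sep="\t", index=False)
                files.append(p)
                _plot_metagene(df, anchor, outdir, files)
            timings[stage] = time.perf_counter() - t0

        if "rpkm" in config.tools:
            stage = "rpkm"
            cols = {}
            for key, tab in groups:
                cols[key[0]] = qc.rpkm(tab, ann)
            rpkm_df = pd.DataFrame(cols)
            rpkm_df.index.name = "gene"
            p = os.path.join(outdir, "rpkm.tsv")
            rpkm_df.to_csv(p, sep="\t", float_format="%.6g")
            files.append(p)
            ribo = [b["sample"] for b in config.bams if b["exp"] == "Ribo"]
            rna = [b["sample"] for b in config.bams if b["exp"] == "RNA"]
            if ribo and rna:
                te_cols = {
                    rs: qc.translational_efficiency(
                        rpkm_df[rs], rpkm_df[rna[0]], config.te_pseudocount
                    )
                    for rs in ribo
                }
                te_df = pd.DataFrame(te_cols)
                te_df.index.name = "gene"
                p = os.path.join(outdir, "translational_efficiency.tsv")
                te_df.to_csv(p, sep="\t", float_format="%.6g")
                files.append(p)
                log(f"TE computed against RNA sample {rna[0]}")

        if "anomaly" in config.tools and summary is not None:
            stage = "anomaly"
            flags = anom.expert_threshold_flags(
                summary,
                {k: tuple(v) for k, v in config.expert_thresholds.items()}
                if config.expert_thresholds else None,
            )
            flags += anom.tukey_flags(summary)
            if config.controls:
                flags += anom.control_flags(summary, config.controls)
            if config.reference_path:
                ref = pd.read_csv(config.reference_path, sep="\t")
                flags += anom.reference_flags(summary, ref)
            p = os.path.join(outdir, "anomalies.tsv")
            anom.flags_to_frame(flags).to_csv(p, sep="\t", index=False,
                                              float_format="%.6g")
            files.append(p)
            n_flagged = sum(f.flagged for f in flags)
            log(f"anomaly screening: {n_flagged}/{len(flags)} checks flagged")

        stage = "manifest"
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        files.append(os.path.join(outdir, "config.yaml"))
        manifest = {
            "config": config.to_dict(),
            "files": {
                os.path.relpath(p, outdir): _sha256(p) for p in sorted(set(files))
            },
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log("pipeline complete")
        write_log()
        return manifest
    except Exception as exc:
        log(f"FAILED at stage '{stage}': {exc}")
        write_log()
        raise StageError(stage, exc) from exc


_REPORT_CSS = ("body{font-family:sans-serif;max-width:1000px;margin:2em auto;}"
               "table{border-collapse:collapse;font-size:12px;}"
               "td,th{border:1px solid #ccc;padding:3px 6px;}"
               "img{max-width:100%;}h2{border-bottom:1px solid #888;}")

_TOOL_TITLES = {
    "summary": "Summary table",
    "read_length": "Read length distribution",
    "gc": "GC content distribution",
    "feature_pct": "Feature percentages",
    "length_periodicity": "Frame periodicity",
    "metagene": "Metagene profiles",
    "rpkm": "RPKM and translational efficiency",
    "anomaly": "Anomaly screening",
}

_TOOL_FILES = {
    "summary": [("summary.tsv", None)],
    "read_length": [("read_length.tsv", "read_length.png")],
    "gc": [("gc.tsv", "gc.png")],
    "feature_pct": [("feature_pct.tsv", "feature_pct.png")],
    "length_periodicity": [(None, "length_periodicity.png")],
    "metagene": [("metagene_start.tsv", "metagene_start.png"),
                  ("metagene_stop.tsv", "metagene_stop.png")],
    "rpkm": [("rpkm.tsv", None), ("translational_efficiency.tsv", None)],
    "anomaly": [("anomalies.tsv", None)],
}


def _embed_png(path: str) -> str:
    with open(path, "rb") as fh:
        b64 = base64.b64encode(fh.read()).decode()
    return f'<img src="data:image/png;base64,{b64}"/>'


def generate_report(outdir: str, config: RunConfig, notes: str = "",
                    max_table_rows: int = 30) -> str:
    """Assemble the bundle in ``outdir`` into a single HTML report.

    Sections follow the configured tool order; each embeds its plot and
    the head of its table.  The full parameter echo is appended, then the
    user notes (section omitted when empty).  Returns the report path.
    """
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>Ribo-seq QC report</title><style>{_REPORT_CSS}</style></head><body>",
        "<h1>Ribo-seq QC report</h1>",
        f"<p>Samples: {', '.join(b['sample'] + ' (' + b['exp'] + ')' for b in config.bams)}</p>",
    ]
    for tool in config.tools:
        entries = _TOOL_FILES.get(tool, [])
        body = []
        for tsv, png in entries:
            if png and os.path.exists(os.path.join(outdir, png)):
                body.append(_embed_png(os.path.join(outdir, png)))
            if tsv and os.path.exists(os.path.join(outdir, tsv)):
                df = pd.read_csv(os.path.join(outdir, tsv), sep="\t")
                note = ("" if len(df) <= max_table_rows
                        else f"<p>first {max_table_rows} of {len(df)} rows</p>")
                body.append(note + df.head(max_table_rows).to_html(index=False))
        if body:
            parts.append(f"<h2>{_TOOL_TITLES.get(tool, tool)}</h2>")
            parts.extend(body)
    parts.append("<h2>Parameters</h2><pre>"
                 + yaml.safe_dump(config.to_dict(), sort_keys=True)
                 + "</pre>")
    text = notes or config.notes
    if text:
        parts.append(f"<h2>Notes</h2><p>{text}</p>")
    parts.append("</body></html>")
    path = os.path.join(outdir, "report.html")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
    return path
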