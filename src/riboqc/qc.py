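"""QC metric surfaces: distributions, periodicity, metagene profiles,
summary table, RPKM and translational efficiency.

All functions consume the annotated alignment table and return tidy
pandas objects suitable for direct TSV export or plotting.  Percentages
always sum to 100 per group and frame fractions to 1 over CDS-mapped
reads; metagene subsampling is uniform without replacement under a fixed
seed and therefore bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation

if TYPE_CHECKING:  # pragma: no cover
    from .alignments import AlignmentTable

__all__ = [
    "MetageneProfile",
    "read_length_distribution",
    "gc_distribution",
    "feature_percentages",
    "frame_periodicity",
    "metagene_profile",
    "complexity",
    "duplication",
    "rpkm",
    "translational_efficiency",
    "summary_table",
    "METRIC_COLUMNS_FIXED",
]

Groups = list[tuple[tuple, "AlignmentTable"]]


def _group_label(key: tuple) -> str:
    return "|".join(str(k) for k in key) if key else "all"


def read_length_distribution(groups: Groups) -> pd.DataFrame:
    """Per-group read-length counts and fractions (fractions sum to 1)."""
    rows = []
    for key, tab in groups:
        counts = tab.df["length"].value_counts().sort_index()
        total = counts.sum()
        for length, n in counts.items():
            rows.append(
                {
                    "group": _group_label(key),
                    "length": int(length),
                    "count": int(n),
                    "fraction": n / total,
                }
            )
    return pd.DataFrame(rows, columns=["group", "length", "count", "fraction"])


def gc_distribution(groups: Groups, bins: int = 20) -> pd.DataFrame:
    """Per-group histogram of read GC fractions over [0, 1]."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for key, tab in groups:
        gc = tab.df["gc"].dropna().to_numpy()
        if gc.size == 0:
            warnings.warn(f"group {_group_label(key)} has no GC values")
            continue
        counts, _ = np.histogram(gc, bins=edges)
        for i, n in enumerate(counts):
            rows.append(
                {
                    "group": _group_label(key),
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "count": int(n),
                    "fraction": n / gc.size,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "bin_left", "bin_right", "count", "fraction"]
    )


def feature_percentages(groups: Groups, by: str = "feature") -> pd.DataFrame:
    """Percent of alignments per value of ``by`` (default: feature type).

    Any read attribute can be used; percentages sum to 100 per group.
    """
    rows = []
    for key, tab in groups:
        if by not in tab.df.columns:
            raise KeyError(f"unknown alignment attribute: {by!r}")
        col = tab.df[by]
        counts = col.value_counts(dropna=False).sort_index()
        total = counts.sum()
        if total == 0:
            continue
        for label, n in counts.items():
            rows.append(
                {
                    "group": _group_label(key),
                    by: "none" if pd.isna(label) else label,
                    "count": int(n),
                    "pct": 100.0 * n / total,
                }
            )
    return pd.DataFrame(rows, columns=["group", by, "count", "pct"])


def frame_periodicity(table: "AlignmentTable") -> tuple[float, float, float]:
    """Fractions of CDS-mapped P-sites in frames 0/1/2 (sum to 1).

    The frame-0 fraction is the sample's headline periodicity metric: a
    translating ribosome steps three nucleotides at a time, so strongly
    periodic libraries concentrate P-sites in frame with the start codon.
    """
    frames = table.df["frame"].dropna()
    if frames.empty:
        return (float("nan"),) * 3
    n = len(frames)
    return tuple(float((frames == f).sum()) / n for f in (0, 1, 2))


@dataclass
class MetageneProfile:
    """Read density relative to the translation start or stop codon."""

    anchor: str  # "start" | "stop"
    positions: np.ndarray
    counts: np.ndarray
    group_key: tuple = ()
    normalized: bool = False

    def normalize(self) -> "MetageneProfile":
        total = self.counts.sum()
        counts = self.counts / total if total > 0 else self.counts.astype(float)
        return MetageneProfile(self.anchor, self.positions, counts,
                               self.group_key, True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": _group_label(self.group_key),
                "anchor": self.anchor,
                "position": self.positions,
                "count": self.counts,
            }
        )


def metagene_profile(
    table: "AlignmentTable",
    annotation: GenomeAnnotation,
    anchor: str = "start",
    window: tuple[int, int] = (-50, 100),
    subsample: tuple[int, int] | None = None,
) -> MetageneProfile:
    """Aggregate P-site density across all major isoforms around an anchor.

    ``anchor="start"`` centres on the first nt of the start codon,
    ``"stop"`` on the first nt of the stop codon.  ``subsample=(n, seed)``
    draws n alignments uniformly without replacement before tallying
    (identity when n >= table size), making large tables cheap to profile
    reproducibly.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    lo, hi = window
    df = table.df
    if subsample is not None:
        n, seed = subsample
        if n < len(df):
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(df), size=n, replace=False))
            df = df.iloc[idx]
    df = df[df["start_dist"].notna()]
    if anchor == "start":
        cds_start = {g: gm.major_isoform.cds_start_t for g, gm in annotation.genes.items()
                     if gm.major_isoform.is_coding}
        rel = df["start_dist"].astype("Int64") - df["gene"].map(cds_start).astype("Int64")
    else:
        rel = -df["end_dist"].astype("Int64")
    rel = rel.dropna().astype(int)
    rel = rel[(rel >= lo) & (rel <= hi)]
    positions = np.arange(lo, hi + 1)
    counts = np.zeros(positions.size, dtype=int)
    vals, cnts = np.unique(rel.to_numpy(), return_counts=True)
    counts[vals - lo] = cnts
    return MetageneProfile(anchor, positions, counts)


def complexity(table: "AlignmentTable") -> float:
    """Distinct (chromosome, strand, start, length) tuples / total records."""
    df = table.df
    if len(df) == 0:
        return float("nan")
    distinct = len(df[["seqnames", "strand", "range_start", "length"]].drop_duplicates())
    return distinct / len(df)


def duplication(table: "AlignmentTable") -> float:
    """Complement of library complexity."""
    c = complexity(table)
    return float("nan") if np.isnan(c) else 1.0 - c


def rpkm(table: "AlignmentTable", annotation: GenomeAnnotation) -> pd.Series:
    """Reads per kilobase of major-isoform transcript per million mapped reads.

    A read counts toward a gene when its (P-site-adjusted) position was
    assigned to that gene; gene length is the spliced length of the major
    isoform; the denominator is the total mapped reads of the table.
    """
    df = table.df
    total = len(df)
    counts = df["gene"].value_counts()
    out = {}
    for gid, gm in annotation.genes.items():
        length = gm.major_isoform.length_t
        n = int(counts.get(gid, 0))
        out[gid] = (n * 1e9) / (total * length) if total > 0 else float("nan")
    return pd.Series(out, name="rpkm").sort_index()


def translational_efficiency(
    ribo_rpkm: pd.Series, rna_rpkm: pd.Series, pseudocount: float = 0.0
) -> pd.Series:
    """Per-gene ratio of Ribo-seq to RNA-seq RPKM.

    With the default zero pseudocount, genes with zero RNA-seq signal get
    NaN (undefined ratio) and a warning; a positive pseudocount
    regularises both numerator and denominator.
    """
    genes = ribo_rpkm.index.union(rna_rpkm.index)
    r = ribo_rpkm.reindex(genes).fillna(0.0) + pseudocount
    m = rna_rpkm.reindex(genes).fillna(0.0) + pseudocount
    undefined = m == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} genes have zero RNA-seq RPKM; TE undefined"
        )
    te = pd.Series(np.where(undefined, np.nan, r / m.replace(0, np.nan)),
                   index=genes, name="te")
    return te.sort_index()


#: Metric columns of the summary table usable for anomaly screening.
METRIC_COLUMNS_FIXED = [
    "total_alignments", "pct_unique", "complexity", "duplication",
    "frame0", "frame1", "frame2", "periodicity",
]


def summary_table(
    tables: list["AlignmentTable"],
    annotation: GenomeAnnotation | None = None,
    unique_mapq: int = 50,
) -> pd.DataFrame:
    """One QC row per sample: totals, uniqueness, feature percentages,
    complexity/duplication and frame periodicity.

    Frame metrics are reported for every sample but are biologically
    meaningful only for Ribo-seq libraries; the ``exp`` column lets
    downstream screens restrict accordingly.  Feature percentage columns
    are named ``pct_<feature>`` and sum to 100 per row.
    """
    from .alignments import AlignmentTable, classify_unique

    merged = AlignmentTable.concat(tables) if len(tables) != 1 else tables[0]
    rows = []
    for sample, df in merged.df.groupby("sample", sort=True):
        sub = AlignmentTable(df.copy())
        exp = df["exp"].iloc[0]
        total = len(df)
        uniq = df["mapq"].map(lambda q: classify_unique(int(q), unique_mapq)).sum()
        f0, f1, f2 = frame_periodicity(sub)
        row = {
            "sample": sample,
            "exp": exp,
            "total_alignments": total,
            "pct_unique": 100.0 * uniq / total if total else float("nan"),
            "complexity": complexity(sub),
            "duplication": duplication(sub),
            "frame0": f0,
            "frame1": f1,
            "frame2": f2,
            "periodicity": f0,
        }
        feats = df["feature"].value_counts()
        for label, n in feats.items():
            row[f"pct_{label}"] = 100.0 * n / total
        rows.append(row)
    out = pd.DataFrame(rows)
    pct_cols = sorted(c for c in out.columns if c.startswith("pct_") and c != "pct_unique")
    fixed = ["sample", "exp", *METRIC_COLUMNS_FIXED]
    out = out[[*fixed, *pct_cols]]
    out[pct_cols] = out[pct_cols].fillna(0.0)
    return out
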