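"""Per-read attribute annotation of BAM alignments.

Loads primary alignments into a filterable table (one row per alignment)
and attaches the full QC attribute set: chromosome/range/strand, sample
and experiment labels, read length, GC fraction, mapq, and — after
P-site adjustment — the adjusted genomic position ``pos``, the gene and
feature it falls in, distances to the transcript 5' end (``start_dist``)
and to the stop codon (``end_dist``) in spliced transcript coordinates
of the gene's major isoform, and the trinucleotide ``frame`` of the
P-site relative to the start codon.

The table is a thin wrapper over a pandas DataFrame; every attribute
supports filtering and grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeAnnotation
from .offsets import OffsetTable

__all__ = [
    "AlignmentTable",
    "load_alignments",
    "compute_gc",
    "classify_unique",
    "annotate",
    "filter_and_group",
]

#: Column order of the alignment table; one column per read attribute.
COLUMNS = [
    "seqnames", "range_start", "range_end", "strand", "sample", "exp",
    "length", "gene", "feature", "pos", "start_dist", "end_dist",
    "gc", "mapq", "frame",
]

_INT_NULLABLE = ("pos", "start_dist", "end_dist", "frame")


@dataclass
class AlignmentTable:
    """Collection of alignment records with per-read attributes.

    ``df`` holds one row per retained alignment.  ``pos``, ``start_dist``,
    ``end_dist`` and ``frame`` are nullable integers (pd.NA encodes the
    'none'/absent state for reads outside an mRNA).
    """

    df: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.df.columns:
                self.df[col] = pd.NA
        self.df = self.df[COLUMNS].reset_index(drop=True)
        for col in _INT_NULLABLE:
            self.df[col] = self.df[col].astype("Int64")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def subset(self, mask) -> "AlignmentTable":
        return AlignmentTable(self.df[mask].copy(), dict(self.provenance))

    def to_tsv(self, path: str) -> str:
        out = self.df.copy()
        out["frame"] = out["frame"].astype(object).where(out["frame"].notna(), "none")
        out.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str) -> "AlignmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"seqnames": str})
        df["frame"] = pd.to_numeric(df["frame"], errors="coerce")
        return cls(df)

    @classmethod
    def concat(cls, tables: list["AlignmentTable"]) -> "AlignmentTable":
        prov: dict[str, Any] = {}
        for t in tables:
            prov.update(t.provenance)
        return cls(pd.concat([t.df for t in tables], ignore_index=True), prov)


def compute_gc(read_sequence: str) -> float:
    """Fraction of G/C bases in a read; N counts in the denominator only."""
    if not read_sequence:
        raise ValueError("empty read sequence")
    s = read_sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def classify_unique(mapq: int, unique_mapq: int = 50) -> bool:
    """True iff the alignment counts as uniquely mapped.

    By convention a mapq of exactly 50 marks a unique alignment and every
    other score marks multi-mapping; the threshold is configurable for
    aligners with a different convention.
    """
    if mapq < 0:
        raise ValueError("mapq must be non-negative")
    return mapq == unique_mapq


def load_alignments(bam_path: str, sample: str, exp: str) -> AlignmentTable:
    """Read a BAM into a pre-annotation alignment table.

    Retains primary, mapped, non-supplementary alignments only — one row
    per sequenced fragment.  Dropped counts are recorded in provenance.
    """
    if exp not in ("Ribo", "RNA"):
        raise ValueError(f"exp must be 'Ribo' or 'RNA', got {exp!r}")
    rows = []
    dropped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                dropped["unmapped"] += 1
                continue
            if read.is_secondary:
                dropped["secondary"] += 1
                continue
            if read.is_supplementary:
                dropped["supplementary"] += 1
                continue
            seq = read.query_sequence
            length = read.query_length or (len(seq) if seq else 0)
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.reference_end,
                    "-" if read.is_reverse else "+",
                    sample,
                    exp,
                    length,
                    compute_gc(seq) if seq else np.nan,
                    read.mapping_quality,
                )
            )
    if not rows:
        warnings.warn(f"BAM {bam_path} yielded no retained alignments")
    df = pd.DataFrame(
        rows,
        columns=["seqnames", "range_start", "range_end", "strand", "sample",
                 "exp", "length", "gc", "mapq"],
    )
    return AlignmentTable(
        df, provenance={sample: {"path": bam_path, "exp": exp, "dropped": dropped}}
    )


def _five_prime_end(row_start: int, row_end: int, strand: str) -> int:
    return row_start if strand == "+" else row_end - 1


def _psite_position(
    annotation: GenomeAnnotation,
    chrom: str,
    strand: str,
    five: int,
    offset: int,
) -> int:
    """Walk ``offset`` nt downstream of the read 5' end.

    The walk happens in spliced transcript space when the 5' end lies on
    an exon of some gene's major isoform (so offsets step across exon
    junctions correctly); otherwise it falls back to a plain strand-aware
    genomic shift.
    """
    if offset == 0:
        return five
    tree = annotation.feature_index.get((chrom, strand))
    if tree is not None:
        gene_ids = sorted(
            {iv.data[1] for iv in tree[five] if iv.data[1] in annotation.genes}
        )
        for gid in gene_ids:
            tm = annotation.genes[gid].major_isoform
            t5 = tm.genomic_to_transcript(five)
            if t5 is None:
                continue
            pt = t5 + offset
            if 0 <= pt < tm.length_t:
                return tm.transcript_to_genomic(pt)
    return five + offset if strand == "+" else five - offset


def annotate(
    table: AlignmentTable,
    annotation: GenomeAnnotation,
    offsets: OffsetTable,
    frame_anchor: str = "start_codon",
) -> AlignmentTable:
    """Attach P-site position, gene, feature, distances and frame.

    ``frame_anchor`` selects the reference point of the frame computation:
    ``"start_codon"`` (default; frame 0 means in frame with the start
    codon) or ``"transcript_start"`` (frame relative to the transcript
    5' end).  Distances and frame are computed on the major isoform of
    the assigned gene and are absent whenever the P-site does not fall on
    an exon of a coding major isoform.  Idempotent for fixed inputs.
    """
    if frame_anchor not in ("start_codon", "transcript_start"):
        raise ValueError(f"unknown frame_anchor {frame_anchor!r}")
    df = table.df
    pos_l: list[Any] = []
    gene_l: list[str] = []
    feat_l: list[str] = []
    sd_l: list[Any] = []
    ed_l: list[Any] = []
    fr_l: list[Any] = []
    cols = ["seqnames", "range_start", "range_end", "strand", "exp", "length"]
    for chrom, start, end, strand, exp, length in df[cols].itertuples(index=False):
        offset = offsets.get(int(length)) if exp == "Ribo" else 0
        five = _five_prime_end(int(start), int(end), strand)
        pos = _psite_position(annotation, chrom, strand, five, offset)
        feature, gene = annotation.assign_feature(chrom, strand, pos)
        start_dist = end_dist = frame = pd.NA
        if gene in annotation.genes:
            tm = annotation.genes[gene].major_isoform
            tpos = tm.genomic_to_transcript(pos)
            if tpos is not None and tm.is_coding:
                start_dist = tpos
                end_dist = tm.cds_stop_t - tpos
                if frame_anchor == "start_codon":
                    frame = (tpos - tm.cds_start_t) % 3
                else:
                    frame = tpos % 3
        pos_l.append(pos)
        gene_l.append(gene)
        feat_l.append(feature)
        sd_l.append(start_dist)
        ed_l.append(end_dist)
        fr_l.append(frame)
    out = df.copy()
    out["pos"] = pd.array(pos_l, dtype="Int64")
    out["gene"] = gene_l
    out["feature"] = feat_l
    out["start_dist"] = pd.array(sd_l, dtype="Int64")
    out["end_dist"] = pd.array(ed_l, dtype="Int64")
    out["frame"] = pd.array(fr_l, dtype="Int64")
    prov = dict(table.provenance)
    prov["annotate_params"] = {"frame_anchor": frame_anchor}
    return AlignmentTable(out, prov)


def _build_mask(df: pd.DataFrame, attr: str, spec: Any) -> pd.Series:
    col = df[attr]
    if callable(spec):
        return col.map(spec).fillna(False).astype(bool)
    if isinstance(spec, tuple) and len(spec) == 2:
        return (col >= spec[0]) & (col <= spec[1])
    if isinstance(spec, (list, set, frozenset)):
        return col.isin(list(spec))
    return col == spec


def filter_and_group(
    table: AlignmentTable,
    filters: dict[str, Any] | None = None,
    group_by: list[str] | None = None,
) -> list[tuple[tuple, AlignmentTable]]:
    """Filter records by attribute predicates, then partition into groups.

    ``filters`` maps attribute name to a scalar (equality), a 2-tuple
    (inclusive range), a list/set (membership) or a callable predicate.
    ``group_by`` names attributes whose value combinations define the
    groups; the returned groups partition the filtered table and are
    sorted by key for determinism.  An unknown attribute raises KeyError.
    """
    df = table.df
    for attr in list(filters or {}) + list(group_by or []):
        if attr not in df.columns:
            raise KeyError(f"unknown alignment attribute: {attr!r}")
    mask = pd.Series(True, index=df.index)
    for attr, spec in (filters or {}).items():
        mask &= _build_mask(df, attr, spec)
    filtered = df[mask]
    if not group_by:
        return [((), AlignmentTable(filtered.copy(), dict(table.provenance)))]
    grouped = filtered.groupby(group_by, dropna=False, observed=True, sort=True)
    out = []
    for key, sub in grouped:
        key_t = key if isinstance(key, tuple) else (key,)
        out.append((key_t, AlignmentTable(sub.copy(), dict(table.provenance))))
    out.sort(key=lambda kv: tuple(str(k) for k in kv[0]))
    return out
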