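"""Genome and annotation model for Ribo-seq QC.

Parses a GFF3/GTF annotation plus a genome FASTA into gene/transcript
models with genomic<->transcript coordinate maps, selects each gene's
major isoform, and provides strand-aware feature lookup for arbitrary
genomic positions.

All internal coordinates are 0-based half-open; 1-based GFF/GTF input is
converted at the parsing boundary.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "GenomeAnnotation",
    "parse_annotation",
    "select_major_isoform",
    "AnnotationError",
]

# Most-specific-wins priority for feature assignment.  Contaminant RNA
# classes outrank protein-coding sub-features so that rRNA/tRNA content
# is visible to QC even where records overlap.  Lower rank wins.
_NC_TYPES = ("rRNA", "tRNA", "ncRNA", "snRNA", "snoRNA", "miRNA", "lnc_RNA")
FEATURE_PRIORITY: dict[str, int] = {}
for _i, _t in enumerate(_NC_TYPES):
    FEATURE_PRIORITY[_t] = _i
FEATURE_PRIORITY.update(
    {
        "CDS": 10,
        "five_prime_UTR": 11,
        "three_prime_UTR": 12,
        "exon": 13,
        "mRNA": 14,
        "transcript": 14,
        "gene": 20,
    }
)
_UNKNOWN_PRIORITY = 15  # between transcript and gene

_TRANSCRIPT_TYPES = {"mRNA", "transcript"} | set(_NC_TYPES)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One isoform: ordered exons and a spliced-coordinate map.

    ``exons`` are genomic 0-based half-open intervals sorted 5'->3' in
    transcript orientation (ascending start on '+', descending on '-').
    ``cds_start_t`` is the transcript coordinate of the first nt of the
    start codon and ``cds_stop_t`` that of the first nt of the stop
    codon; both are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_t: int | None = None
    cds_stop_t: int | None = None
    _cum: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        cum, total = [], 0
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(
                    f"empty exon interval ({s}, {e}) in {self.transcript_id}"
                )
            cum.append(total)
            total += e - s
        self._cum = cum
        self.length_t = total

    @property
    def is_coding(self) -> bool:
        return self.cds_start_t is not None

    @property
    def cds_length(self) -> int | None:
        if not self.is_coding:
            return None
        return self.cds_stop_t - self.cds_start_t + 3

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Transcript coordinate of genomic position, or None if intronic
        or outside the transcript span."""
        for (s, e), base in zip(self.exons, self._cum):
            if s <= gpos < e:
                if self.strand == "+":
                    return base + (gpos - s)
                return base + (e - 1 - gpos)
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.length_t:
            raise ValueError(
                f"transcript position {tpos} outside [0, {self.length_t})"
            )
        i = bisect_right(self._cum, tpos) - 1
        s, e = self.exons[i]
        off = tpos - self._cum[i]
        return s + off if self.strand == "+" else e - 1 - off

    def transcript_interval_blocks(self, t_lo: int, t_hi: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending, 0-based half-open, merged) covered by
        the transcript interval [t_lo, t_hi)."""
        positions = sorted(self.transcript_to_genomic(t) for t in range(t_lo, t_hi))
        blocks: list[list[int]] = []
        for p in positions:
            if blocks and p == blocks[-1][1]:
                blocks[-1][1] = p + 1
            else:
                blocks.append([p, p + 1])
        return [(s, e) for s, e in blocks]

    @property
    def genomic_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel]
    major: int = 0

    @property
    def major_isoform(self) -> TranscriptModel:
        return self.transcripts[self.major]


def select_major_isoform(gene: GeneModel) -> int:
    """Index of the gene's major isoform.

    Rule: coding beats non-coding; then longest CDS; then longest spliced
    length; remaining ties break to the lexicographically smallest
    transcript_id.  Deterministic and independent of input record order.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")

    def key(t: TranscriptModel):
        return (
            0 if t.is_coding else 1,
            -(t.cds_length or 0),
            -t.length_t,
            t.transcript_id,
        )

    ranked = sorted(range(len(gene.transcripts)), key=lambda i: key(gene.transcripts[i]))
    return ranked[0]


class GenomeAnnotation:
    """Indexed annotation: gene models, feature interval index, genome sequence."""

    def __init__(
        self,
        genes: dict[str, GeneModel],
        feature_index: dict[tuple[str, str], IntervalTree],
        fasta: Fasta,
        source_dialect: str,
    ):
        self.genes = genes
        self.feature_index = feature_index
        self.fasta = fasta
        self.source_dialect = source_dialect

    def assign_feature(self, chromosome: str, strand: str, pos: int) -> tuple[str, str]:
        """(feature label, gene_id) of the most specific same-strand record
        overlapping ``pos``; ("Other", "Other") when none does."""
        tree = self.feature_index.get((chromosome, strand))
        if tree is None:
            return ("Other", "Other")
        hits = tree[pos]
        if not hits:
            return ("Other", "Other")
        best = min(
            hits,
            key=lambda iv: (
                FEATURE_PRIORITY.get(iv.data[0], _UNKNOWN_PRIORITY),
                iv.data[1],
            ),
        )
        return best.data

    def sequence(self, chromosome: str, start: int, end: int) -> str:
        """Forward-strand genome sequence on [start, end), uppercase."""
        return str(self.fasta[chromosome][start:end]).upper()

    def major_isoforms(self):
        """Iterate (gene_id, major TranscriptModel) pairs."""
        for gid, g in self.genes.items():
            yield gid, g.major_isoform


def _detect_dialect(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gtf":
        return "GTF"
    if ext in (".gff", ".gff3"):
        return "GFF3"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9:
                attrs = fields[8]
                if 'gene_id "' in attrs or 'transcript_id "' in attrs:
                    return "GTF"
                if "=" in attrs:
                    return "GFF3"
            break
    return "GFF3"


def _feature_gene_id(feat, dialect: str, db) -> str | None:
    if dialect == "GTF":
        vals = feat.attributes.get("gene_id")
        return vals[0] if vals else None
    # GFF3: walk Parent chain up to the gene record
    cur = feat
    for _ in range(5):
        if cur.featuretype == "gene":
            return cur.id
        parents = list(db.parents(cur, level=1))
        if not parents:
            return cur.id if cur.featuretype in _TRANSCRIPT_TYPES else None
        cur = parents[0]
    return None


def parse_annotation(annotation_path: str, fasta_path: str) -> GenomeAnnotation:
    """Parse GFF3/GTF + FASTA into a fully indexed :class:`GenomeAnnotation`.

    Dialect is auto-detected from the extension, then content.  Transcripts
    without CDS records are carried as non-coding.  In GTF input,
    ``stop_codon`` records are folded into the CDS so that coding spans
    include the stop codon under both dialects.

    Raises
    ------
    AnnotationError
        For empty/malformed annotation or chromosomes absent from the FASTA.
    """
    for p in (annotation_path, fasta_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    dialect = _detect_dialect(annotation_path)
    try:
        db = gffutils.create_db(
            annotation_path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted errors on bad input
        raise AnnotationError(
            f"failed to parse annotation {annotation_path}: {exc}"
        ) from exc

    n_records = sum(1 for _ in db.all_features())
    if n_records == 0:
        raise AnnotationError(f"annotation file {annotation_path} contains no records")

    fasta = Fasta(fasta_path)
    fasta_names = set(fasta.keys())
    ann_chroms = {f.seqid for f in db.all_features()}
    missing = sorted(ann_chroms - fasta_names)
    if missing:
        raise AnnotationError(
            "annotation chromosomes missing from FASTA: " + ", ".join(missing)
        )

    genes: dict[str, GeneModel] = {}
    feature_index: dict[tuple[str, str], IntervalTree] = {}

    def add_interval(chrom, strand, start0, end, label, gene_id):
        tree = feature_index.setdefault((chrom, strand), IntervalTree())
        tree[start0:end] = (label, gene_id)

    for feat in db.all_features():
        gid = _feature_gene_id(feat, dialect, db)
        add_interval(
            feat.seqid, feat.strand, feat.start - 1, feat.end, feat.featuretype, gid or "Other"
        )

    for gene_feat in db.features_of_type("gene"):
        gid = (
            gene_feat.attributes.get("gene_id", [gene_feat.id])[0]
            if dialect == "GTF"
            else gene_feat.id
        )
        transcripts = []
        for tfeat in db.children(gene_feat, level=1):
            if tfeat.featuretype not in _TRANSCRIPT_TYPES:
                continue
            tid = (
                tfeat.attributes.get("transcript_id", [tfeat.id])[0]
                if dialect == "GTF"
                else tfeat.id
            )
            exons = sorted(
                (c.start - 1, c.end) for c in db.children(tfeat, featuretype="exon")
            )
            if not exons:
                exons = [(tfeat.start - 1, tfeat.end)]
            cds = sorted(
                (c.start - 1, c.end) for c in db.children(tfeat, featuretype="CDS")
            )
            if dialect == "GTF":
                stops = sorted(
                    (c.start - 1, c.end)
                    for c in db.children(tfeat, featuretype="stop_codon")
                )
                cds = sorted(cds + stops)
            strand = tfeat.strand
            if strand == "-":
                exons = exons[::-1]
            tm = TranscriptModel(
                transcript_id=tid,
                chromosome=tfeat.seqid,
                strand=strand,
                exons=exons,
            )
            if cds:
                cds_len = sum(e - s for s, e in cds)
                first_cds_g = cds[0][0] if strand == "+" else max(e for _, e in cds) - 1
                cds_start_t = tm.genomic_to_transcript(first_cds_g)
                if cds_start_t is None:
                    raise AnnotationError(
                        f"CDS of {tid} does not lie on its exons"
                    )
                if cds_len >= 3 and cds_start_t + cds_len <= tm.length_t:
                    tm.cds_start_t = cds_start_t
                    tm.cds_stop_t = cds_start_t + cds_len - 3
            transcripts.append(tm)
        if not transcripts:
            continue
        transcripts.sort(key=lambda t: t.transcript_id)
        gm = GeneModel(
            gene_id=gid,
            chromosome=gene_feat.seqid,
            strand=gene_feat.strand,
            transcripts=transcripts,
        )
        gm.major = select_major_isoform(gm)
        genes[gid] = gm

    return GenomeAnnotation(genes, feature_index, fasta, dialect)
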