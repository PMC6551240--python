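"""P-site offset inference from start-codon metagene density.

A ribosome's P-site sits a length-dependent distance downstream of the
footprint 5' end.  For each read length, the unadjusted 5' ends are
tallied relative to the start codons of all major isoforms; the largest
in-frame peak strictly upstream of the start codon gives the offset for
that length (the canonical initiating-ribosome pile-up).  Lengths with
too few supporting reads, or with no in-frame upstream signal, fall back
to a configurable default offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation

if TYPE_CHECKING:  # pragma: no cover
    from .alignments import AlignmentTable

__all__ = [
    "OffsetTable",
    "start_anchored_density",
    "infer_offset",
    "build_offset_table",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_READS",
    "DEFAULT_FALLBACK_OFFSET",
]

DEFAULT_WINDOW: tuple[int, int] = (-40, 20)
DEFAULT_MIN_READS: int = 50
DEFAULT_FALLBACK_OFFSET: int = 12


@dataclass
class OffsetTable:
    """Read length -> P-site offset map with per-length diagnostics.

    ``entries`` holds inferred (or fallback) offsets for every length
    observed during inference; ``get`` serves the fallback offset for
    lengths never seen.  Diagnostics per length: ``n_reads`` in the
    window, ``peak_pos`` / ``peak_height`` of the winning upstream peak,
    and whether the fallback rule fired.
    """

    entries: dict[int, int] = field(default_factory=dict)
    diagnostics: dict[int, dict] = field(default_factory=dict)
    fallback_offset: int = DEFAULT_FALLBACK_OFFSET

    def get(self, length: int) -> int:
        return self.entries.get(length, self.fallback_offset)

    def __contains__(self, length: int) -> bool:
        return length in self.entries

    @classmethod
    def fixed(cls, offset: int) -> "OffsetTable":
        """A table that serves one constant offset for every length."""
        return cls(entries={}, fallback_offset=offset)

    def to_tsv(self, path: str, diagnostics_path: str | None = None) -> str:
        pd.DataFrame(
            sorted(self.entries.items()), columns=["length", "offset"]
        ).to_csv(path, sep="\t", index=False)
        if diagnostics_path:
            rows = [
                {"length": ln, **self.diagnostics.get(ln, {})}
                for ln in sorted(self.entries)
            ]
            pd.DataFrame(rows).to_csv(diagnostics_path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str, fallback_offset: int = DEFAULT_FALLBACK_OFFSET) -> "OffsetTable":
        df = pd.read_csv(path, sep="\t")
        entries = {int(r.length): int(r.offset) for r in df.itertuples(index=False)}
        for ln, off in entries.items():
            if not 0 <= off <= ln:
                raise ValueError(f"offset {off} outside [0, {ln}] for length {ln}")
        return cls(entries=entries, fallback_offset=fallback_offset)


def start_anchored_density(
    table: "AlignmentTable",
    annotation: GenomeAnnotation,
    length: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Metagene count vector of unadjusted 5' ends around start codons.

    Position 0 is the first nucleotide of the start codon of each coding
    major isoform; the vector spans ``window`` inclusive (index 0 maps to
    ``window[0]``).  Only Ribo-seq reads of the given length contribute,
    each through the gene whose major isoform carries its 5' end.
    """
    lo, hi = window
    if not (lo < 0 <= hi):
        raise ValueError(f"window must satisfy lo < 0 <= hi, got {window}")
    counts = np.zeros(hi - lo + 1, dtype=int)
    df = table.df
    sel = df[(df["exp"] == "Ribo") & (df["length"] == length)]
    if sel.empty:
        warnings.warn(f"no Ribo-seq reads of length {length}")
        return counts
    for chrom, start, end, strand in sel[
        ["seqnames", "range_start", "range_end", "strand"]
    ].itertuples(index=False):
        five = int(start) if strand == "+" else int(end) - 1
        tree = annotation.feature_index.get((chrom, strand))
        if tree is None:
            continue
        gene_ids = sorted(
            {iv.data[1] for iv in tree[five] if iv.data[1] in annotation.genes}
        )
        for gid in gene_ids:
            tm = annotation.genes[gid].major_isoform
            if not tm.is_coding:
                continue
            t5 = tm.genomic_to_transcript(five)
            if t5 is None:
                continue
            rel = t5 - tm.cds_start_t
            if lo <= rel <= hi:
                counts[rel - lo] += 1
            break
    return counts


def infer_offset(
    density: np.ndarray,
    window: tuple[int, int],
    length: int,
    min_reads: int = DEFAULT_MIN_READS,
    fallback_offset: int = DEFAULT_FALLBACK_OFFSET,
) -> tuple[int, dict]:
    """Offset = distance from the largest in-frame upstream peak to the start codon.

    A periodic library shows 3-nt-spaced peaks upstream of the start
    codon; the peaks of the dominant frame class (the residue class
    mod 3 carrying the most upstream density) are the in-frame ones, and
    the initiating-ribosome pile-up is their largest member.  Candidates
    are therefore strictly upstream positions (p < 0) in the dominant
    frame class; offset = -argmax of density over candidates, ties at
    equal height breaking toward the smaller offset.  If the window holds
    fewer than ``min_reads`` reads, or no candidate has any signal, the
    fallback offset is used and flagged in the diagnostics.
    """
    lo, hi = window
    total = int(density.sum())
    diag = {
        "n_reads": total,
        "peak_pos": None,
        "peak_height": 0,
        "fallback_used": False,
    }
    class_mass = [0, 0, 0]
    for p in range(lo, 0):
        class_mass[p % 3] += int(density[p - lo])
    dominant = max(range(3), key=lambda c: (class_mass[c], -c))
    best_p, best_h = None, 0
    # iterate upstream positions of the dominant class from -1/-2/-3
    # outward so the first maximum found has the smallest |p|
    start = -((3 - dominant) % 3) or -3
    for p in range(start, lo - 1, -3):
        h = int(density[p - lo])
        if h > best_h:
            best_p, best_h = p, h
    if total < min_reads or best_p is None:
        diag["fallback_used"] = True
        offset = fallback_offset
    else:
        offset = -best_p
        diag["peak_pos"] = best_p
        diag["peak_height"] = best_h
    if offset > length:
        diag["fallback_used"] = True
        offset = min(fallback_offset, length)
    return offset, diag


def build_offset_table(
    table: "AlignmentTable",
    annotation: GenomeAnnotation,
    lengths: set[int] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_reads: int = DEFAULT_MIN_READS,
    fallback_offset: int = DEFAULT_FALLBACK_OFFSET,
) -> OffsetTable:
    """Infer one offset per read length present in the sample's Ribo reads."""
    df = table.df
    observed = df.loc[df["exp"] == "Ribo", "length"]
    use = sorted(lengths) if lengths is not None else sorted(observed.unique())
    out = OffsetTable(fallback_offset=fallback_offset)
    for length in use:
        dens = start_anchored_density(table, annotation, int(length), window)
        off, diag = infer_offset(dens, window, int(length), min_reads, fallback_offset)
        out.entries[int(length)] = off
        out.diagnostics[int(length)] = diag
    return out
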