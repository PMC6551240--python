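"""Synthetic genome, annotation and aligned-read generator.

Builds miniature FASTA + GFF3/GTF genomes and coordinate-sorted BAM files
with controlled statistical structure — per-read-length P-site offsets,
in-frame read fraction, start-codon pileup, rRNA/tRNA contamination,
duplication rate and a unique/multi-mapping mapq mix — so that every QC
component can be exercised and validated without any external download.

Reads are emitted already aligned (BAM); upstream fastq processing and
mapping are outside the scope of the toolkit.  Multi-mapping is emulated
purely through mapq values.  Ribo-seq reads are placed so that the read
5' end plus the true length-specific offset lands on a codon boundary
with probability equal to the configured in-frame fraction (the
remainder split evenly between frames 1 and 2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genome import TranscriptModel, parse_annotation

__all__ = ["SimSpec", "SimulatedGenome", "simulate_genome", "simulate_reads",
           "reference_metrics_fixture"]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimSpec:
    """Parameters of a simulated Ribo-seq/RNA-seq study.

    Defaults describe a small but realistic high-quality plant-style
    library: footprints of 27-29 nt with canonical ~12 nt 5'-to-P-site
    offsets, 70% of P-sites in frame 0, mild rRNA/tRNA carry-over, 10%
    duplicate alignments and 85% uniquely mapping reads.
    """

    n_genes: int = 20
    n_chromosomes: int = 2
    utr5_range: tuple[int, int] = (30, 60)
    cds_codons_range: tuple[int, int] = (100, 200)
    utr3_range: tuple[int, int] = (30, 60)
    exons_range: tuple[int, int] = (1, 1)
    intron_range: tuple[int, int] = (60, 150)
    intergenic_range: tuple[int, int] = (200, 400)
    n_rrna_loci: int = 2
    n_trna_loci: int = 2
    rrna_length_range: tuple[int, int] = (150, 300)
    trna_length_range: tuple[int, int] = (80, 100)
    frac_rrna: float = 0.05
    frac_trna: float = 0.02
    offsets: dict[int, int] = field(default_factory=lambda: {27: 11, 28: 12, 29: 13})
    length_probs: dict[int, float] = field(
        default_factory=lambda: {27: 0.25, 28: 0.5, 29: 0.25}
    )
    in_frame_fraction: float = 0.7
    start_pileup_weight: float = 0.1
    reads_per_sample: int = 5000
    duplication_rate: float = 0.1
    unique_fraction: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_rrna", "frac_trna", "in_frame_fraction",
                     "start_pileup_weight", "duplication_rate", "unique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_rrna + self.frac_trna > 1.0:
            raise ValueError("contaminant read fractions sum to more than 1")
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if set(self.length_probs) - set(self.offsets):
            raise ValueError("every simulated read length needs a true offset")


@dataclass
class _Locus:
    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    kind: str  # protein_coding | rRNA | tRNA
    model: TranscriptModel
    utr5_len: int = 0
    cds_len: int = 0  # includes stop codon


@dataclass
class SimulatedGenome:
    fasta_path: str
    gff3_path: str
    loci: list[_Locus]
    chrom_seqs: dict[str, str]

    def write_gtf(self, path: str) -> str:
        _write_gtf(self.loci, path)
        return path


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


def simulate_genome(spec: SimSpec, outdir: str, prefix: str = "sim") -> SimulatedGenome:
    """Write a deterministic FASTA + GFF3 pair for the given spec.

    Every protein-coding gene carries a single isoform with
    5'UTR - ATG...stop CDS - 3'UTR structure (multi-exon when
    ``exons_range`` allows), distributed over both strands; rRNA/tRNA
    contaminant loci are annotated as non-coding genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursor: dict[str, int] = {c: 0 for c in chrom_names}
    loci: list[_Locus] = []

    def place_locus(chrom: str, locus_seq: str) -> int:
        gap = int(rng.integers(*spec.intergenic_range))
        parts[chrom].append(_random_seq(rng, gap))
        start = cursor[chrom] + gap
        parts[chrom].append(locus_seq)
        cursor[chrom] = start + len(locus_seq)
        return start

    # protein-coding genes
    for i in range(spec.n_genes):
        chrom = chrom_names[i % spec.n_chromosomes]
        strand = "+" if i % 2 == 0 else "-"
        utr5 = int(rng.integers(spec.utr5_range[0], spec.utr5_range[1] + 1))
        codons = int(rng.integers(spec.cds_codons_range[0], spec.cds_codons_range[1] + 1))
        utr3 = int(rng.integers(spec.utr3_range[0], spec.utr3_range[1] + 1))
        spliced = _random_seq(rng, utr5) + _random_cds(rng, codons) + _random_seq(rng, utr3)
        T = len(spliced)
        cds_len = 3 * (codons + 2)

        n_exons = int(rng.integers(spec.exons_range[0], spec.exons_range[1] + 1))
        n_exons = min(n_exons, max(1, T // 40))
        if n_exons > 1:
            cuts = sorted(rng.choice(np.arange(20, T - 20), size=n_exons - 1, replace=False))
        else:
            cuts = []
        t_bounds = [0, *map(int, cuts), T]
        exon_t = [(t_bounds[j], t_bounds[j + 1]) for j in range(n_exons)]

        locus_parts, exon_local = [], []
        pos = 0
        for j, (a, b) in enumerate(exon_t):
            if j > 0:
                ilen = int(rng.integers(spec.intron_range[0], spec.intron_range[1] + 1))
                locus_parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
                pos += ilen
            locus_parts.append(spliced[a:b])
            exon_local.append((pos, pos + (b - a)))
            pos += b - a
        locus_seq = "".join(locus_parts)
        L = len(locus_seq)
        if strand == "-":
            locus_seq = _revcomp(locus_seq)
            exon_local = [(L - e, L - s) for s, e in exon_local]  # keep 5'->3' order

        start = place_locus(chrom, locus_seq)
        exons = [(start + s, start + e) for s, e in exon_local]
        tm = TranscriptModel(
            transcript_id=f"{prefix}_t{i + 1:03d}",
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_start_t=utr5,
            cds_stop_t=utr5 + cds_len - 3,
        )
        loci.append(
            _Locus(
                gene_id=f"{prefix}_g{i + 1:03d}",
                transcript_id=tm.transcript_id,
                chromosome=chrom,
                strand=strand,
                kind="protein_coding",
                model=tm,
                utr5_len=utr5,
                cds_len=cds_len,
            )
        )

    # contaminant loci (single-exon, non-coding)
    conts = [("rRNA", spec.rrna_length_range)] * spec.n_rrna_loci + [
        ("tRNA", spec.trna_length_range)
    ] * spec.n_trna_loci
    for k, (kind, lrange) in enumerate(conts):
        chrom = chrom_names[k % spec.n_chromosomes]
        strand = "+" if k % 2 == 0 else "-"
        length = int(rng.integers(lrange[0], lrange[1] + 1))
        start = place_locus(chrom, _random_seq(rng, length))
        tm = TranscriptModel(
            transcript_id=f"{prefix}_{kind.lower()}_t{k + 1:02d}",
            chromosome=chrom,
            strand=strand,
            exons=[(start, start + length)],
        )
        loci.append(
            _Locus(
                gene_id=f"{prefix}_{kind.lower()}_g{k + 1:02d}",
                transcript_id=tm.transcript_id,
                chromosome=chrom,
                strand=strand,
                kind=kind,
                model=tm,
            )
        )

    for c in chrom_names:  # trailing pad
        parts[c].append(_random_seq(rng, 100))

    chrom_seqs = {c: "".join(parts[c]) for c in chrom_names}
    fasta_path = os.path.join(outdir, f"{prefix}.fa")
    with open(fasta_path, "w") as fh:
        for c in chrom_names:
            fh.write(f">{c}\n")
            s = chrom_seqs[c]
            for j in range(0, len(s), 70):
                fh.write(s[j : j + 70] + "\n")
    if os.path.exists(fasta_path + ".fai"):
        os.remove(fasta_path + ".fai")

    gff3_path = os.path.join(outdir, f"{prefix}.gff3")
    _write_gff3(loci, gff3_path)
    return SimulatedGenome(fasta_path, gff3_path, loci, chrom_seqs)


def _blocks_gff(tm: TranscriptModel, t_lo: int, t_hi: int) -> list[tuple[int, int]]:
    """1-based inclusive genomic blocks of a transcript interval."""
    return [(s + 1, e) for s, e in tm.transcript_interval_blocks(t_lo, t_hi)]


def _write_gff3(loci: list[_Locus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            tm = loc.model
            g1, g2 = tm.genomic_start + 1, tm.genomic_end
            c, st = loc.chromosome, loc.strand
            line = lambda typ, a, b, attrs: fh.write(
                f"{c}\tsim\t{typ}\t{a}\t{b}\t.\t{st}\t.\t{attrs}\n"
            )
            line("gene", g1, g2, f"ID={loc.gene_id}")
            ttype = "mRNA" if loc.kind == "protein_coding" else loc.kind
            line(ttype, g1, g2, f"ID={loc.transcript_id};Parent={loc.gene_id}")
            for j, (s, e) in enumerate(sorted(tm.exons)):
                line("exon", s + 1, e,
                     f"ID={loc.transcript_id}.exon{j + 1};Parent={loc.transcript_id}")
            if loc.kind == "protein_coding":
                for j, (a, b) in enumerate(_blocks_gff(tm, 0, loc.utr5_len)):
                    line("five_prime_UTR", a, b,
                         f"ID={loc.transcript_id}.utr5.{j + 1};Parent={loc.transcript_id}")
                for j, (a, b) in enumerate(
                    _blocks_gff(tm, loc.utr5_len, loc.utr5_len + loc.cds_len)
                ):
                    line("CDS", a, b,
                         f"ID={loc.transcript_id}.cds;Parent={loc.transcript_id}")
                t3_lo = loc.utr5_len + loc.cds_len
                for j, (a, b) in enumerate(_blocks_gff(tm, t3_lo, tm.length_t)):
                    line("three_prime_UTR", a, b,
                         f"ID={loc.transcript_id}.utr3.{j + 1};Parent={loc.transcript_id}")


def _write_gtf(loci: list[_Locus], path: str) -> None:
    # GTF convention: CDS excludes the stop codon, emitted as stop_codon
    with open(path, "w") as fh:
        for loc in loci:
            tm = loc.model
            g1, g2 = tm.genomic_start + 1, tm.genomic_end
            c, st = loc.chromosome, loc.strand
            attrs = f'gene_id "{loc.gene_id}"; transcript_id "{loc.transcript_id}";'
            gattrs = f'gene_id "{loc.gene_id}";'
            line = lambda typ, a, b, at: fh.write(
                f"{c}\tsim\t{typ}\t{a}\t{b}\t.\t{st}\t.\t{at}\n"
            )
            line("gene", g1, g2, gattrs)
            line("transcript", g1, g2, attrs)
            for s, e in sorted(tm.exons):
                line("exon", s + 1, e, attrs)
            if loc.kind == "protein_coding":
                cds_hi = loc.utr5_len + loc.cds_len - 3
                for a, b in _blocks_gff(tm, loc.utr5_len, cds_hi):
                    line("CDS", a, b, attrs)
                for a, b in _blocks_gff(tm, cds_hi, cds_hi + 3):
                    line("stop_codon", a, b, attrs)


def _read_to_segment(
    tm: TranscriptModel,
    five_t: int,
    length: int,
    chrom_seq: str,
    mapq: int,
    name: str,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    blocks = tm.transcript_interval_blocks(five_t, five_t + length)
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = tm.chromosome
    a.reference_start = blocks[0][0]
    a.mapping_quality = mapq
    a.flag = 0 if tm.strand == "+" else 16
    cigar = []
    for j, (s, e) in enumerate(blocks):
        if j > 0:
            cigar.append((3, s - blocks[j - 1][1]))  # N gap
        cigar.append((0, e - s))  # M
    a.cigartuples = cigar
    a.query_sequence = "".join(chrom_seq[s:e] for s, e in blocks)
    a.query_qualities = pysam.qualitystring_to_array("I" * length)
    return a


def simulate_reads(
    spec: SimSpec,
    genome: SimulatedGenome,
    out_bam: str,
    sample: str = "sample1",
    exp: str = "Ribo",
    seed: int | None = None,
    n_reads: int | None = None,
) -> str:
    """Simulate one sample's aligned reads and write a sorted, indexed BAM.

    Ribo-seq reads: a CDS codon is drawn (start codon up-weighted by
    ``start_pileup_weight``), a frame shift of 0/1/2 applied with
    probability ``in_frame_fraction`` / rest split evenly, and the read
    5' end placed ``offsets[length]`` nt upstream of that P-site in
    transcript space.  RNA-seq reads fall uniformly over transcripts.
    Contaminant reads fall uniformly over rRNA/tRNA loci.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_total = spec.reads_per_sample if n_reads is None else n_reads
    n_base = max(1, round(n_total * (1.0 - spec.duplication_rate)))

    coding = [l for l in genome.loci if l.kind == "protein_coding"]
    rrna = [l for l in genome.loci if l.kind == "rRNA"]
    trna = [l for l in genome.loci if l.kind == "tRNA"]
    lengths = np.array(sorted(spec.length_probs))
    lprobs = np.array([spec.length_probs[int(l)] for l in lengths])

    def draw_category() -> str:
        u = rng.random()
        if rrna and u < spec.frac_rrna:
            return "rRNA"
        if trna and u < spec.frac_rrna + spec.frac_trna:
            return "tRNA"
        return "gene"

    def draw_shift() -> int:
        u = rng.random()
        if u < spec.in_frame_fraction:
            return 0
        return 1 if u < spec.in_frame_fraction + (1 - spec.in_frame_fraction) / 2 else 2

    def draw_placement(category: str, length: int, shift: int):
        if category in ("rRNA", "tRNA"):
            pool = rrna if category == "rRNA" else trna
            loc = pool[int(rng.integers(len(pool)))]
            return loc.model, int(rng.integers(0, loc.model.length_t - length + 1))
        loc = coding[int(rng.integers(len(coding)))]
        tm = loc.model
        if exp == "RNA":
            return tm, int(rng.integers(0, tm.length_t - length + 1))
        offset = spec.offsets[length]
        n_codons = (loc.cds_len - 3) // 3  # sense codons only
        for _ in range(50):
            if rng.random() < spec.start_pileup_weight:
                codon = 0
            else:
                codon = int(rng.integers(0, n_codons))
            five = tm.cds_start_t + 3 * codon + shift - offset
            if 0 <= five and five + length <= tm.length_t:
                return tm, five
        return tm, max(0, tm.cds_start_t - offset)

    # Base reads are kept distinct in (transcript, 5' end, length) so the
    # duplication dial maps exactly onto the distinct-alignment metric;
    # duplicates are then added as verbatim copies.  On a position clash
    # only the placement (gene/codon) is redrawn — category, length and
    # frame shift are held fixed so their marginals stay unbiased.
    base: list[tuple[TranscriptModel, int, int]] = []
    seen: set[tuple[str, int, int]] = set()
    for _ in range(n_base):
        category = draw_category()
        length = int(rng.choice(lengths, p=lprobs))
        shift = draw_shift()
        tm, five = draw_placement(category, length, shift)
        for _attempt in range(200):
            if (tm.transcript_id, five, length) not in seen:
                break
            tm, five = draw_placement(category, length, shift)
        seen.add((tm.transcript_id, five, length))
        base.append((tm, five, length))
    picks = list(range(n_base)) + [
        int(rng.integers(0, n_base)) for _ in range(n_total - n_base)
    ]
    mapqs = np.where(
        rng.random(n_total) < spec.unique_fraction,
        50,
        rng.choice([1, 3, 10], size=n_total),
    )

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": len(s)} for c, s in sorted(genome.chrom_seqs.items())
            ],
        }
    )
    segs = []
    for i, pick in enumerate(picks):
        tm, five, length = base[pick]
        segs.append(
            _read_to_segment(
                tm, five, length, genome.chrom_seqs[tm.chromosome],
                int(mapqs[i]), f"{sample}.r{i + 1}", header,
            )
        )
    segs.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(out_bam)
    return out_bam


def reference_metrics_fixture(
    spec: SimSpec,
    outdir: str,
    n_samples: int = 6,
    n_reads: int | None = None,
) -> str:
    """Build a synthetic good-quality reference QC-metric table.

    Runs the full annotate -> offsets -> summary pipeline over
    ``n_samples`` independently simulated samples of the given spec and
    writes their per-sample QC rows to ``reference_metrics.tsv``.  This
    synthetic table stands in for curated reference libraries when
    screening user samples against a reference corpus.
    """
    from .alignments import load_alignments, annotate
    from .offsets import build_offset_table
    from .qc import summary_table

    os.makedirs(outdir, exist_ok=True)
    genome = simulate_genome(spec, outdir, prefix="ref")
    ann = parse_annotation(genome.gff3_path, genome.fasta_path)
    tables = []
    for i in range(n_samples):
        bam = os.path.join(outdir, f"ref_s{i + 1}.bam")
        simulate_reads(
            spec, genome, bam, sample=f"ref_s{i + 1}", exp="Ribo",
            seed=spec.seed + 1000 + i, n_reads=n_reads,
        )
        tab = load_alignments(bam, sample=f"ref_s{i + 1}", exp="Ribo")
        offs = build_offset_table(tab, ann)
        tables.append(annotate(tab, ann, offs))
    summary = summary_table(tables, ann)
    path = os.path.join(outdir, "reference_metrics.tsv")
    summary.to_csv(path, sep="\t", index=False)
    return path
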