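# Methods

This note documents the models, conventions and numerical choices behind
`riboqc`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate and annotation model

All internal coordinates are 0-based half-open; 1-based GFF3/GTF/SAM
conventions are converted at the parsing boundary. Annotation dialect is
auto-detected from the file extension, then from the attribute syntax.
In GTF input, `stop_codon` records are folded into the CDS so that
coding spans include the stop codon under both dialects.

Each gene is represented by one **major isoform**, selected as: coding
beats non-coding, then longest CDS, then longest spliced length, then
lexicographically smallest transcript id. The rule is deterministic and
independent of record order in the file. All transcript-coordinate
quantities (`start_dist`, `end_dist`, `frame`, metagene positions, RPKM
gene lengths) are computed on the major isoform.

Feature assignment is strand-specific and most-specific-wins:
rRNA/tRNA/other ncRNA classes outrank protein-coding sub-features
(contamination must stay visible to QC), then
CDS > five_prime_UTR > three_prime_UTR > exon > mRNA/transcript > gene;
a position overlapping nothing on its strand is `Other`. Feature labels
are exactly the types present in the annotation file, plus the reserved
`Other`.

## P-site model

A footprint's P-site lies a length-dependent distance downstream of its
5′ end. For each read length the unadjusted 5′ ends are aggregated
relative to the start codons of all coding major isoforms over a
window of [−40, +20] nt (position 0 = first nt of the start codon; the
window comfortably covers all footprint lengths in use). A periodic
library shows 3-nt-spaced peaks; the peaks of the **dominant frame
class** — the residue class mod 3 carrying the most upstream density —
are the in-frame ones, and the largest of them is the
initiating-ribosome pile-up. The offset is the distance from that peak
to the start codon. Defining candidates by the dominant class rather
than by positions ≡ 0 mod 3 matters: true offsets are frequently not
multiples of three (e.g. 11 nt for 27-mers, 13 nt for 29-mers), so the
initiation peak generally does not sit on a codon boundary.

Numerical details: ties at equal peak height break toward the smaller
offset; lengths with fewer than `min_reads = 50` reads in the window, or
with no upstream signal at all, fall back to a configurable default of
12 nt (the canonical eukaryotic 5′→P-site distance) and are flagged in
the per-length diagnostics. Offsets are clamped to [0, read length].
In practice calibration needs on the order of 50+ reads per length
inside the window, i.e. a few thousand reads per sample on a small
genome; below that the fallback keeps 28-mers usable but misadjusts
neighbouring lengths.

P-site placement walks the offset in **spliced transcript space**
whenever the 5′ end lies on an exon of a major isoform, so offsets step
across exon junctions correctly; otherwise it falls back to a plain
strand-aware genomic shift. RNA-seq reads get offset 0 (their 5′ end is
their position). Frame is `(t(pos) − t(start)) mod 3` on the major
isoform, reported only when the P-site falls on an exon of a coding
major isoform; the anchor is configurable to the transcript 5′ end
instead of the start codon (`frame_anchor="transcript_start"`), since
"relative to the transcription start" and "in frame with the start
codon" differ — the start codon is the default because triplet
periodicity is a property of translation.

## QC metrics

* **Periodicity**: fraction of CDS-mapped P-sites in frame 0 (frames
  sum to 1 over reads with a defined frame).
* **Complexity / duplication**: distinct (chromosome, strand, start,
  length) tuples divided by total records, and its complement. These are
  deliberately simple library-complexity proxies computable from a BAM
  alone; they are not UMI-aware.
* **RPKM** = reads·10⁹ / (total mapped reads in sample × major-isoform
  spliced length in nt). A read counts toward the gene its P-site
  (Ribo) or 5′ end (RNA) was assigned to. RPKM is invariant under
  whole-sample duplication.
* **Translational efficiency** = (RPKM_ribo + c) / (RPKM_rna + c) with
  pseudocount c = 0 by default; genes with zero RNA signal are reported
  as undefined (NaN) and warned about rather than silently clipped. The
  ratio-of-RPKM form is the minimal standard definition; no statistical
  test is attached (differential testing is out of scope).
* **Metagene profiles** anchor at the first nt of the start or stop
  codon and sum P-site counts per relative position across all major
  isoforms. Optional subsampling is uniform without replacement under a
  caller-supplied seed, hence bit-reproducible, and is the identity when
  n reaches the table size.

Percent vectors (feature percentages, per-group fractions) sum to
100 / 1 by construction before rounding.

## Anomaly screening

Four independent strategies over the per-sample summary metrics:

1. **Expert thresholds** — direction-aware cutoffs; defaults
   periodicity ≥ 0.50, CDS% ≥ 50, rRNA% ≤ 20, tRNA% ≤ 10. These are
   tool defaults chosen as loose sanity bounds, not published norms;
   every value is configurable.
2. **Tukey's fence within the cohort** — flag values strictly outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles use linear interpolation
   (the common "type 7" convention); values exactly on a fence are not
   flagged; fewer than 4 samples skips the strategy with a warning.
3. **Controls** — percent error |x − mean(controls)| / |mean(controls)|,
   flagged strictly above 25%; zero control means skip the metric with a
   warning.
4. **Reference corpus** — strategy 2's fences computed from an external
   reference metric table (schema-compatible with the summary table).
   The package ships no curated corpus; `reference_metrics_fixture`
   builds a synthetic good-quality one, and users substitute their own
   TSV.

All verdicts (flagged or not) are emitted with the observed value, the
fence/reference and a human-readable reason.

## Synthetic-data generator

`SimSpec` defaults describe a small high-quality footprint library:
27–29 nt reads (25/50/25%), true offsets 27:11 / 28:12 / 29:13,
in-frame fraction 0.7, 10% start-codon pile-up weight, 5% rRNA and 2%
tRNA read contamination, 10% duplication, 85% uniquely-mapping (mapq 50)
reads, 20 genes on 2 chromosomes with 30–60 nt UTRs and 100–200 codon
CDSs. Genes alternate strands; exon counts are configurable (single-exon
by default, multi-exon for coordinate stress tests). Contaminant loci
are annotated rRNA/tRNA genes.

Ribo-seq reads are placed codon-first: draw a codon (start codon
up-weighted), a frame shift (0 with the in-frame probability, else 1/2
evenly), then set the 5′ end `offset[L]` nt upstream of that P-site in
transcript space. Base reads are kept distinct in (transcript, 5′ end,
length) so the duplication dial maps exactly onto the
distinct-alignment metric; on a position clash only the placement is
redrawn, keeping category/length/frame marginals unbiased. Duplicates
are verbatim copies. Multi-mapping is emulated purely through mapq
values.

Not emulated: sequencing errors and base qualities, splice-junction
*reads* (reads lie within exons; genes themselves may be multi-exon),
UMIs, paired ends, biased nucleotide composition, and real digestion
heterogeneity. Passing tests therefore demonstrate correctness of the
measurement machinery under controlled conditions, not robustness to
every artefact of real libraries.

## Pipeline and reproducibility

`run_pipeline` validates all inputs up front, then runs annotation →
per-sample offset calibration → the selected tools → anomaly screening,
writing every table as TSV, plots as PNG/PDF, and a `manifest.json`
with a sha256 checksum per file; `run.log` records input checksums, the
full parameter dump and per-stage timings. All stochastic steps
(subsampling) take the config seed, so identical configs over identical
inputs reproduce every table byte-for-byte. The HTML report embeds the
selected tools' figures and table heads, the full parameter echo, and
optional user notes (section omitted when empty), in tool order.

## Problem sizes

Tests and the acceptance script run on simulated data sized for
sharpness per unit cost: 3,000–5,000 reads per sample for recovery
checks (binomial error on the in-frame fraction ≈ 0.008 at n ≈ 3,000),
12–20 genes per genome, 1,000 random vectors for the fence oracle, and
two 2×2,500-read pipeline runs for the byte-identity check.

## Known limitations

* One offset table per sample; no per-gene or per-codon refinement, and
  no A-site/E-site offsets.
* Reads are assigned to at most one gene (first coding major isoform
  carrying the 5′ end, then the feature index at the adjusted
  position); overlapping genes on the same strand resolve
  deterministically but coarsely.
* `start_dist` follows the transcript 5′ end, so it conflates
  transcription start with UTR length for genes with inaccurate UTR
  annotation.
* Differential translation testing (fold-change significance) is out of
  scope by design; the package stops at RPKM/TE.
* The expert thresholds and the synthetic reference corpus are
  placeholders for lab-specific calibration, not community standards.
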