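"""Build a miniature Ribo-seq study: genome, annotation and aligned reads.

The generator writes a FASTA + GFF3 pair (protein-coding genes with
UTR/CDS structure on both strands, plus rRNA/tRNA contaminant loci) and
a coordinate-sorted BAM whose reads carry known P-site offsets, in-frame
fraction, duplication rate and mapq mix — a fully controlled ground
truth for the QC tools.
"""

import collections

import pysam

from riboqc import SimSpec, simulate_genome, simulate_reads

OUT = "scratch/example01"

spec = SimSpec(seed=1, n_genes=12, reads_per_sample=4000)
genome = simulate_genome(spec, OUT)
bam = simulate_reads(spec, genome, f"{OUT}/ribo.bam", sample="demo", exp="Ribo")

print(f"FASTA      : {genome.fasta_path}")
print(f"GFF3       : {genome.gff3_path}")
print(f"BAM        : {bam}")
print(f"loci       : {collections.Counter(l.kind for l in genome.loci)}")
with pysam.AlignmentFile(bam) as fh:
    lengths = collections.Counter(r.query_length for r in fh.fetch(until_eof=True))
print(f"read counts by length: {dict(sorted(lengths.items()))}")
print("Lengths 27/28/29 nt carry true P-site offsets 11/12/13; 70% of")
print("P-sites are in frame 0 — the QC tools should measure exactly that.")
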