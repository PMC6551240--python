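"""Metagene P-site density around translation start and stop codons.

Ribo-seq libraries pile up at initiation and show 3-nt periodic density
across the CDS; the profile anchors every major isoform at its start (or
stop) codon and sums P-site counts per relative position.
"""

import numpy as np

from riboqc import (
    SimSpec, simulate_genome, simulate_reads, parse_annotation,
    load_alignments, build_offset_table, annotate, metagene_profile,
)

OUT = "scratch/example04"

spec = SimSpec(seed=4, reads_per_sample=5000)
genome = simulate_genome(spec, OUT)
ann = parse_annotation(genome.gff3_path, genome.fasta_path)
bam = simulate_reads(spec, genome, f"{OUT}/ribo.bam", sample="demo", exp="Ribo")
table = load_alignments(bam, "demo", "Ribo")
atable = annotate(table, ann, build_offset_table(table, ann))

start = metagene_profile(atable, ann, anchor="start", window=(-30, 60))
peak = start.positions[np.argmax(start.counts)]
cds = start.positions >= 0
inframe = start.counts[cds & (start.positions % 3 == 0)].sum() / start.counts[cds].sum()
print(f"start anchor: {start.counts.sum()} P-sites in window, initiation peak "
      f"at {peak:+d} nt, CDS in-frame share {inframe:.2f}")

stop = metagene_profile(atable, ann, anchor="stop", window=(-60, 10))
print(f"stop anchor : {stop.counts.sum()} P-sites in window; density ends at "
      f"{stop.positions[stop.counts > 0].max():+d} nt (ribosomes stop at the stop codon)")

sub = metagene_profile(atable, ann, anchor="start", window=(-30, 60),
                       subsample=(1000, 7))
print(f"\nsubsampled profile (n=1000, seed=7) tallies {sub.counts.sum()} P-sites —")
print("uniform without replacement, so reruns are bit-identical.")
print("Expected: a sharp peak at 0 (initiation) and ~70% of downstream")
print("P-site density on codon positions (frame 0).")
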