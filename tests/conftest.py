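"""Shared fixtures: a hand-written toy locus and simulated datasets.

All data are generated programmatically; nothing is read from disk
fixtures.  Session scope keeps the simulations cheap to reuse.
"""

import os
import textwrap

import pytest

from riboqc.alignments import annotate, load_alignments
from riboqc.genome import parse_annotation
from riboqc.offsets import build_offset_table
from riboqc.simulate import SimSpec, simulate_genome, simulate_reads

# --- hand-written toy locus -------------------------------------------------
# chrT (300 nt): gene tg1 on '+' with two isoforms.
#   tg1.t1: exons 10-100, 150-250 (1-based, inclusive); CDS 40-100 + 150-220
#   tg1.t2: exon 10-250 single block; CDS 40-219 (shorter CDS)
TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chrT\ttoy\tgene\t10\t250\t.\t+\t.\tID=tg1
    chrT\ttoy\tmRNA\t10\t250\t.\t+\t.\tID=tg1.t1;Parent=tg1
    chrT\ttoy\texon\t10\t100\t.\t+\t.\tID=tg1.t1.e1;Parent=tg1.t1
    chrT\ttoy\texon\t150\t250\t.\t+\t.\tID=tg1.t1.e2;Parent=tg1.t1
    chrT\ttoy\tfive_prime_UTR\t10\t39\t.\t+\t.\tID=tg1.t1.u5;Parent=tg1.t1
    chrT\ttoy\tCDS\t40\t100\t.\t+\t.\tID=tg1.t1.c;Parent=tg1.t1
    chrT\ttoy\tCDS\t150\t220\t.\t+\t.\tID=tg1.t1.c;Parent=tg1.t1
    chrT\ttoy\tthree_prime_UTR\t221\t250\t.\t+\t.\tID=tg1.t1.u3;Parent=tg1.t1
    chrT\ttoy\tmRNA\t10\t250\t.\t+\t.\tID=tg1.t2;Parent=tg1
    chrT\ttoy\texon\t10\t250\t.\t+\t.\tID=tg1.t2.e1;Parent=tg1.t2
    chrT\ttoy\tCDS\t40\t219\t.\t+\t.\tID=tg1.t2.c;Parent=tg1.t2
    """
)


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    gff = d / "toy.gff3"
    gff.write_text(TOY_GFF3)
    fa = d / "toy.fa"
    seq = ("ACGT" * 80)[:300]
    fa.write_text(">chrT\n" + seq + "\n")
    return str(gff), str(fa)


@pytest.fixture(scope="session")
def toy_annotation(toy_paths):
    return parse_annotation(*toy_paths)


# --- simulated default-condition dataset ------------------------------------

@pytest.fixture(scope="session")
def sim_spec():
    return SimSpec(seed=11, reads_per_sample=3000)


@pytest.fixture(scope="session")
def sim_genome(sim_spec, tmp_path_factory):
    return simulate_genome(sim_spec, str(tmp_path_factory.mktemp("simg")))


@pytest.fixture(scope="session")
def sim_annotation(sim_genome):
    return parse_annotation(sim_genome.gff3_path, sim_genome.fasta_path)


@pytest.fixture(scope="session")
def ribo_table(sim_spec, sim_genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("simbam")
    bam = os.path.join(str(d), "ribo1.bam")
    simulate_reads(sim_spec, sim_genome, bam, sample="ribo1", exp="Ribo", seed=21)
    return load_alignments(bam, "ribo1", "Ribo")


@pytest.fixture(scope="session")
def rna_table(sim_spec, sim_genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("simbam_rna")
    bam = os.path.join(str(d), "rna1.bam")
    simulate_reads(sim_spec, sim_genome, bam, sample="rna1", exp="RNA",
                   seed=22, n_reads=1500)
    return load_alignments(bam, "rna1", "RNA")


@pytest.fixture(scope="session")
def sim_offsets(ribo_table, sim_annotation):
    return build_offset_table(ribo_table, sim_annotation)


@pytest.fixture(scope="session")
def annotated_table(ribo_table, sim_annotation, sim_offsets):
    return annotate(ribo_table, sim_annotation, sim_offsets)


# --- multi-exon genome for coordinate/frame stress tests --------------------

@pytest.fixture(scope="session")
def multiexon_genome(tmp_path_factory):
    spec = SimSpec(seed=7, n_genes=12, exons_range=(2, 4), reads_per_sample=1500)
    genome = simulate_genome(spec, str(tmp_path_factory.mktemp("mx")))
    return spec, genome


@pytest.fixture(scope="session")
def multiexon_annotation(multiexon_genome):
    _, genome = multiexon_genome
    return parse_annotation(genome.gff3_path, genome.fasta_path)
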