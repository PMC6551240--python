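"""Alignment loading, per-read attributes, filtering/grouping."""

import os
import warnings

import pandas as pd
import pysam
import pytest

from riboqc.alignments import (
    AlignmentTable,
    annotate,
    classify_unique,
    compute_gc,
    filter_and_group,
    load_alignments,
)
from riboqc.offsets import OffsetTable
from riboqc.simulate import simulate_reads


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("GGGG", 1.0), ("ATNN", 0.0), ("acgc", 0.75)],
)
def test_compute_gc(seq, expected):
    assert compute_gc(seq) == pytest.approx(expected)


def test_compute_gc_empty_is_error():
    with pytest.raises(ValueError):
        compute_gc("")


@pytest.mark.parametrize(
    "mapq,unique_mapq,expected",
    [(50, 50, True), (1, 50, False), (49, 50, False), (255, 255, True)],
)
def test_classify_unique(mapq, unique_mapq, expected):
    assert classify_unique(mapq, unique_mapq) is expected


def _write_toy_bam(path, n_primary=5, n_secondary=2, n_unmapped=0):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chrT", "LN": 300}]}
    )
    segs = []
    for i in range(n_primary + n_secondary + n_unmapped):
        a = pysam.AlignedSegment(header)
        a.query_name = f"r{i}"
        a.query_sequence = "A" * 28
        a.query_qualities = pysam.qualitystring_to_array("I" * 28)
        if i >= n_primary + n_secondary:
            a.flag = 4  # unmapped
        else:
            a.reference_name = "chrT"
            a.reference_start = 10 + i
            a.cigarstring = "28M"
            a.mapping_quality = 50
            a.flag = 256 if i >= n_primary else 0
        segs.append(a)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(path)


class TestLoadAlignments:
    def test_secondary_and_unmapped_dropped(self, tmp_path):
        p = str(tmp_path / "toy.bam")
        _write_toy_bam(p, n_primary=5, n_secondary=2, n_unmapped=1)
        tab = load_alignments(p, "s", "Ribo")
        assert len(tab) == 5
        assert tab.provenance["s"]["dropped"] == {
            "unmapped": 1, "secondary": 2, "supplementary": 0,
        }

    def test_read_length_is_read_bases(self, tmp_path):
        p = str(tmp_path / "toy.bam")
        _write_toy_bam(p, n_primary=1, n_secondary=0)
        tab = load_alignments(p, "s", "Ribo")
        assert tab.df["length"].tolist() == [28]

    def test_empty_bam_warns_not_crashes(self, tmp_path):
        p = str(tmp_path / "empty.bam")
        _write_toy_bam(p, n_primary=0, n_secondary=0)
        with pytest.warns(UserWarning, match="no retained"):
            tab = load_alignments(p, "s", "Ribo")
        assert len(tab) == 0

    def test_bad_exp_label_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            load_alignments("x.bam", "s", "ribo")


def _mk_table(rows):
    df = pd.DataFrame(
        rows,
        columns=["seqnames", "range_start", "range_end", "strand", "sample",
                 "exp", "length", "gc", "mapq"],
    )
    return AlignmentTable(df)


class TestAnnotate:
    # major isoform of toy gene tg1 is tg1.t2: one exon (9, 250),
    # cds_start_t=30, cds_stop_t=207
    def test_psite_at_start_codon(self, toy_annotation):
        tab = _mk_table([("chrT", 27, 55, "+", "s", "Ribo", 28, 0.5, 50)])
        out = annotate(tab, toy_annotation, OffsetTable.fixed(12))
        row = out.df.iloc[0]
        assert row["pos"] == 39  # genomic of cds_start_t
        assert row["frame"] == 0
        assert row["start_dist"] == 30
        assert row["end_dist"] == 207 - 30  # cds_stop_t - cds_start_t

    def test_psite_four_nt_downstream_is_frame_one(self, toy_annotation):
        tab = _mk_table([("chrT", 31, 59, "+", "s", "Ribo", 28, 0.5, 50)])
        out = annotate(tab, toy_annotation, OffsetTable.fixed(12))
        assert out.df.iloc[0]["frame"] == 1

    def test_intergenic_psite(self, toy_annotation):
        tab = _mk_table([("chrT", 270, 298, "+", "s", "Ribo", 28, 0.5, 50)])
        out = annotate(tab, toy_annotation, OffsetTable.fixed(12))
        row = out.df.iloc[0]
        assert row["gene"] == "Other" and row["feature"] == "Other"
        assert pd.isna(row["frame"]) and pd.isna(row["start_dist"])

    def test_transcript_start_anchor(self, toy_annotation):
        tab = _mk_table([("chrT", 27, 55, "+", "s", "Ribo", 28, 0.5, 50)])
        out = annotate(tab, toy_annotation, OffsetTable.fixed(12),
                       frame_anchor="transcript_start")
        assert out.df.iloc[0]["frame"] == 30 % 3

    def test_rna_reads_use_five_prime_end(self, toy_annotation):
        tab = _mk_table([("chrT", 39, 67, "+", "s", "RNA", 28, 0.5, 50)])
        out = annotate(tab, toy_annotation, OffsetTable.fixed(12))
        assert out.df.iloc[0]["pos"] == 39  # no offset applied to RNA

    def test_idempotent(self, annotated_table, sim_annotation, sim_offsets):
        again = annotate(annotated_table, sim_annotation, sim_offsets)
        pd.testing.assert_frame_equal(again.df, annotated_table.df)

    def test_frame_matches_base_walk_oracle(self, multiexon_genome,
                                            multiexon_annotation, tmp_path):
        spec, genome = multiexon_genome
        bam = str(tmp_path / "mx.bam")
        simulate_reads(spec, genome, bam, sample="mx", exp="Ribo", seed=3)
        tab = load_alignments(bam, "mx", "Ribo")
        offs = OffsetTable(entries=dict(spec.offsets))
        out = annotate(tab, multiexon_annotation, offs)
        walks = {}
        for gid, gm in multiexon_annotation.genes.items():
            tm = gm.major_isoform
            bases = []
            for s, e in tm.exons:
                bases.extend(range(s, e) if tm.strand == "+" else range(e - 1, s - 1, -1))
            walks[gid] = ({g: i for i, g in enumerate(bases)}, tm)
        checked = 0
        for row in out.df.itertuples():
            if pd.isna(row.frame) or row.gene not in walks:
                continue
            index, tm = walks[row.gene]
            tpos = index[row.pos]
            assert row.frame == (tpos - tm.cds_start_t) % 3
            assert row.start_dist == tpos
            assert row.end_dist == tm.cds_stop_t - tpos
            checked += 1
        assert checked > 500


class TestFilterAndGroup:
    def test_filter_feature_cds(self, annotated_table):
        groups = filter_and_group(annotated_table, filters={"feature": "CDS"})
        (_, tab), = groups
        assert set(tab.df["feature"]) == {"CDS"}
        assert len(tab) > 0

    def test_partition_property(self, annotated_table):
        groups = filter_and_group(annotated_table, group_by=["length"])
        assert sum(len(t) for _, t in groups) == len(annotated_table)

    def test_range_filter_and_group(self, annotated_table):
        groups = filter_and_group(
            annotated_table,
            filters={"length": (27, 29), "exp": "Ribo"},
            group_by=["length"],
        )
        assert 1 <= len(groups) <= 3
        for (length,), tab in groups:
            assert 27 <= length <= 29

    def test_callable_filter(self, annotated_table):
        groups = filter_and_group(annotated_table, filters={"gc": lambda g: g > 0.5})
        (_, tab), = groups
        assert (tab.df["gc"] > 0.5).all()

    def test_unknown_attribute_named_in_error(self, annotated_table):
        with pytest.raises(KeyError, match="not_an_attr"):
            filter_and_group(annotated_table, filters={"not_an_attr": 1})

    def test_tsv_roundtrip(self, annotated_table, tmp_path):
        p = str(tmp_path / "tab.tsv")
        annotated_table.to_tsv(p)
        back = AlignmentTable.from_tsv(p)
        assert len(back) == len(annotated_table)
        pd.testing.assert_series_equal(
            back.df["frame"].astype("Int64"), annotated_table.df["frame"],
            check_names=False,
        )
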