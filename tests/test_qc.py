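"""QC metric surfaces: distributions, periodicity, metagene, RPKM/TE, summary."""

import numpy as np
import pandas as pd
import pytest

from riboqc.alignments import AlignmentTable, annotate, filter_and_group
from riboqc.offsets import OffsetTable
from riboqc.qc import (
    complexity,
    duplication,
    feature_percentages,
    frame_periodicity,
    gc_distribution,
    metagene_profile,
    read_length_distribution,
    rpkm,
    summary_table,
    translational_efficiency,
)

COLS = ["seqnames", "range_start", "range_end", "strand", "sample", "exp",
        "length", "gc", "mapq"]


def _table(rows, extra=None):
    df = pd.DataFrame(rows, columns=COLS)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return AlignmentTable(df)


def _rows(n, length=28, gc=0.5, start=0, sample="s", exp="Ribo", mapq=50):
    return [("c1", start + i, start + i + length, "+", sample, exp, length, gc, mapq)
            for i in range(n)]


class TestDistributions:
    def test_single_length_group(self):
        groups = [(("g",), _table(_rows(10)))]
        dist = read_length_distribution(groups)
        assert dist["fraction"].tolist() == [1.0]

    def test_length_fractions(self):
        rows = _rows(2, length=27) + _rows(6, length=28) + _rows(2, length=29)
        dist = read_length_distribution([((), _table(rows))])
        assert dist.set_index("length")["fraction"].to_dict() == {
            27: 0.2, 28: 0.6, 29: 0.2,
        }

    def test_groups_normalized_independently(self, annotated_table):
        groups = filter_and_group(annotated_table, group_by=["length"])
        dist = read_length_distribution(groups)
        sums = dist.groupby("group")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_gc_point_mass(self):
        dist = gc_distribution([((), _table(_rows(5, gc=0.5)))], bins=10)
        hit = dist[dist["count"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["bin_left"] == 0.5 and hit.iloc[0]["fraction"] == 1.0

    def test_gc_matches_direct_tally(self, annotated_table):
        dist = gc_distribution([((), annotated_table)], bins=20)
        gc = annotated_table.df["gc"].to_numpy()
        direct, _ = np.histogram(gc, bins=np.linspace(0, 1, 21))
        assert dist["count"].tolist() == direct.tolist()

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning):
            dist = gc_distribution([(("e",), _table([]))])
        assert dist.empty


class TestFeaturePercentages:
    def test_two_features(self):
        tab = _table(_rows(80) + _rows(20), extra=None)
        tab.df["feature"] = ["CDS"] * 80 + ["rRNA"] * 20
        fp = feature_percentages([((), tab)])
        assert fp.set_index("feature")["pct"].to_dict() == {"CDS": 80.0, "rRNA": 20.0}

    def test_single_feature_is_100(self):
        tab = _table(_rows(7))
        tab.df["feature"] = "CDS"
        fp = feature_percentages([((), tab)])
        assert fp["pct"].tolist() == [100.0]

    def test_sums_to_100_on_fixture(self, annotated_table):
        fp = feature_percentages(filter_and_group(annotated_table, group_by=["sample"]))
        assert np.allclose(fp.groupby("group")["pct"].sum(), 100.0, atol=1e-9)

    def test_by_frame(self, annotated_table):
        fp = feature_percentages([((), annotated_table)], by="frame")
        labels = set(fp["frame"])
        assert {0, 1, 2} <= labels
        assert fp["pct"].sum() == pytest.approx(100.0)


class TestFramePeriodicity:
    def test_all_in_frame(self):
        tab = _table(_rows(5), extra={"frame": 0})
        assert frame_periodicity(tab) == (1.0, 0.0, 0.0)

    def test_mixed_frames(self):
        tab = _table(_rows(10), extra={"frame": [0] * 6 + [1] * 2 + [2] * 2})
        assert frame_periodicity(tab) == (0.6, 0.2, 0.2)

    def test_recovers_generator_fraction(self, annotated_table, sim_spec):
        f0, f1, f2 = frame_periodicity(annotated_table)
        n = annotated_table.df["frame"].notna().sum()
        sigma = np.sqrt(0.7 * 0.3 / n)
        assert abs(f0 - sim_spec.in_frame_fraction) < 3 * sigma
        assert f0 + f1 + f2 == pytest.approx(1.0)


def _psite_reads(annotation, tpositions, length=28):
    """Reads whose P-site (offset 12) lands at the given transcript
    positions of the toy major isoform."""
    tm = annotation.genes["tg1"].major_isoform
    rows = []
    for tp in tpositions:
        g5 = tm.transcript_to_genomic(tp - 12)
        rows.append(("chrT", g5, g5 + length, "+", "s", "Ribo", length, 0.5, 50))
    tab = _table(rows)
    return annotate(tab, annotation, OffsetTable.fixed(12))


class TestMetagene:
    def test_spike_at_start_codon(self, toy_annotation):
        tm = toy_annotation.genes["tg1"].major_isoform
        tab = _psite_reads(toy_annotation, [tm.cds_start_t] * 9)
        prof = metagene_profile(tab, toy_annotation, anchor="start", window=(-30, 30))
        assert prof.counts.sum() == 9
        assert prof.positions[np.argmax(prof.counts)] == 0

    def test_spike_upstream_of_stop(self, toy_annotation):
        tm = toy_annotation.genes["tg1"].major_isoform
        tab = _psite_reads(toy_annotation, [tm.cds_stop_t - 30] * 4)
        prof = metagene_profile(tab, toy_annotation, anchor="stop", window=(-60, 10))
        assert prof.positions[np.argmax(prof.counts)] == -30

    def test_subsample_identity_when_n_is_table_size(self, annotated_table,
                                                     sim_annotation):
        full = metagene_profile(annotated_table, sim_annotation)
        same = metagene_profile(annotated_table, sim_annotation,
                                subsample=(len(annotated_table), 1))
        assert np.array_equal(full.counts, same.counts)

    def test_subsample_reproducible(self, annotated_table, sim_annotation):
        a = metagene_profile(annotated_table, sim_annotation, subsample=(500, 42))
        b = metagene_profile(annotated_table, sim_annotation, subsample=(500, 42))
        c = metagene_profile(annotated_table, sim_annotation, subsample=(500, 43))
        assert np.array_equal(a.counts, b.counts)
        assert a.counts.sum() <= 500
        assert not np.array_equal(a.counts, c.counts)  # different seed

    def test_subsample_converges_to_full_shape(self, annotated_table, sim_annotation):
        full = metagene_profile(annotated_table, sim_annotation).normalize()
        sub = metagene_profile(annotated_table, sim_annotation,
                               subsample=(2500, 0)).normalize()
        # large subsample tracks the full profile closely in L1
        assert np.abs(full.counts - sub.counts).sum() < 0.2

    def test_normalize(self, annotated_table, sim_annotation):
        prof = metagene_profile(annotated_table, sim_annotation).normalize()
        assert prof.counts.sum() == pytest.approx(1.0)
        assert prof.normalized


class TestComplexity:
    def test_all_identical(self):
        tab = _table([("c1", 5, 33, "+", "s", "Ribo", 28, 0.5, 50)] * 4)
        assert complexity(tab) == 0.25
        assert duplication(tab) == 0.75

    def test_all_distinct(self):
        tab = _table(_rows(10))
        assert complexity(tab) == 1.0 and duplication(tab) == 0.0

    def test_matches_set_oracle(self, ribo_table):
        df = ribo_table.df
        oracle = len({
            (r.seqnames, r.strand, r.range_start, r.length)
            for r in df.itertuples()
        }) / len(df)
        assert complexity(ribo_table) == pytest.approx(oracle)


class TestRpkmTe:
    def test_hand_calculation(self, toy_annotation):
        # 10 of 1000 reads on tg1 (major isoform spliced length 241)
        tab = _table(_rows(1000))
        tab.df["gene"] = ["tg1"] * 10 + ["Other"] * 990
        val = rpkm(tab, toy_annotation)["tg1"]
        assert val == pytest.approx(10 * 1e9 / (1000 * 241))

    def test_zero_reads_zero_rpkm(self, toy_annotation):
        tab = _table(_rows(100))
        tab.df["gene"] = "Other"
        assert rpkm(tab, toy_annotation)["tg1"] == 0.0

    def test_invariant_under_sample_duplication(self, annotated_table,
                                                sim_annotation):
        single = rpkm(annotated_table, sim_annotation)
        doubled = rpkm(AlignmentTable.concat([annotated_table, annotated_table]),
                       sim_annotation)
        pd.testing.assert_series_equal(single, doubled)

    def test_te_ratio(self):
        te = translational_efficiency(pd.Series({"g": 10.0}), pd.Series({"g": 5.0}))
        assert te["g"] == pytest.approx(2.0)

    def test_te_zero_ribo(self):
        te = translational_efficiency(pd.Series({"g": 0.0}), pd.Series({"g": 5.0}))
        assert te["g"] == 0.0

    def test_te_undefined_when_rna_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            te = translational_efficiency(pd.Series({"g": 1.0}), pd.Series({"g": 0.0}))
        assert np.isnan(te["g"])

    def test_te_pseudocount(self):
        te = translational_efficiency(
            pd.Series({"g": 1.0}), pd.Series({"g": 0.0}), pseudocount=1.0
        )
        assert te["g"] == pytest.approx(2.0)


class TestSummaryTable:
    def test_fields_match_direct_computation(self, annotated_table, sim_annotation):
        s = summary_table([annotated_table], sim_annotation)
        assert len(s) == 1
        row = s.iloc[0]
        df = annotated_table.df
        assert row["total_alignments"] == len(df)
        assert row["pct_unique"] == pytest.approx(100 * (df["mapq"] == 50).mean())
        assert row["complexity"] == pytest.approx(complexity(annotated_table))
        f0, f1, f2 = frame_periodicity(annotated_table)
        assert row["periodicity"] == pytest.approx(f0)
        assert row["frame0"] + row["frame1"] + row["frame2"] == pytest.approx(1.0)
        pct_cols = [c for c in s.columns if c.startswith("pct_") and c != "pct_unique"]
        assert s[pct_cols].sum(axis=1).iloc[0] == pytest.approx(100.0)

    def test_identical_samples_identical_rows(self, annotated_table, sim_annotation):
        clone = AlignmentTable(annotated_table.df.assign(sample="copy"))
        s = summary_table([annotated_table, clone], sim_annotation)
        a, b = s.drop(columns=["sample"]).iloc[0], s.drop(columns=["sample"]).iloc[1]
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_ribo_and_rna_both_reported(self, annotated_table, rna_table,
                                        sim_annotation, sim_offsets):
        arna = annotate(rna_table, sim_annotation, sim_offsets)
        s = summary_table([annotated_table, arna], sim_annotation)
        assert set(s["exp"]) == {"Ribo", "RNA"}
        assert s["periodicity"].notna().all()  # present for both experiments
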