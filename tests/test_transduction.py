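"""Transduction chain unit tests: SV filtering/merging against graph
oracles, source attribution, the somatic/sex filter, and dedup."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from retrocall.transduction import (attach_source_elements, filter_sv_calls,
                                    merge_dedupe_calls, merge_sv_calls,
                                    somatic_and_sex_filter,
                                    subtract_germline_svs,
                                    summarize_source_activity)

SV_COLS = ["sample", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b",
           "support", "mapq", "length"]


def sv(sample="S", t="TRA", ca="chr1", pa=1000, cb="chr2", pb=5000,
       support=5, mapq=60, length=100_000):
    return (sample, t, ca, pa, cb, pb, support, mapq, length)


def svs_df(rows):
    return pd.DataFrame(rows, columns=SV_COLS)


class TestSvFilter:
    @pytest.mark.parametrize("support,mapq,kept", [
        (2, 60, False),   # below support minimum
        (3, 37, False),   # MAPQ boundary fails the strict inequality
        (3, 38, True),
        (10, 60, True),
    ])
    def test_support_and_mapq_rules(self, support, mapq, kept):
        out = filter_sv_calls(svs_df([sv(support=support, mapq=mapq)]))
        assert (len(out) == 1) is kept

    def test_matches_rowwise_oracle(self):
        rng = np.random.default_rng(2)
        rows = [sv(support=int(rng.integers(0, 8)),
                   mapq=int(rng.integers(0, 61)), pa=int(p))
                for p in rng.integers(0, 1_000_000, size=200)]
        df = svs_df(rows)
        got = filter_sv_calls(df)
        oracle = [r for r in rows if r[6] >= 3 and r[7] > 37]
        assert len(got) == len(oracle)
        assert got["pos_a"].tolist() == [r[3] for r in oracle]


class TestSvMerge:
    def test_same_type_within_200bp_merged(self):
        out = merge_sv_calls(svs_df([sv(pa=1000, pb=5000, support=4),
                                     sv(pa=1150, pb=5100, support=5)]))
        assert len(out) == 1 and out.iloc[0]["support"] == 9

    def test_beyond_200bp_unmerged(self):
        out = merge_sv_calls(svs_df([sv(pa=1000), sv(pa=1250)]))
        assert len(out) == 2

    def test_different_type_unmerged(self):
        out = merge_sv_calls(svs_df([sv(t="DEL"), sv(t="DUP")]))
        assert len(out) == 2

    def test_transitive_chain_matches_connected_components_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 20))
            rows = [sv(pa=int(rng.integers(0, 2000)),
                       pb=int(rng.integers(5000, 7000))) for _ in range(n)]
            df = svs_df(rows)
            got = merge_sv_calls(df)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if (abs(rows[i][3] - rows[j][3]) <= 200
                            and abs(rows[i][5] - rows[j][5]) <= 200):
                        g.add_edge(i, j)
            comps = list(nx.connected_components(g))
            assert len(got) == len(comps)
            assert sorted(got["support"]) == sorted(
                sum(rows[i][6] for i in c) for c in comps)

    def test_explicit_chain_merges_transitively(self):
        out = merge_sv_calls(svs_df([sv(pa=1000, pb=5000),
                                     sv(pa=1150, pb=5000),
                                     sv(pa=1300, pb=5000)]))
        assert len(out) == 1


class TestGermlineSubtraction:
    def test_short_sv_excluded_by_length_rule(self):
        out = subtract_germline_svs(svs_df([sv(length=900)]), svs_df([]))
        assert len(out) == 0

    def test_tumor_sv_matching_normal_excluded(self):
        t = svs_df([sv(pa=1000, pb=5000)])
        n = svs_df([sv(pa=1100, pb=5100)])
        assert len(subtract_germline_svs(t, n)) == 0

    def test_disjoint_sets_identity_on_length_passing(self):
        t = svs_df([sv(pa=1000, length=900), sv(pa=50_000, length=5000)])
        n = svs_df([sv(pa=900_000)])
        out = subtract_germline_svs(t, n)
        assert out["pos_a"].tolist() == [50_000]


def catalog_df(rows):
    return pd.DataFrame(rows, columns=[
        "element_id", "cytoband", "chrom", "start", "end", "strand",
        "three_prime_end", "germline_active", "cancer_active"])


CATALOG = catalog_df([
    ("L1HS000", "22q12.1", "chr1", 10_000, 16_000, "+", 16_000, True, True),
    ("L1HS001", "9q32", "chr1", 40_000, 46_000, "-", 40_000, False, True),
    ("L1HS002", "Yp11.2", "chrY", 1_000, 7_000, "+", 7_000, False, False),
])


class TestSourceAttachment:
    def test_end_within_1000bp_attributed(self):
        out = attach_source_elements(
            svs_df([sv(ca="chr1", pa=16_800, cb="chr2", pb=500_000)]),
            CATALOG)
        assert len(out) == 1
        r = out.iloc[0]
        assert r["source_id"] == "L1HS000"
        assert (r["chrom"], r["pos"]) == ("chr2", 500_000)

    def test_end_beyond_1000bp_not_attributed(self):
        out = attach_source_elements(
            svs_df([sv(ca="chr1", pa=17_500, cb="chr2", pb=500_000)]),
            CATALOG)
        assert len(out) == 0

    def test_nearest_wins_tie_flagged_ambiguous(self):
        cat = catalog_df([
            ("L1HS010", "1q21.1", "chr1", 0, 6000, "+", 6000, False, False),
            ("L1HS011", "1q21.2", "chr1", 7000, 13_000, "-", 7000, False,
             False)])
        # end at 6500: exactly 500 bp from both 3' ends
        out = attach_source_elements(
            svs_df([sv(ca="chr1", pa=6500, cb="chr2", pb=1)]), cat)
        assert out.iloc[0]["source_id"] == "L1HS010"
        assert bool(out.iloc[0]["ambiguous_source"])
        # nearest (not first) wins when distances differ
        out = attach_source_elements(
            svs_df([sv(ca="chr1", pa=6900, cb="chr2", pb=1)]), cat)
        assert out.iloc[0]["source_id"] == "L1HS011"
        assert not bool(out.iloc[0]["ambiguous_source"])

    def test_matches_exhaustive_nearest_neighbor_oracle(self):
        rng = np.random.default_rng(4)
        cat = catalog_df([
            (f"L1HS{i:03d}", "1q", "chr1", p, p + 6000, "+", p + 6000,
             False, False)
            for i, p in enumerate(sorted(rng.integers(
                0, 1_000_000, size=30)))])
        svs = svs_df([sv(ca="chr1", pa=int(p), cb="chr2", pb=int(i))
                      for i, p in enumerate(rng.integers(
                          0, 1_100_000, size=200))])
        got = attach_source_elements(svs, cat)
        tp = cat["three_prime_end"].to_numpy()
        ids = cat["element_id"].to_numpy()
        expect = {}
        for r in svs.itertuples():
            d = np.abs(tp - r.pos_a)
            if d.min() <= 1000:
                expect[r.pos_b] = ids[int(np.argmin(d))]
        assert len(got) == len(expect)
        for r in got.itertuples():
            assert expect[r.pos] == r.source_id


def tcalls_df(rows):
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "pos", "source_id", "cytoband", "tclass",
        "support", "ambiguous_source", "sv_type", "sv_length"])


class TestSomaticSexFilter:
    def test_female_y_source_removed_male_kept(self):
        calls = tcalls_df([
            ("F1", "chr1", 100, "L1HS002", "Yp11.2", "3'", 5, False,
             "TRA", 10_000),
            ("M1", "chr1", 100, "L1HS002", "Yp11.2", "3'", 5, False,
             "TRA", 10_000)])
        out = somatic_and_sex_filter(
            calls, None, {"F1": "female", "M1": "male"}, CATALOG)
        assert out["sample"].tolist() == ["M1"]

    def test_insertion_site_near_panel_removed(self):
        calls = tcalls_df([("S", "chr1", 1000, "L1HS000", "22q12.1", "3'",
                            5, False, "TRA", 10_000)])
        panel = pd.DataFrame({"sample": "PON0", "chrom": "chr1",
                              "pos": [1100], "family": "LINE-1"})
        out = somatic_and_sex_filter(calls, panel, {"S": "male"}, CATALOG)
        assert len(out) == 0

    def test_missing_sex_raises(self):
        calls = tcalls_df([("S", "chr1", 1000, "L1HS000", "22q12.1", "3'",
                            5, False, "TRA", 10_000)])
        with pytest.raises(ValueError, match="sex"):
            somatic_and_sex_filter(calls, None, {}, CATALOG)


def cand_df(rows):
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "window_start", "window_end", "family",
        "pos_support", "neg_support", "somatic"])


class TestDedupe:
    def test_same_sample_within_200bp_collapse(self):
        t = tcalls_df([
            ("S", "chr1", 1000, "L1HS000", "22q12.1", "3'", 5, False,
             "TRA", 10_000),
            ("S", "chr1", 1150, "L1HS000", "22q12.1", "3'", 4, False,
             "TRA", 10_000)])
        out = merge_dedupe_calls(t, cand_df([]))
        assert len(out) == 1

    def test_same_position_different_samples_kept_separate(self):
        t = tcalls_df([
            ("S1", "chr1", 1000, "L1HS000", "22q12.1", "3'", 5, False,
             "TRA", 10_000),
            ("S2", "chr1", 1000, "L1HS000", "22q12.1", "3'", 5, False,
             "TRA", 10_000)])
        assert len(merge_dedupe_calls(t, cand_df([]))) == 2

    def test_dual_evidence_flagged_once(self):
        t = tcalls_df([("S", "chr1", 1000, "L1HS000", "22q12.1", "3'", 5,
                        False, "TRA", 10_000)])
        c = cand_df([("S", "chr1", 1050, 1150, "LINE-1", 3, 3, True)])
        out = merge_dedupe_calls(t, c)
        assert len(out) == 1
        assert out.iloc[0]["method"] == "both"
        assert out.iloc[0]["source_id"] == "L1HS000"

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(5)
        pos = sorted(rng.integers(0, 5000, size=15).tolist())
        t = tcalls_df([("S", "chr1", p, "L1HS000", "22q12.1", "3'", 5,
                        False, "TRA", 10_000) for p in pos])
        out = merge_dedupe_calls(t, cand_df([]))
        g = nx.Graph()
        g.add_nodes_from(range(len(pos)))
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(pos[i] - pos[j]) <= 200:
                    g.add_edge(i, j)
        assert len(out) == nx.number_connected_components(g)


class TestSourceSummary:
    def test_dominant_source_fraction(self):
        rows = [("S", "chr1", i, "A", "22q12.1", "3'", 5, False, "TRA", 1)
                for i in range(160)]
        rows += [("S", "chr1", 10_000 + i * 1000, f"B{i % 40}", "x", "3'",
                  5, False, "TRA", 1) for i in range(186)]
        out = summarize_source_activity(tcalls_df(rows))
        top = out.iloc[0]
        assert top["source_id"] == "A" and top["count"] == 160
        assert round(100 * top["fraction"]) == 46
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_single_call_is_hundred_percent(self):
        out = summarize_source_activity(tcalls_df([
            ("S", "chr1", 1, "A", "x", "3'", 5, False, "TRA", 1)]))
        assert out.iloc[0]["fraction"] == 1.0
        assert not out.iloc[0]["recurrent"]

    def test_empty_input_gives_empty_summary(self):
        assert len(summarize_source_activity(tcalls_df([]))) == 0


def test_end_to_end_recovery_on_noise_free_tables(small_cohort):
    """Every planted transduction with passing support/MAPQ is attributed
    to its true source element."""
    import retrocall as rc
    sex = small_cohort.clinical.set_index("sample")["sex"].to_dict()
    calls = rc.transduction_pipeline(
        small_cohort.tumor_svs, small_cohort.normal_svs,
        small_cohort.annotation.l1hs, small_cohort.panel_calls, sex)
    truth = small_cohort.truth
    td = truth[truth["transduction"]]
    for t in td.itertuples():
        m = calls[(calls["sample"] == t.sample)
                  & (calls["chrom"] == t.chrom)
                  & ((calls["pos"] - t.pos).abs() <= 200)]
        assert len(m) == 1
        assert m.iloc[0]["source_id"] == t.source_id
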