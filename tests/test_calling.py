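"""Insertion caller unit tests: anchor selection, clustering against a
brute-force oracle, reciprocal pairing, and the somatic/decoy filters."""

import numpy as np
import pandas as pd
import pytest

from retrocall.calling import (cluster_discordant_pairs,
                               filter_decoy_regions,
                               filter_somatic_against_panel,
                               pair_reciprocal_clusters,
                               select_anchor_reads)


def make_pair(sample="S", c1="chr1", s1=1000, strand1="+", q1=30, f1="",
              c2="L1", s2=0, strand2="-", q2=30, f2="LINE-1"):
    return dict(sample=sample, chrom1=c1, start1=s1, end1=s1 + 100,
                strand1=strand1, mapq1=q1, family1=f1,
                chrom2=c2, start2=s2, end2=s2 + 100, strand2=strand2,
                mapq2=q2, family2=f2)


class TestAnchorSelection:
    def test_nonrepetitive_end_is_anchor(self):
        pairs = pd.DataFrame([make_pair(q1=30, q2=20)])
        out = select_anchor_reads(pairs)
        assert len(out) == 1
        assert out.iloc[0]["chrom"] == "chr1"
        assert out.iloc[0]["family"] == "LINE-1"

    def test_repeat_masked_second_end_anchors_first(self):
        pairs = pd.DataFrame([make_pair(q1=30, q2=20, f1="", f2="Alu")])
        out = select_anchor_reads(pairs)
        assert out.iloc[0]["start"] == 1000 and out.iloc[0]["family"] == \
            "Alu"

    def test_equal_mapq_both_repetitive_takes_first_end(self):
        pairs = pd.DataFrame([make_pair(q1=30, q2=30, f1="LINE-1",
                                        f2="LINE-1")])
        out = select_anchor_reads(pairs)
        assert len(out) == 1
        assert out.iloc[0]["chrom"] == "chr1"

    def test_zero_mapq_under_equal_rule_excluded(self):
        pairs = pd.DataFrame([make_pair(q1=0, q2=0, f1="LINE-1",
                                        f2="LINE-1")])
        assert len(select_anchor_reads(pairs)) == 0

    def test_no_repetitive_end_dropped(self):
        pairs = pd.DataFrame([make_pair(f1="", f2="")])
        assert len(select_anchor_reads(pairs)) == 0


def anchors(starts, strand="+", sample="S", chrom="chr1", family="LINE-1"):
    return pd.DataFrame({
        "sample": sample, "chrom": chrom,
        "start": list(starts), "end": [s + 100 for s in starts],
        "strand": strand, "mapq": 60, "family": family,
    })


def brute_force_clusters(starts, join_distance):
    """O(n^2) single-linkage membership oracle on anchor starts."""
    starts = sorted(starts)
    n = len(starts)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if i != j and abs(starts[i] - starts[j]) <= join_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(starts[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestClustering:
    def test_three_anchors_at_threshold_form_one_cluster(self):
        out = cluster_discordant_pairs(anchors([100, 150, 200]),
                                       join_distance=100)
        assert len(out) == 1 and out.iloc[0]["count"] == 3

    def test_two_anchors_below_minimum_discarded(self):
        assert len(cluster_discordant_pairs(anchors([100, 150]))) == 0

    def test_gap_splits_clusters_matching_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            starts = sorted(rng.integers(0, 20_000, size=30).tolist())
            jd = int(rng.integers(50, 1000))
            got = cluster_discordant_pairs(anchors(starts), min_reads=1,
                                           join_distance=jd)
            # compare cluster spans against the oracle's member groups
            oracle = brute_force_clusters(starts, jd)
            assert [min(g) for g in oracle] == sorted(
                got["start"].tolist())
            assert [max(g) for g in oracle] == sorted(
                (got["end"] - 100).tolist())

    def test_inner_coordinates_follow_strand_rule(self):
        plus = cluster_discordant_pairs(anchors([100, 150, 300]))
        assert plus.iloc[0]["inner"] == 400  # rightmost anchor end
        minus = cluster_discordant_pairs(anchors([100, 150, 300],
                                                 strand="-"))
        assert minus.iloc[0]["inner"] == 100  # leftmost anchor start


def clusters_df(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "strand",
                                       "count", "start", "end", "inner",
                                       "family"])


class TestReciprocalPairing:
    def test_simple_reciprocal_pair(self):
        cl = clusters_df([
            ("S", "chr1", "+", 3, 800, 1000, 1000, "LINE-1"),
            ("S", "chr1", "-", 4, 1050, 1300, 1050, "LINE-1")])
        out = pair_reciprocal_clusters(cl)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["window_start"], r["window_end"]) == (1000, 1050)
        assert (r["pos_support"], r["neg_support"]) == (3, 4)

    def test_different_families_not_paired(self):
        cl = clusters_df([
            ("S", "chr1", "+", 3, 800, 1000, 1000, "LINE-1"),
            ("S", "chr1", "-", 3, 1050, 1300, 1050, "Alu")])
        assert len(pair_reciprocal_clusters(cl)) == 0

    def test_nearest_wins_and_tie_goes_to_leftmost_plus(self):
        # two + clusters compete for one - cluster
        cl = clusters_df([
            ("S", "chr1", "+", 3, 700, 900, 900, "LINE-1"),
            ("S", "chr1", "+", 3, 800, 1000, 1000, "LINE-1"),
            ("S", "chr1", "-", 3, 1050, 1300, 1050, "LINE-1")])
        out = pair_reciprocal_clusters(cl)
        assert len(out) == 1
        assert out.iloc[0]["window_start"] == 1000  # nearest + cluster
        # exact tie: equidistant + clusters at 1000 and 1100 around 1050
        cl = clusters_df([
            ("S", "chr1", "+", 3, 800, 1000, 1000, "LINE-1"),
            ("S", "chr1", "+", 3, 900, 1100, 1100, "LINE-1"),
            ("S", "chr1", "-", 3, 1050, 1300, 1050, "LINE-1")])
        out = pair_reciprocal_clusters(cl)
        assert out.iloc[0]["window_start"] == 1000  # leftmost wins tie

    def test_each_cluster_used_once(self):
        cl = clusters_df([
            ("S", "chr1", "+", 3, 700, 900, 900, "LINE-1"),
            ("S", "chr1", "+", 3, 800, 1000, 1000, "LINE-1"),
            ("S", "chr1", "-", 3, 1050, 1300, 1050, "LINE-1"),
            ("S", "chr1", "-", 3, 1200, 1400, 1200, "LINE-1")])
        out = pair_reciprocal_clusters(cl)
        assert len(out) == 2
        assert out["window_start"].tolist() == [900, 1000]


def candidates_df(rows):
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "window_start", "window_end", "family",
        "pos_support", "neg_support", "somatic"])


class TestSomaticFilter:
    def panel(self, positions, chrom="chr1"):
        return pd.DataFrame({"sample": "PON0", "chrom": chrom,
                             "pos": positions, "family": "LINE-1"})

    def test_candidate_within_window_removed(self):
        cands = candidates_df([("S", "chr1", 1000, 1050, "LINE-1", 3, 3,
                                False)])
        out = filter_somatic_against_panel(cands, self.panel([1200]))
        assert len(out) == 0  # 150 bp from window edge

    def test_candidate_beyond_window_kept(self):
        cands = candidates_df([("S", "chr1", 1000, 1050, "LINE-1", 3, 3,
                                False)])
        out = filter_somatic_against_panel(cands, self.panel([1300]))
        assert len(out) == 1 and bool(out.iloc[0]["somatic"])

    def test_cross_family_masking(self):
        """A germline Alu within 200 bp masks a somatic LINE-1 call."""
        cands = candidates_df([("S", "chr1", 1000, 1050, "LINE-1", 3, 3,
                                False)])
        panel = pd.DataFrame({"sample": "PON0", "chrom": "chr1",
                              "pos": [1100], "family": "Alu"})
        assert len(filter_somatic_against_panel(cands, panel)) == 0

    def test_matches_bruteforce_distance_oracle(self):
        rng = np.random.default_rng(1)
        n, m = 300, 300
        cands = candidates_df([
            ("S", "chr1", int(s), int(s) + int(rng.integers(0, 60)),
             "LINE-1", 3, 3, False)
            for s in rng.integers(0, 500_000, size=n)])
        panel = self.panel(sorted(rng.integers(0, 500_000, size=m)))
        got = filter_somatic_against_panel(cands, panel)

        def dist(lo, hi, p):
            return lo - p if p < lo else (p - hi if p > hi else 0)

        keep = []
        for r in cands.itertuples():
            if all(dist(r.window_start, r.window_end, p) > 200
                   for p in panel["pos"]):
                keep.append((r.chrom, r.window_start, r.window_end))
        assert keep == list(zip(got["chrom"], got["window_start"],
                                got["window_end"]))


class TestDecoyFilter:
    def test_decoy_contig_removed_and_chr1_kept(self):
        cands = candidates_df([
            ("S", "hs37d5", 100, 150, "LINE-1", 3, 3, True),
            ("S", "chr1", 100, 150, "LINE-1", 3, 3, True)])
        out = filter_decoy_regions(cands, ["hs37d5"])
        assert out["chrom"].tolist() == ["chr1"]

    def test_empty_decoy_list_is_identity(self):
        cands = candidates_df([("S", "chr1", 100, 150, "LINE-1", 3, 3,
                                True)])
        out = filter_decoy_regions(cands, [])
        pd.testing.assert_frame_equal(out, cands)

    def test_unknown_contig_warns_and_keeps(self, caplog):
        cands = candidates_df([("S", "chrUn_xyz", 100, 150, "LINE-1", 3, 3,
                                True)])
        with caplog.at_level("WARNING"):
            out = filter_decoy_regions(cands, ["hs37d5"],
                                       known_contigs=["chr1"])
        assert len(out) == 1 and "chrUn_xyz" in caplog.text


def test_row_order_invariance(small_cohort):
    """Shuffling evidence rows leaves the call set unchanged."""
    import retrocall as rc
    base = rc.call_insertions(small_cohort.tumor_pairs)
    shuffled = small_cohort.tumor_pairs.sample(
        frac=1.0, random_state=0).reset_index(drop=True)
    again = rc.call_insertions(shuffled)
    pd.testing.assert_frame_equal(base, again)
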