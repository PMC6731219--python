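"""Somatic retrotransposon insertion calling from discordant read pairs.

The caller follows the TraFiC-style recipe: anchor-read selection (the end
mapping to non-repetitive sequence anchors the pair), single-linkage
clustering of same-strand anchors, reciprocal pairing of a plus-strand and a
minus-strand cluster whose inner coordinates bracket the breakpoint, somatic
filtering against matched-normal and panel-of-normals germline calls with a
200 bp window, and removal of calls on decoy contigs.  Cluster support
minima are three reads in the tumor (s = 3) and three in the normal
(gm = 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as rio

log = logging.getLogger(__name__)

MIN_READS = 3          # s = 3 tumor / gm = 3 normal cluster minimum
SOMATIC_WINDOW = 200   # bp, panel/matched-normal filtering window
JOIN_DISTANCE = 500    # bp, anchor single-linkage gap (library-insert scale)
PAIRING_WINDOW = 500   # bp, max inner-coordinate distance for reciprocal pairing


def select_anchor_reads(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pick the anchor end of each discordant pair.

    Pairs where one end carries a repeat-family label are anchored on the
    other (non-repetitive) end.  Pairs with both ends non-repetitive are
    dropped (no family to call).  When both ends are repetitive with equal
    mapping quality above 0, the first end is the anchor; pairs with any
    MAPQ of 0 under that rule are excluded.

    Returns one row per retained pair with columns
    sample, chrom, start, end, strand, mapq, family.
    """
    fam1 = pairs["family1"].fillna("").astype(str)
    fam2 = pairs["family2"].fillna("").astype(str)
    rep1 = fam1 != ""
    rep2 = fam2 != ""

    anchor_first = (~rep1 & rep2)
    anchor_second = (rep1 & ~rep2)
    both_rep = rep1 & rep2
    equal_ok = (both_rep & (pairs["mapq1"] == pairs["mapq2"])
                & (pairs["mapq1"] > 0) & (pairs["mapq2"] > 0))
    anchor_first |= equal_ok

    out = []
    for mask, side, fam in ((anchor_first, "1", fam2),
                            (anchor_second, "2", fam1)):
        sub = pairs.loc[mask]
        if not len(sub):
            continue
        out.append(pd.DataFrame({
            "sample": sub["sample"],
            "chrom": sub[f"chrom{side}"],
            "start": sub[f"start{side}"].astype(int),
            "end": sub[f"end{side}"].astype(int),
            "strand": sub[f"strand{side}"],
            "mapq": sub[f"mapq{side}"].astype(int),
            "family": fam.loc[sub.index],
        }))
    if not out:
        return pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                     "strand", "mapq", "family"])
    res = pd.concat(out).sort_index()
    return res.reset_index(drop=True)


def cluster_discordant_pairs(anchored: pd.DataFrame,
                             min_reads: int = MIN_READS,
                             join_distance: int = JOIN_DISTANCE
                             ) -> pd.DataFrame:
    """Single-linkage clusters of same-strand anchors.

    Anchors on the same sample/chromosome/strand whose sorted starts are
    within ``join_distance`` of the previous anchor join one cluster.
    Clusters with fewer than ``min_reads`` members are discarded.  The inner
    coordinate is the rightmost anchor end for plus clusters (P_R_POS) and
    the leftmost anchor start for minus clusters (N_L_POS); family is the
    majority vote (ties broken lexicographically).
    """
    cols = ["sample", "chrom", "strand", "count", "start", "end", "inner",
            "family"]
    if not len(anchored):
        return pd.DataFrame(columns=cols)
    rows = []
    for (sample, chrom, strand), sub in anchored.groupby(
            ["sample", "chrom", "strand"], sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        starts = sub["start"].to_numpy()
        breaks = np.flatnonzero(np.diff(starts) > join_distance)
        edges = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(edges[:-1], edges[1:]):
            grp = sub.iloc[a:b]
            if len(grp) < min_reads:
                continue
            inner = (int(grp["end"].max()) if strand == "+"
                     else int(grp["start"].min()))
            counts = grp["family"].value_counts()
            fam = sorted(counts[counts == counts.max()].index)[0]
            rows.append((sample, chrom, strand, len(grp),
                         int(grp["start"].min()), int(grp["end"].max()),
                         inner, fam))
    return pd.DataFrame(rows, columns=cols)


def pair_reciprocal_clusters(clusters: pd.DataFrame,
                             pairing_window: int = PAIRING_WINDOW
                             ) -> pd.DataFrame:
    """Pair each plus cluster with its nearest same-family minus cluster.

    Greedy nearest-first assignment: candidate (+, -) pairs within
    ``pairing_window`` of each other (by inner coordinate, overlap allowed
    to accommodate target-site duplication) are taken in order of
    increasing distance, ties broken by leftmost plus cluster; each cluster
    is used at most once.  The breakpoint window is the interval between
    the two inner coordinates.
    """
    cols = rio.SCHEMAS["candidates"]
    if not len(clusters):
        return pd.DataFrame(columns=cols)
    rows = []
    for (sample, chrom, family), sub in clusters.groupby(
            ["sample", "chrom", "family"], sort=True):
        plus = sub[sub["strand"] == "+"].reset_index(drop=True)
        minus = sub[sub["strand"] == "-"].reset_index(drop=True)
        if not len(plus) or not len(minus):
            continue
        cand = []
        for i, p in plus.iterrows():
            for j, m in minus.iterrows():
                d = abs(int(m["inner"]) - int(p["inner"]))
                if d <= pairing_window:
                    cand.append((d, int(p["inner"]), i, j))
        used_p: set[int] = set()
        used_m: set[int] = set()
        for d, pin, i, j in sorted(cand):
            if i in used_p or j in used_m:
                continue
            used_p.add(i)
            used_m.add(j)
            p, m = plus.loc[i], minus.loc[j]
            lo, hi = sorted((int(p["inner"]), int(m["inner"])))
            rows.append((sample, chrom, lo, hi, family,
                         int(p["count"]), int(m["count"]), True))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["sample", "chrom", "window_start"],
                           kind="stable").reset_index(drop=True)


def _interval_point_distance(lo: int, hi: int, pos: int) -> int:
    if pos < lo:
        return lo - pos
    if pos > hi:
        return pos - hi
    return 0


def filter_somatic_against_panel(candidates: pd.DataFrame,
                                 panel_calls: pd.DataFrame,
                                 matched_normal_calls: pd.DataFrame
                                 | None = None,
                                 window: int = SOMATIC_WINDOW
                                 ) -> pd.DataFrame:
    """Remove candidates near any germline call (any family).

    A candidate is dropped when a panel or matched-normal germline call on
    the same chromosome lies within ``window`` bp of its breakpoint window
    (edge distance; 0 when inside).  Matched-normal calls are compared
    per-sample, panel calls cohort-wide.
    """
    if not len(candidates):
        return candidates.copy()
    panel_pos: dict[str, np.ndarray] = {}
    if panel_calls is not None and len(panel_calls):
        for chrom, sub in panel_calls.groupby("chrom"):
            panel_pos[str(chrom)] = np.sort(sub["pos"].to_numpy())
    normal_pos: dict[tuple[str, str], np.ndarray] = {}
    if matched_normal_calls is not None and len(matched_normal_calls):
        for (sample, chrom), sub in matched_normal_calls.groupby(
                ["sample", "chrom"]):
            normal_pos[(str(sample), str(chrom))] = np.sort(
                sub["pos"].to_numpy())

    def near(pos_arr, lo, hi):
        if pos_arr is None or not len(pos_arr):
            return False
        i = np.searchsorted(pos_arr, lo - window)
        j = np.searchsorted(pos_arr, hi + window, side="right")
        for p in pos_arr[i:j]:
            if _interval_point_distance(lo, hi, int(p)) <= window:
                return True
        return False

    keep = []
    for r in candidates.itertuples():
        lo, hi = int(r.window_start), int(r.window_end)
        hit = near(panel_pos.get(str(r.chrom)), lo, hi) or near(
            normal_pos.get((str(r.sample), str(r.chrom))), lo, hi)
        keep.append(not hit)
    n_drop = len(keep) - sum(keep)
    if n_drop:
        log.info("somatic filter removed %d/%d candidates",
                 n_drop, len(keep))
    out = candidates.loc[keep].copy()
    out["somatic"] = True
    return out.reset_index(drop=True)


def filter_decoy_regions(candidates: pd.DataFrame,
                         decoy_contigs: list[str],
                         known_contigs: list[str] | None = None
                         ) -> pd.DataFrame:
    """Drop candidates on decoy contigs (e.g. hs37d5)."""
    if not decoy_contigs or not len(candidates):
        return candidates.copy()
    if known_contigs is not None:
        unknown = (set(candidates["chrom"]) - set(known_contigs)
                   - set(decoy_contigs))
        for contig in sorted(unknown):
            log.warning("candidate on unknown contig %r kept", contig)
    keep = ~candidates["chrom"].isin(decoy_contigs)
    return candidates.loc[keep].reset_index(drop=True)


def germline_calls_from_pairs(pairs: pd.DataFrame,
                              min_reads: int = MIN_READS,
                              join_distance: int = JOIN_DISTANCE,
                              pairing_window: int = PAIRING_WINDOW
                              ) -> pd.DataFrame:
    """Run anchoring + clustering + reciprocal pairing on normal-sample
    evidence and return germline calls as (sample, chrom, pos, family)."""
    anchored = select_anchor_reads(pairs)
    clusters = cluster_discordant_pairs(anchored, min_reads, join_distance)
    cands = pair_reciprocal_clusters(clusters, pairing_window)
    if not len(cands):
        return pd.DataFrame(columns=rio.SCHEMAS["panel_calls"])
    return pd.DataFrame({
        "sample": cands["sample"], "chrom": cands["chrom"],
        "pos": ((cands["window_start"] + cands["window_end"]) // 2)
        .astype(int),
        "family": cands["family"],
    })


@dataclass
class CallerParams:
    min_reads: int = MIN_READS
    join_distance: int = JOIN_DISTANCE
    pairing_window: int = PAIRING_WINDOW
    somatic_window: int = SOMATIC_WINDOW


def call_insertions(tumor_pairs: pd.DataFrame,
                    normal_pairs: pd.DataFrame | None = None,
                    panel_calls: pd.DataFrame | None = None,
                    decoy_contigs: list[str] = (),
                    params: CallerParams | None = None) -> pd.DataFrame:
    """Full calling chain: anchor -> cluster -> pair -> somatic filter -> decoy."""
    params = params or CallerParams()
    anchored = select_anchor_reads(tumor_pairs)
    clusters = cluster_discordant_pairs(anchored, params.min_reads,
                                        params.join_distance)
    cands = pair_reciprocal_clusters(clusters, params.pairing_window)
    log.info("caller: %d pairs -> %d clusters -> %d candidates",
             len(tumor_pairs), len(clusters), len(cands))
    normal_calls = None
    if normal_pairs is not None and len(normal_pairs):
        normal_calls = germline_calls_from_pairs(
            normal_pairs, params.min_reads, params.join_distance,
            params.pairing_window)
    somatic = filter_somatic_against_panel(
        cands, panel_calls if panel_calls is not None
        else pd.DataFrame(columns=rio.SCHEMAS["panel_calls"]),
        normal_calls, params.somatic_window)
    return filter_decoy_regions(somatic, list(decoy_contigs))
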