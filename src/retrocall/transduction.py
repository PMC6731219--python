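"""LINE-1 3'/orphan transduction calling from structural-variant calls.

Transductions mobilize unique sequence downstream of a source LINE-1's 3'
end; an SV with one end near a full-length reference L1HS 3' end and the
other end elsewhere marks a transduction and identifies its source locus.
The filter chain runs in a fixed order: support/MAPQ filter -> same-type
merge (200 bp, transitive) -> germline SV subtraction (length > 1000 bp) ->
source attachment (1000 bp from the 3' end) -> somatic/sex filter ->
dedup against cluster-based insertion calls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io as rio

log = logging.getLogger(__name__)

MIN_SUPPORT = 3
MIN_MAPQ = 37            # strictly greater-than
MERGE_WINDOW = 200       # bp, same-type SV merging and somatic filtering
MIN_SV_LENGTH = 1000     # bp, germline subtraction applies above this
SOURCE_PROXIMITY = 1000  # bp from the catalog element's 3' end


def filter_sv_calls(svs: pd.DataFrame, min_support: int = MIN_SUPPORT,
                    min_mapq: int = MIN_MAPQ) -> pd.DataFrame:
    """Keep SVs with support >= min_support and MAPQ strictly > min_mapq."""
    keep = (svs["support"] >= min_support) & (svs["mapq"] > min_mapq)
    return svs.loc[keep].reset_index(drop=True)


def _union_find(n: int):
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    return find, union


def merge_sv_calls(svs: pd.DataFrame,
                   window: int = MERGE_WINDOW) -> pd.DataFrame:
    """Transitively merge same-sample, same-type SVs whose corresponding
    ends are each within ``window`` bp.

    The merged call takes support = sum of members, each end span = union,
    length = max member length, MAPQ = max.
    """
    if not len(svs):
        return svs.copy()
    out_rows = []
    for (sample, svtype), sub in svs.groupby(["sample", "sv_type"],
                                             sort=True):
        sub = sub.reset_index(drop=True)
        n = len(sub)
        find, union = _union_find(n)
        ca = sub["chrom_a"].to_numpy()
        cb = sub["chrom_b"].to_numpy()
        pa = sub["pos_a"].to_numpy()
        pb = sub["pos_b"].to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                if (ca[i] == ca[j] and cb[i] == cb[j]
                        and abs(int(pa[i]) - int(pa[j])) <= window
                        and abs(int(pb[i]) - int(pb[j])) <= window):
                    union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            g = sub.iloc[members]
            out_rows.append((
                sample, svtype, g["chrom_a"].iloc[0],
                int(g["pos_a"].mean()), g["chrom_b"].iloc[0],
                int(g["pos_b"].mean()), int(g["support"].sum()),
                int(g["mapq"].max()), int(g["length"].max()),
            ))
    out = pd.DataFrame(out_rows, columns=rio.SCHEMAS["sv_calls"])
    return out.sort_values(["sample", "sv_type", "chrom_a", "pos_a"],
                           kind="stable").reset_index(drop=True)


def subtract_germline_svs(tumor_svs: pd.DataFrame,
                          normal_svs: pd.DataFrame,
                          min_length: int = MIN_SV_LENGTH,
                          window: int = MERGE_WINDOW) -> pd.DataFrame:
    """Keep tumor merged SVs of length > min_length with no same-type
    normal merged SV matching both ends within ``window`` bp."""
    keep_len = tumor_svs["length"] > min_length
    tum = tumor_svs.loc[keep_len].reset_index(drop=True)
    if not len(tum) or normal_svs is None or not len(normal_svs):
        return tum
    keep = []
    norm_by_type = dict(tuple(normal_svs.groupby("sv_type")))
    for r in tum.itertuples():
        nn = norm_by_type.get(r.sv_type)
        hit = False
        if nn is not None:
            m = ((nn["chrom_a"] == r.chrom_a) & (nn["chrom_b"] == r.chrom_b)
                 & ((nn["pos_a"] - r.pos_a).abs() <= window)
                 & ((nn["pos_b"] - r.pos_b).abs() <= window))
            hit = bool(m.any())
        keep.append(not hit)
    return tum.loc[keep].reset_index(drop=True)


def attach_source_elements(somatic_svs: pd.DataFrame, catalog: pd.DataFrame,
                           proximity: int = SOURCE_PROXIMITY
                           ) -> pd.DataFrame:
    """Attribute SVs to reference L1HS source elements.

    An SV is kept iff one of its ends lies within ``proximity`` bp of a
    catalog element's 3'-end coordinate (same chromosome); that end links
    the source and the other end becomes the insertion site.  The nearest
    element wins; an exact distance tie goes to the lowest element id and
    is flagged ambiguous.
    """
    cols = rio.SCHEMAS["transductions"] + ["sv_type", "sv_length"]
    if not len(somatic_svs) or not len(catalog):
        return pd.DataFrame(columns=cols)
    cat_by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("element_id").reset_index(drop=True)
        for c, sub in catalog.groupby("chrom")}

    def nearest(chrom, pos):
        sub = cat_by_chrom.get(str(chrom))
        if sub is None:
            return None, None, False
        d = (sub["three_prime_end"] - pos).abs().to_numpy()
        dmin = d.min()
        if dmin > proximity:
            return None, None, False
        hits = np.flatnonzero(d == dmin)
        row = sub.iloc[hits[0]]  # lowest id: sub sorted by element_id
        return row, int(dmin), len(hits) > 1

    rows = []
    for r in somatic_svs.itertuples():
        a, da, amb_a = nearest(r.chrom_a, r.pos_a)
        b, db, amb_b = nearest(r.chrom_b, r.pos_b)
        if a is None and b is None:
            continue
        if b is None or (a is not None and da <= db):
            src, amb = a, amb_a
            site_chrom, site_pos = r.chrom_b, int(r.pos_b)
        else:
            src, amb = b, amb_b
            site_chrom, site_pos = r.chrom_a, int(r.pos_a)
        rows.append((r.sample, site_chrom, site_pos, src["element_id"],
                     src["cytoband"], "3'", int(r.support), bool(amb),
                     r.sv_type, int(r.length)))
    return pd.DataFrame(rows, columns=cols)


def classify_transductions(calls: pd.DataFrame,
                           site_evidence: pd.DataFrame | None = None,
                           window: int = MERGE_WINDOW) -> pd.DataFrame:
    """Label each call 3' or orphan.

    A call is a 3' transduction when LINE-1 family read evidence also maps
    at the insertion-site end (the element body inserted with the
    transduced flank); with no such evidence the flank inserted alone and
    the call is an orphan transduction.  ``site_evidence`` is an anchored
    evidence table with columns sample, chrom, start, end, family.
    """
    out = calls.copy()
    if not len(out):
        return out
    if site_evidence is None or not len(site_evidence):
        out["tclass"] = "orphan"
        return out
    ev = site_evidence[site_evidence["family"] == "LINE-1"]
    by_key = dict(tuple(ev.groupby(["sample", "chrom"])))
    classes = []
    for r in out.itertuples():
        sub = by_key.get((r.sample, r.chrom))
        has_l1 = sub is not None and bool(
            ((sub["start"] <= r.pos + window)
             & (sub["end"] >= r.pos - window)).any())
        classes.append("3'" if has_l1 else "orphan")
    out["tclass"] = classes
    return out


def somatic_and_sex_filter(calls: pd.DataFrame,
                           panel_calls: pd.DataFrame | None,
                           sample_sex: dict[str, str] | pd.Series,
                           catalog: pd.DataFrame,
                           window: int = MERGE_WINDOW) -> pd.DataFrame:
    """Filter insertion-site ends against the panel of normals (200 bp) and
    drop calls whose source element lies on chromosome Y in females."""
    if not len(calls):
        return calls.copy()
    sex = dict(sample_sex) if not isinstance(sample_sex, dict) \
        else sample_sex
    missing = set(calls["sample"]) - set(sex)
    if missing:
        raise ValueError(f"sample sex missing for {sorted(missing)}")
    src_chrom = catalog.set_index("element_id")["chrom"]
    panel_pos: dict[str, np.ndarray] = {}
    if panel_calls is not None and len(panel_calls):
        for chrom, sub in panel_calls.groupby("chrom"):
            panel_pos[str(chrom)] = np.sort(sub["pos"].to_numpy())
    keep = []
    for r in calls.itertuples():
        arr = panel_pos.get(str(r.chrom))
        near_panel = arr is not None and bool(
            (np.abs(arr - r.pos) <= window).any())
        y_in_female = (sex[r.sample] == "female"
                       and str(src_chrom.get(r.source_id, "")) in
                       ("chrY", "Y"))
        keep.append(not (near_panel or y_in_female))
    n_drop = len(keep) - sum(keep)
    if n_drop:
        log.info("somatic/sex filter removed %d/%d transduction calls",
                 n_drop, len(keep))
    return calls.loc[keep].reset_index(drop=True)


def merge_dedupe_calls(transduction_calls: pd.DataFrame,
                       cluster_insertions: pd.DataFrame,
                       window: int = MERGE_WINDOW) -> pd.DataFrame:
    """Unify transduction calls with cluster-based insertion calls.

    Within-sample, same-family calls within ``window`` bp collapse to one
    record (transitive, connected components).  Records found by both
    methods are flagged dual-evidence and counted once.  Returns the
    unified insertion table (schema ``insertions`` core columns).
    """
    recs = []
    for r in cluster_insertions.itertuples():
        recs.append({
            "sample": r.sample, "chrom": r.chrom,
            "window_start": int(r.window_start),
            "window_end": int(r.window_end), "family": r.family,
            "method": "cluster", "source_id": "",
        })
    for r in transduction_calls.itertuples():
        recs.append({
            "sample": r.sample, "chrom": r.chrom,
            "window_start": int(r.pos), "window_end": int(r.pos),
            "family": "LINE-1", "method": "transduction",
            "source_id": r.source_id,
        })
    if not recs:
        return pd.DataFrame(columns=[
            "sample", "chrom", "window_start", "window_end", "midpoint",
            "family", "method", "source_id"])
    df = pd.DataFrame(recs)
    df["midpoint"] = (df["window_start"] + df["window_end"]) // 2
    out_rows = []
    for (sample, chrom, family), sub in df.groupby(
            ["sample", "chrom", "family"], sort=True):
        sub = sub.sort_values("midpoint", kind="stable").reset_index(
            drop=True)
        n = len(sub)
        find, union = _union_find(n)
        mid = sub["midpoint"].to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                if abs(int(mid[i]) - int(mid[j])) <= window:
                    union(i, j)
                else:
                    break  # sorted midpoints: later j only farther
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for members in sorted(groups.values(), key=lambda m: m[0]):
            g = sub.iloc[members]
            methods = set(g["method"])
            src = next((s for s in g["source_id"] if s), "")
            out_rows.append((
                sample, chrom, int(g["window_start"].min()),
                int(g["window_end"].max()),
                int(g["midpoint"].iloc[0]), family,
                "both" if len(methods) > 1 else next(iter(methods)), src))
    out = pd.DataFrame(out_rows, columns=[
        "sample", "chrom", "window_start", "window_end", "midpoint",
        "family", "method", "source_id"])
    out["midpoint"] = (out["window_start"] + out["window_end"]) // 2
    return out.sort_values(["sample", "chrom", "window_start"],
                           kind="stable").reset_index(drop=True)


def summarize_source_activity(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-source transduction counts and fractions (recurrent = count >= 2)."""
    cols = ["source_id", "count", "fraction", "recurrent"]
    attributed = calls[calls["source_id"] != ""] if len(calls) else calls
    if not len(attributed):
        return pd.DataFrame(columns=cols)
    counts = (attributed.groupby("source_id").size()
              .sort_values(ascending=False, kind="stable"))
    total = int(counts.sum())
    return pd.DataFrame({
        "source_id": counts.index, "count": counts.to_numpy(),
        "fraction": counts.to_numpy() / total,
        "recurrent": counts.to_numpy() >= 2,
    }).reset_index(drop=True)


def transduction_pipeline(tumor_svs: pd.DataFrame,
                          normal_svs: pd.DataFrame,
                          catalog: pd.DataFrame,
                          panel_calls: pd.DataFrame | None,
                          sample_sex: dict[str, str],
                          site_evidence: pd.DataFrame | None = None,
                          min_support: int = MIN_SUPPORT,
                          min_mapq: int = MIN_MAPQ,
                          merge_window: int = MERGE_WINDOW,
                          min_length: int = MIN_SV_LENGTH,
                          proximity: int = SOURCE_PROXIMITY) -> pd.DataFrame:
    """Fixed-order transduction chain (see module docstring)."""
    svs = filter_sv_calls(tumor_svs, min_support, min_mapq)
    svs = merge_sv_calls(svs, merge_window)
    normals = merge_sv_calls(normal_svs, merge_window) \
        if len(normal_svs) else normal_svs
    svs = subtract_germline_svs(svs, normals, min_length, merge_window)
    calls = attach_source_elements(svs, catalog, proximity)
    calls = classify_transductions(calls, site_evidence, merge_window)
    calls = somatic_and_sex_filter(calls, panel_calls, sample_sex, catalog,
                                   merge_window)
    return calls
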