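"""Insertion annotation: breakpoints, poly-A/T tails, orientation, gene
context, and track-based densities.

Orientation logic: an insertion that integrated in reverse orientation with
respect to the reference exposes a poly-A at its 5'-mapped breakpoint, so a
poly-A call implies reverse insertion strand and a poly-T call implies
forward.  Combined with the strand of the gene hit, this yields sense
(reverse-in-plus-gene or forward-in-minus-gene) or antisense orientation.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd


def define_breakpoint_window(p_r_pos: int | None,
                             n_l_pos: int | None
                             ) -> tuple[int, int, int, bool]:
    """Breakpoint window from the reciprocal clusters' inner coordinates.

    Returns (start, end, midpoint, partial).  With one coordinate missing
    the window degenerates to the single coordinate and is flagged partial.
    Midpoint is the floor of the arithmetic mean.
    """
    if p_r_pos is None and n_l_pos is None:
        raise ValueError("both inner coordinates missing")
    if p_r_pos is None or n_l_pos is None:
        pos = int(p_r_pos if p_r_pos is not None else n_l_pos)
        return pos, pos, pos, True
    lo, hi = sorted((int(p_r_pos), int(n_l_pos)))
    return lo, hi, (lo + hi) // 2, False


_A_RUN = re.compile("AAA")
_T_RUN = re.compile("TTT")


def call_poly_tail(split_reads: pd.DataFrame, chrom: str, midpoint: int,
                   window: int = 200, min_reads: int = 2,
                   min_run: int = 3) -> str:
    """Call the insertion poly-tail from split reads near the breakpoint.

    Poly-A: >= ``min_reads`` forward-strand reads starting with >=
    ``min_run`` consecutive A within ``midpoint +/- window/2``.  Poly-T:
    reverse-strand reads ending with the T run.  Either call is discarded
    when the corresponding base run appears in the reference context of an
    overlapping read (the run is genomic, not an appended tail).  Both
    qualifying -> 'none' (conflicting evidence).
    """
    if not len(split_reads):
        return "none"
    half = window // 2
    sub = split_reads[(split_reads["chrom"] == chrom)
                      & (split_reads["pos"] >= midpoint - half)
                      & (split_reads["pos"] <= midpoint + half)]
    if not len(sub):
        return "none"
    a_pat = "A" * min_run
    t_pat = "T" * min_run
    fwd = sub[sub["strand"] == "+"]
    rev = sub[sub["strand"] == "-"]
    n_a = int(fwd["seq"].str.startswith(a_pat).sum())
    n_t = int(rev["seq"].str.endswith(t_pat).sum())
    ctx = sub["ref_context"].fillna("")
    a_in_ref = bool(ctx.str.contains(a_pat, regex=False).any())
    t_in_ref = bool(ctx.str.contains(t_pat, regex=False).any())
    a_ok = n_a >= min_reads and not a_in_ref
    t_ok = n_t >= min_reads and not t_in_ref
    if a_ok and t_ok:
        return "none"
    if a_ok:
        return "A"
    if t_ok:
        return "T"
    return "none"


def assign_orientation(poly_tail: str, gene_strand: str | None
                       ) -> tuple[str, str]:
    """Map (poly tail, gene strand) to (insertion strand, orientation).

    A -> reverse, T -> forward; sense = reverse-in-plus or forward-in-minus
    gene; antisense = the two remaining combinations; anything missing ->
    unknown.
    """
    strand = {"A": "reverse", "T": "forward"}.get(poly_tail, "unknown")
    if strand == "unknown" or gene_strand not in ("+", "-"):
        return strand, "unknown"
    sense = (strand == "reverse") == (gene_strand == "+")
    return strand, "sense" if sense else "antisense"


def annotate_gene_context(chrom: str, window_start: int, window_end: int,
                          genes: pd.DataFrame, exons: pd.DataFrame
                          ) -> tuple[list[str], str, str]:
    """Classify a breakpoint window as exon / intron / intergenic.

    Exon when the window overlaps any protein-coding transcript exon
    (precedence over intron), intron when within any protein-coding gene
    body, else intergenic with the nearest gene recorded for expression
    tests.  Returns (overlapping gene ids, region class, nearest gene id).
    """
    coding = genes[genes["coding"]] if "coding" in genes else genes
    on_chrom = coding[coding["chrom"] == chrom]
    if not len(on_chrom):
        return [], "intergenic", ""
    # windows may be zero-width [s, s]: treat them as closed intervals
    ov = on_chrom[(on_chrom["start"] <= window_end)
                  & (window_start < on_chrom["end"])]
    gene_ids = sorted(ov["gene_id"])
    if not gene_ids:
        mid = (window_start + window_end) // 2
        d = np.minimum(np.abs(on_chrom["start"].to_numpy() - mid),
                       np.abs(on_chrom["end"].to_numpy() - mid))
        nearest = on_chrom["gene_id"].to_numpy()[int(np.argmin(d))]
        return [], "intergenic", str(nearest)
    ex = exons[exons["gene_id"].isin(gene_ids)]
    ex = ex[(ex["chrom"] == chrom) & (ex["start"] <= window_end)
            & (window_start < ex["end"])]
    region = "exon" if len(ex) else "intron"
    return gene_ids, region, gene_ids[0]


def _interval_label_lookup(track: pd.DataFrame):
    by_chrom = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[str(chrom)] = (sub["start"].to_numpy(),
                                sub["end"].to_numpy(),
                                sub["label"].to_numpy())

    def lookup(chrom, pos):
        entry = by_chrom.get(str(chrom))
        if entry is None:
            return None
        s, e, lab = entry
        i = np.searchsorted(s, pos, side="right") - 1
        if i >= 0 and pos < e[i]:
            return lab[i]
        return None
    return lookup


def compute_insertion_density(records: pd.DataFrame,
                              track: pd.DataFrame) -> pd.DataFrame:
    """Insertions per Mbp for each label of a partition track.

    Bin membership is decided by the breakpoint midpoint.  The bp-weighted
    mean of label densities equals the genome-wide density.
    """
    sizes = (track.assign(bp=track["end"] - track["start"])
             .groupby("label")["bp"].sum())
    lookup = _interval_label_lookup(track)
    counts = {label: 0 for label in sizes.index}
    for r in records.itertuples():
        lab = lookup(r.chrom, int(r.midpoint))
        if lab in counts:
            counts[lab] += 1
    rows = []
    for label, bp in sizes.items():
        dens = counts[label] / (bp / 1e6) if bp > 0 else np.nan
        rows.append((label, counts[label], int(bp), dens))
    return pd.DataFrame(rows, columns=["label", "count", "bp",
                                       "density_per_mbp"])


def _coverage_intervals(sets: list[pd.DataFrame], chrom: str,
                        min_cover: int) -> list[tuple[int, int]]:
    """Intervals on one chromosome covered by >= min_cover of the sets."""
    events: list[tuple[int, int]] = []
    for df in sets:
        sub = df[df["chrom"] == chrom]
        # each set contributes boolean coverage: merge its intervals first
        merged = _merge_adjacent(
            [(int(r.start), int(r.end)) for r in sub.itertuples()])
        for s, e in merged:
            events.append((s, 1))
            events.append((e, -1))
    if not events:
        return []
    events.sort()
    out = []
    depth = 0
    open_start = None
    for pos, delta in events:
        new_depth = depth + delta
        if depth < min_cover <= new_depth and open_start is None:
            open_start = pos
        elif open_start is not None and new_depth < min_cover <= depth:
            if pos > open_start:
                out.append((open_start, pos))
            open_start = None
        depth = new_depth
    return _merge_adjacent(out)


def _merge_adjacent(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(iv):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect(a: list[tuple[int, int]],
               b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]],
              b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    b = sorted(b)
    j = 0
    for s, e in sorted(a):
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def derive_open_chromatin(dnase_sets: list[pd.DataFrame],
                          callable_regions: pd.DataFrame,
                          min_cell_lines: int = 2) -> pd.DataFrame:
    """Open/closed chromatin partition of the callable genome.

    Open = bases covered by DNase regions in >= ``min_cell_lines`` of the
    four cell-line sets, intersected with callable regions; closed =
    callable minus open.  The two labels partition the callable genome.
    """
    rows = []
    for chrom, sub in callable_regions.groupby("chrom"):
        callable_iv = _merge_adjacent(
            [(int(r.start), int(r.end)) for r in sub.itertuples()])
        open_iv = _intersect(
            _coverage_intervals(dnase_sets, str(chrom), min_cell_lines),
            callable_iv)
        closed_iv = _subtract(callable_iv, open_iv)
        rows += [(chrom, s, e, "open") for s, e in open_iv]
        rows += [(chrom, s, e, "closed") for s, e in closed_iv]
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return out.sort_values(["chrom", "start"],
                           kind="stable").reset_index(drop=True)


def annotate_insertions(insertions: pd.DataFrame,
                        split_reads: pd.DataFrame,
                        genes: pd.DataFrame, exons: pd.DataFrame,
                        replication_track: pd.DataFrame,
                        chromatin_track: pd.DataFrame,
                        tail_window: int = 200) -> pd.DataFrame:
    """Attach poly-tail, orientation, gene context, and track labels to a
    unified insertion table (adds/overwrites the annotation columns)."""
    out = insertions.copy()
    rep_lookup = _interval_label_lookup(replication_track)
    chrom_lookup = _interval_label_lookup(chromatin_track)
    gene_strand = genes.set_index("gene_id")["strand"].to_dict()
    sr_by_sample = dict(tuple(split_reads.groupby("sample"))) \
        if len(split_reads) else {}

    tails, strands, orients = [], [], []
    gene_col, region_col, nearest_col = [], [], []
    rep_col, chromatin_col = [], []
    for r in out.itertuples():
        mid = int(r.midpoint)
        sr = sr_by_sample.get(r.sample,
                              split_reads.iloc[0:0] if len(split_reads)
                              else pd.DataFrame(
                                  columns=["chrom", "pos", "strand", "seq",
                                           "ref_context"]))
        tail = call_poly_tail(sr, r.chrom, mid, tail_window)
        gids, region, nearest = annotate_gene_context(
            r.chrom, int(r.window_start), int(r.window_end), genes, exons)
        gstrand = gene_strand.get(gids[0]) if len(gids) == 1 else (
            gene_strand.get(gids[0]) if gids and len({
                gene_strand.get(g) for g in gids}) == 1 else None)
        strand, orient = assign_orientation(tail, gstrand)
        rep = rep_lookup(r.chrom, mid)
        chromatin = chrom_lookup(r.chrom, mid)
        tails.append(tail)
        strands.append(strand)
        orients.append(orient)
        gene_col.append(",".join(gids))
        region_col.append(region)
        nearest_col.append(nearest)
        rep_col.append(-1 if rep is None else int(rep))
        chromatin_col.append("uncallable" if chromatin is None
                             else str(chromatin))
    out["poly_tail"] = tails
    out["strand"] = strands
    out["orientation"] = orients
    out["gene_ids"] = gene_col
    out["region_class"] = region_col
    out["nearest_gene"] = nearest_col
    out["replication_bin"] = rep_col
    out["chromatin"] = chromatin_col
    return out
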