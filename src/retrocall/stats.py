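"""Cohort statistics: recurrence tallies, fragile-site fractions, the
Fisher-Pitman permutation test, the rank-uniformity expression association
test, and insertion/AI-breakpoint colocalization."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def tally_recurrent_genes(annotated: pd.DataFrame, genes: pd.DataFrame,
                          census: pd.DataFrame | None = None,
                          tpm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene insertion counts over the cohort.

    An insertion overlapping several genes counts once per gene; recurrent
    means count >= 2.  Optional census roles and median TPM are attached.
    """
    counts: dict[str, int] = {}
    for gid_str in annotated["gene_ids"]:
        if not isinstance(gid_str, str) or not gid_str:
            continue
        for gid in gid_str.split(","):
            counts[gid] = counts.get(gid, 0) + 1
    rows = []
    roles = {}
    if census is not None and len(census):
        roles = census.set_index("gene_id")["role"].to_dict()
    for gid in sorted(counts):
        med_tpm = float(tpm.loc[gid].median()) \
            if tpm is not None and gid in tpm.index else np.nan
        rows.append((gid, counts[gid], counts[gid] >= 2,
                     roles.get(gid, ""), med_tpm))
    return pd.DataFrame(rows, columns=[
        "gene_id", "insertion_count", "recurrent", "census_role",
        "median_tpm"])


def fragile_site_fractions(insertions: pd.DataFrame,
                           ai_events: pd.DataFrame,
                           fragile_sites: pd.DataFrame) -> pd.DataFrame:
    """Insertion and AI fractions per fragile site.

    Insertion fraction = insertions within the site / total insertions.
    AI fraction = focal AI events (both breakpoints inside the site) /
    total AI events.  Category: ratio > 1 -> retrotransposon-high,
    0 < ratio < 1 -> AI-high, AI fraction 0 -> undefined.
    """
    total_ins = len(insertions)
    total_ai = len(ai_events)
    if total_ins == 0:
        raise ValueError("zero total insertions")
    rows = []
    for site in fragile_sites.itertuples():
        in_site = insertions[
            (insertions["chrom"] == site.chrom)
            & (insertions["midpoint"] >= site.start)
            & (insertions["midpoint"] < site.end)]
        focal = ai_events[
            (ai_events["chrom"] == site.chrom)
            & (ai_events["start"] >= site.start)
            & (ai_events["end"] <= site.end)] if total_ai else ai_events
        ins_frac = len(in_site) / total_ins
        ai_frac = len(focal) / total_ai if total_ai else 0.0
        if ai_frac == 0.0:
            ratio, cat = np.nan, "undefined"
        else:
            ratio = ins_frac / ai_frac
            cat = ("retrotransposon-high" if ratio > 1
                   else "AI-high" if ratio > 0 else "undefined")
        rows.append((site.gene_id, len(in_site), ins_frac, len(focal),
                     ai_frac, ratio, cat))
    return pd.DataFrame(rows, columns=[
        "site", "insertion_count", "insertion_fraction", "ai_count",
        "ai_fraction", "ratio", "category"])


def fisher_pitman_test(group1, group2, reps: int = 100_000,
                       seed: int | None = None,
                       exact_limit: int = 100_000) -> float:
    """Two-sample Fisher-Pitman permutation test (two-sided p-value).

    The statistic is the sum of group-1 values.  All C(n, n1) assignments
    are enumerated when feasible (<= ``exact_limit``), otherwise ``reps``
    Monte Carlo draws approximate the permutation distribution.  Two-sided
    p uses the symmetric tail of the statistic centered at its permutation
    mean.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    n, n1 = pooled.size, g1.size
    obs = g1.sum()
    center = n1 * pooled.mean()
    dev = abs(obs - center)
    tol = 1e-9 * max(1.0, float(np.abs(pooled).sum()))
    if math.comb(n, n1) <= exact_limit:
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            s = pooled[list(idx)].sum()
            if abs(s - center) >= dev - tol:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        s = pooled[rng.permutation(n)[:n1]].sum()
        if abs(s - center) >= dev - tol:
            count += 1
    return (count + 1) / (reps + 1)


def rank_uniformity_expression_test(tpm: pd.DataFrame,
                                    insertion_genes: pd.DataFrame,
                                    n_perm: int = 100_000,
                                    seed: int | None = None
                                    ) -> tuple[float, float, pd.DataFrame]:
    """Test whether insertions associate with expression of their nearest
    genes via rank uniformity.

    For each (gene, carrier sample) pair, the carrier's TPM rank among all
    expression samples (ascending, ties broken randomly) is recorded.  The
    statistic is the chi-square sum-of-squared-error of the rank frequency
    table (one bin per rank) against uniform; p is the add-one-corrected
    fraction of ``n_perm`` uniformly re-drawn rank tables with a statistic
    >= observed.

    ``insertion_genes`` needs columns sample, gene_id.  Returns
    (statistic, p, frequency table).
    """
    rng = np.random.default_rng(seed)
    samples = list(tpm.columns)
    s_count = len(samples)
    if s_count < 2:
        raise ValueError("need >= 2 expression samples")
    ranks: list[int] = []
    skipped = 0
    for r in insertion_genes.itertuples():
        if r.gene_id not in tpm.index or r.sample not in tpm.columns:
            skipped += 1
            continue
        vals = tpm.loc[r.gene_id, samples].to_numpy(dtype=float)
        order = np.lexsort((rng.random(s_count), vals))  # random tie-break
        rank_of = np.empty(s_count, dtype=int)
        rank_of[order] = np.arange(1, s_count + 1)
        ranks.append(int(rank_of[samples.index(r.sample)]))
    if skipped:
        import logging
        logging.getLogger(__name__).warning(
            "rank test skipped %d insertions with genes absent from the "
            "TPM matrix", skipped)
    if not ranks:
        raise ValueError("no usable (gene, sample) observations")
    ranks_arr = np.asarray(ranks)
    n_obs = ranks_arr.size
    expected = n_obs / s_count
    observed = np.bincount(ranks_arr, minlength=s_count + 1)[1:]
    stat = float(((observed - expected) ** 2 / expected).sum())

    # vectorized null: n_perm tables of n_obs uniform ranks
    exceed = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n_obs, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        draws = rng.integers(0, s_count, size=(m, n_obs))
        flat = (np.arange(m)[:, None] * s_count + draws).ravel()
        counts = np.bincount(flat, minlength=m * s_count).reshape(
            m, s_count)
        stats = ((counts - expected) ** 2 / expected).sum(axis=1)
        exceed += int((stats >= stat - 1e-12).sum())
        done += m
    p = (exceed + 1) / (n_perm + 1)
    freq = pd.DataFrame({"rank": np.arange(1, s_count + 1),
                         "observed": observed, "expected": expected})
    return stat, p, freq


def colocalize_with_ai_breakpoints(insertions: pd.DataFrame,
                                   ai_events: pd.DataFrame,
                                   window: int = 5000) -> pd.DataFrame:
    """Insertions whose midpoint lies within +/- window bp of a same-sample
    AI segment breakpoint; each insertion reported at most once."""
    bp_by_key: dict[tuple[str, str], np.ndarray] = {}
    for (sample, chrom), sub in ai_events.groupby(["sample", "chrom"]):
        bps = np.concatenate([sub["start"].to_numpy(),
                              sub["end"].to_numpy()])
        bp_by_key[(str(sample), str(chrom))] = np.sort(bps)
    rows = []
    for r in insertions.itertuples():
        arr = bp_by_key.get((str(r.sample), str(r.chrom)))
        if arr is None:
            continue
        d = np.abs(arr - int(r.midpoint))
        if d.min() <= window:
            rows.append((r.sample, r.chrom, int(r.midpoint),
                         int(arr[int(np.argmin(d))]), int(d.min())))
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "midpoint", "ai_breakpoint", "distance"])
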