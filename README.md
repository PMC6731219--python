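# retrocall

Somatic retrotransposon insertions — mostly LINE-1 retrotranspositions —
are a hallmark of gastrointestinal tumors. `retrocall` is a tested,
reusable pipeline for characterizing them in a tumor/normal whole-genome
cohort: it calls insertions from discordant read-pair clusters, attributes
LINE-1 3′/orphan transductions to their reference source elements from
structural-variant calls, annotates every insertion (poly-A/T tail,
orientation, gene context, replication timing, chromatin state), and fits
the cohort-level association models (insertion-count regression,
disease-specific survival). A fully synthetic cohort generator with known
ground truth makes every stage testable offline.

It is aimed at cancer-genomics analysts who already have extracted
evidence tables (discordant pairs, split reads, DELLY-style SV calls) and
want a transparent, parameterized reimplementation of the analysis rather
than a black-box caller.

## Method

**Insertion calling.** Discordant pairs with one end in a repeat family
are anchored on the non-repetitive end. Same-strand anchors are clustered
by single linkage; a plus cluster and a minus cluster of the same family
whose inner coordinates (`P_R_POS` = rightmost plus-anchor end, `N_L_POS`
= leftmost minus-anchor start) lie within a pairing window form a
candidate insertion, requiring ≥ 3 supporting reads per cluster (s = 3
tumor, gm = 3 normal). Candidates within 200 bp of any germline call from
the matched normal or a panel of normals, or on decoy contigs (hs37d5),
are removed.

**Transduction attribution.** SV calls with ≥ 3 supporting reads and
MAPQ > 37 are transitively merged (same type, both ends within 200 bp),
filtered against merged normal SVs (length > 1000 bp), and kept when one
end lies within 1000 bp of the 3′ end of a full-length reference L1HS
element — that end identifies the source locus, the other end the
insertion site. Site-side panel filtering (200 bp), a chrY-source filter
for female samples, and 200 bp within-sample dedup against the cluster
caller yield the unified insertion set.

**Annotation.** Poly-A is called when ≥ 2 forward split reads begin with
≥ 3 consecutive A within ±100 bp of the breakpoint midpoint (guarded
against reference A-runs; symmetric for poly-T on reverse reads). Poly-A
implies a reverse-strand insertion, poly-T forward; combined with the
gene strand this gives sense/antisense orientation. Densities
(insertions/Mbp) are computed over a five-bin replication-timing
partition (0 = earliest) and an open/closed chromatin partition (open =
DNase in ≥ 2 of 4 cell lines ∩ callable regions).

**Cohort statistics and clinical models.** Per-gene recurrence
(recurrent = ≥ 2 insertions), fragile-site insertion/AI fraction ratios,
a rank-uniformity permutation test for insertion–expression association
(chi-square on the rank frequency table, 100,000 permutations), the
exact two-sample Fisher–Pitman permutation test, CIMP scoring from
MS-MLPA probes (gene methylated at ≥ 25% of probes; CIMP-H at 5–8 of 8
genes), OLS on log(1 + count) with clinical covariates, and a Cox
proportional-hazards model (insertions/10, stratified by tumor location,
Grambsch–Therneau diagnostics). Validation false-positive rates get exact
Clopper–Pearson binomial intervals.

## Worked example

```python
import retrocall as rc

cfg = rc.SyntheticConfig(n_tumors=20, seed=7)
cohort = rc.simulate_cohort(cfg)

calls = rc.call_insertions(cohort.tumor_pairs, cohort.normal_pairs,
                           cohort.panel_calls,
                           cohort.annotation.decoy_contigs)
print("planted somatic truths:", int(cohort.truth["somatic"].sum()))
print("somatic calls:", len(calls))

sex = cohort.clinical.set_index("sample")["sex"].to_dict()
tcalls = rc.transduction_pipeline(cohort.tumor_svs, cohort.normal_svs,
                                  cohort.annotation.l1hs,
                                  cohort.panel_calls, sex)
print("transductions:", len(tcalls))
print(rc.summarize_source_activity(tcalls).head(3).to_string(index=False))

tally = rc.estimate_false_positive_rate([False] * 24 + [True] * 76)
print(f"FPR {tally.false_positive_rate:.0%} "
      f"CI [{tally.ci_low:.0%}, {tally.ci_high:.0%}]")
```

prints

```
planted somatic truths: 689
somatic calls: 655
transductions: 47
source_id  count  fraction  recurrent
  L1HS000     29  0.617021       True
  L1HS001      3  0.063830       True
  L1HS002      2  0.042553       True
FPR 24% CI [16%, 34%]
```

The 655 calls are the 689 planted truths minus the ~5% planted below the
3-read support threshold and those masked by a germline insertion within
the 200 bp somatic window — the caller recovers 100% of eligible truths
(see `tests/test_acceptance.py`). `L1HS000` is the planted dominant
source element; with only 47 transductions its 62% share sits within
sampling error of the configured 46%. The validation tally (24 false
calls among 100 reviewed) yields a 24% false-positive rate with an exact
95% interval of 16–34%.

The same stages are available from a shell:

```bash
retrocall all --seed 7 --outdir out/
```

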