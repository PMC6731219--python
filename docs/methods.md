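# Methods

This note documents the models and procedures implemented in `retrocall`,
the defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions.

## Coordinate and file conventions

All intervals are 0-based half-open internally. BED output keeps that
convention; GFF3 export converts to 1-based inclusive at the labeled
export point (`io.write_gff3`). Every artifact is a TSV with a documented
header (`io.SCHEMAS`); a mismatched header fails at line 1.

## Insertion calling

The caller works from discordant read-pair tables, not alignments.

* **Anchor selection.** A pair is usable when at least one end carries a
  repeat-family label; the non-repetitive end anchors it. When both ends
  are repetitive with equal mapping quality above 0, the first end is the
  anchor; any MAPQ of 0 under that rule excludes the pair.
* **Clustering.** Single linkage over same-sample/chromosome/strand
  anchor starts with a join distance of 500 bp (library-insert scale; the
  upstream caller's internal value is not published, so this is a
  declared approximation, configurable). Clusters need ≥ 3 members
  (s = 3 tumor, gm = 3 normal). Inner coordinates: plus cluster →
  rightmost anchor end; minus cluster → leftmost anchor start.
* **Reciprocal pairing.** Candidate (+, −) cluster pairs of the same
  family within a 500 bp pairing window are assigned greedily by
  increasing inner-coordinate distance, ties to the leftmost plus
  cluster; each cluster is used once. Overlap of inner coordinates is
  allowed (target-site duplications invert them). The breakpoint window
  is [min, max] of the two inner coordinates; its midpoint (floor of the
  mean) is the point used for track lookups.
* **Somatic filtering.** A candidate is removed when any germline call —
  matched normal or panel of normals, of any family — lies within 200 bp
  of the breakpoint window (edge distance, 0 when inside). Applying the
  filter across families is deliberate: a germline Alu can mask a nearby
  somatic LINE-1 call; the alternative (same-family only) is one flag
  away. Decoy-contig calls (hs37d5) are dropped; unknown contigs warn
  and are kept.

## Transduction attribution

Fixed filter order, asserted by `transduction_pipeline`:
support/MAPQ → merge → germline subtraction → source attachment →
somatic/sex filter → dedup.

* MAPQ > 37 is strict: a call at exactly 37 fails.
* Merging is transitive (connected components) over same-sample,
  same-type SVs whose corresponding ends are each within 200 bp. The
  merged call sums support and averages end positions.
* Germline subtraction applies to merged tumor SVs with length
  > 1000 bp and requires both ends of a normal SV of the same type to
  match within 200 bp (the both-ends reading was chosen; either-end
  subtraction would be strictly more aggressive).
* Source attachment: an SV survives when either end is within 1000 bp of
  a catalog element's 3′-end coordinate (right edge for + elements, left
  edge for −). The nearest element wins; exact ties go to the lowest
  element id and are flagged ambiguous. The other end becomes the
  insertion site.
* 3′ vs orphan class: a call is 3′ when LINE-1-family read evidence also
  maps at the insertion site (element body co-inserted), orphan
  otherwise. The discrimination rule is configurable because only the
  class names, not the rule, are established; absent evidence the class
  defaults to orphan.
* Dedup: within-sample, same-family calls within 200 bp collapse
  (transitively); calls found by both the cluster caller and the SV
  route are flagged `both` and counted once.

## Annotation

* **Poly-tail.** The 200 bp tail-search window is read as total width
  (midpoint ± 100 bp); the alternative reading (± 200) is one parameter
  away. Poly-A needs ≥ 2 forward split reads starting with ≥ 3
  consecutive A; the call is discarded when an overlapping read's
  reference context contains the same run (the run is genomic). Poly-T is
  symmetric on reverse reads at the read end. Conflicting A and T
  evidence yields no call.
* **Orientation.** A → reverse insertion strand, T → forward; sense =
  reverse-in-plus-gene or forward-in-minus-gene. The truth table is
  exhaustive; no tail or no unambiguous gene strand → unknown.
* **Gene context.** Exon takes precedence over intron when transcripts
  disagree; all overlapping protein-coding genes are reported, and
  intergenic insertions record the nearest gene for expression tests.
* **Densities.** Bin membership is decided by the breakpoint midpoint
  (a window straddling a bin edge is not split). Replication timing uses
  five bins, label 0 earliest. Open chromatin = bases in ≥ 2 of the 4
  DNase cell-line sets, intersected with callable regions; closed =
  callable − open; each cell-line set contributes boolean coverage
  (overlapping intervals within one set count once).

## Cohort statistics

* **Fisher–Pitman.** Statistic = sum of group-1 values; exact
  enumeration when C(n, n1) ≤ 10⁵, else Monte Carlo with an add-one
  corrected p. Two-sided p by the symmetric tail of the centered
  statistic.
* **Rank-uniformity expression test.** One rank per (gene, carrier
  sample) pair — a gene with carriers in several samples contributes one
  rank per carrier. Ranks are ascending TPM positions with ties broken
  randomly under the run seed, which keeps ranks integral and preserves
  null uniformity. The frequency table has one bin per rank (S bins for
  S samples); the statistic is Σ (O − E)²/E with E = N/S; p is the
  add-one-corrected exceedance fraction over uniformly re-drawn rank
  tables. Genes absent from the TPM matrix are skipped with a warning.
* **Fragile sites.** Insertion fraction = site insertions / cohort
  insertions; AI fraction counts only focal events (both segment
  breakpoints inside the site). Ratio > 1 → retrotransposon-high,
  0 < ratio < 1 → AI-high, AI fraction 0 → undefined.
* **AI colocalization.** An insertion colocalizes when its midpoint is
  within ± 5000 bp of any same-sample AI breakpoint; counted once.

## Clinical models

* **CIMP.** Probe threshold = normal-sample mean + 3 SD per probe (the
  threshold derivation is not quantified in the source methodology; the
  3-SD rule is a conventional stand-in and is configurable). Gene
  methylated at ≥ 25% of its probes; CIMP-H at 5–8 of the 8 panel genes.
  Scoring is monotone in the probe calls.
* **Driver rules.** Variant filters: coverage ≥ 4, allelic fraction
  ≥ 10%, quality ≥ 20. KRAS: non-synonymous at codons 12, 13, 61, 117,
  146; BRAF: V600E only; TP53: any non-synonymous change.
* **Regression.** OLS on log(1 + count) — the offset handles zero
  counts and is configurable. Covariates: CIMP-H, AI/10%, TP53, MSI,
  coverage/10, age/10, male, Dukes B/C/D, proximal location; complete
  cases only. Goodness of fit is the sum of squared standardized
  residuals against chi-square with n − p df; variance inflation factors
  screen collinearity, and exact rank deficiency raises an error naming
  a culprit pair.
* **Cox.** lifelines partial-likelihood fit, baseline stratified by
  tumor location; covariates insertions/10, MSI, CIMP-H, BRAF, age
  [55, 75) and ≥ 75 (reference < 55), male, Dukes B/C/D, AI/10%.
  Diagnostics: Grambsch–Therneau scaled-Schoenfeld test per term. No
  events raises; an event-free stratum warns.
* **Validation FPR.** Clopper–Pearson (beta-quantile) intervals by
  default — they reproduce the published 16–34% bounds for 24/100 — with
  Wilson as an option (it reproduces them too; the published method is
  not stated).

## Synthetic cohort

The generator emulates the study conditions at the extracted-table
level; it does not simulate reads, alignment, or repeat masking.

* **Counts.** log(1 + count) = b0 + 0.607·CIMP-H + 0.0826·(AI%/10) +
  N(0, 0.85), rounded. The log-normal form was chosen over a negative
  binomial so that the planted effects live exactly on the scale the
  regression fits — parameter recovery is then a clean test of the
  model code rather than of a transformation bias. With the default
  dispersion 0.85 the marginal distribution has mean ≈ 25 and median
  ≈ 17, matching the emulated cohort's summary statistics (the source
  reports no distributional form); the variance is several-fold the
  mean, i.e. strongly overdispersed.
* **Placement.** Probability ∝ segment length × 4.19^(bin/4) for
  replication bin (late/early ratio 3.06/0.73) × 1.854 for closed
  chromatin (1.78/0.96). Family mix 5024:13:20:15 over
  LINE-1:Alu:SVA:ERV; transduction fraction 346/5072 of LINE-1
  insertions; source shares 46% dominant, 7% and 6% secondary, remainder
  uniform over the other active elements. Catalog loci keep ≥ 10 kb
  separation so nearest-3′-end attribution is well defined.
* **Evidence.** Each above-threshold somatic truth emits 3 + Poisson(2)
  anchor pairs per strand flanking the position and ≥ 2 split reads
  carrying the planted tail (8–30 nt, uniform; only the ≥ 3-base
  detection rule is established). Sub-threshold truths (5% by default)
  emit exactly 2 pairs. Germline truths emit identical evidence in tumor
  and matched normal and panel calls in a random half of the panel
  normals. Transduction SVs place one end within ± 300 bp of the source
  3′ end, support 3 + Poisson(5), MAPQ 60; noise SVs are added at 20% of
  the signal count (arbitrary, configurable) with mixed MAPQ so the > 37
  filter is exercised; 5 germline SVs per sample appear in both tumor
  and normal tables.
* **Survival.** Event times are exponential with log-hazard
  0.108·(count/10) + Dukes effects (0, 0.452, 1.77, 2.78) + 0.26 for
  proximal location (so location stratification matters); censoring is
  an independent exponential process tuned to a 70% censoring fraction,
  a typical disease-specific-survival censoring level for a CRC cohort.
* **Methylation / expression.** CIMP-H samples get 5–8 methylated panel
  genes (2 of 4 probes hot at ratio ≈ 0.5), CIMP-L 0–4; non-hot probes
  stay below the normal mean + 3 SD threshold by construction, so
  scoring recovers the assigned class exactly. The TPM matrix covers the
  first 34 samples with log-normal values and, by default, no
  insertion–expression dependence (the null), switchable via
  `expression_insertion_effect`.

**What passing tests show — and do not.** Recovery of 100% of eligible
planted insertions demonstrates the clustering/pairing/filter logic is
correct under noise-free, well-separated evidence; it says nothing about
sensitivity under real alignment artifacts, mapping ambiguity in young
repeats, or coverage fluctuations, which the generator does not model.
Likewise the exact CIMP recovery reflects the planted separation of
probe ratios, not assay noise.

## Problem sizes

The default test-suite simulations use 10–40 tumors for pipeline
recovery, n = 2000 for regression/Cox parameter recovery, 200 replicates
× 1000 permutations for null calibration of the rank test, and ≤ 500
element instances for the brute-force interval oracles — sizes at which
the checked properties are already sharp while the whole suite runs in
well under a minute per file.

## Known limitations

* The upstream caller's exact join and pairing distances are not
  published; the 500 bp defaults are declared approximations.
* Orphan/3′ discrimination depends on optional site-side evidence; with
  none supplied all calls are labeled orphan.
* Source attribution is by nearest 3′ end; an insertion that lands
  within the attachment window of another catalog element is genuinely
  ambiguous and can be attributed to the wrong locus.
* No imputation: clinical models use complete cases only.
* Survival curves are exported as step-function tables; no plotting.
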