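# Methods

## Study design emulated

The package models a five-library DGE tag-sequencing contrast: one
microcycle-conidiation baseline medium (SYA) against four
normal-conidiation media (quarter-strength SDAY, and SYA enriched in
sucrose, nitrate or phosphate — SR, NR, PR). Each condition contributes a
single library of short cDNA tags anchored at the 3'-most restriction site
of each transcript; there are no replicates, which is why an exact
conditional test on the pair of counts, rather than a dispersion-based
model, is the appropriate statistic.

## Exact tag-count test

For counts `x` (library A, size `N1`) and `y` (library B, size `N2`) the
conditional kernel

    P(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) )

is a negative binomial with `x+1` successes and success probability
`N1/(N1+N2)`. Numerical choices:

* Both tails are summed **directly** in log space (log-gamma terms combined
  with `logsumexp`). The upper tail is never obtained as `1 − lower`: that
  subtraction loses all relative precision once the tail is below ~1e−12,
  and tails down to ~1e−200 arise in practice.
* The upper-tail summation stops at
  `max((x+1)r + 8·sqrt((x+1)r(1+r)), y) + 60/log1p(1/r) + 20` with
  `r = N2/N1`. The first part covers the distribution bulk (mean plus eight
  standard deviations of the kernel), the second adds enough
  geometric-decay terms (ratio `r/(1+r)`) to bound the discarded mass more
  than twenty-five decades below the retained sum.
* The two-sided p-value is `min(1, 2·min(P(Y≤y), P(Y≥y)))`, with the
  observation included in both tails. Because the point mass `P(y|x)` would
  otherwise sit in different tails for the two orientations, the statistic
  is evaluated in a canonical orientation — the library with the higher
  per-tag rate plays the role of `y` (ties broken toward the larger
  count) — which makes it exactly invariant under exchanging
  `(x, N1) ↔ (y, N2)`. This reproduces the closed form
  `p(0, 20 | N1=N2) = 2^-19`.
* p-values are clamped into `(0, 1]`; the clamp at the smallest positive
  double only matters beyond counts of ~10⁵.

Effect size is the log2 ratio of TPM values with zero counts floored at
`zero_floor = 1` tag, so presence/absence genes receive a finite, callable
ratio. FDR is Benjamini–Hochberg step-up per comparison (the four pairwise
screens are corrected independently, mirroring a design where each
subtractive library is built on its own); genes with `x = y = 0` are
excluded before the correction so untestable genes do not dilute the FDR.
Default thresholds: α = 0.001 on the FDR and |log2 ratio| > 1.

## Subtractive set logic

A *subtractive library* is the set of significant genes of one ordered
comparison (baseline SYA vs one other medium) with their directions. Two
screens consume the four canonical subtractive libraries:

* **Pattern sets** — genes up on the non-SYA side in all four comparisons
  (`normal_up`) or up on SYA in all four (`microcycle_up`). The two sets
  are disjoint by construction.
* **Nutrient-specific sets** — from the SYA-vs-nutrient subtractive
  library, remove every gene *expressed* on quarter-strength SDAY or on
  the other two nutrient media. "Expressed" defaults to an unambiguous
  count ≥ 1, the most permissive reading, which makes removal aggressive
  and the surviving sets small; the threshold is the
  `min_expressed_count` config knob. Direction labels are relative to the
  nutrient medium ("up" = higher than on SYA). The three sets are not
  forced disjoint; overlaps are reported rather than deduplicated, and the
  removal accounting records which library's expression excluded each
  candidate.

`venn_partition` provides the generic disjoint-region accounting over 2–4
named sets used in the run summaries.

## Enrichment

Upper-tail hypergeometric test per term, summed in log space from the
smallest terms upward; `k` may be passed as an array for one `(n, K, N)`
to score many overlap values at once. The background defaults to all genes
carrying at least one annotation in the namespace; terms with no annotated
background genes are skipped rather than given p = 1, again to avoid FDR
dilution. Q-values are BH across the tested terms of the namespace
(applied identically to GO-style and pathway-style maps), significance at
Q ≤ 0.05. Annotation maps are flat gene→term assignments; no
ontology-graph propagation is performed — propagating ancestors is left to
pre-processing.

## Tag processing

* Tag dialect: anchor `CATG` plus a 17-base body (21-mer tags) by default;
  both are configurable. Every anchor occurrence followed by a full body
  is indexed; a gene's 3'-most such tag is its *signature tag*.
* Cleaning applies, in order: non-ACGT removal, adaptor-prefix removal,
  and removal of distinct tags with copies < `min_copies` (default 2,
  i.e. singleton removal). Each rule logs removed distinct tags and
  copies; cleaning is idempotent.
* Mapping is exact by default (`max_mismatch = 0`). With
  `max_mismatch = 1`, an unmatched tag is rescued only when exactly one
  indexed tag lies within Hamming distance 1 and that tag maps to one
  gene; a tag reaching the index otherwise (an ambiguous neighbour, or
  two or more neighbour tags — even of the same gene, a vanishingly rare
  corner) counts as mapped-ambiguous. Copies are always conserved:
  unambiguous + ambiguous + unmapped = total clean. Mapping is
  sense-strand only.
* TPM = count / clean-library size × 10⁶.

## Simulator

The generator exists so every downstream stage can be validated against a
known truth. What it emulates:

* **Abundance** — log-normal draws (location 1.0, scale 1.5) renormalized
  to the simplex: a few transcripts dominate while most are rare, the
  heavy-tailed copy-number spectrum typical of DGE libraries; at the
  default scale more than half the genes sit at low copy numbers.
* **Planted classes** — `normal_up` genes ×fold-change (default 8) on the
  four normal-conidiation media; `microcycle_up` ×fold-change on SYA;
  each nutrient-specific class expressed **only** on its nutrient medium.
  For the nutrient classes the SYA level is `nutrient_sya_factor` ×
  baseline: the pipeline default is 0 (specifically-expressed genes,
  the study condition), while `plan_truth` called directly defaults to
  `1/fold_change`, a softer alternative for power exploration — at the
  default depths the 8-fold SYA-vs-nutrient contrast (≈5 vs ≈36 counts)
  sits at the edge of detectability at FDR < 0.001, which is worth knowing
  when choosing between the two.
* **Planted abundance floor** — planted genes are floored at 1.25e−4 of
  the simplex (≈120 TPM after the final renormalization), so planted
  effects are detectable at the default depth of 300 000 tags per
  condition. Scaled-down designs (tests, examples) raise the floor in
  proportion as they lower the depth, keeping planted genes near the same
  expected count level.
* **Sequencing** — multinomial sampling of the per-condition depth over
  gene signature tags (expected weights renormalized per condition, so
  realized totals equal the requested depth exactly), followed by
  independent per-base substitution errors (default 0.001) and
  replacement of an `adaptor_rate` fraction of copies by a fixed
  adaptor-prefixed 21-mer. One master seed; per-condition streams are
  derived by SHA-256 hashing of (seed, condition), so adding a condition
  never perturbs the others, and identical config+seed yields
  byte-identical libraries.

What it does **not** model: quality scores, indels, PCR duplicates,
GC bias, paired ends, or ambiguous shared tags at realistic rates (random
17-mer bodies make cross-gene tag collisions vanishingly rare, so the
mapped-ambiguous path is exercised mainly by constructed fixtures).
Passing recovery tests therefore demonstrate the correctness of the
statistics and set logic under the stated noise model, not robustness to
every artifact of real sequencing.

## Problem sizes used in the checks

The acceptance checks run the exact-test oracle grid at
`(x, y) ∈ [0,100]²` for depth pairs from `{10⁴, 10⁶}`; the null
calibration at 2 000 genes × 200 000 tags × 50 seeds; the planted-design
recovery at the default config (3 000 genes, 300 000 tags per condition);
the hypergeometric oracle at every valid input with N ≤ 60; enrichment
recovery over 100 seeds; and determinism on a 250-gene design. These
sizes were chosen so the full suite completes in a few minutes on one
CPU while still exercising every code path at realistic count levels.

## Known limitations

* Single-library-per-condition designs only; no replicate handling or
  dispersion estimation (use a count-regression framework when replicates
  exist).
* The exact test's discreteness makes it conservative at small counts;
  the null-calibration check measures this rather than correcting it.
* The nutrient screens inherit the "expressed = count ≥ 1" convention;
  with very deep libraries a single stray mapped copy removes a
  candidate, so `min_expressed_count` (or a TPM threshold upstream)
  should be raised in proportion to depth.
* Reference catalogues are taken as given transcript sequences; there is
  no genomic alignment, splice handling or reverse-complement search by
  default.
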