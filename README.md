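# dgetag

Analysis of digital gene expression (DGE) tag-sequencing experiments across a
multi-condition design, built around the study layout used to dissect the
conidiation pattern shift of the entomopathogenic fungus *Metarhizium
acridum*: a microcycle-conidiation baseline medium (SYA) contrasted with four
normal-conidiation media — quarter-strength SDAY and SYA enriched in sucrose
(SR), nitrate (NR) or phosphate (PR).

The package is aimed at computational biologists who need a tested, fully
reproducible implementation of the classic tag-count analysis stack:

* **Tag processing** — anchored-tag extraction from a transcript reference
  (NlaIII-style `CATG` + 17 nt body by default), raw-tag cleaning (non-ACGT,
  adaptor-prefixed, low-copy removal with per-rule accounting), unambiguous
  tag-to-gene mapping (exact or unique Hamming-1 rescue) and TPM
  normalization.
* **Differential expression** — the Audic–Claverie exact test for a pair of
  tag libraries, Benjamini–Hochberg FDR, and pairwise "subtractive library"
  screening at FDR < 0.001 and |log2 ratio| > 1.
* **Set screens** — four-way intersections yielding genes consistently up
  during normal or microcycle conidiation, nutrient-specific screens that
  remove every DEG expressed on the other media, and Venn-region accounting.
* **Enrichment** — upper-tail hypergeometric GO/pathway enrichment against a
  genome background with BH Q-values (significant at Q ≤ 0.05).
* **Simulation** — a five-condition tag-library generator with planted
  truth (heavy-tailed abundances, fold-change classes, nutrient-specific
  classes, per-base error and adaptor contamination), so the whole pipeline
  is testable end-to-end with known ground truth and without any download.

## The core statistic

For a gene observed `x` times among `N1` clean tags in one library and `y`
times among `N2` clean tags in another, the exact test conditions on `x` and
scores `y` under the null of equal relative abundance:

    P(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

a negative binomial with `x+1` successes and success probability
`N1/(N1+N2)`. Both tails are summed in log space and the two-sided p-value is
`min(1, 2·min(P(Y≤y), P(Y≥y)))`, evaluated in the orientation that makes the
statistic exactly symmetric under exchanging the two libraries (so
`p(x=0, y=20, N1=N2) = 2^-19`). Genes are called per comparison at
BH-FDR < α with `|log2((y/N2)/(x/N1))| > 1`, zero counts floored at 1 tag.

Enrichment of a gene set of size `n` against a background of `N` genes uses
the upper-tail hypergeometric probability of observing at least `k` of the
`K` term-annotated background genes.

## Worked example

```sh
python examples/06_full_pipeline.py
```

runs every stage on a reduced planted design (400 genes, 40 000 tags per
condition) and prints:

```
recovery of the planted classes:
             class  planted  called  precision  recall
         normal_up       10      10        1.0     1.0
     microcycle_up       15      15        1.0     1.0
  sucrose_specific        6       6        1.0     1.0
  nitrate_specific        6       6        1.0     1.0
phosphate_specific        6       6        1.0     1.0
```

Each row compares a called gene set with its planted class: `normal_up` and
`microcycle_up` are the four-way intersections of the subtractive libraries,
the three nutrient rows are the subtractive screens after removing genes
expressed on the other media. Precision/recall of 1.0 means the screens
recovered exactly the planted genes. The same run writes all artifacts
(count tables, per-comparison DEG tables, gene sets, Venn regions,
enrichment tables, a manifest with content digests) into an output
directory; `dgetag run-all --outdir OUT --seed 11` is the shell equivalent,
and `dgetag simulate/process/compare/screen/enrich` rerun single stages from
saved artifacts. The other `examples/*.py` scripts walk through each
capability in isolation.

## Layout

```
src/dgetag/        simulate, tags, de, screen, enrich, config, pipeline, io, cli
tests/             pytest suite (unit, property and acceptance tests)
examples/          one narrative script per capability
scripts/           acceptance.py
docs/methods.md    models, parameters, defaults and limitations
```
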