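# neuromarker

A tested, reusable implementation of the multi-stage biomarker-discovery
procedure used in case–control transcriptomic studies of neurodegenerative
disease (the motivating application is sporadic amyotrophic lateral
sclerosis, sALS): differential expression screening, tissue-specificity
filtering, protein–protein-interaction (PPI) module and hub-gene consensus,
competing-endogenous-RNA (ceRNA) network assembly, diagnostic/prognostic
biomarker evaluation, and case–control SNP association.

It is a library, not a command-line tool: the public API plus the short
narrative scripts in `examples/` are the interface. Every stage is driven
either by user files in plain-text formats (TSV/CSV/GMT) or by the built-in
synthetic generators, which plant recoverable ground truth so the whole
pipeline is testable without any external database.

## The procedure

Candidate sets shrink stage by stage:

1. **Differential expression** (`dge`). Per-gene moderated t statistics
   (empirical-Bayes variance squeezing, as in limma) on log2 matrices;
   Benjamini–Hochberg adjustment; DEGs are genes with |log2FC| > 1.5
   (strict) and adjusted p ≤ 0.05 (inclusive). DEG sets from multiple
   cohorts are intersected, and their union merged into one matrix.
2. **Tissue specificity** (`tissue`). A gene is organ-system-specific when
   its top atlas tissue exceeds 10× the median of its profile and the
   second-highest tissue is ≤ top/3, with the top tissue(s) in one system.
3. **PPI network** (`network`). Edges with combined score > 0.4 (strict;
   STRING 0–1000 scores auto-rescaled) form the graph. MCODE-style
   seed-and-grow clustering finds dense modules scored density × V with
   density = E/(V(V−1)), i.e. score = E/(V−1). Five centralities — MCC,
   Degree, DMNC (E/V^1.7), MNC, clustering coefficient — are ranked and the
   top-14 lists (ties inclusive) intersected into consensus hubs, then
   intersected with the nervous-system-specific set.
4. **Enrichment** (`enrich`). Hypergeometric over-representation and
   pre-ranked weighted running-sum enrichment with a gene-permutation null;
   gates q < 0.05 and permutation FDR < 0.25; gene sets from GMT files,
   size-bounded to [5, 5000] after intersection with the universe.
5. **ceRNA network** (`cerna`). Target miRNAs kept when predicted by ≥ 4 of
   5 sources; lncRNA/circRNA interactions need CLIP support ≥ 5; circRNA
   isoforms collapse to the most-sampled/highest-scoring one; an ncRNA joins
   a gene's network when it sponges a strict majority of that gene's
   consensus miRNAs. The result is strictly tripartite.
6. **Biomarker evaluation** (`evaluate`). AUC of the ROC curve
   (Mann–Whitney; ties half-credited) for diagnosis; median-split
   Kaplan–Meier curves with the two-sample log-rank test for prognosis.
7. **SNP association** (`genetics`). From per-group genotype counts
   (mm/Mm/MM): allele tables, the minor-allele frequency ratio
   cases/controls with a Katz log-scale 95% CI — reported as the headline,
   with the classical Woolf-CI odds ratio alongside — Pearson allele
   chi-square, and dominant-model (carrier vs non-carrier) Fisher exact test.

## Worked example

```bash
python examples/07_snp_association.py
```

prints, for a 30+30 case–control design with genotype counts 2/11/17 vs
1/3/26:

```
minor allele: cases 25.0% vs controls 8.3%
frequency ratio 3.000 (95% CI 1.164-7.732), allele p = 0.014
major-allele ratio 0.818 (95% CI 0.694-0.965)
odds ratio (Woolf) 3.667 (95% CI 1.238-10.863)
dominant-model Fisher p = 0.0204
```

The minor allele is three times as frequent in cases; the CI excluding 1 and
the allele test p = 0.014 mark it as a putative risk factor. The frequency
ratio (3.000) and the cross-product odds ratio (3.667) are deliberately
printed side by side because association tables often conflate them.

`examples/08_full_pipeline.py` generates a complete synthetic input bundle
and runs every stage end-to-end, printing the shrinking candidate sets and
the planted truths they recover; the other examples cover one stage each.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the dense-module scores of three reference PPI clusters (14
nodes/60 edges, 15/50, 9/28) by constructing graphs with exactly those
counts and applying the package's score = density × V convention, writing
one JSON entry per target.
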