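# Methods

This note documents the statistical models, the conventions chosen where the
procedure is conventionally underspecified, what the synthetic generators do
and do not emulate, and the numerical details that affect results.

## Differential expression

Expression is assumed log2-scale. A guard transform applies log2(x+1) when
the matrix maximum exceeds 50 (a log2 microarray value above 50 does not
occur in practice); negative values on a linear-scale matrix are an error.
Duplicate gene IDs (multi-probe genes) collapse to the probe with the
highest mean expression before testing, so downstream network stages see one
record per gene.

The test is a per-gene two-sample t with empirical-Bayes variance
squeezing: a scaled inverse-chi-square prior (s²₀, d₀) is fitted to the
per-gene pooled variances by the method of moments on log variances, and
each gene's variance is replaced by the posterior mean
(d₀s²₀ + d·s²_g)/(d₀ + d) with d + d₀ degrees of freedom. At the tiny group
sizes this pipeline targets (5v4, 3v3) the ordinary pooled t — with or
without a variance floor — loses enough power that a planted 2-fold effect
over 0.5 SD noise is recovered below the 80% level this package's own
recovery suite demands; the moderated t restores it (≈ 93% sensitivity,
null raw-p rate ≈ 0.049). The implementation is cross-checked against
Bioconductor `limma::eBayes` in the test suite (t agrees to < 0.5%
relative). `shrinkage="floor"` (5th-percentile variance floor) and
`shrinkage=None` (plain pooled t) remain available; in every mode a
residual zero-variance gene gets p = 1 when its fold change is 0 and p = 0
otherwise.

Multiple testing is Benjamini–Hochberg. The DEG filter is |log2FC| > 1.5
strict and p_adj ≤ 0.05 inclusive — the boundary semantics follow the
screening rule as quoted, and the ≤ at exactly 0.05 is a documented choice
(the alternative strict reading changes only measure-zero cases).

## Tissue specificity

The median in rule 1 (top > 10 × median) is the median across tissues of
that gene's profile, matching how per-gene atlas profiles are read. Rule 2
compares the single second-highest tissue value against top/3, inclusively.
When the median is 0, rule 1 degenerates to top > 0, so all-zero profiles
are never specific. Tissues tied at the top spanning more than one organ
system fail the single-system requirement; the call is flagged
`tied_across_systems`. Both rules are ratios, so calls are invariant under
positive scaling of a profile. A default tissue → organ-system mapping (12
tissues over nervous, haematologic/immune, digestive, respiratory,
circulatory, placenta, endocrine, genital) ships with the package; any
two-column CSV or YAML mapping can replace it.

## PPI modules and centralities

Edge scores are combined-confidence values in [0, 1]; integer columns above
1 are treated as the 0–1000 dialect and divided by 1000. The score filter is
strict (> 0.4), duplicate edges keep the maximum score, self-loops are
dropped.

MCODE weighting: each node's weight is k × density of the highest k-core of
its closed neighborhood. Seeds are taken in decreasing weight order; growth
includes unvisited neighbors with weight ≥ seed weight × (1 − node score
cutoff), breadth-first to the depth limit; complexes must contain a 2-core;
haircut (on by default) iteratively trims degree-1 nodes; fluff is off by
default; modules need ≥ 3 nodes and positive score. The reported module
score is density × V with density = E/(V(V−1)) — equivalently E/(V−1) —
the convention under which a 14-node/60-edge module scores 4.615. Note this
is *not* the undirected-graph density 2E/(V(V−1)); the halved form is what
reproduces the reference scores, and the score identity is asserted in the
tests. Dense blocks connected by bridge edges can merge into one module;
that is inherent to seed-and-grow expansion, not an artifact.

Centralities: MCC is Σ(|C|−1)! over maximal cliques containing the node
(a node in no triangle therefore gets its degree); MNC is the order of the
largest connected component of the open neighborhood; DMNC divides that
component's edge count by V^1.7 (the method's published exponent); the
clustering coefficient and degree are standard. Maximal cliques come from a
pivoting Bron–Kerbosch enumeration, guarded to refuse graphs above 5000
nodes. Rankings sort by score descending with lexicographic tie-break;
top-k keeps every node tied with the k-th score so no tied gene is dropped
arbitrarily. The hub consensus is the plain intersection of all top-k sets.

## Enrichment

ORA is the one-sided hypergeometric upper tail with BH adjustment across
sets; sets are intersected with the analysis universe and then size-bounded
(defaults 5–5000). Pre-ranked enrichment uses the weighted
Kolmogorov–Smirnov running sum (hits weighted |score|^w normalized to 1,
misses 1/(N−N_h)); ES is the extreme deviation; the null permutes set
membership over gene labels (the pipeline consumes ranked lists, so
phenotype permutation is unavailable by construction). NES divides ES by the
mean |null ES| of matching sign; p and FDR are one-sided on that
matching-sign null, with the single-set FDR reducing to the normalized tail
fraction. All permutation output is deterministic under a fixed seed. A set
covering the whole ranked list has no misses and is rejected rather than
given an arbitrary score.

## ceRNA assembly

Consensus targeting requires a (miRNA, gene) pair in ≥ 4 distinct sources;
raising the threshold can only shrink the set (asserted as a property).
miRNA identifiers are matched case-insensitively with -3p/-5p arms kept
distinct. "Present in most predictions" is implemented as a strict majority
of a gene's consensus miRNAs — a reproducible reading of "most",
configurable via `majority`. circRNA isoform collapse orders candidates by
(samples desc, score desc, ID asc). The assembled graph is checked
tripartite on every build: every edge touches a miRNA.

## Biomarker evaluation

AUC is computed rank-based (Mann–Whitney with half-credit ties), which
equals the trapezoidal area under the empirical ROC curve; a per-gene flag
inverts direction for markers where low expression is disease-like. The
prognostic split is at the median with ties assigned low, making the split
deterministic; groups with fewer than 2 samples are an error. Kaplan–Meier
estimation and the log-rank test (hypergeometric variance at each distinct
event time, chi-square df = 1) are delegated to lifelines.

## SNP association

Allele counts derive from genotypes as minor = 2·mm + Mm. The headline
statistic is the minor-allele frequency ratio cases/controls with the Katz
log-scale CI, exp(ln r ± z·√(1/a − 1/n₁ + 1/c − 1/n₂)); association tables
in the literature sometimes print this quantity labeled "OR", so the
classical cross-product odds ratio with the Woolf CI is always reported
alongside, clearly labeled (on the reference counts: 3.000 vs 3.667). Zero
minor-allele counts flag the result degenerate; no continuity correction is
applied silently. Percentages round half-up to one decimal. The
dominant-model headline is the two-sided Fisher exact test on carriers vs
non-carriers, with Pearson (± Yates) and the 2×3 genotype chi-square
reported for transparency — on the reference counts these give 0.020,
0.010/0.022 and 0.034 respectively, a spread worth reporting because no
single "genotype p" convention is universal. The minor allele defaults to
the rarer pooled allele, overridable per SNP.

## Synthetic worlds

All generators draw from one seed through fixed, named substreams
(SeedSequence spawn keys), so adding a generator never changes another's
output and identical configs are bit-identical.

- **Expression**: gene baselines uniform on [4, 12] log2 units, i.i.d.
  Gaussian noise (SD 0.5 default), planted genes shifted +2.0 log2 in cases;
  default design 5 cases vs 4 controls, 1000 genes, 50 planted. Generated
  directly on log2 scale: only the log2 matrix feeds downstream math, so
  probe-level artifacts, batch effects and platform differences are
  deliberately not modeled — a green recovery test says the screen works on
  clean log2 data, not that it survives batch confounding.
- **Atlas**: near-uniform background (1 ± 20%), planted genes get value 50
  in one nervous-system tissue; both screening rules pass by construction.
- **PPI**: Erdős–Rényi background (n = 150, p = 0.02) with disjoint planted
  blocks (sizes 14/15/9 by default, mirroring reference cluster sizes) at
  within-block p = 0.9; block edges score U(0.7, 1), background
  U(0.15, 0.95), so the 0.4 filter never cuts planted structure.
- **Predictions**: each miRNA is carried by exactly its profile's number of
  sources (default cycle 5,4,3,2,1,0 over 30 miRNAs), so the support-≥4
  consensus has an exact planted answer.
- **Survival**: exponential event times with log-hazard β·z over
  standardized expression (β = 1.5 default, baseline median 36 months);
  censoring is an independent Bernoulli(censor_rate) with the censoring
  time uniform before the event — a simplification of administrative
  censoring that fixes the expected censored fraction exactly.
- **Genotypes**: Hardy–Weinberg within group; controls at MAF 0.083, cases
  at rr × 0.083 (rr = 3.0 default), 30+30 subjects. Exact enumeration puts
  Katz-CI coverage of the planted ratio at 0.968 in this design — within
  the 93–97% band the recovery suite checks, but near its edge, so the
  coverage test uses 5000 fixed seeds to keep Monte-Carlo noise small.

## Known limitations

- MCODE module boundaries depend on seed order under ties; ties are broken
  lexicographically for determinism, which may differ from other
  implementations.
- The pre-ranked FDR for a single set equals its permutation p; the
  multi-set FDR is not the full rescaled-NES pooling of the original
  method.
- The survival generator's uniform-before-event censoring is not a hazard
  model of dropout; censoring is independent of expression by construction.
- No annotation content ships with the package: enrichment, predictions and
  interactions are whatever files the user supplies.
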