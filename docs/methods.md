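# Methods

## The model

`cernascope` treats ceRNA inference as a conjunction of explicit gates over a
two-group log2 expression matrix and two directed interaction tables
(lncRNA→miRNA, miRNA→mRNA). A triple (l, m, g) is asserted when three
independent conditions hold: l and g are both differentially expressed, their
profiles are co-expressed above a stringent Pearson threshold, and both hops
of the miRNA bridge are present in the interaction tables. The resulting
network is strictly tripartite — co-expression selects nodes, it never
becomes an edge — so a lncRNA's degree equals its number of distinct
mediating miRNAs, which is what the hub gate (degree > 20, strict) is
applied to.

### Differential expression

Per gene, fold change is 2^(mean₂(case) − mean₂(control)) — a geometric-mean
ratio, the microarray norm — and significance is Welch's unequal-variance
t-test on the log2 intensities. The gates are FC ≥ 2.0 (up) / FC ≤ 0.5
(down), both inclusive, with raw p < α = 0.05 and no multiple-testing
correction: the FC gate is doing the error control at this stage (under the
default noise level it removes essentially all α-level false positives; see
the null-calibration tests). The choice of Welch's t is a documented
stand-in for whatever vendor statistic produced the original array p-values;
moderated/empirical-Bayes variants are a deliberate non-goal, and the test
is exposed on its own (`welch_t_test`) so it can be validated against an
exhaustive label-permutation oracle. Degenerate zero-variance inputs use a
fixed convention: both groups flat and equal → p = 1; both flat, unequal →
p = 0. Non-finite values are rejected at load time, never imputed.

### Co-expression

All dif-lncRNA × dif-mRNA pairs are tested over the pooled case+control
samples (a per-group option exists; pooled is the default because the
network is meant to describe the joint study). The retention rule is
r > 0.97 (strict) and p < 0.01, with p from the t-transform
t = r√(n−2)/√(1−r²) on n−2 df. The signed threshold is taken literally;
`use_absolute=True` switches to |r| for users who follow the common
absolute-value variant. With n = 8 the r-gate already implies p ≪ 0.01, so
the p-gate is redundant under the default design but enforced as written.
Zero-variance profiles are skipped and logged rather than raising, since a
flat probe is a data artifact, not a caller error.

### Graph analytics

The PPI loader keeps edges with combined score ≥ 0.7 (inclusive), drops
self-loops and merges duplicates keeping the maximum score. k-core
decomposition is the standard iterative pruning (networkx); the test suite
checks it against a from-scratch repeated-deletion oracle on hundreds of
random graphs. The dense-module detector follows the molecular-complex
(MCODE) scheme: vertex weight = k of the highest k-core of the node's closed
neighborhood × that core's density; seeds are taken in decreasing weight
order (degree ≥ 2 to seed); growth admits unvisited neighbors with weight ≥
seed-weight × (1 − node-score-cutoff) up to the depth limit; grown sets
without a 2-core are discarded; a single-pass haircut removes
singly-connected members; score = density × size. Node-score cutoff 0.2,
haircut on and fluff off are the published defaults, configurable. Two
deliberate determinism choices: all ties break lexicographically on node id,
and nodes of a rejected candidate module stay visited so each node belongs
to at most one module regardless of input order.

### Enrichment

Over-representation uses the upper hypergeometric tail
p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n) with the universe defaulting to all
mRNAs on the matrix, set-size bounds applied to the set∩universe count, and
Benjamini–Hochberg adjustment across the tested sets of a collection. Term
collections are plain GMT inputs; no ontology-graph propagation is
attempted. The GSEA enrichment score is the signed maximum deviation of the
weighted Kolmogorov–Smirnov running sum (hits weighted by |metric|^exponent,
exponent 1 by default; misses decrement 1/(N−N_set)). Significance uses a
**gene-permutation** null — set membership reshuffled along the ranked
list — with two-sided smoothed p = (1+#{|ES*| ≥ |ES|})/(n_perm+1). Phenotype
permutation is intentionally not offered: a 4 + 4 design admits only 70
label splits, too few for a usable permutation null.

### Validation statistics

2^−ΔΔCt quantification: ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = meanΔCt(case) − meanΔCt(control) (group means — the samples are
unpaired), fold = 2^−ΔΔCt, with per-sample relative quantities
2^−(ΔCt − meanΔCt(control)) emitted for plotting and testing. The
Mann–Whitney U comparison is exact (scipy's exact method, checked against a
full labeling enumeration) for tie-free samples with n₁+n₂ ≤ 12 and
otherwise a tie- and continuity-corrected normal approximation; the method
used is always reported. The switch point is chosen so that an 8 vs 8
validation cohort exercises the approximation path, which is therefore the
tested path for realistic input sizes. Amplification-efficiency correction
(Pfaffl) is out of scope.

## The synthetic generator

The generator emulates the study design the pipeline targets: 4 case and 4
control arrays, 2 000 mRNAs and 500 lncRNAs measured on the log2 scale, 300
miRNA identifiers that appear only in the interaction tables (the assay does
not measure miRNA expression). Baseline log2 intensities are uniform in
[6, 12] — a plausible array range — with gaussian per-array noise
(sd 0.25). Sixty mRNAs and thirty lncRNAs are shifted by ±2 log2 units in
the case group (half up, half down). Co-expression is planted by **profile
sharing**: a paired mRNA's profile is its partner lncRNA's profile
(re-centred on the mRNA's own baseline) plus noise of sd 0.02, which
guarantees the r > 0.97 gate is reachable with only eight samples — a
latent-factor model would not give that guarantee at n = 8. Forty triples
are wired through forty distinct miRNAs, thirty of them through one
designated hub lncRNA (so its network degree, 30, clears the > 20 hub gate
while every other lncRNA has degree ~1). Background interaction rows are
added at rate 0.002 per possible pair. The PPI list contains one planted
clique with scores in [0.9, 1] over DE mRNAs plus sparse random edges
(scores 0.4–0.9, half of which survive the 0.7 load filter); the clique size
defaults to 22 so that clique members also clear the whole-network hub gate
(degree > 20), keeping the final three-way core-gene intersection
non-degenerate under default conditions. One gene set of 50 genes (30
planted DE mRNAs + 20 background) is emitted as the enrichment positive
control among 19 random sets.

What the generator does **not** model: probe-level artifacts, batch effects,
normalization, heavy-tailed or intensity-dependent noise, correlated
background genes, miRNA expression. Consequently, passing recovery tests
shows the pipeline's gates and graph logic are correct and calibrated under
idealized gaussian conditions; it does not certify performance on real
arrays, where normalization quality and correlation structure dominate. One
realistic artifact the defaults do surface: with 4 + 4 samples, any two
same-direction DE genes are strongly correlated through the group shift
alone, so the r > 0.97 gate retains a few hundred such pairs beyond the
planted thirteen — exactly the behavior a real small-n design exhibits —
and the interaction tables are what keep the assembled network specific.

## Numerical and design choices

- Determinism everywhere: one `numpy` Generator seeded from the config;
  every output table sorted on a stated key; floats written at 6 significant
  digits; fixed seed ⇒ byte-identical bundles (tested).
- Pipeline caching is checksum-based per stage (inputs + parameters +
  upstream outputs); a rerun with unchanged inputs reuses stage files
  verbatim.
- Boundary conventions are inclusive where the gates read "≥" (FC ≥ 2.0,
  score ≥ 0.7, ceRNA-PPI degree ≥ 4) and strict where they read ">"
  (r > 0.97, hub degree > 20); each boundary has a dedicated test.
- The core-gene step is a generic n-way named-set intersection rather than a
  hard-coded three-way merge, because the natural inputs (ceRNA mRNAs,
  ceRNA-PPI hubs, whole-PPI hubs) vary between analyses; the pipeline wires
  the three-set variant and the membership table it writes is the tabular
  Venn diagram.
- Acceptance-style checks run at deliberately modest problem sizes — twenty
  replicate studies at the default design, a 50 000-gene null matrix, 500–
  1 000 permutations per GSEA call — chosen so the full suite completes in
  about a minute while keeping Monte-Carlo standard errors far inside the
  asserted margins.

## Known limitations

- The DE stage offers no moderated variance estimator; with 4 samples per
  group, per-gene variance estimates are noisy and the Welch test is
  conservative (the measured null rate at α = 0.05 is ~4–5%).
- miRNA identifiers are opaque strings; no miRBase normalization or version
  reconciliation is attempted.
- MCODE's non-published tie-break details differ between implementations;
  module membership here is reproducible but may differ at the margins from
  other tools on graphs with symmetric weight ties.
- GSEA offers only the gene-permutation null; phenotype permutation would
  require a larger design than the package targets.
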