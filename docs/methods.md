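# Methods

This note documents the models, conventions, and numerical choices behind
`netmark`, and what its synthetic benchmarks do and do not establish.

## Network model and topology

Networks are simple undirected graphs over opaque, case-sensitive protein
identifiers.  Loading enforces simplicity: self-loops (homodimer entries
common in PPI databases) are dropped and counted in a load report,
duplicate edges are collapsed, `{A,B} = {B,A}`.  Identifier mapping
(probe→symbol, symbol harmonization) is treated as upstream curation and
is out of scope.  Edge lists cannot represent isolated nodes, so writing
and re-reading a graph preserves the non-isolated subgraph; all analyses
run on the giant connected component, where this is immaterial.

**Traffic** is betweenness centrality in one fixed convention: undirected,
unordered source–target pairs, fractional dependencies (each pair
contributes `σ_st(v)/σ_st`), endpoints excluded, no normalization.
Computation uses Brandes' algorithm (via networkx); the test suite
verifies equality with an explicit all-shortest-paths enumeration oracle
on hundreds of random connected graphs.  Published traffic tables from
other tools may use a different global scaling (ordered pairs, or raw
path counts); *ranks*, which drive everything downstream, are invariant
to such scaling, so rank-level agreement — not value-level — is the
supported contract.  Bottleneck ranks break ties by traffic desc, degree
desc, then identifier asc, making the ranking a deterministic permutation.

The degree–traffic association uses Spearman's ρ (average ranks for
ties) with a label-permutation p-value and the add-one estimator
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm)`, so p is never 0; the
default `n_perm = 10 000` gives resolution 1e-4.  An asymptotic option
exists for quick looks.

On reference networks of this domain the mean degree is reported as
`2m/n` (the standard definition); one published description of a
2532-node / 6131-edge component prints 4.25 where `2m/n` is 4.84 — the
package reports the standard quantity and leaves the discrepancy to the
source.

## Modularity clustering

Modularity is Newman–Girvan: `Q = Σ_c [e_c/m − (d_c/2m)²]`.  The "random
expectation" term is realized by the configuration model (degree-
preserving rewiring), the standard null when none other is named.
Clustering is agglomerative: start from singletons; at each step merge
the connected module pair with the largest `ΔQ = e_ij/m − d_i d_j/(2m²)`;
stop when no merge is strictly positive.  Only connected pairs are
considered (merging disconnected modules cannot increase Q).  Ties on ΔQ
are broken by the lexicographically smallest module-id pair, where a
module's id is its lexicographically smallest member, so the merge log
and the final partition are reproducible without a seed.  The returned Q
is recomputed from the final assignment (self-consistency is asserted in
tests against both a direct oracle and networkx's community modularity).

Modules smaller than `min_size` (default 3, the smallest module size
worth reporting) are flagged, not deleted — the partition stays total.
The number of modules is algorithm-variant output, not a contract:
different greedy variants produce different counts on the same network.

**Resolution limit.** Agglomerative modularity maximization cannot hold a
community whose total degree is far below `sqrt(2m)`; with m ≈ 6000 that
is ≈ 110, i.e. ~20+ nodes at mean degree 5.  A 5-node module attached to
the giant component will always be absorbed by some neighbour.  This
shapes the synthetic benchmark design (below) and is a real caveat when
comparing against tools whose greedy variant stops differently.

Per-module statistics follow the standard schema: NP (proteins), IntraMI
(edges inside), InterMI (edges with exactly one endpoint inside), TotInt
= IntraMI + InterMI, and MTraffic.  No standard definition of a module
traffic summary exists; here **MTraffic is the sum of betweenness
centrality of the module's nodes computed on the module's induced
subgraph** — a measure of internal routing structure independent of the
module's embedding.  Published MTraffic columns computed by other tools
are not expected to match.

## Enrichment

Each (module, term) pair is tested with a two-tailed Fisher exact test on
the 2×2 membership table over the gene universe.  The two-sided p-value
uses the minimum-likelihood rule (sum of hypergeometric probabilities of
all tables with the observed margins whose probability does not exceed
the observed one); mid-p is not used.  The default universe is the
clustered network's genes intersected with the annotation universe — the
conservative background when the analysis is network-scoped — and is
configurable.  BH correction is applied across all module × term pairs
within one namespace (BP, CC, or MIR treated as separate families);
significance is adjusted p < 0.01 by default.  miRNA target sets ride the
identical machinery as MIR-namespace gene sets; miRNA expression is not
modelled.  GO-graph ancestor propagation and annotation-snapshot choices
are out of scope, so enrichment results on real data are inherently
snapshot-dependent.

## Differential expression

Outcome labels follow the ejection-fraction rule: good ⇔ EF > 40%.
Group comparison is the two-sided Mann–Whitney U test: exact permutation
distribution when `n1 + n2 ≤ 20` and the pooled values are tie-free,
otherwise the normal approximation with tie and continuity corrections.
Data constant across both groups returns p = 1 (no evidence by
construction).  Direction is the sign of (median poor − median good),
reported separately from the two-sided p.

Module-level differential expression is the Mann–Whitney test applied to
the per-sample *module-mean profile* (unweighted mean over the module's
genes that have expression data; genes without data are dropped with a
logged count), BH-corrected across modules.  This is a deliberate,
simple instantiation of "gene-set level differential expression" —
chosen because module means are also the classifier inputs — and other
gene-set statistics would give different module p-values.  Missing
values in the matrix are rejected outright; no imputation policy is
implied.

qPCR quantities use ΔCt normalization against a housekeeping reference:
`expr(s, g) = 2^(Ct(s, ref) − Ct(s, g))`.  The reference column is
identically 1, and any per-sample additive Ct shift (loading/input
differences) cancels exactly.

## Classification

The classifier is logistic regression with an L2 penalty on the
non-intercept coefficients: maximize `ℓ(β0, β) − λ‖β‖²` with λ = 1e-8 by
default — numerically a near-unpenalized fit whose penalty only
guarantees a finite optimum on separable data.  Features are
standardized to mean 0 / SD 1 (population convention); with
`scaler_scope="fold"` (default) the scaler is estimated inside each
training fold, which is leakage-free; `"global"` scaling over the whole
dataset is available for compatibility with whole-dataset-preprocessing
workflows.  Constant training columns pass through as zeros with a
warning.

Fitting is damped IRLS (Newton with backtracking line search on the
penalized negative log-likelihood).  Numerical safeguards: IRLS weights
floored at 1e-9 and a 1e-9 ridge added to the Newton system — both
affect only the step, not the optimum (the gradient is exact);
convergence is declared when the max absolute parameter change drops
below `tol` (1e-8) or the gradient inf-norm is negligible.  With λ > 0
the objective is strictly concave, so the optimum is unique; tests check
agreement with an independent quasi-Newton optimizer to 1e-5 and with
scikit-learn's implementation at moderate penalty.

Evaluation is leave-one-out cross-validation: each sample is scored with
the predicted probability of poor outcome from a model trained on the
other n−1; pooled out-of-fold scores give the AUC in the Mann–Whitney
form (ties 0.5), with *poor* as the positive class.  A known LOOCV
pathology is asserted rather than hidden: on balanced data a pure-noise
feature scores *below* 0.5 on average, because deleting one sample tilts
the training prevalence against the held-out class.  Train-on-one-
dataset / score-on-another designs (e.g. fit on microarray, score a qPCR
cohort) use the same fit/score primitives (`fit_panel` / `score_panel`).

Panel families assembled by the pipeline: (1) mean profiles of modules
with corrected DE p ≤ 0.05; (2) the individual expressed genes of those
modules; (3) the union of top-k-traffic genes with nominal DE p ≤ 0.02
and the significant modules' DE genes.  Both thresholds are configurable;
the defaults are the levels at which reported discovery hits of this
analysis type pass.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their scenario, seed included
(numpy PCG64 via `default_rng`), so outputs are reproducible across runs
and platforms for a pinned numpy generation.

* `synth_network` — planted-partition graphs: within-block edge
  probability `p_in`, between-block `p_out` (`p_in > p_out`).  Realized
  densities converge to the probabilities (checked at block size 200
  within 3 binomial SEs).
* `synth_expression` — `baseline + effect·1[poor] + N(0, noise_sd)` per
  gene/sample on a log-intensity-like scale; effects are expressed in
  noise-SD units so power statements are scale-free.  EF values are drawn
  consistently with the labels: good uniform on 45–73%, poor uniform on
  20–40% (the printed ranges of the cohort design this emulates).
  Default cohort 16 good / 16 poor.
* `synth_annotations` — random null gene sets of size 5–50 plus planted
  terms included verbatim.
* `synth_ct` — cycle thresholds in 15–35 with a shared per-sample
  loading shift (cancelled by ΔCt) and a low-variance reference gene.

The **study-sized preset** (`paper_shaped_preset`) is the package's
end-to-end benchmark: 100 planted 25-node blocks (~2500 nodes, p_in =
0.15, p_out = 6e-4, mean degree ≈ 5), a 16/16 cohort, an 11-sample Ct
table, and annotations with planted terms.  One block is the *prognostic
module*: its genes carry a 0.8-SD class effect with a 5-gene signature
core at 1.5 SD, and three high-degree nodes elsewhere act as
differentially expressed bottlenecks (1.5 SD).  The prognostic module is
block-sized rather than a handful of genes deliberately: a 5-node
community sits far below the greedy algorithm's resolution limit at this
edge count and would provably be absorbed, so a benchmark planting it
could not be recovered by the method being benchmarked.  The 5-gene core
preserves the "small signature inside a module" structure at the
expression level.

What passing synthetic tests shows: the pipeline's machinery is correct
(oracle equivalence), its statistics are calibrated under the null, and
planted structure of realistic size and effect is recovered.  What it
does not show: performance on real cohorts — real microarray data have
correlated genes, batch structure, heavy tails, and probe-level noise
that independent Gaussian generators do not emulate, and real PPI
networks have heavy-tailed degree distributions unlike planted-partition
blocks.  Published AUCs from real cohorts are therefore not reproduction
targets of the synthetic benchmark.

## Test and benchmark sizes

Chosen as the package's own accuracy/time trade-off: traffic oracle
equivalence on 400 random connected graphs of ≤ 12 nodes (acceptance)
plus 60 (unit); Fisher-vs-enumeration exhaustively for all tables with
total ≤ 14 plus 300 seeded tables with totals to 60; Mann–Whitney
exact-vs-enumeration for all group-size pairs with n1 + n2 ≤ 12; greedy-Q
versus exhaustive set-partition search on graphs of ≤ 7 nodes (Bell(7) =
877 partitions per graph, 60 + 25 cases); null calibration over 40
cohorts × 200 genes; LOOCV noise-pathology average over 100 seeds.

## Known limitations

* Greedy modularity's resolution limit (above); no Louvain/Leiden or
  overlapping communities.
* Module-level DE is tied to the module-mean statistic; alternative
  gene-set statistics are not implemented.
* Enrichment performs no GO ancestor closure or term-redundancy
  reduction.
* The expression pipeline assumes gene-level, complete matrices;
  normalization and probe collapsing are upstream.
* Exact Mann–Whitney requires tie-free data; tied small samples fall
  back to the corrected normal approximation.
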