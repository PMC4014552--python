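# Methods notes

This note records the modeling assumptions, parameter choices and numerical
conventions behind `survwalk`, and what the synthetic benchmark does and
does not demonstrate.

## Survival screen

Each feature is dichotomized at its own mean (strictly greater → "high";
ties at the mean → "low", so a constant feature produces one empty group and
is excluded from the screen rather than failing it). Groups are compared
with the standard two-group log-rank test: at each distinct event time the
observed deaths in group 1 are compared with the hypergeometric expectation
given the at-risk counts, and the statistic (O₁ − E₁)²/V is referred to a
χ² distribution with 1 df (two-sided). Tied event times use the
hypergeometric variance term `d·(n₁/n)·(1−n₁/n)·(n−d)/(n−1)`. If no events
occur at all, V = 0 and the test is undefined; the screen reports p = 1 by
convention. The implementation is vectorized across features (one pass over
the sorted event table for the whole matrix); the suite checks it against
`lifelines.statistics.logrank_test` to ~1e-14 on random data with ties.

The screen recomputes each feature's mean within whatever sample set is
analyzed (training half, testing half, a grade subgroup): the split rule is
part of the method, not a fitted parameter carried across sets.

Measured calibration (also recomputed by `scripts/acceptance.py`): at
α = 0.001 on null cohorts of 160 samples the selection rate is ≈ 0.0010–
0.0013 over 20 000 null features — nominal within binomial error.

## Pathway enrichment and selection

Enrichment is the exact hypergeometric upper tail P(X ≥ r) for a pathway
with t gene nodes in a genome of m genes against an n-gene query
(`scipy.stats.hypergeom.sf`). Only gene-type pathway nodes count toward t
and the overlap; compounds and other node types never enter the counts. The
genome size m defaults to the number of distinct genes in the expression
matrix and can be fixed in `RunConfig`.

Benjamini–Hochberg adjustment is applied within each tested family
separately: the gene-level query over all pathways is one family, each
miRNA's target query is another. A pathway is a survival pathway when the
gene-level test passes p < 0.01 and FDR < 0.15 *and* at least one survival
miRNA's target enrichment passes p < 0.01 in it (the regulator count
threshold is configurable; 1 is the default reading of "regulated by
survival miRNAs"). Results are sorted by pathway id so selection is
independent of input order.

## Random walk with restart

The walk runs per pathway on the column-normalized adjacency matrix W
(node order fixed lexicographically; W[i, j] is the probability of stepping
j → i). Conventions:

- **Edge direction.** Pathway edges are treated as undirected by default.
  Curated signaling graphs are sparse, and strict directionality strands
  restart mass in sinks, starving upstream regulators of score; a
  `directed` mode is available in `RunConfig` for graphs where direction is
  trusted.
- **Dangling nodes** (no outgoing edge in directed mode, isolated nodes
  otherwise) receive a self-loop before normalization, keeping W
  column-stochastic and the walk mass conserved.
- **Seeds.** Survival genes and the focal miRNA's support-filtered targets,
  intersected with the pathway's gene nodes, each with p⁰ = 1/|seeds|.
  A pathway none of whose gene nodes is a seed is skipped with a warning —
  the walk is undefined there.
- **Iteration.** p⁽ᵗ⁺¹⁾ = (1−r)·W·p⁽ᵗ⁾ + r·p⁰ with r = 0.7. The map is an
  L1 contraction with factor (1−r), so the fixed point is unique and the
  iteration cannot fail to converge; the stopping rule is L1 change below
  10⁻⁶ ("the difference" is not otherwise specified; L1 matches the
  probability interpretation). At r = 0.7 this leaves the iterate within
  ~4·10⁻⁷ of the fixed point; the acceptance suite measures ≤ 1e-5 in L∞
  against the closed form p* = r·(I − (1−r)W)⁻¹p⁰ on random graphs.
- **Core genes.** k = ⌈0.03 · G⌉ with G the number of *gene* nodes; ties at
  the boundary break lexicographically so runs are deterministic. Non-gene
  nodes participate in the walk (they carry flow) but are never ranked or
  returned.

## Module assembly and sub-modules

The per-miRNA core sets merge into a bipartite module; every edge keeps the
set of pathways that produced it. A gene reached through exactly one
pathway carries that pathway as its class, otherwise "multi" — the same
rule the published module uses for its 13 gene classes.

Sub-modules: genes are clustered on the gene × miRNA incidence matrix with
uncentered-correlation distance, 1 − Σxy/(‖x‖‖y‖) (the Cluster 3.0
definition; all-zero profiles sit at distance 1 from everything), complete
linkage, tree cut into k clusters (k = 4 by default, matching the published
module; how the original analysis fixed exactly four combines clustering
with regulatory structure and is not fully specified, so k is exposed).
Identical incidence profiles merge at height 0, so a degenerate module can
yield fewer than k clusters. Each miRNA joins the cluster holding the
largest share of its neighbor genes; ties go to the first cluster in label
order. miRNA assignment to gene clusters is this package's rule — the
original figure clusters the heat map jointly without stating one.

Printed signature tables use symbol ranges ("FZD1-FZD10"); the parser
expands a token as a range only when both sides share an identical
alphanumeric prefix followed by an integer, which leaves hyphenated miRNA
names ("miR-455-5p", "let-7b") intact and rejects mismatched or backwards
ranges.

## Signature evaluation

The matched miRNA and mRNA matrices are stacked over shared samples and
z-scored by row (feature), then by column (sample) — row first so platform
scale goes away before sample offsets are removed. Normalization runs on
the **full merged profile and the signature is restricted afterwards**.
The order matters: normalizing after restriction would let a small
signature normalize against itself, and the column z-score of a
two-feature signature cancels exactly the common component that carries
the prognostic signal (measured: a planted pair evaluates to p ≈ 0.97
restrict-first vs p ≈ 4·10⁻¹¹ normalize-first).

Risk grouping is K-means with K = 2 on samples (10 restarts, best inertia,
deterministic per seed). The cluster with the higher observed death rate is
"high-risk"; ties fall back to shorter median survival, then to a
lexicographic rule — the labeling must be deterministic and the original
description does not fix it. Nearest-centroid evaluation leaves one sample
out, clusters the rest, risk-labels those clusters by death rate, and
assigns the held-out sample to the nearer centroid (Euclidean; an exact tie
goes to high-risk).

Top-n optimization evaluates the top n screen-ranked genes for each
n ∈ 2..25 and returns the n minimizing the log-rank p (ties → smallest n)
together with the whole p-vs-n curve. The curve, not the argmin, is the
stable object: under resampling the argmin of a stochastic curve is noisy
even when small signatures are systematically better, so downstream use
should inspect the curve.

Partial-sample perturbation swaps n samples between a fixed training and
testing partition before a full rerun; shuffle-and-split redraws the whole
partition (500 repeats by default). Both report stability as the
recurrence ratio |original ∩ rerun| / |original|.

## Synthetic benchmark

`generate_cohort` emulates a mixed-grade glioma cohort: 160 samples,
log-scale expression with N(0, 1) marginals, exponential survival with
hazard h₀·exp(β·risk), h₀ = ln 2 / 680 days (risk-0 median ≈ 680 days, the
cohort scale), β = 1.5, risk = mean(planted driver genes) − mean(planted
miRNAs). Censoring is administrative: C ~ U(0, c_max) independent of death
time, with c_max calibrated by bisection so the expected censored fraction
is 0.45 (≈ the 57.5%-alive cohort composition after the 30-day filter).
Grades are risk tertiles; age and gender are decorative.

Planted features share a latent factor (co-expression 0.9, N(0, 1)
marginals preserved). This is both biologically motivated — module genes
in tumors are co-expressed; that is the premise of module signatures — and
statistically necessary: with independent drivers the mean-risk construction
divides the per-feature hazard coefficient by the number of drivers, and no
single feature survives a P < 0.001 screen at effect 1.5. With the shared
factor, each driver carries nearly the factor's full signal (measured
per-driver screen power 0.94–0.98 at n = 160).

Default geometry: 2000 genes, 100 miRNAs, 8 planted genes of which 2 are
hazard drivers, 2 planted miRNAs; 20 pathways of 140 gene nodes (+5
non-gene nodes), the first 6 planted. Each planted pathway contains the 2
drivers plus 3 of the 6 remaining planted genes (round-robin, so each is
covered by 3 pathways), all wired at distance 1 from the drivers; decoy
pathways contain no planted genes. 140 gene nodes puts the top-3% cutoff at
⌈4.2⌉ = 5 — exactly the planted genes per pathway. The target map gives
every planted pair support 6–11 and decoy pairs 1–5, so the ≥ 6 filter
recovers exactly the planted regulations.

Measured end-to-end behavior (20 replicates, also recomputed by
`scripts/acceptance.py`): mean planted-gene recovery ≈ 0.85–0.96, decoy
recovery 0. Failures are all-or-nothing: in a small fraction of replicates
the latent factor realization is too weakly aligned with the realized
survival times and the whole block misses the screen — the honest behavior
of a P < 0.001 screen at this effect size and cohort size.

What the benchmark does **not** show: real cohorts have correlated
backgrounds, batch structure, non-exponential hazards, grade-dependent
censoring and pathway graphs with hubs and modules; the generator has none
of these. Passing tests demonstrate that the machinery is correct and that
the pipeline recovers a planted signal under its stated assumptions, not
that the biological module would be recovered from any particular real
dataset.

## Problem sizes and determinism

Simulation-based tests use 10–50 replicates at the default cohort geometry
(seconds per batch with the vectorized screen); the acceptance script uses
20 replicates per stochastic quantity. All randomized stages consume seeds
derived deterministically from one master seed (`RunConfig.rng_seed` /
`--seed`), so every pipeline rerun with the same inputs and seed is
byte-identical, including CLI outputs.
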