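# Methods

## Scope and data model

`fosnet` analyses group-wise regional activity tables: one
animals × regions matrix of Fos-positive cell densities (cells/mm²) per
factorial cell of a genotype × treatment × stress design. All inference is
within-group; groups are compared through their derived network summaries
(edge counts, hubs, module counts, Q), as is standard for c-Fos functional
connectomics, not through a joint model.

## Correlation networks

Per group, the inter-regional Pearson matrix is computed pairwise-complete
(each pair uses the animals with both regions quantified), because single
regions are occasionally unquantifiable in individual animals. A region
that is constant across animals has no defined correlation: its row/column
is stored as missing (never as 0) and the region is excluded, with a log
record, before any distance computation. Pairs supported by fewer than
three complete animals are flagged as low-support.

Thresholding uses fixed Pearson cutoffs, not per-n critical values:
low 0.79, primary 0.83, high 0.87 for positive edges, and a single negative
cutoff −0.83. All four live in the run configuration, never in stage logic.
Alternative published conventions (low 0.78; negative −0.87) ship as the
constants `ALT_LOW_THRESHOLD` / `ALT_NEGATIVE_THRESHOLD`. For a fixed sign
the three edge sets are nested by construction; this is asserted on random
inputs rather than assumed. Thresholded networks are binary for metric
computation; the full weighted matrix is kept separately for community
detection.

## Centralities and the composite hub rule

Degree counts supra-threshold edges per level. Betweenness centrality is
computed with Brandes' accumulation on the binarised primary network,
normalised by (R−1)(R−2) over ordered source–target pairs, so a node on the
only geodesic of a 3-node path scores exactly 1. Weighted betweenness is
available behind a flag but off by default: degree is defined on
"significant" (thresholded) edges, and a single betweenness column per
region is the convention this rule reproduces.

A region is a hub when its degree reaches the 80th percentile in *all
three* positive confidence networks and its betweenness reaches the 80th
percentile (primary network). Percentiles use the nearest-rank method over
the full region panel — the cutoff is the value at rank ⌈0.8·R⌉ — with ties
kept, so the rule is reproducible without interpolation ambiguity; in a
vertex-transitive graph (e.g. a cycle) all regions tie and all qualify,
which is documented deterministic behaviour. A flag relaxes the degree
requirement to the primary level only, since published phrasings of the
rule differ on whether the percentile applies per level. A completely
disconnected network yields no hubs, with a warning.

## Spectral community detection

Communities maximise Newman modularity on the weighted correlation network.
Under the default `positive_only` policy negative weights are dropped
(Wᵢⱼ = max(rᵢⱼ, 0)); under `signed`, the asymmetric signed modularity
Q\* = Q⁺ − (m⁻/(m⁺+m⁻)) Q⁻ is used, which penalises negative weight inside
modules at a reduced rate. Positive-only is the default because the
positive and negative networks are conventionally analysed separately and
no signed convention is canonical for this analysis; both policies are
first-class.

The optimiser is recursive bisection by the leading eigenvector of the
(generalised) modularity matrix, with two refinement stages:

1. per-split Kernighan–Lin node-swap fine-tuning (flip each node at most
   once per pass, keep the best prefix);
2. after the recursion, a global KL chain over modules — tentative
   single-node moves to any module (or a fresh singleton), accepting the
   best prefix of each pass — iterated to a fixed point.

Stage 2 matters: greedy bisection alone can lock a small graph into a
two-way cut whose Q is ~12% below the optimum; with it, the partition
matches the exhaustively enumerated optimum (every set partition, ≤ 8
nodes) to within a 0.95 Q-ratio on all validation fixtures, and in practice
to ratio ≈ 1.0. Determinism: dense symmetric eigensolver, eigenvector
oriented so its first non-negligible entry is positive, zero entries
assigned to the positive side, lexicographic tie-breaks in the greedy
passes. Connected components are processed independently; zero-weight and
singleton components become singleton modules; Q of the returned partition
is never below the all-in-one partition's 0.

## Hierarchical modularity

Each region's profile is its row of the correlation matrix, self-correlation
included (a flag excludes the two self entries per pair; the choice is not
material on realistic inputs). Pairwise Euclidean distances feed a
complete-linkage agglomeration — inter-cluster distance is the maximum
pairwise distance, which makes merge heights monotone — with ties broken on
the lexicographically smallest cluster-index pair. The tree is cut at
`fraction × maximum merge height`; merges at exactly the cut height are
kept (≤ convention), so fraction 1.0 always yields one module. Module
counts are profiled over fractions 0.50–0.95 in steps of 0.05, including
the primary 0.70 cut; each group's dendrogram is normalised by its own
maximum height so counts are comparable across groups.

## Factorial ANOVA stage

Per region, a between-subjects factorial ANOVA with Type-III sums of
squares under sum-to-zero coding (cell sizes n = 5–9 are unbalanced;
Type III is the reporting convention in this literature, and on balanced
data it coincides with sequential SS — asserted in tests). Pairwise group
contrasts use t statistics on the pooled residual variance with Bonferroni
adjustment p_adj = min(1, m·p), α = 0.05. Per-region analyses are *not*
corrected across regions — the correction family is the within-region
post-hoc set — and the report says so, so users can layer an FDR step.
A fully constant response is reported as F = 0, p = 1 rather than 0/0.

## Synthetic cohort generator

The generator draws each group from a correlated log-normal model: a latent
Gaussian vector with the planted target correlation, exponentiated so each
region has the requested mean and coefficient of variation. Log-normal
marginals are positive and right-skewed like count densities; the
literature-scale defaults are per-region means drawn once log-uniformly over 30–900 cells/mm²
and cv = 0.5, giving SEM/mean ≈ 19% at n = 7 (published tables show 10–30%).
The Pearson correlation realised on the density scale is attenuated relative
to the latent target by (e^{rσ²}−1)/(e^{σ²}−1), σ² = ln(1+cv²) — under 3% at
cv 0.5 — which recovery tolerances absorb.

Target matrices are exchangeable within/between blocks plus hub boosts
(hub rows raised by `hub_extra_r`, capped at 0.99), repaired to positive
semidefiniteness by alternating projection (eigenvalue clipping ↔ unit
diagonal and cap restoration). Seeding: one master seed; per-group child
seeds by CRC-32 of `seed:group`, so adding a group never changes another
group's draws.

Two canonical scenarios are provided:

* **Module recovery** — 60 regions, 3 equal modules, within-r 0.8,
  between-r 0.1, n = 40 per cohort.
* **Hub recovery** — 60 regions, uniform background r 0.72, 12 hub regions
  boosted by 0.15 (hub pairs ≈ 0.87), n = 40. The background sits about one
  correlation-sampling SD below the low threshold and the hub pairs at the
  high threshold, so "hub" is well-defined ground truth; 12 hubs is the
  nominal top-20% fraction an 80th-percentile rule selects from 60 regions.
  A modular base is deliberately *not* used here: interchangeable
  within-module hubs split shortest-path mass, and whole-module sampling
  fluctuations at n = 40 push a module's hubs across the global percentile
  cutoffs — that design measures module sampling noise, not hub
  detectability (mean Jaccard ≈ 0.7 versus ≈ 0.95 for the uniform design).

What the generator does **not** emulate: spatial structure within regions,
count discreteness at low densities, sex effects (sexes pooled), litter or
batch structure, and measurement error correlated across regions within an
animal. Passing recovery tests therefore show the chain is correct and
well-calibrated under the stated covariance model, not that real cohorts of
n = 5–9 animals identify hubs or modules reliably — at those sizes
correlation sampling noise is large, which is precisely why the synthetic
validation runs at n = 40.

## A known sampling limit of the 0.70 tree cut

With the exchangeable 0.8/0.1 block target, each module is dominated by one
latent factor, so realized between-module block correlations at n = 40
fluctuate with SE ≈ 0.157. When one block drifts high, the corresponding
3→2 complete-linkage merge drops below 0.70 of the maximum height and the
cut returns two modules. Measured consequence (and fully determined by the
target correlation and n — no generator choice affects it): the 0.70 cut
returns exactly 3 modules in ≈ 76–92% of cohorts depending on the seed
stream, and the mean ARI against the planted labels is ≈ 0.92 pooled across
streams but fluctuates by ± 0.03 for a single 50-cohort estimate. Spectral
detection, which uses all pairwise weights rather than a single linkage
height, recovers the planted modules with ARI 1.0 throughout. This is why
the module-count profile (counts across many cut fractions) rather than any
single cut is the recommended summary.

## Numerical and engineering choices

* Percentile cutoffs: nearest-rank, no interpolation; ties qualify.
* Eigen-solvers: dense symmetric (`eigh`) throughout; no iterative solvers,
  so results are platform-stable; refinement tie-breaks lexicographic.
* Correlations clipped to [−1, 1]; diagonals set exactly to 1.
* Complete linkage is implemented directly (the deterministic tie-break is
  part of the contract); scipy's implementation serves as an independent
  height oracle in the tests, as do explicit path enumeration for
  betweenness, exhaustive partition enumeration for Q, literal double sums
  for the Q formula, and hand-built sum-coded design matrices for Type-III
  F statistics.
* Pipeline outputs use fixed float formatting and sorted manifests; the
  manifest records config, config hash, seed and version but no wall-clock
  time, so identical runs are byte-identical.
* Validation problem sizes: oracle sweeps use all connected graphs on ≤ 6
  nodes plus 200 random graphs (≤ 12 nodes) for betweenness and ~67 fixture
  graphs (≤ 8 nodes) for modularity; recovery simulations use 50 cohorts of
  n = 40; invariant sweeps 500 random inputs; the ANOVA null calibration
  200 replicates at n = 8 per cell, judged against the exact binomial 95%
  interval — an acceptance band that by construction has a ~5% false-alarm
  rate for any single seeded run.

## Limitations

Fixed correlation thresholds ignore the strong dependence of the Pearson
null distribution on n; with n = 5–9 animals an r of 0.83 is not a
constant-α criterion across groups of different sizes (the package
deliberately reproduces the fixed-cutoff convention; per-n critical values
are out of scope). Partial correlations, shrinkage estimation, edge-level
permutation tests, consensus clustering and resolution sweeps are likewise
out of scope. The ANOVA stage assumes independent animals and homoscedastic
cells; repeated-measures and survival-type endpoints are not covered.
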