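# Methods notes

## Data model

An EMA panel is long-format: one row per *completed* prompt, keyed by
(subject, day 1–6, prompt slot 1–8), with 19 Likert items on a 1–7 scale and
the binary context item `Being-Alone`. Wellbeing items arrive positively
coded in raw exports and are stored reverse-coded (`Lacking-…`, r′ = 8 − r)
so that larger always means worse; ingesting an already reverse-coded file
is a no-op, making the coding step an involution. An item skipped inside an
otherwise completed prompt is kept as missing and handled by pairwise
deletion downstream — we found no defensible rule for discarding a whole
prompt over one skipped item. All matrices index items in one canonical
reporting order, so matrix layouts are reproducible across runs.

The clinical (SIPS) table has one row per subject with 0–6 integer scores.
Items endorsed (non-zero) by ≤ 10% of subjects are dropped before PCA
(strictly-greater retention): in 22q11DS samples this removes
grandiosity-type items, which are rarely reported in this population.

## Mixed-model edge estimation

Every edge is the fixed slope of a random-intercept model
`Y_ij = β0 + β1 X_ij + u_j + ε_ij`, fit by REML. Because the pipeline fits
hundreds of such models per network (and tens of thousands inside the
permutation null), the solver is a dedicated profiled-REML routine: with
θ = τ²/σ², the marginal covariance is σ²(I + θZZ′); β and σ² have closed
forms given θ (Sherman–Morrison per group), so the fit is a bounded 1-D
optimization over log θ with O(G·p²) cost per objective evaluation. The
test suite cross-checks coefficients, standard errors and variance
components against statsmodels' `MixedLM` to ~4 significant digits.
Inference on β is the Wald z test (statsmodels' convention). A fit whose
optimal intercept variance is zero — including the single-subject case —
degenerates smoothly to ordinary least squares and is flagged.

Design choices:

- **Scaling.** Items are z-scored over pooled observations before every
  network regression so slopes are comparable across pairs and usable as
  common-scale edge weights. `fit_edge` itself fits the data it is given
  (`standardize=False` default) so generative-truth recovery can be checked
  on the raw scale.
- **Lag pairing.** Lag-1 pairs are adjacent *scheduled* slots on the same
  day with both prompts completed; a missed intermediate prompt breaks the
  pair, and overnight pairs are excluded by default (`any_consecutive`
  additionally pairs slot 8 with slot 1 of the next day). Pairing uses the
  (day, slot) grid, not wall-clock timestamps.
- **FDR families.** BH step-up at q = 0.05, one family per matrix kind: all
  ordered cross-sectional pairs (k·(k−1)) and all ordered lagged pairs
  including self-loops (k²).
- **Symmetrization.** The undirected cross-sectional network averages the
  two directional retained slopes, a pruned direction counting as 0.
  Moderation (β₃) matrices stay directional.
- Items with fewer than 3 distinct observed values (e.g. the binary context
  flag) are dropped from network estimation with a warning.

The moderated model `Y = β0 + β1X + β2S + β3(X·S) + u_j + ε` takes a
subject-constant dimension score S, z-scored across subjects (not
observations, so unequal prompt counts do not reweight the scale), and
reports the interaction slope β₃.

## Clinical dimensions

PCA of the filtered SIPS matrix is mean-centered and unscaled by default
(covariance PCA, the default of the common numerical environments);
a `standardize` switch enables correlation-matrix PCA since the original
analyses do not state which was used. Components whose variance fraction
strictly exceeds 0.10 are retained; component 1 is oriented so its mean
loading is positive (it reads as overall severity). Subgroups come from 1-D
k-means (k = 2, 50 restarts, seeded); the higher-centroid group is labeled
"high" (severity) or "pos" (valence contrast).

Group comparisons use the Pearson chi-square **without** Yates continuity
correction — recomputing the published demographic tables (e.g. psychotic
disorders 13.81, sex splits 0.55/2.20, anxiety 2.41) matches the
uncorrected statistic exactly and the corrected one does not — and the
pooled-variance two-sample t (age 0.40/p 0.69 reproduces likewise). The
per-item intensity report correlates per-subject mean intensity with a
dimension score (subject-level n), but the accompanying subgroup t tests
are observation-level: prompts are pooled within groups, which
pseudo-replicates (observations within a subject are not independent) but
matches how such tables are conventionally printed; interpret those p-values
accordingly.

## Network embedding

The embedding is PCA of the symmetrized weighted adjacency, nodes as
observations. The diagonal is unspecified in the source analyses; the
default sets it to each node's mean off-diagonal weight, which keeps the
diagonal from dominating component 1 (a `zero` switch exists). Coordinates
are projections on the first two components, each axis rescaled to
max |value| = 1 so in-layer distances are commensurate with the unit
inter-layer gap of the 3D assembly. PCA signs are arbitrary, so axes are
anchored for reproducibility: the designated cognitive anchor item
(`Hallucinations`) gets negative x and the affective-distress items a
positive mean y, reproducing the conventional left-cognitive /
upper-distress quadrant layout. Fidelity is the Pearson correlation between
pairwise 2D distance and edge weight over unordered pairs; on networks with
community structure it is reliably negative.

## Tractography

Edge length is 1/|slope| — the absolute value so that strong *negative*
couplings also conduct paths (sign is kept as edge metadata); pruned pairs
have no edge. Because lagged edges are the only TL1→TL2 connections and
nothing returns, every interlayer path contains exactly one transition.
Shortest paths use a Dijkstra with total order (length, hops, lexicographic
node-name sequence), making results platform-independent under exact ties;
an exhaustive simple-path enumeration serves as the oracle in tests. Bundles
are k-means on the 12-dimensional anchor vectors (50 restarts, seeded);
`k="auto"` maximizes mean silhouette over k ∈ [4, 12], while fixed k = 9
mirrors the granularity reported for real cohorts of this design.

Per-node diffusion is the mean successor-minus-node displacement over
traversing paths (terminal TL2 nodes contribute their incoming
displacement), so the z-component is never negative; alternatives such as
whole-path direction or bundle-weighted means were considered and rejected
as less local. Longitudinal betweenness counts traversing shortest paths
per node (endpoints included) and per edge.

## Two-population comparison

Both subgroups' networks and paths are computed on the **pooled-sample
embedding**, held fixed, so anchor coordinates are comparable and the
shared start/end coordinates of a matched pair are well defined. Matched
(start, end) pairs reachable in both populations are clustered on
18-dimensional vectors (start, exit-A, exit-B, entry-A, entry-B, end). A
bundle's divergence statistic is the mean between-population distance of
its matched 12-d anchor vectors divided by the mean within-population
pairwise distance. The null permutes subjects across populations
(preserving sizes), rebuilds both networks and paths, and re-evaluates the
statistic on the bundle's *fixed* pair set — the hypothesis is about
trajectory differences, not bundle membership — with the embedding also
held fixed. p is the proportion of permuted ratios ≥ the observed one; a
permutation in which fewer than 2 of the bundle's pairs are reachable in
both permuted groups counts as not exceeding (it carries no evidence of
divergence), and a zero within-spread with positive between-distance counts
as +inf. With n permutations, p has granularity 1/n (0.002 at the full
n = 500).

Because shortest paths are discrete objects, the statistic has atoms (two
stable populations can pick identical paths, giving ratio 0); the
calibration study below therefore uses a generative design with a rich
enough path space that ties are rare.

## Synthetic cohorts

Latent item states follow a first-order VAR with per-subject random
intercepts: within a day,
`z_t = a_j + Bᵀ(z_{t−1} − a_j) + (I + C)ε_t`, with lag coupling B
(spectral radius < 1 enforced), contemporaneous mixing C, innovation scale
`noise_sd` = 1 and intercept scale `intercept_sd` = 0.8. The state
re-initializes toward the subject mean each morning, matching the same-day
lag pairing downstream. Scores are the latent values discretized by six
unit-spaced thresholds (1 + number of thresholds strictly below); the
context flag is i.i.d. Bernoulli(0.35); each scheduled prompt is completed
independently with probability `compliance` = 0.52, emulating ~25 of 48
prompts, and cohorts default to 68 subjects. Group B subjects may get a lag
coupling offset (`group_coupling_delta`) for two-population contrasts. The
clinical table derives a severity trait from each subject's standardized
mean intercept (so severity tracks momentary intensity) plus an independent
valence contrast, mapped through an 18×2 loading matrix
(all-positive severity column; positive symptoms −0.5 / negative +0.5 on
the contrast) with round-and-clip to 0–6.

What the generator does **not** emulate: skewed/zero-inflated item
distributions, time-of-day and weekday effects, autocorrelated missingness
(missingness here is completely at random), measurement reactivity, and
floor effects of rarely endorsed items. Passing recovery tests therefore
show the estimator chain is correct for its assumed model class, not that
real EMA data satisfy those assumptions. Likert discretization plus
z-scoring attenuates slopes by roughly 5–10% at the default thresholds,
which the recovery tolerances accommodate.

## Calibration study sizes

Chosen once, as the package's own desk-scale study conditions:

- Slope recovery: 60 subjects × 20 observations, true slope 0.5, 50 seeds
  (mean error observed ≈ 0.001); moderation β₃ = 0.3, 10 seeds.
- FDR null: 20 cohorts of 60 subjects, 19 items, compliance 0.52; retained
  edge fraction ≈ 0.1% (bound 8%).
- Shortest-path oracle: 200 random two-layer graphs of 3–8 items vs
  exhaustive DFS enumeration.
- Permutation-test calibration: 100 null cohorts (20 subjects, 6 items
  chained cross couplings 0.3, four lag couplings 0.35, compliance 0.8),
  19 permutations each — a scaled-down null with the same exchangeability
  structure as the full 500-permutation test. First-bundle p-values:
  rejection rate 0.05–0.08 at α = 0.05, Kolmogorov–Smirnov uniformity
  p ≈ 0.2–0.7 across runs.
- Embedding fidelity: 20 two-community cohorts (8 items, two blocks,
  within-block coupling 0.35, 40 subjects); distance–weight correlation
  negative with p < 0.01 in 20/20.

## Known limitations

- Massed pairwise mixed models ignore conditioning on other items (this is
  not a partial-correlation / graphical-VAR network) — by design.
- Observation-level t tests in the intensity report pseudo-replicate (see
  above).
- The divergence test conditions on bundles derived from the observed
  grouping; under the null this is close to exchangeable (calibration
  confirms) but it is not an exact permutation test of bundle membership.
- Wald z inference on mixed-model slopes is asymptotic; with very few
  subjects, p-values near the FDR boundary should be treated with care.
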