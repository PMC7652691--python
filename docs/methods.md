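# Methods

This note records the statistical model, the parameter conventions, the
scope of the synthetic-cohort generator, the numerical choices, and the
known limitations of the `corisk` package.

## Cohort model

The unit of analysis is a 1:1 matched case-control cohort: `n` cases
(patients readmitted within 30 days of discharge) and `n` controls (not
readmitted), each described by `K` binary comorbidity indicators. The
container (`CohortMatrix`) stores patient ids, a 0/1 outcome vector and the
`n_patients x K` indicator matrix; CSV IO validates binary entries, header
shape and id uniqueness and names the offending row/column on failure.

Two pre-analysis filters mirror common claims-data practice and are applied
per cohort, in order:

1. drop patients with zero comorbidities (they carry no pairwise
   information and would only dilute the "rest" stratum);
2. drop comorbidities below a prevalence threshold (default 1%), then drop
   any patients left with zero comorbidities. `mode="individual"` applies
   the threshold per column; `mode="combined"` removes the rarest columns
   greedily only while their *combined* prevalence stays below the
   threshold. Every removal is reported in the pipeline's accounting.

## Pairwise combinatorial risk (supervised)

For each unordered comorbidity pair (A, B) the **overall test** forms the
2x2 table of exposure *E = A and B both present* against readmission and
computes:

- the cross-product odds ratio, with the Haldane–Anscombe correction
  (+0.5 to all four cells) whenever any cell is zero;
- the Woolf (logit) 95% CI, `exp(log OR ± z * sqrt(1/a + 1/b + 1/c + 1/d))`
  with `z = Phi^-1(0.975)` (the exact quantile, not 1.96), computed on the
  corrected cells when the correction applies;
- a two-sided Fisher exact p-value on the *uncorrected* counts (a Pearson
  chi-square alternative is switchable via `p_method="chi2"`).

Tables with a degenerate margin (no exposed patients, no cases, etc.) are
untestable; such pairs are retained in the output with a null result and
excluded from the multiplicity family. All testable overall p-values in a
cohort form one Benjamini–Hochberg family; a pair is significant when its
BH-adjusted p falls below `alpha` (default 0.05).

For each significant pair two **directionality tests** restrict the sample
to patients carrying A or B (or both) and contrast the doubly-exposed
group against each singly-exposed group ("A&B vs A alone", "A&B vs B
alone"), using the same OR/CI/p machinery. The two directional test
families are BH-adjusted separately. The oriented outcome is summarized as
a pattern: `both`, `a_only`, `b_only` (naming which single-comorbidity
reference the pair significantly out-risks) or `neither`.

**Replication rule.** A pair replicates iff it is significant overall in
both cohorts *and* shows the identical oriented directional pattern
(orientation is aligned before comparison, so (A,B)/`a_only` in one cohort
matches (B,A)/`b_only` in the other). Pairs with pattern `neither` never
replicate: an overall signal with no attributable direction is not a
directional finding.

## Bipartite biclustering (unsupervised)

Readmitted patients carrying at least one replicated comorbidity, the
replicated comorbidities, and the presence indicators form an undirected
bipartite graph. Its partition quality is Barber's bipartite modularity

    Q_B = (1/m) * sum_ij (A_ij - k_i d_j / m) * [g_i == g_j]

with `m` edges and one-mode degrees `k`, `d`. `Q_B = 0` for the
all-in-one-community partition on any graph, and `(c-1)/c` for `c` equal
disjoint bicliques — both used as test oracles.

**Optimizer.** BRIM-style alternating exact half-steps: given comorbidity
labels, every patient's optimal label is the argmax of its modularity-row
sums (nodes whose best contribution is negative become detached
singletons); then the roles swap; iterate to a fixed point. Because the
half-steps alone are prone to fragmenting local optima, each descent is
followed by a greedy refinement that repeatedly merges the community pair
with the largest positive cross-modularity term and re-descends, keeping
the merge only if Q does not drop. The search runs from deterministic
inits (all-one-community, all-singletons) plus `restarts` random inits for
every community count 1..`max_communities`, all driven by one seeded
generator. Ties between equal-Q optima break toward fewer communities,
then the lexicographically smallest canonical label vector, making the
result reproducible bit-for-bit. On random graphs of ≤ 10 nodes the
optimizer provably attains the global optimum (checked against exhaustive
enumeration of comorbidity set partitions; given comorbidity communities
each patient's optimal contribution is `max(0, max_c S_ic)`, so only
comorbidity partitions need enumerating).

**Significance.** The permutation null re-draws a uniform random bipartite
graph with the same node sets and edge count (degree sequences *not*
preserved — the question is whether structure exceeds what size and
density alone produce; a degree-preserving double-edge-swap null is
available as `null="degree"` for sensitivity). Each null graph is
re-optimized with the same settings and `p = (1 + #{Q_rand >= Q_obs}) /
(R + 1)`, so the smallest attainable p with R permutations is `1/(R+1)`.

**Cross-cohort stability.** The comorbidity-node partitions of the two
cohorts are compared by the Rand index (fraction of pairs co-clustered in
both or separated in both, computed via the pair-count contingency
formula); the permutation null shuffles which element carries which label
in the second partition (cluster sizes preserved), same p convention. The
adjusted Rand index is reported alongside.

## CoRisk integration

Each replicated pair contributes directed **risk arrows** from its
training-cohort pattern: `a_only` gives the single arrow B → A (the pair
out-risks A alone, so the arrow points at A), `b_only` gives A → B, and
`both` gives two opposing arrows. Arrows are annotated with the pair's
overall OR; nodes carry their single-comorbidity OR.

Patients are classified **inner** (more than one replicated comorbidity)
or **outer** (exactly one); the 2 x C tally of that split across
biclusters is tested for heterogeneity with a Pearson chi-square without
continuity correction. **Asymmetrical hubs** are comorbidities whose risk
in-degree exceeds their out-degree.

**Exploded layout.** A seeded Fruchterman–Reingold layout of the bipartite
graph is computed, then each community is rigidly translated along the
unit vector from the global centroid to the community centroid by
`explode_factor` times the layout radius, preserving within-community
distances exactly. Above 3,000 nodes the quadratic full-graph layout is
replaced by a hybrid at linear cost: comorbidities are laid out by force
direction on their patient-overlap projection and each patient sits at the
mean of its comorbidities' positions plus seeded Gaussian jitter
(sd 0.08 in layout units). The network exports to GraphML and JSON (one
schema: node type/community/class/OR/coordinates, edge kind bipartite vs
risk) and round-trips through `read_network`; `plot_network` renders an
SVG.

## Synthetic cohort generator

The generator must satisfy two requirements at once: cases carry planted
block structure (for biclustering recovery) and outcomes follow a logistic
model on the indicators (for planted odds ratios). It resolves this with
two rejection-sampled candidate streams sharing one seeded PCG64
generator:

- **case candidates**: a block is assigned by cumulative patient-fraction
  lookup (or none), indicators drawn Bernoulli(`p_in`) inside the block
  and Bernoulli(`p_out`) outside; the candidate is *accepted as a case*
  when a Bernoulli(sigmoid(eta)) draw is 1, with
  `eta = intercept + mains . x + 0.5 x' L x` (L the symmetric planted
  log-OR matrix, zero diagonal);
- **control candidates**: background presence only, accepted when the
  outcome draw is 0.

Under this design the empirical pair log-OR equals the planted coefficient
in expectation: when the pair exposure determines eta,
`OR = [s_E/(1-s_E)] / [s_0/(1-s_0)] = exp(beta)` with `s = sigmoid`.
With `L = 0` and no blocks, all pair ORs are exactly 1 (verified by
Monte-Carlo in the tests). Drawing stops, with a `ComputationError`
naming the shortfall, if acceptance would need more than
`max_draw_factor` (default 100) times the requested count.

Presets (package choices, stated as such):

- `medicare_like(n_cases, seed)`: K = 37 comorbidities, background
  prevalence `p_out = 0.0436` — the single value that simultaneously gives
  ~19% of patients with zero comorbidities (removed by the first filter)
  and a median of 2 comorbidities among the retained, matching the shape
  of an elderly claims cohort; 7 two-comorbidity blocks (5% of cases
  each, `p_in = 0.3`) with their pairs planted at log 2.
- `planted_blocks(n_cases, seed)`: the *recovery* conditions — 7 blocks of
  4 comorbidities (K = 28), one-eighth of cases each, `p_in = 0.3`,
  `p_out = 0.02`, all 42 within-block pairs planted at log 2. Block size
  4 matters: for blocks of 2 comorbidities the maximum-modularity
  partition genuinely splits the blocks (confirmed against the exhaustive
  oracle), so a size-2 design cannot be recovered by *any* correct
  modularity maximizer; from size 3 up the planted partition is the
  optimum.

Every synthetic cohort writes a ground-truth JSON sidecar (block
memberships, planted matrix, full config) used by the recovery tests.

**Generator scope.** The generator does not model the matching covariates
(age, sex, race) — matching is assumed already done; comorbidity
correlations beyond the planted blocks; time-to-readmission; or
measurement error in the indicators. Consequently the tests demonstrate
statistical correctness (null calibration, type-I control, effect and
structure recovery) of the pipeline, not robustness to confounding or
model misspecification in real claims data.

## Numerical and reproducibility choices

- All normal quantiles are exact (`scipy.stats.norm.ppf`), not 1.96.
- Fisher exact p-values always use the uncorrected counts even when the
  OR/CI use Haldane-corrected cells.
- BH adjustment delegates to `statsmodels` and is tested against a
  brute-force step-up oracle for every family size ≤ 12.
- All permutation p-values use the `(r + 1)/(R + 1)` convention; the RI
  comparison uses a 1e-12 tolerance on the ≥ so ties at the observed value
  count as extreme.
- Every stochastic component takes an explicit integer seed (< 2^31) and
  is driven by `numpy.random.default_rng`; the CLI maps one user seed to
  per-stage seeds by fixed offsets. Pipeline reports are deterministic for
  a fixed config — wall-clock timings go to the log only.
- Problem sizes in the test suite (e.g. 200 runs x R = 99 for calibration,
  50 seeds x n = 5,000 x K = 10 for type-I, n = 50,000 with 7 blocks of 4
  for end-to-end recovery) are package choices sized to run in a few
  minutes on one CPU while keeping Monte-Carlo error well below the
  asserted margins.

## Limitations

- The directionality patterns are descriptive contrasts, not a causal
  ordering; an arrow A → B says the pair out-risks B alone, nothing about
  mechanism or temporal precedence.
- FDR is controlled per family within each cohort; the replication rule is
  a conjunction filter, not a formal combined-cohort error rate.
- The density-preserving modularity null answers "more structure than a
  random graph of this size and density"; degree-driven structure is only
  addressed by the optional degree-preserving null.
- Barber modularity has intrinsic resolution limits: very small planted
  communities (2 comorbidities) are split at the true optimum, so absence
  of a planted bicluster at small scale is not an optimizer failure.
- The BRIM-with-merges optimizer is exact only on small graphs (verified
  ≤ 10 nodes); at scale it is a well-seeded heuristic with restarts, like
  all modularity maximizers.
- The generator's exact-OR property holds for the planted interaction
  given the design above; with many overlapping planted pairs the
  marginal pair ORs can drift from the planted values (interactions
  combine additively in eta).
- Published reference tallies in `corisk.reference` are recomputation
  inputs (a 2 x 7 patient table from a 2010 Medicare hip-fracture
  cohort); the underlying patient-level claims are restricted and not
  reproducible here.
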