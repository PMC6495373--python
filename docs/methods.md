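# Methods

`paleoferm` implements the computational chain used to argue that yeasts
isolated from ancient beverage vessels descend from the fermentation
cultures once kept in them.  Each stage is a self-contained model or test;
this note records the underlying assumptions, the parameters that matter,
and the choices made where the methodology was genuinely open.

## Species delimitation on a barcode tree

The unit of analysis is a phylogenetic tree of barcode sequences (e.g. LSU
rRNA) with branch lengths in substitutions per base (SPB).  Reference tips
carry species labels; the set of patristic distances between conspecific
reference pairs defines the empirical scale of within-species divergence.
For a query isolate we take the patristic distance `d_obs` to its closest
relative and ask whether `d_obs` is plausible under the intraspecific
distribution.

Two tests are provided, and every result records which was used:

- **empirical** — the add-one exceedance rule, `p = (#{x >= d_obs} + 1) /
  (n + 1)`.  Simple and assumption-free, but it floors at `1/(n+1)`: a
  query beyond the largest reference value cannot be graded further.
- **parametric** (default) — the right-tail probability of a
  maximum-likelihood lognormal (optionally gamma) fitted to the positive
  intraspecific distances, with `floc = 0`.  This extends the tail beyond
  the observed maximum, which is exactly the regime where novel-species
  candidates live.  With fewer than 5 strictly positive reference values
  the fit is unreliable and the code falls back to empirical with a
  warning.

The verdict is `novel-species-candidate` iff `p < alpha` (default 0.05).
The lognormal was preferred over the gamma as the default because
patristic distances are strictly positive with a multiplicative error
structure; both are exposed.

Patristic distances are computed in one post-order traversal (pairs are
resolved at their lowest common ancestor), so the cost is quadratic in tip
count with no per-pair path searches, and the result is independent of
root placement.

## Intertree distances and conflict assessment

Gene-tree conflict is assessed with Robinson–Foulds distances.
Bipartitions are taken on the unrooted form, trivial single-tip splits are
excluded, and each split is stored canonically as the tip-set not
containing the lexicographically smallest tip; a bifurcating root's two
child edges collapse to one unrooted edge with their summed length.  The
unweighted distance is the symmetric-difference count; the weighted
variant sums `|w1 - w2|` over the union of bipartitions with weight 0 for
an absent split.  Raw weights are the default; a `normalized` flag divides
by the maximum attainable value, since the original analyses do not state
which convention their weighted distances used.

Trees are then grouped with DBSCAN over the precomputed distance matrix
(default radius 0.03, matching the radius at which the original analysis
maximised cluster count).  Rows are processed in sorted-id order so
border-point assignment is reproducible; the clustering itself delegates
to scikit-learn.

## Alignment curation

- **Centroid dereplication** (default identity 0.99): greedy, longest
  sequence first (ties by id); a sequence joins the first centroid it
  matches at or above the threshold, else founds a cluster.  Pairwise
  identity = matches / aligned columns of a global alignment (match +1,
  mismatch 0, linear gap cost −1, end gaps penalized), excluding
  gap–gap columns; sequences are uppercased and U folded to T.  The
  identity denominator and the processing order are conventions — the
  tools that popularised this scheme leave them implicit — so both are
  documented here and fixed.
- **Gap trimming** (default 0.8): a column is removed iff its gap
  proportion strictly exceeds the threshold ("over 0.8"), so a column at
  exactly 0.8 survives.  Trimming is idempotent.
- **Parsimony-informative columns**: at least two non-gap states, each in
  at least two sequences; gaps are not a state.
- **Ortholog occupancy** (defaults: one representative in ≥ 50% of
  reference genomes, rounded up, and in ≥ 3 isolates): `one_to_one`
  demands exactly one copy; switching it off accepts any nonzero count.

## CNV signature scoring

Given a copy-number table for two closely related isolates and a signature
assigning each ortholog cluster an expected direction (duplication or
deletion, characteristic of beverage-adapted yeasts), only signature
clusters where the pair differs are scored, and each is awarded to exactly
one isolate: the higher-copy isolate for an expected duplication, the
lower for an expected deletion.  Direction is therefore evaluated
*relative to the other isolate of the pair*, not against an absolute
baseline — the pairwise reading matches how isolate pairs are compared
throughout; an absolute-baseline variant would need an external reference
copy number the data do not carry.

The concordance split `(count_a, count_b)` is tested against the equal
(n/2, n/2) expectation with a 1-df chi-square, no continuity correction.
A paired two-sided t test over per-cluster copy-number differences
(Welch two-sample by flag) compares the full profiles.  All-zero
differences report p = 1 exactly; a constant nonzero difference makes the
paired statistic undefined and the error message points at the Welch
variant.

## Growth-curve fingerprinting

OD600 trajectories are fitted replicate-by-replicate to the logistic
model `N(t) = K / (1 + ((K − N0)/N0) e^{−rt})` by nonlinear least squares.
Initialisation: `K` from the maximum reading, `N0` from the first reading
clipped to ≥ 1e-6, `r` from the slope of the linearised form
`log(N/(K−N))` over interior points; convergence at relative RSS change
< 1e-10.  Flat series are flagged degenerate (r unidentifiable) rather
than raising; non-convergent fits return the best point with
`converged=False`.  Replicates are fitted individually — not a fit on the
replicate mean — so the replicate spread of `r` is preserved for the
two-sided Welch t test against the control strain (≥ 3 replicate colonies
per side required).

Mean fitted parameter vectors (K, N0, r) per strain are projected by PCA:
columns standardised to zero mean and unit variance, economy SVD,
components ordered by explained variance, and each component signed so
its largest-magnitude loading is positive.  Zero-variance columns are
dropped with a warning.  PCA on fitted parameters is the default
operationalisation of "distance between growth curves"; the strain's
Euclidean distance to the control in score space is reported alongside
the similarity call, which follows the rate test (`similar` iff
p > 0.01 — a single alpha; the published figure's two thresholds of 0.01
and 0.02 leave the band between them ambiguous, so raw p is always
reported).

The correlation between fingerprint and vessel origin is point-biserial.
How the original r = 0.95 was paired is unstated, so
`origin_correlation` accepts either the continuous distance (negated, so
beverage-like scores high) or the binary similarity call.  On synthetic
data where all strains share identical K and N0, those two standardized
columns are pure fit noise and dilute the distance-based correlation —
a dilution real data, with genuine between-strain K/N0 variation, would
not show in the same way; the call-based pairing is the one under which
perfect fingerprinting yields r = 1.

## Isolation-frequency enrichment

Recovery outcomes over sample groups (putative beverage vessels vs
controls) form a 2×2 table tested with Fisher's exact test, implemented
by complete enumeration of the margin-preserving tables with
log-factorial (lgamma) arithmetic — exact at totals into the thousands.
The two-sided rule sums point probabilities ≤ that of the observed table
(with 1e-7 relative slack against float ties), the convention of
mainstream statistical software; tail-doubling is available by flag.
Lamp, sediment/stone and off-site samples carry distinct categories so
the composition of the "control" group is an explicit, logged choice.

## Beverage analytics

- Relative peak area = compound area / (ethanol area / ethanol percent)
  × 1000; ethanol percent comes from distillation as an external column.
- Percent-of-max scales each compound column to its maximum = 100;
  all-zero columns pass through with a warning.
- Beer colour: SRM = 12.7 × A430, EBC = 25.0 × A430.
- Carbohydrates: OLS standard line of 485-nm absorbance on glucose
  concentration; the unknown is inverted through the line and scaled by
  the dilution factor (1 ml to 1 l = 1000×); readings outside the
  standard range are flagged as extrapolations, not rejected.
- Clustering: Ward variance-minimisation on Euclidean distances (the
  ward.D2 convention — distances squared inside the criterion), via
  scipy's linkage; merge heights are therefore monotone.  Heat-map-style
  analyses cluster the percent-of-max matrix by default (raw by flag),
  on either axis.
- Node support: features of the non-clustered axis are resampled with
  replacement; bp = percentage of bootstrap dendrograms containing the
  identical leaf set.  The approximately-unbiased variant runs the
  multiscale bootstrap at scale factors 0.5–1.4 of the feature count and
  extrapolates: with `z(ρ) = Φ⁻¹(1 − BP(ρ))` and `σ = 1/√ρ`, fit
  `z = vσ + c/σ` by least squares and report `AU = 1 − Φ(v − c)`.
  Degenerate nodes (BP 0 or 1 at every scale) fall back to the mean BP
  clamped away from the boundary by `1/(2B)`.  bp is the default; both
  are reported side by side when AU is requested.

## Synthetic data

The generators emulate the statistical structure of each input with
planted ground truth; one global seed fans out through fixed per-generator
`SeedSequence` spawn keys, so adding a generator never perturbs existing
outputs, and every generator is a pure function of its `SimSpec`.

- **Species tree**: per-species subtrees built by random sequential
  joining with Exp(intra-scale) edges (default 0.005 SPB), hung on a star
  backbone whose edges are `inter/2 + Exp(inter/2)` (default inter 0.2
  SPB) — the floor guarantees the intra/inter separation rather than
  leaving it to exponential tails.  Conspecific queries graft as a
  sibling of a reference tip; novel queries hang off the backbone.
  Exponential lengths were chosen for being memoryless and
  scale-parameterised; nothing deeper is implied.
- **Growth curves**: logistic trajectories, replicate-level `r` jitter
  (sd 0.02/h), additive OD noise (sd 0.02) truncated at 0; beverage
  strains share the control regime (r = 0.5/h), others a shifted one
  (r = 0.25/h), so the regimes sit 12.5 jitter-sd apart.  K = 1.3 and
  N0 = 0.05 are typical wort-culture OD600 values.
- **CNV**: baseline copy number 2; each of the 79 signature clusters is
  perturbed toward isolate A's expected direction with probability
  f = 0.85 (≈ 67/79), else toward B; non-signature clusters get
  direction-free background jitter.
- **Isolation**: 21 beverage vs 110 control samples at rates 6/21 and
  2/110.
- **Compounds**: cluster log-mean profiles with spread `separation ×
  noise_sigma` plus lognormal within-cluster noise.

What the generators deliberately do **not** emulate: sequence-level
evolution (trees are drawn directly, not inferred from simulated
alignments), plate-reader artefacts (drift, lag phases, evaporation),
assembly- or mapping-induced copy-number error, site-level heterogeneity
in isolation success, or compound-compound covariance.  Passing the
recovery suites therefore shows the inference machinery is correct under
its own model assumptions, not that those assumptions hold for any
particular excavation.

## Numerical conventions

Distance-equality tolerance 1e-9 absolute throughout the tree code;
ties in closest-relative and merge-candidate searches break
lexicographically; empirical p-values are clamped into (0, 1];
all matrices are label-addressed across module boundaries so row order
never silently matters.

## Problem sizes

The test suite validates the exact test exhaustively over all 2×2 tables
with grand total ≤ 60 against an independent hypergeometric oracle, the
patristic code on 200 random trees of up to 50 tips, Robinson–Foulds on
all 15 binary 5-tip topologies, delimitation and CNV recovery over 20
seeds each, the logistic grid at r ∈ {0.2, 0.5, 1.0} × noise sd ∈
{0, 0.01, 0.05} × 50 replicates, and Ward clustering on 200 random
6-point sets with B = 1000 bootstrap support on the planted compound
clusters.

## Known limitations

- The parametric membership test conditions on the fitted family; a
  misspecified tail (e.g. heavy-tailed rate variation across the barcode
  tree) shifts p.  The empirical rule is the assumption-free fallback.
- Dereplication is greedy and order-dependent by construction, as in the
  tools that established the scheme; centroid sets are stable under
  duplicate injection but not under arbitrary reordering beyond the
  documented length-descending rule.
- AU support is a desk-scale implementation of the multiscale
  extrapolation; it matches bp closely at strong separation but is not a
  drop-in replacement for mature implementations at marginal support
  levels.
- The chi-square neutral-split test assumes each signature cluster is an
  independent Bernoulli trial; linked clusters (shared segmental events)
  would inflate significance.
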