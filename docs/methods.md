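# Methods

## The analysis chain

`fosnet` implements the correlation-based ("functional connectivity")
analysis commonly applied to regional c-Fos counts. The unit of
observation is one animal's mean c-Fos+ cell count per region (bilateral
counts averaged across sections); counts are therefore stored as reals.
For each (genotype, condition) group with n ≥ 4 animals, the Pearson
correlation of every region pair across the group's animals is computed,
with a two-sided p-value from t = r·√(n−2)/√(1−r²) on n−2 df. Two-sided
is the default because sidedness is a modeling choice with real
consequences at small n: at n = 7, two-sided p < 0.05 requires
|r| > 0.754, so the significance filter dominates an r > 0.60 edge
threshold. A one-sided switch (`sided="one-sided"`) halves the p for
positive r.

**Network density.** Group matrices are compared on the Fisher scale:
Z = arctanh(r), with |r| clamped to 1 − 1e−7 so degenerate r = ±1 stays
finite; the clamp leaves the round-trip tanh(arctanh(r)) exact to well
below 1e−6 over |r| ≤ 0.999. Each off-diagonal upper-triangle Z is
treated as one observation in an ordinary-least-squares genotype ×
condition ANOVA (type-II sums of squares; with 21 regions and 4 exposure
groups this gives 840 observations and residual df 836), followed by all
pairwise group contrasts as pooled-variance t tests with Bonferroni
adjustment. Group means are reported back on the r scale as
tanh(mean Z). This pair-level design mirrors the df structure of the
published form of the analysis, but the observations are **not
independent** — pairs within one matrix share the same animals — so the
F and p values are anti-conservative whenever true correlation structure
is present. The caveat is recorded in every run's provenance file, and
the package's own error-rate study (see below) calibrates the null only
under a structureless generator, where the dependence is negligible
(measured false-positive contrast rate 5% at α = 0.05).

**Graphs.** The graph for a group keeps all regions as nodes and adds an
edge for each pair with r > threshold_r AND p < alpha (defaults 0.60 and
0.05, strict inequalities). With the default threshold every edge is a
positive correlation; the threshold itself is the only positivity
constraint, so diagnostic settings such as threshold_r = −1, alpha = 1
yield the complete graph. Missing entries (zero-variance regions, which
are flagged rather than dropped) never form edges.

**Communities.** Modularity optimization is the classic two-phase greedy
scheme: repeated seeded-random sweeps move each node to the neighboring
community with the largest positive modularity gain (ties and zero gain
keep the current community), then communities are aggregated into
super-nodes and the process repeats until a whole phase makes no move.
Community detection uses the r edge weights by default (`weighted=False`
switches to topology only); degree, z and P are always computed on the
unweighted topology, following the standard node-role definitions. The
resolution parameter defaults to 1 and is exposed. Determinism: a fixed
seed fixes the sweep order and hence the partition; isolates always end
as singletons; a graph with no edges is defined to have Q = 0. Greedy
optimization is a local search: on small fixtures it reaches the
exhaustive-enumeration maximum for cliques, stars, paired triangles and
planted two-block graphs, but on the 6-node path it provably cannot
(the first sweep pairs adjacent nodes and aggregation can only merge,
never split, super-nodes), settling at Q = 0.26 against the global 0.30.
The test suite documents this case explicitly.

**Node roles.** κ_is counts node i's edges into community s;
k_i = Σ_s κ_is. The within-community z standardizes κ_i,s_i over the
node's own community using the population SD (so z has mean 0 and SD 1
within every non-degenerate community); communities of size 1 or zero SD
give z = 0 with a `degenerate_community` flag rather than dropping the
node, keeping scatter-plot node counts constant. P_i = 1 − Σ_s(κ_is/k_i)²
is 0 for provincial nodes and approaches 1 as edges spread over
communities; isolates get P = 0 with an `isolate` flag. Hub ranking is
descriptive (descending P, ties by z then label); numeric hub cutoffs are
user-supplied only, since customary usage identifies hubs from scatter
position rather than fixed thresholds.

**Behavioral indexes.** Chamber preference (Tc−To)/(Tc+To)×100 and
close-proximity preference (Tnc−Tno)/(Tnc+Tno)×100, both in
[−100, 100], antisymmetric under swapping the social and object
quantities and invariant to rescaling both times. A zero denominator
(animal never in the side chambers / never in proximity) yields a
missing value with a reason code — never 0, which would fabricate "no
preference". Group statistics are limited to mean/SD/n.

## The synthetic-data generator

The generator exists to give every pipeline stage a ground truth; it
emulates the design of the motivating experiments (21 named regions, 2
genotypes × 3 exposure conditions, 7 subjects/group) rather than any
particular dataset.

Counts follow a Gaussian latent-factor model. With one global factor g,
one factor f_m per planted community and unit-variance noise,

    x_i = a·g + b·f_c(i) + [hubs: h·Σ_{m≠c(i)} f_m] + s_i·e_i,
    a = √rho_between,  b = √(rho_within − rho_between),
    h = (rho_hub − rho_between)/b,

with s_i chosen to make Var(x_i) = 1. The implied matrix is
LLᵀ + diag(s²), positive semidefinite for every feasible loading choice —
the reason a factor construction was used instead of writing a block
matrix directly, which is easily non-PSD once hubs are added. Counts are
mean_count + dispersion·x truncated at zero; the defaults
(mean_count = 50, dispersion = 10) keep truncation below ~10⁻⁶
probability per cell, so the planted correlations survive essentially
unchanged. Feasibility requires s_i² ≥ 0; for a hub this bounds
rho_hub ≤ rho_between + √((1−rho_within)(rho_within−rho_between)/(M−1)).
Hub defaults sit near this bound (0.4 under the default 0.6/0.1 spec,
0.36 for the 0.8/0.1 recovery study whose bound is 0.3646): planted hubs
exist to be detectable, and the bound is the strongest cross-community
coupling the model admits. Group effects, when wanted, are additive mean
shifts per (region, group) applied before truncation. One RNG is seeded
per call; the seed is recorded in the outputs.

Behavioral trials allocate a fixed fraction (2/3) of the session to the
side chambers, set the conspecific-chamber time so the expected chamber
index equals `preference_strength`, add truncated Gaussian noise
(`noise_sd`, seconds), and derive proximity times as jittered fractions
of chamber times — so all trial invariants (Tnc ≤ Tc, times summing
within the session) hold by construction, and at noise 0 the index hits
its target exactly.

What the generator does **not** emulate: count discreteness and
mean-variance coupling of real cell counts, inter-batch and
inter-section variability, anatomically informed community structure,
negative functional coupling, and any resemblance to the real effect
sizes of a particular experiment. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under a known truth — not
that real c-Fos networks are recovered with these error rates.

## Calibration studies (computed by `scripts/acceptance.py` and the test suite)

- **Planted-structure recovery**: rho_within 0.8 / rho_between 0.1,
  3 communities of 7, hubs MO and Pir at the feasibility bound, n = 30
  subjects, 20 seeds; recovery = adjusted Rand index > 0.9 of the
  detected vs planted partition, hub recovery = both hubs at or above
  the 75th percentile of P with P > 0. n = 30 rather than 7 because at
  n = 7 the edge filter passes only |r| > 0.754 and graphs are too
  sparse for stable partitions; n = 30 is the regime where a planted
  truth is recoverable at all. Hub recovery is the tightest of these
  margins: even at the feasibility bound, cross-community correlations
  (~0.36) rarely clear the 0.60 edge threshold, so each hub materializes
  only a few cross edges.
- **Density error rates**: the null study draws all four exposure groups
  from the structureless generator (rho = 0) and counts any
  Bonferroni-significant contrast as a false positive; the power study
  plants overall connectivity 0.7 vs 0.1 (single community spanning all
  regions) at n = 30 and requires all contrasts significant.
- **Behavioral calibration**: 500 trials at preference 50, noise 30 s;
  the mean computed index must sit within ±3 of the target.

## Numerical choices and degenerate inputs

- Pearson matrices are symmetrized exactly ((R+Rᵀ)/2 after corrcoef) and
  the diagonal forced to 1; zero-variance regions produce NaN rows that
  stay in the matrix and are excluded pairwise downstream.
- p for |r| = 1 is 0 by convention (the t statistic diverges).
- Louvain gain comparisons use a 1e−12 threshold to avoid float cycling;
  community labels are relabeled by first-node order so equal seeds give
  identical, not merely equivalent, assignments.
- TSV outputs use fixed 6-decimal formatting, making repeated seeded
  runs byte-identical; every pipeline output names the configuration
  hash (output location excluded from the hash) in a leading comment.
- Problem sizes in the shipped studies (20 seeds, n ≤ 30, 21 regions)
  are the package's chosen defaults for a desk-scale validation; all are
  parameters, not constants.

## Known limitations

- The pair-level density ANOVA inherits the dependence caveat above;
  a subject-level resampling scheme would be the principled alternative
  but would no longer match the customary df structure.
- Greedy modularity optimization is a local search (path-graph example
  above); no simulated-annealing refinement is provided.
- No multiple-testing correction is applied to the 210 edge tests by
  default, matching the plain p < 0.05 edge criterion; Benjamini–
  Hochberg can be layered on by filtering the correlation tables before
  graph construction.
- Comparisons of node roles across networks built from different region
  sets are not meaningful; the package deliberately offers no such
  comparison.
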