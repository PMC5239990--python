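# Methods

`roughrelief` implements a two-stage hybrid system for tabular clinical
diagnosis: a feature-selection stage that combines ReliefF weighting with
rough-set attribute reduction, and a classification stage that evaluates
each resulting attribute subset (reduct) with boosted decision-tree
ensembles. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## The decision-table model

All stages operate on a *decision table* S = (U, C ∪ {d}, V, F): a finite
universe U of objects, condition attributes C (each tagged `real`,
`nominal`, `ordered`, or `binary`), one fully observed decision attribute
d, and per-attribute value domains. Missing condition values are carried
by a dedicated NA sentinel, never a numeric code, and every stage defines
its behavior on them: discretization passes them through, ReliefF handles
them probabilistically, and indiscernibility treats MISSING as one more
category.

## Discretization

Rough-set reduction needs categorical data, so real attributes are
equal-width binned first. For an attribute with observed range [m, M] and
`n_bins` bins, cuts sit at m + i·(M−m)/n_bins. Assignment is right-closed
(a value equal to a cut falls in the lower bin); values outside the fitted
range — possible when cuts fitted on a training fold are applied to test
data — clip into the boundary bins. A constant attribute yields a single
bin rather than an error.

`n_bins` defaults to 4. With hundreds of objects and 13 attributes this
keeps equivalence classes populated; fewer bins blur real risk gradients,
many more fragment the table into singleton blocks and inflate the
dependency degree artificially. Binning is fitted on the full dataset
before feature selection, matching the pipeline order of the original
two-stage design; a `per_fold_binning` option refits cuts inside each
training fold for strictly leakage-free classification estimates.
The 4-level vessel count is typed ordered-discrete and exempt from
binning: interval-coding a 4-value count is lossy with no benefit.

## ReliefF weighting

ReliefF scores attribute relevance by contrast: for each anchor instance,
it finds the k nearest *hits* (same class) and, per other class c, the k
nearest *misses*, nearest by the Manhattan sum of per-attribute `diff`
values. An attribute's weight decreases by its average diff to hits and
increases by the prior-weighted (P(c)/(1−P(class of anchor))) average diff
to misses, averaged over anchors. Weights therefore live in [−1, 1]:
strongly positive means the attribute separates classes locally, near
zero means class-independent.

`diff` is 0/1 for categorical attributes and |v₁−v₂|/range for real ones.
Missing values are handled probabilistically with class-conditional
relative frequencies estimated from the observed values: with one side
missing, diff = 1 − P(observed value | class of the missing instance);
with both missing, diff = 1 − Σ_v P(v|class₁)·P(v|class₂). A class with
no observed values for an attribute falls back to the attribute's global
frequencies.

Defaults: k = 10 neighbors; every instance serves as an anchor
(deterministic; the classic random-m subsampling is available behind
`n_samples` + seed for large tables); weights are computed on the
discretized table. The selection threshold δ defaults to 0.02 with strict
inequality (w > δ keeps the attribute).

Distance ties are pervasive on categorical data, so the k-th-neighbor
boundary is handled by fractional averaging: all instances tied at the
boundary distance share the remaining neighbor slots equally. This keeps
the weights deterministic *and* exactly invariant under reordering of the
objects, which an index-based tie-break cannot achieve. One consequence
worth knowing: in the presence of strong relevant attributes, the weights
of irrelevant attributes drift slightly negative (≈ −0.04 at n = 500)
rather than sitting at zero — neighbor selection is dominated by the
relevant attributes, and within those neighborhoods the irrelevant
attribute looks marginally more variable among hits than among misses.
Irrelevant-attribute weights are near zero exactly when the class is
independent of all attributes.

## Rough-set reduction

The algebra is classical: objects are indiscernible under P ⊆ C when they
agree on every attribute of P; the lower/upper approximations of X ⊆ U
are the unions of blocks contained in / intersecting X; the positive
region pos_P(d) is the union of P-blocks that are pure in the decision;
the dependency degree γ_P(d) = |pos_P(d)|/|U|; and the significance of
a ∈ P is γ_P(d) − γ_{P∖{a}}(d) ≥ 0. All dependency comparisons use exact
integer positive-region counts — γ values are rationals with denominator
|U|, so reduct acceptance (γ_P = γ_C) is exact equality, never a float
tolerance.

A *reduct* is a minimal subset preserving γ_C(d). Two finders exist:

* **Exhaustive scan** (≤15 attributes): subsets enumerated by increasing
  size; a subset is kept when it reaches the full dependency and contains
  no previously kept reduct. By monotonicity of γ this yields exactly the
  subset-minimal preservers. This is the oracle the GA is tested against.
* **GA search**: chromosomes are inclusion bitmasks over C. The initial
  population is biased by the ReliefF ranking — each bit switches on with
  probability equal to the min–max-normalized weight clipped to
  [0.1, 0.9] — so highly ranked attributes enter early. Fitness is
  γ_P/γ_C − λ·|P|/|C| with a +1 bonus for exact preservation, making
  preserving individuals strictly dominate all others; λ = 0.1 mildly
  prefers small subsets without ever trading dependency for size.
  Tournament selection (size 2), uniform crossover (rate 0.6), bit-flip
  mutation (0.02/bit), elitism of one; empty masks are repaired by
  activating the top-weight attribute. Every preserving individual met in
  any generation is post-processed to minimality by greedily deleting
  members (lowest ReliefF weight first) while dependency is preserved;
  single-deletion minimality implies full minimality by monotonicity.
  Distinct minimal subsets are accumulated across the whole run, so the
  search returns a *set* of reducts, not one. Defaults: population 50,
  100 generations, fully seeded.

A table whose full condition set has γ_C = 0 (every block mixed) is
rejected: reduct search is meaningless there, and the error surfaces
early rather than returning arbitrary subsets. This matters for noisy
categorical data — see the fixture-design discussion below.

## Classification

The base learner is a C4.5-style tree with instance weights: splits chosen
by weighted gain ratio among attributes whose information gain is at least
the average of the positive-gain candidates; nominal/binary attributes
split multiway, real/ordered ones on the best midpoint threshold
(ties in gain go to the lowest threshold; ties in gain ratio to the
earlier column). Leaves predict the weighted majority, ties resolved
toward the globally more prevalent class, then the lower label. Stopping:
node purity, total node weight < 2·min_leaf_weight, or the optional depth
cap. `min_leaf_weight` = 2 in whole-instance units — incoming weights are
rescaled to sum to n, which makes tree induction invariant under uniform
weight scaling (and is what lets boosting pass its sum-to-1 weights
straight in). No error-based pruning by default: boosting wants low-bias
learners; a depth cap is available where pruning would be wanted.
At prediction time an unseen category or missing value routes to the
child that carried the greatest training weight.

The ensemble is AdaBoost.M1 by reweighting: weights start uniform; each
round fits a tree, computes the weighted error ε, and — if ε < 0.5 —
votes with weight α = ½·ln((1−ε)/ε), multiplying instance weights by
e^{±α} and renormalizing. A round with ε ≥ 0.5 (including exactly 0.5) is
discarded and weights reset to uniform. A round with ε = 0 receives a
capped vote (α = 10) and, because the deterministic reweighting would
regrow the identical tree from the reset uniform state forever, training
stops there — the ensemble is functionally the capped single tree. If
every round is discarded (possible only on unsplittable balanced data)
the single uniform-weight tree is kept with vote 1 and a warning, so
prediction stays defined. The ensemble score of an instance is the
α-weighted vote sum normalized to [−1, 1]; the sign predicts, with exact
zero going to the positive (disease) class. A resampling variant
(weighted bootstrap per round) is available behind a flag.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(FP+TN) and accuracy
(TP+TN)/total, with disease presence as the positive class; percentages
are rounded only at presentation. A metric with an empty denominator is
NaN, never silently 0. ROC curves sweep distinct score thresholds in
descending order with tied scores grouped into single steps; AUC is the
trapezoid rule, which equals the pairwise-comparison probability
P(score⁺ > score⁻) + ½·P(equal).

Two protocols: repeated stratified 70/30 splits (test size round(0.3·|U|),
per-class quotas by largest remainder, so test prevalence stays within
one object of the global one) and leave-one-out (jackknife). The headline
figure is the best test accuracy over 10 seeded repetitions × ensemble
sizes {50, 100, 150} × reducts — a best-of protocol, reported as such;
ties prefer the smaller reduct, then the smaller ensemble. The pipeline
writes a run manifest (config echo plus every derived seed) sufficient to
reproduce a run bit-identically.

## Synthetic data: what it emulates and what it does not

`make_table` plants known structure: *relevant* attributes jointly
determine the class through a sum-threshold rule (class 1 iff the level
codes sum past the midpoint of the achievable range — an additive risk
score, the typical structure of clinical indices, and learnable by greedy
trees, which a parity rule deliberately is not); *redundant* attributes
are bijectively relabeled copies of relevant ones, hence
partition-identical — the strongest redundancy the rough-set machinery
must detect; *noise* attributes are class-independent with 2–4 levels.
All relevant attributes of one table share a single level count (3 or 4,
drawn per table): under an additive rule an attribute with fewer levels
than its peers is only marginally informative, so mixed level counts
would plant "relevant" attributes that no marginal filter can see and
make the ground truth ill-posed as a selection benchmark. With no label
noise the minimal reducts are exactly the transversals picking one
representative per duplicate group, and this ground truth is verified
against the exhaustive scan in the tests. Label noise is modelled as
independent flips at rate `flip_noise` < 0.5.

The noisy end-to-end experiment (600 objects, 5% flips) uses 3 relevant +
1 redundant + 2 noise attributes. The choice balances two constraints of
the method itself: exact-dependency reduction needs γ_C > 0, which fails
when blocks are large (few relevant attributes ⇒ every block catches a
flip), while denoising by the classifier needs blocks with enough
objects (too many relevant attributes ⇒ two objects per cell and the
Bayes rate of ≈95% is unreachable). Three relevant attributes with 3–4
levels give ~30–60 cells at n = 600, the consistent-but-populated regime
the method is designed for — comparable to the binned 13-attribute
heart-disease table.

`make_statlog_like` reproduces the heart-disease *schema*: the 13
attribute kinds and domains, truncated-normal real attributes whose
truncated moments are numerically matched to the published means and
standard deviations (ST depression additionally carries a 45% point mass
at zero — no truncated normal attains its sd/mean ratio of 1.09), fixed
plausible categorical marginals, and a logistic class rule over a subset
of risk attributes. It reproduces marginals and kinds only — not the
real joint dependence structure — so pipeline results on it demonstrate
that the protocol runs and is reproducible, not that the published
accuracy on the real benchmark is matched. Passing tests on these
fixtures show the algorithms implement their definitions and recover
planted structure; they do not certify clinical performance.

## Problem sizes in the standard runs

The shipped acceptance computation uses 50 small tables for the
GA-vs-exhaustive agreement, 50 seeded datasets (n = 500) for the ReliefF
ranking rate, one noisy planted run (n = 600) and one 270-row stand-in
run under the full default protocol; the test suite uses 100 tables /
100 datasets for the corresponding checks and 1000 random tables for the
algebraic identities. These sizes give stable rates while keeping a full
run in the minutes range on one core.

## Known limitations

* Exact-dependency reducts are brittle under label noise by construction;
  variable-precision rough sets would relax this but are out of scope.
* The GA guarantees that whatever it returns is a true minimal reduct,
  not that it finds *all* reducts; coverage grows with population,
  generations, and the quality of the ReliefF bias.
* C4.5 here has no error-based pruning or missing-value fractional
  instances; missing values route to the heaviest child.
* ReliefF weight magnitudes depend on discretization; rankings are far
  more stable than raw values, and the selection threshold δ should be
  read against the ranking, not as an absolute relevance scale.
* The jackknife protocol retrains one model per object and is intended
  for small tables or cheap learners.
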