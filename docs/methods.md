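# Methods

`metasig` implements a biomarker-discovery procedure for class-labelled
protein-abundance panels, built around four ideas: per-sample z-scoring,
pairwise-difference *metafeatures*, exact combinatorial feature selection,
and consensus-driven pruning of suspect training labels.

## Normalisation and metafeatures

Each sample's row is standardised across the panel:
`z_ij = (x_ij − μ_i) / σ_i`, with `μ_i`, `σ_i` the mean and standard
deviation of sample `i` over all base proteins.  A z-score therefore
expresses a protein's abundance *relative to the rest of the panel in the
same sample*, not relative to other samples.  The standard deviation uses
the `n − 1` denominator by default; the population convention is available
via `sd_convention="population"` since source datasets do not always state
which was used.  A constant row is a hard error (`σ_i = 0`).

For every unordered protein pair `(a, b)` the metafeature `z_a − z_b` is
appended.  The two orientations are equivalent (negations of each other),
so only the canonical orientation — `a` before `b` in panel order — is
stored, giving `n(n−1)/2` derived columns for an `n`-protein panel
(7,140 for `n = 120`).  Metafeatures are always computed on z-scores.
Because row z-scoring removes any per-sample additive offset, metafeatures
are invariant to sample-level shifts of the raw data; a metafeature's value
depends only on the two proteins involved.

## Entropy/MDL feature filter

Features (base and metafeatures alike) are filtered by recursive binary
discretization: the candidate cut minimising the weighted child class
entropy is accepted when its information gain exceeds the
minimum-description-length cost

```
gain > log2(N−1)/N + [log2(3^c − 2) − (c·Ent(S) − c1·Ent(S1) − c2·Ent(S2))]/N
```

and recursion continues inside each induced interval.  A feature with no
accepted cut is discarded.  Numerical choices: candidate cuts are midpoints
between adjacent distinct values and are restricted to class-boundary
points (sufficient for optimality of the entropy criterion); ties among
equal-gain cuts go to the smallest cut value; equal values always share an
interval; recursion depth is unlimited (the MDL rule is the only stopping
criterion).  The filter is fit on training samples only — and re-fit from
scratch at every pruning iteration, since removing samples changes which
features carry class information.  Classification never uses discretized
values; they exist only to filter features and to define the selection
problem.  A naive all-midpoints reference implementation
(`metasig.reference`) validates the fast path exactly on small instances.

## (α, β)-k feature-set selection

From the discretized training matrix, every pair of samples in different
classes contributes the set `D(p)` of features whose interval values
differ; every same-class pair contributes the agreement set `S(q)`.  The
selection problem: choose exactly `k` features so each between-class pair
is distinguished by ≥ α chosen features and each within-class pair agrees
on ≥ β of them; among feasible sets, maximise total pair coverage
`Σ_p |x ∩ D(p)| + Σ_q |x ∩ S(q)|` (equivalently, each feature weighted by
the number of pairs it explains; difference- and similarity-coverage carry
equal weight, a documented interpretation since the cited IP formulations
leave the objective's exact form open).

α is the largest value keeping the problem feasible at fixed `k` with β
ignored; the minimum of `|D(p)|` over pairs (capped at `k`) bounds it from
above but is not automatically achievable, because one `k`-set must serve
all pairs simultaneously — candidates are checked by an IP feasibility
solve, decrementing from the cap.  β is then the largest value (bounded by
the within-pair agreement counts and `k`) keeping the joint problem
feasible, with the forced features included in the check.  A between-class
pair with identical discretized profiles admits no separating feature; in
strict mode this is an error naming the pair, while the pruning loop runs
non-strict, where such pairs simply drive α to 0 (exactly what the
minimum-count rule implies) — this arises routinely when a mislabelled
sample shadows a sample of its true class.

Known features may be *forced* into the signature (dropped with a warning
if the filter rejected them).  The IP is solved exactly by HiGHS
(`scipy.optimize.milp`) with zero MIP gap, single-threaded, features in
name order; with multiple optima the deterministic run's optimum is
reported and the objective value is logged so alternates are detectable.
An exhaustive `C(m, k)` enumeration backs the solver in tests.

## Classifier panel and disagreement

The signature is evaluated by a 25-member classifier panel spanning seven
families (Bayesian, linear, instance-based, meta-ensemble, rule, tree,
centroid), all with library defaults — no tuning, no cross-validation.
Two deliberate settings: k-NN appears with k = 2 as well as k = 1 to make
the two members distinct, and the centroid member is plain nearest-centroid
(shrinkage zero), because shrinkage is itself a feature selector and
selection has already happened.  Classifiers train on continuous values of
the case/control training samples; samples labelled `other` (e.g. other
dementias) receive predictions but are excluded from all metrics.
Sensitivity treats the case class as positive; panel summaries are
unweighted means/SDs over the 25 members.  Score ties predict control.

The panel intentionally mixes *smoothing* members (naive Bayes, LDA,
logistic, linear SVM, k-NN with k > 1, nearest centroid), which cannot
memorise a contradictory label, with *interpolating* members (1-NN,
unpruned trees, bagged forests), which always resubstitute correctly.  The
per-sample disagreement count `d_s` — panel members whose resubstitution
prediction contradicts the recorded label — therefore separates samples
whose label the data supports (`d_s ≈ 0`) from suspect ones
(`d_s ≈` number of smoothing members).

## Pruning loop

Each iteration: re-fit filter → re-derive α, β → solve the IP → fit panel →
flag every training sample with `d_s` at or above the smallest integer
count exceeding `τ·N` (strictly more than a fraction τ of the panel; for
N = 25, τ = 0.30 the threshold is 8).  All flagged samples are removed
together.  Stopping rules: no sample over the threshold; the new signature
equals the previous one as a set; the training set would shrink below
`min_train_fraction` of its original size (default 0.5); or a hard
iteration cap.  `strip_single_features` is provided as a one-shot
post-processing step producing the metafeature-only reduct of a mixed
signature; it is not a loop stage.

Defaults: `k = 10`, `τ = 0.30`, panel size 25.

## Synthetic data

The generator emulates the statistical regime the method assumes, with
ground truth retained for scoring:

* background proteins: `x_ij = b_i + ε_ij`, baseline `b_i ~ N(0, 1)` shared
  by the whole row (removed by z-scoring), `ε ~ N(0, background_sd)`;
* single markers: cases shifted by `single_effect`;
* imbalance pairs `(f1, f2)`: both members receive a per-sample shared
  offset `~N(0, shared_noise_sd)` plus antisymmetric class shifts of
  `± imbalance_effect/2` with opposite sign on the two members.  Member
  class-mean gap is therefore `imbalance_effect` with standard deviation
  `≈ √(1 + background_sd² + shared_noise_sd²)`, while the pair difference
  has gap `2·imbalance_effect` at spread `√2·background_sd` — with the
  default `imbalance_effect = 3`, `shared_noise_sd = 8`, members sit around
  Cohen's d ≈ 0.37 (below the entropy filter's acceptance at these sample
  sizes) while the difference sits at d ≈ 4;
* a configurable fraction of training labels flipped uniformly at random
  without replacement (exact count, `round(fraction · n)`), modelling
  clinically mislabelled participants.

Raw abundances are emitted, never pre-z-scored data, so the pipeline's own
normalisation path is always exercised.  Class sizes are exact, and a fixed
config + seed reproduces the dataset bit for bit.  The generator does not
model cytokine co-regulation structure, heavy-tailed abundance
distributions, batch effects, or an "other dementia" class — recovery
results on it demonstrate the machinery's correctness and calibration, not
clinical performance.

## Validation studies (`metasig.studies`)

Problem sizes are scaled so each study runs in minutes on one core; the
full clinical scale (120 proteins → 7,260 columns) makes each exact IP
solve minutes long and is exercised structurally (expansion counts) rather
than end to end.

* **Pair recovery** — 30 proteins, 25+25 samples, two planted imbalance
  pairs, no single markers, `k = 6`: the signature must contain both
  planted pair-difference metafeatures.  The pairs-only design keeps the
  row mean class-neutral; with single markers present, *every* z-scored
  column picks up a small class displacement through μ_i (the panel-relative
  nature of z-scores), and pair members would no longer sit below the
  filter on their own.
* **Mislabel recovery** — 20 proteins, 40+43 samples, strong planted
  effects (4 raw SD), 5 flipped labels, `k = 10` with the planted single
  markers forced (modelling the usual practice of anchoring the search on a
  previously validated marker panel): the loop's removed set must equal the
  planted flip set.  At materially smaller training sizes this degrades: the filter and
  the coverage-maximising IP adapt to observed labels and can *absorb* a
  flip by selecting columns on which it resembles its recorded class — a
  genuine failure mode of selection-before-validation, and the very reason
  the pruning loop re-derives everything per iteration.
* **Oracle agreement** — the discretizer against the naive all-midpoints
  reference (200 random instances, n ≤ 30) and the IP solver against
  exhaustive enumeration (100 random instances, ≤ 15 features, k ≤ 4),
  both requiring exact agreement.

## Known limitations

* Exact-set mislabel recovery is statistical, not guaranteed; individual
  flips can be absorbed (above) and borderline clean samples occasionally
  cross the 30% threshold.
* The panel reproduces family diversity with scikit-learn members, not any
  specific historical implementations; per-classifier numbers are not
  comparable across toolkits, only panel-level consensus behaviour is.
* The IP scales to a few hundred post-filter features comfortably;
  full-panel (7,260-column) instances are solvable but slow on one core.
* With several equally optimal signatures the reported one is the
  deterministic solver's choice; alternates are only detectable through the
  logged objective.
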