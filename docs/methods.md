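# Methods

## The problem

In a randomized trial with two or more arms, the average treatment effect
can mask subgroups of patients for whom a different arm is the better
choice.  `dipmtree` grows a classification tree over candidate covariates
to find such subgroups and to recommend an arm per patient.  The outcome Y
is either continuous or a right-censored survival time with a 0/1 status
indicator; in both cases higher Y is the clinically better direction (for
survival this means the event is harmful, so longer times are better).

## Split criteria G_t

The strength of splitting a node t into children {x ≤ c} / {x > c} (or
{x ∈ S} for nominal covariates) is a treatment-by-split interaction test
statistic:

* **continuous, 2 arms** — fit E[Y] = β₀ + β₁·arm + β₂·z + β₃·arm·z, with
  z the left-child indicator; G_t is the squared Wald t for β₃ (df 1).
* **continuous, K ≥ 3 arms** — joint Wald χ² of the K−1 interaction
  coefficients of the saturated arm × child two-way layout (df K−1).
* **survival, 2 arms** — Cox proportional-hazards model with covariates
  (arm, z, arm·z); G_t is the squared Wald z of the interaction (df 1).
* **survival, K ≥ 3 arms** — joint Wald χ² of the K−1 hazard-interaction
  coefficients (df K−1).

These forms were chosen because they are the natural interaction-tree
statistics, are comparable across candidate splits of different covariates
(via their χ² scale), and reduce to each other across arm counts.  The
continuous statistics are evaluated in closed form from arm × child cell
counts, sums and sums of squares: the models are saturated, so the
interaction contrasts are cell-mean differences with covariance
s²(a·11' + diag(d)), inverted analytically (Sherman–Morrison).  This is
algebraically identical to the design-matrix OLS Wald statistic (verified
against statsmodels to 1e−10 in the tests) and is what makes the embedded
forests fast enough to be routine.

The survival statistics use an in-package Newton–Raphson maximizer of the
Cox partial likelihood with Breslow tie handling: at most 25 iterations,
convergence when the maximum absolute score falls below 1e−8, step-halving
whenever the likelihood would decrease.  The covariance is the inverse
observed information (pseudo-inverse, with a degeneracy flag, when the
information is rank-deficient).  The fitter is deterministic and never
raises inside the tree search; any degenerate or non-convergent fit yields
G_t = 0 with `converged=False`, which simply makes that split
non-competitive.  The test suite checks the fitter against a brute-force
grid/Nelder–Mead maximizer of an independently coded Breslow partial
likelihood, and the Kaplan–Meier estimator against lifelines.

**Admissibility.** A continuous interaction fit requires at least 2 rows in
every arm × child cell and positive residual variance (residual sum of
squares above 1e−10 of the total sum of squares — practically-constant
responses are treated as degenerate).  A survival fit requires every
arm × child cell nonempty and at least one event per child (and at least K
events for K ≥ 3).  Inadmissible splits score zero.

Nodes in which an arm is entirely absent are tested with the arms that
remain (a node with 2 of 3 arms gets the two-arm statistic); a node with
fewer than two arms is terminal.

## Depth variable importance and the embedded forest

At each node of the overall tree a random forest of *embedded* trees is
grown on bootstrap resamples of the node's rows (resample size = node
size).  Embedded trees are greedy: at each embedded node `mtry` covariates
are drawn without replacement and the admissible split with the largest
G_t is taken; growth stops at depth `maxdepth2`, below `2·nmin2` rows, or
with no admissible split.  For each embedded tree T and covariate j,

    score(T, j) = Σ_{t ∈ T_j} 2^(−L(t)) · G_t ,

where T_j is the set of nodes split by j and L(t) the node depth with the
root at depth 1 (so the root contributes weight 1/2).  Scores are summed
over the forest; the covariate with the largest total splits the overall
node, at the best split found by exhaustive scan over that covariate's
candidates.  If every score is zero the node becomes terminal — there is
deliberately no fallback to exhaustive search, which keeps the
forest-guided and exhaustive methods distinct.  G_t is evaluated on the
resampled rows themselves (no out-of-bag evaluation), the most direct
reading of the score.

Defaults: `ntree=50`, `mtry=ceil(√p)`, `maxdepth2=6`,
`nmin2=max(5, nmin/2)`.  These are conventional random-forest-style
settings; the method's published description does not fix them.  The
random-number streams are derived per (overall node, embedded tree) with
counter-based child seeds, so trees are reproducible given one seed and
enlarging `ntree` does not perturb earlier trees.  A test hook
(`resample=False` with `ntree=1`, `mtry=p`) collapses the forest; together
with `maxdepth2=2` (a root-only embedded split) the forest-guided tree is
then provably identical to the exhaustive tree, which the suite asserts
node-for-node.  Note that `maxdepth2=2` is required for the tree-level
equivalence: a deeper single embedded tree accumulates importance below
its root and can legitimately rank another covariate first.

## The overall tree

Both builders (`build_dipm_tree`, `build_spm_tree`) share one recursion
and differ only in variable selection (forest vs. global argmax).  A node
is terminal when it has fewer than `nmin` rows (default 20), is at
`maxdepth` (default 4, matching the shallow trees this method is meant to
produce), has fewer than two arms, a degenerate outcome (constant Y; for
survival: no events or a single observed time), or no admissible split.
Candidate cutpoints are midpoints of consecutive distinct observed values;
nominal covariates contribute every category subset up to complement
symmetry (reported as the smaller side, lexicographic tie-break), falling
back to the k−1 outcome-ordered splits above 10 observed categories to
keep enumeration polynomial.  Ties in G_t go to the smaller cutpoint /
lexicographically first subset / earlier covariate column.  Nodes are
recorded in level order with 1-based ids; the left child always receives
{x ≤ c} or {x ∈ S}, and a value exactly at a cutpoint routes left.

Every node carries its **optimal treatment**: the arm with the largest
within-node mean response, or — for survival — the largest restricted mean
survival time (area under the within-arm Kaplan–Meier curve truncated at
the node's largest observed time).  RMST is used instead of a within-node
hazards fit because it is defined even in small leaves where proportional
hazards cannot be fitted.  Ties go to the smallest arm code (first arm by
order of appearance in the data).

**Pruning** collapses any internal node whose two children are terminal
with the same optimal treatment, deepest-first, iterating to a fixed point
(a merge can create a new same-label sibling pair).  Surviving nodes keep
their id, membership, split and label.

**Prediction** routes each subject root-to-leaf through the stored rules
and reports the leaf's optimal treatment plus the leaf's per-arm
summaries.  An unseen nominal category routes right with a warning;
refusing to predict would make the tool brittle in deployment.

## Synthetic trials

The simulator emulates a parallel-arm randomized trial: arms assigned
independently of covariates with fixed allocation ratios; independent
covariates (ordinal = uniform integer grid 1..levels, binary =
Bernoulli(1/2), nominal = uniform categories); a covariate-defined
subgroup (one or more AND-ed threshold/subset conditions) with a
per-(subgroup × arm) effect.  Continuous outcomes are
Y = μ₀ + effect·σ + N(0, σ²) with effects in σ units, so scenarios are
scale-free.  Survival outcomes are exponential with rate
λ₀·exp(log-HR(subgroup, arm)) and independent exponential censoring whose
rate is calibrated by root-finding so the expected censored fraction hits
the target.  Named presets fix the study conditions used throughout the
tests:

* `sign-reversal` — n=400, two arms (1:1), binary X1 flips a ±1.5σ
  treatment effect, nine 10-level ordinal noise covariates.  This is the
  canonical recovery scenario.
* `null` — same shape, all effects zero.
* `anorexia-like` — n=300, three arms, one strong 25-level ordinal
  covariate; the third arm is globally best and the first-vs-second
  contrast is larger above the covariate median (the default n is larger
  than the 72-patient trial it is shaped after, so the planted structure
  is recoverable at test scale).
* `gbsg2-like` — n=686, two arms (0.64/0.36), survival with λ₀ = 5·10⁻⁴
  per day and 56% censoring; an ordinal covariate gates the benefit of
  the treated arm (log-HR −0.7 inside vs +0.2 outside).

What the simulator deliberately does **not** model: correlated covariates,
non-proportional hazards, informative censoring, covariate-dependent
censoring, missing data.  Passing recovery tests therefore demonstrate the
machinery under clean randomized-trial assumptions, not robustness to
observational-data pathologies.

## Numerical and design notes

* Complete cases only: any missing value in a role column is an error.
* Arms are recoded 0..K−1 by first appearance (label map retained);
  nominal categories are coded by sorted label so results are invariant to
  row order.
* Tree tables serialize floats with 17 significant digits; write → read →
  write is byte-identical.
* Ordinal covariates are not standardized (the criteria are invariant to
  monotone relabeling of the split variable anyway, since only the induced
  partition matters).
* The exhaustive builder is fully deterministic; the forest-guided builder
  is deterministic given its seed.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the canonical sign-reversal
recovery at its stated size (n=400, 50 seeds, defaults: ~1.5 s per fit),
criterion/oracle comparisons on 10–60-row toys, pruning on 100 random
trees, and the 72-patient anorexia example (5 seeds, depth-2 trees).
Survival unit tests use n = 120–300 with `ntree` ≤ 20, sized so the Cox
refits inside embedded forests stay interactive.  A full-scale DIPM fit on
the 686-patient GBSG cohort takes about two minutes and is exercised as an
I/O example rather than in the default checks.

## Known limitations

* The interaction-Wald forms of G_t are this package's own definition of
  the split criteria; other implementations of the same method family may
  use different statistics and produce different trees on the same data
  (observed on the GBSG cohort, where the root variable differs from the
  published example tree).
* No honest estimation or cost-complexity pruning: leaf summaries are
  computed on the training data and are optimistic.
* Wald statistics in small cells are approximate; the admissibility rules
  bound, but do not remove, small-sample anti-conservatism.
* Breslow tie handling is adequate for the tie densities of clinical
  data but less accurate than Efron under heavy ties.
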