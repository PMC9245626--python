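# dipmtree

Subgroup-identification classification trees for precision medicine.

In a randomized trial the average effect can hide subgroups of patients for
whom a different arm is the better choice. `dipmtree` grows a tree over
candidate covariates (binary / ordinal / nominal) to find such subgroups and
recommend a treatment per patient, for continuous outcomes or right-censored
survival times with two or more arms. It is aimed at biostatisticians
analysing trial data and at methodologists who want a transparent, fully
seeded reference implementation to experiment against.

## The method

The split strength at node *t* is a treatment-by-split interaction
statistic G_t: the squared Wald statistic of the arm×child interaction in a
linear model (continuous Y) or Cox proportional-hazards model (survival),
and the joint Wald χ² of the K−1 interaction coefficients when there are
K ≥ 3 arms. To pick the *variable* that splits a node, a random forest of
"embedded" trees is grown on bootstrap resamples of the node's rows, and
each covariate *j* is scored by depth variable importance

    score(T, j) = Σ_{t ∈ T_j} 2^(−L(t)) · G_t

summed over the forest, where T_j are the nodes split by *j* and L(t) is
the node depth (root = 1) — strong splits near the root count most. The
best split of the winning covariate then partitions the node
(`build_dipm_tree`). A classical exhaustive-search tree that simply takes
the single best split over all covariates is included for comparison
(`build_spm_tree`). After growth, `prune_same_treatment` collapses sibling
leaves that recommend the same arm, and `predict_optimal_treatment` routes
new patients to a leaf and its recommended arm. Each leaf's optimal
treatment is the arm with the best within-leaf mean response, or the
largest restricted mean survival time for survival outcomes.

A synthetic randomized-trial generator with planted subgroup structure
(`dipmtree.synthetic_data`) makes every stage testable without external
data; see `docs/methods.md` for the model details, defaults and
limitations.

## Worked example

The 72-patient anorexia weight-change trial (three arms: cognitive
behavioural treatment, control, family treatment; covariate = pre-study
weight; response = post-study weight) ships as a test fixture:

```sh
dipmtree fit --data tests/data/anorexia.csv \
             --model "Postwt ~ Treat | Prewt" --maxdepth 2 --seed 1
```

prints the node table

```
node,depth,nsubj,splitvar,vartype,splitval,lchild,rchild,G,besttrt,terminal
1,1,72,Prewt,ordinal,86.550000000000011,2,3,13.776336817254162,FT,0
2,2,56,,,,,,,FT,1
3,2,16,,,,,,,FT,1
```

The root splits the cohort at a pre-study weight of 86.55 lb with
interaction statistic G = 13.78 (df 2), and family treatment (FT) is the
recommended arm in both subgroups — the split is informative about effect
*size* (the CBT-vs-control contrast differs across the two leaves, visible
in the per-arm means of a `--out-render` export), not about which arm wins.

The same pipeline end to end on a synthetic trial with a planted
sign-reversal subgroup:

```sh
dipmtree simulate --scenario sign-reversal --seed 4 --out trial.csv
dipmtree fit --data trial.csv --model "Y ~ treatment | ." \
             --seed 4 --prune --out-tree tree.csv
dipmtree predict --tree tree.csv --data trial.csv --out pred.csv
```

Here the fitted tree roots on the planted subgroup variable with one leaf
per arm:

```
node,depth,nsubj,splitvar,vartype,splitval,lchild,rchild,G,besttrt,terminal
1,1,400,X1,ordinal,0.5,2,3,221.53478022972683,1,0
2,2,187,,,,,,,0,1
3,2,213,,,,,,,1,1
```

and `pred.csv` recommends arm 0 for the 187 subjects with X1 = 0 and arm 1
for the rest, matching the generative truth. `dipmtree fit --out-render
tree.json --render-format json` exports per-leaf boxplot/Kaplan–Meier
summaries; `--out-render tree.dot` writes Graphviz text.

The library API mirrors the CLI: `read_clinical_table`, `build_dipm_tree`
/ `build_spm_tree`, `prune_same_treatment`, `predict_optimal_treatment`,
`export_tree_render`, and `simulate_continuous_trial` /
`simulate_survival_trial`.

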