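# pcthmc

Decision trees and bagged ensembles for **hierarchical multi-label gene
function prediction**, with precision/recall-based evaluation.

A gene usually carries several functions at once, and the functions live
in a hierarchy — a rooted tree (MIPS FunCat, slash-path classes such as
`4/3/1`) or a DAG (the Gene Ontology, where a term can have multiple
parents).  Annotations and predictions must respect the *hierarchy
constraint*: having a function implies having all of its ancestors.
`pcthmc` is for computational biologists and machine-learning researchers
who want a single interpretable model that predicts a gene's entire
function vector at once — and a corrected, order-independent PR evaluation
for score matrices from any predictor.

## The model in brief

A **predictive clustering tree** is grown top-down; each split maximises
the reduction of

    Var(S) = (1/|S|) Σ_k d²(v_k, v̄),   d²(a,b) = Σ_i w(c_i)·(a_i − b_i)²,

where v_k is the binary function vector of gene k and the class weights
w(c) = w0 · mean_j w(p_j(c)) (default w0 = 0.75) decay with depth, so
errors near the top of the hierarchy cost more.  Growth stops when an
F-test finds no significant reduction or a child would drop below
`min_leaf` (default 5) genes.  Each leaf stores its mean function vector
(the *prototype*); component i is the fraction of the leaf's genes with
function c_i.  Prototypes are parent-monotone, so thresholding them gives
hierarchy-consistent predictions.  Bagging k = 50 such trees and averaging
their vectors gives the ensemble variant; out-of-bag estimation is
included.  Evaluation produces function-wise and pooled (micro-averaged)
PR curves, AU(pooled-PR), mean per-class AUPRC and AUROC.

See `docs/methods.md` for the full account.

## Worked example

Generate a planted-rule benchmark (10 function classes in a random tree,
600 genes, 10% label noise), train a 50-tree ensemble, predict and
evaluate:

```bash
pcthmc synth --classes 10 --instances 600 --noise 0.1 --seed 7 --out-prefix yeastlike
pcthmc train --data yeastlike.data.tsv --hierarchy yeastlike.hierarchy.tsv \
             --ensemble --trees 50 --seed 7 --out model.json
pcthmc predict --model model.json --data yeastlike.data.tsv \
               --hierarchy yeastlike.hierarchy.tsv --out pred.tsv
pcthmc evaluate --predictions pred.tsv --truth yeastlike.data.tsv \
                --hierarchy yeastlike.hierarchy.tsv
```

which prints (training-set resubstitution, hence the high numbers):

```
AU(pooled-PR)	0.9909
mean per-class AUPRC	0.9778
mean per-class AUROC	0.9945
classes evaluated	10
classes without test positives	0
```

`AU(pooled-PR)` is the area under the micro-averaged PR curve obtained by
sweeping one global threshold over all gene–class scores (frequent,
shallow functions weigh more); `mean per-class AUPRC` averages the areas
of the per-function curves, treating every function equally; both would be
the class frequency for an uninformative constant scorer.  Evaluation
works on any gene × class score matrix, so predictions from other systems
can be scored the same way.

Every leaf doubles as an `if … then …` rule.  From the same data, a single
tree's most precise rules for one deep class (planted ground truth:
`x000 > 0.907`):

```python
>>> from pcthmc import PCTParams, build_tree, extract_rules
>>> from pcthmc.synthetic import SyntheticConfig, make_dataset
>>> d, rules = make_dataset(SyntheticConfig(n_classes=10, n_instances=600,
...                                         label_noise_rate=0.1, seed=7))
>>> tree = build_tree(d, PCTParams(rng_seed=7))
>>> for r in extract_rules(tree, "c003", min_score=0.8)[:1]:
...     print(r)
if x004 > 0.632018 and x000 > 0.758417 and x000 > 0.909673 and x001 > 0.185837 and x002 <= 0.613706 then c003 (score 0.889, n=9)
```

The `tune` command reproduces the full protocol: the F-test significance
is selected from {0.001, 0.005, 0.01, 0.05, 0.1, 0.125} on a 1/3
validation split by AU(pooled-PR), then the final model is retrained on
all training data.

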