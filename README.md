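# histocyto

Histocytometry of multiplex-stained tumor images with active-learning cell
classification.

Tumor endothelial cells (EC) are the direct target of antiangiogenic
therapy, but they are rare, irregularly shaped, and scattered through
heterogeneous tissue, so training a cell classifier from examples picked
freely by a human pathologist inherits that human's selection bias.
`histocyto` implements the alternative: a sparse logistic-regression
classifier that *chooses its own training examples*, querying the expert
for the cells that are most informative about its parameters, and
automatically deciding which features matter. Around that core the package
provides everything needed to go from unmixed stain channels to per-cell
biology: nuclear segmentation, per-cell feature extraction, analyte
(Ki67 / p-ERK / p-STAT3) quantification with background correction, and
rater-agreement statistics — plus a synthetic-data generator with known
ground truth so the whole pipeline is testable without any image downloads.

It is aimed at quantitative-pathology researchers and methods developers
who want a transparent, scriptable reference implementation of
information-driven active learning for cell classification.

## The core algorithm

Cells are feature vectors x with labels y ∈ {−1, +1} (+1 = EC) under a
logistic model P(y = +1 | x) = σ(βᵀx). Training maximizes the L1-penalized
log-likelihood

    Σᵢ ln σ(yᵢ βᵀxᵢ) − λ ‖β₋₀‖₁ ,    λ = √n_labeled,

with |b| smoothed as √(b² + ε_s), so uninformative features are driven to
(nearly) zero while training proceeds. At each iteration the algorithm
computes the regularized Fisher information of the labeled set,

    I(β) = Σᵢ σ(βᵀxᵢ)(1 − σ(βᵀxᵢ)) xᵢxᵢᵀ + ε·D ,

and queries the unlabeled cell that maximizes det(I + w(x)·xxᵀ) — the
D-optimal choice, the one that shrinks coefficient uncertainty fastest.
By the matrix determinant lemma this is the argmax of the cheap score
w(x)·xᵀI⁻¹x, so a pool of hundreds of thousands of cells can be scanned per
iteration. The run stops when the information gain ln det I plateaus or a
query budget is exhausted. Given the same seed and oracle, the algorithm
queries the same cells and produces the same classifier, every time.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Train on the standard synthetic benchmark — 1000 cells, 4 informative and
40 noise features, class separation of 2 within-class standard deviations:

```python
from histocyto.synthetic import TabularSpec, make_feature_dataset, simulated_oracle
from histocyto import active as al

pool = make_feature_dataset(TabularSpec(seed=1))
oracle = simulated_oracle(pool)          # answers label queries from ground truth
state = al.run_active_learning(pool, oracle, al.ALConfig(seed=1, max_iterations=50))

rest = pool[~pool["cell_id"].isin(state.labeled_ids)]
_, pred = al.predict_table(state.model, rest)
acc = (pred == rest["label"].to_numpy()).mean()
print(f"labeled cells:      {len(state.labeled)}")
print(f"held-out accuracy:  {acc:.3f}")
print(f"selected features:  {al.selected_features(state.model)}")
print(f"information gain:   {state.gain_history[0]:.2f} -> {state.gain_history[-1]:.2f}")
```

prints

```
labeled cells:      52
held-out accuracy:  0.965
selected features:  ['inf_01', 'inf_04', 'inf_03', 'inf_02', 'noise_23']
information gain:   -886.12 -> 94.86
```

After labeling only 52 of 1000 cells (2 seeds + 50 queries) the classifier
reaches 96.5% accuracy on the 948 cells it never saw labels for, and its
selected-feature list contains all four truly informative features while
39 of the 40 noise features have been zeroed out. The information gain —
the log-determinant of the Fisher information — rises from the
near-singular initial state to a well-conditioned estimate.

The same loop runs from the shell over real (or simulated) images:

```
histocyto simulate --kind images --out sim --n-images 1 --seed 3
histocyto segment  --image sim/img000_nuclear.tif --out labels.tif
histocyto features --labels labels.tif --channel nuclear=sim/img000_nuclear.tif \
                   --channel CD34=sim/img000_CD34.tif --out feats.csv
histocyto train    --features feats.csv --oracle oracle.json --out model.json
histocyto classify --model model.json --features feats.csv --out pred.csv
histocyto evaluate --truth ref.csv --pred pred.csv --out metrics.json
```

`histocyto benchmark` reproduces the learning-curve comparison of active
learning against random-sampling logistic regression and PCA / t-test /
MRMR feature pre-selection, and `histocyto analyte` quantifies per-cell
analyte positivity from a corrected stain channel.

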