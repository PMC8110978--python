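# bayesteach

Bayesian teaching for explainable AI: select the explanations — example
images or pixel-level saliency maps — that best teach a human observer
*what a classifier will do*, and simulate how much such explanations can
help.

The package is for researchers in computational cognitive science and
human-centred machine learning who study *fidelity*: how well an observer
predicts a model's classifications (a second-order quantity, distinct
from the model's own accuracy). It provides the full pipeline around that
question — a probabilistic explainee model, explanation scoring and
selection, saliency-map generation, two-alternative forced-choice (2AFC)
session design, and idealized-agent analysis — all runnable end to end on
built-in synthetic backends with known ground truth.

## The model

An explanation is scored by how strongly it would lead an *explainee
model* to reproduce the target model's decision. For a target item `d*`
predicted as `y*`, with two example items from `y*` (the pair `τ*`) and
two from an alternative category `y` (the pair `τ`), the **simulated
explainee fidelity** is

    f_L(y* | τ*, τ, d*) = f(d*|τ*) / ( f(d*|τ*) + f(d*|τ) ),

and the **teaching distribution** over candidate example sets is
`P_T ∝ f_L`, normalized over the candidate space. The explainee is a
probabilistic linear discriminant analysis (PLDA) model: after an affine
map `u = A⁻¹(x − m)` the within-class covariance is the identity and the
between-class covariance is diagonal `Ψ`, so the class-predictive density
given two examples has the closed form

    f(d* | τ) = N( u* | Ψ/(2Ψ+I)·(u₁+u₂) ,  Ψ/(2Ψ+I) + I ),

evaluated coordinate-wise in log space. At pixel level, the saliency map
of image `d` for category `y` is the Monte-Carlo expectation of random
masks weighted by the classifier's probability on the masked image,

    E[M|y,d] ≈ Σᵢ mᵢ g(y|d,mᵢ) / Σᵢ g(y|d,mᵢ),

with masks drawn from a sigmoid-squashed Gaussian process (mean −100,
marginal sd 100, RBF length scale 22.4 px at 224×224) and rendered either
as a jet overlay or as a spatially varying blur with window width
`w(z) = ceil(30/(1+exp(20z−10)))`. See `docs/methods.md` for the full
account.

## Worked example

Score and select explanatory examples for a two-category problem:

```python
import numpy as np
from bayesteach import (
    FeatureDataset, SelectionPolicy, build_candidate_sets,
    compute_fidelities_batch, fit_plda, select_examples, to_latent,
)

rng = np.random.default_rng(0)
X = np.vstack([[1, 1] + rng.standard_normal((30, 2)),
               [-1, -1] + rng.standard_normal((30, 2))])
data = FeatureDataset(X=X, labels=np.repeat(["husky", "wolf"], 30))

model = fit_plda(data)
print("psi =", np.round(model.psi, 3))

lat = {i: u for i, u in zip(data.item_ids, to_latent(data.X, model))}
pool = build_candidate_sets(list(range(1, 30)), list(range(30, 60)),
                            n_pairs_per_category=50, seed=1)
compute_fidelities_batch(pool, lat[0], lat, model.psi)
f = np.array([c.fidelity for c in pool])
print(f"{len(pool)} candidates, fidelity range [{f.min():.3f}, {f.max():.3f}]")

for c, b in select_examples(pool, SelectionPolicy(kind="helpful", seed=2), 3):
    print(f"examples {c.pair_target} vs {c.pair_alt}: f_L = {c.fidelity:.3f} (bin {b})")
```

```
psi = [1.853 0.   ]
2500 candidates, fidelity range [0.509, 0.987]
examples (14, 15) vs (42, 54): f_L = 0.948 (bin 4)
examples (9, 14) vs (38, 48): f_L = 0.885 (bin 4)
examples (17, 18) vs (30, 37): f_L = 0.942 (bin 4)
```

The fitted `psi` concentrates the class signal on one latent axis (the
second axis carries none). Each selected candidate holds two "husky" and
two "wolf" examples whose fidelity exceeds the helpful threshold 0.8:
shown these four items, the explainee would classify the target as the
model does with probability ≥ 0.885.

The same stages are available from the shell. Generate a default 2AFC
session (150 trials, 50 where the model is right, 100 where it is wrong)
from a synthetic backend and run the three reference agents over it:

```
$ bayesteach gen-trials --seed 7 --out session.csv
wrote 150 trials (50 model-correct) -> session.csv
$ bayesteach simulate-agents --manifest session.csv --seed 7 --out responses.csv
random: fidelity=44.0% sensitivity=44.0% specificity=44.0%
perfect: fidelity=100.0% sensitivity=100.0% specificity=100.0%
belief_projecting: fidelity=33.3% sensitivity=100.0% specificity=0.0%
responses -> responses.csv
```

The belief-projecting agent — a perfectly accurate observer who assumes
the model always agrees with them — shows the signature profile this
design is built to expose: it catches every correct model prediction
(100% sensitivity), misses every model error (0% specificity), and lands
at 33.3% overall fidelity because the session contains twice as many
model errors as correct classifications. Other subcommands:
`bayesteach make-fixtures`, `bayesteach teach-select`,
`bayesteach saliency` (`--render blur|jet`).

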