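# ospreycaps

Training capsule networks without gradients: the osprey optimization
algorithm, a modified variant with chaotic draws and Gaussian mutation,
and a small capsule classifier for two-class blood-smear images whose
entire flat parameter vector is the optimizer's search space.

## The problem

Classifying white blood cells in stained smear images as normal
lymphocytes or leukemic blasts is a standard screening task in acute
lymphoblastic leukemia work. Capsule networks suit it — class capsules
output a vector `v_j` whose length encodes class presence and whose
orientation encodes pose — but their usual gradient training is not the
only option. This package trains the network *derivative-free*: a
population metaheuristic searches the cube `[−1, 1]^n` over all weights
and biases, minimising the margin loss

```
L = Σ_c T_c·max(0, m₊ − ‖v_c‖)² + λ(1 − T_c)·max(0, ‖v_c‖ − m₋)²
```

with `m₊ = 0.9`, `m₋ = 0.1`, `λ = 0.5`.

The optimizer is the osprey optimization algorithm (OOA): each member
of a population hunts a "fish" chosen among strictly better members
(global phase, `Y + r ⊙ (SA − I·Y)` with `I ∈ {1,2}`), then makes a
`1/t`-shrinking local move, with greedy acceptance of strict
improvements only. The modified variant (MOP) replaces the uniform `r`
draws of both phases with sinusoidal chaos-map iterates
(`p ← a·p²·sin πp`, `a = 2.3`) and adds a multiplicative Gaussian
mutation step `Y ← Y ⊙ (1 + k·g)` with a randomly decreasing scale
`k = u·(1 − t/T)`.

The package also ships the ten analytic benchmark functions used to
validate the optimizer, the smear augmentation operators (rotation,
shear, reflection, translation, scale), a synthetic two-class smear
generator, Pascal-VOC XML annotation I/O, the full evaluation-metric
panel (precision, recall, accuracy, specificity, F1, F-beta, linear
weighted kappa, AUC, Jaccard), and seeded benchmark / ablation /
cross-validation harnesses. See `docs/methods.md` for the model and
design details.

## Worked example

Minimise the 10-dimensional Ackley function with MOP:

```python
from ospreycaps import get_function, SearchSpace, OptimizerConfig, run

f = get_function("ackley", 10)
space = SearchSpace.cube(f.lower_bound, f.upper_bound, f.dimension)
res = run(f, space, OptimizerConfig(N=30, T=200, variant="mop", seed=42))
print(f"best value: {res.best_value:.3e}")
print(f"evaluations: {res.evaluations}")
print(f"history[0], history[-1]: {res.history[0]:.3f}, {res.history[-1]:.3e}")
```

prints

```
best value: 4.441e-16
evaluations: 18030
history[0], history[-1]: 14.090, 4.441e-16
```

The best member starts at Ackley ≈ 14.09 after random initialisation
and the greedy two-phase-plus-mutation loop drives it to the
double-precision floor of the function (the optimum value is 0);
`evaluations` counts every objective call (`N + 3NT` for MOP).

Training the capsule net on synthetic smears and cross-validating:

```python
from ospreycaps.experiments import CapsNetTrainer, cross_validate
from ospreycaps.imaging import SyntheticSmearConfig, generate_synthetic_dataset

images = generate_synthetic_dataset(SyntheticSmearConfig(seed=123), 75)
trainer = CapsNetTrainer(method="mop", N=20, T=50)
report = cross_validate(images, k=2, trainer=trainer, seed=0)
print(report[["fold", "accuracy", "f1", "kappa", "auc"]])
```

Everything is also reachable from the shell:

```
ospreycaps benchmark --function sphere --dim 10 --variant mop --runs 20 --out results.csv
ospreycaps synth --n 100 --seed 7 --out data/
ospreycaps train --data data/ --variant mop --out model.json
ospreycaps ablation --data synthetic --runs 10 --out ablation.csv
```

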