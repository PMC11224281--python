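"""Reproducible experiment harnesses.

* :func:`run_benchmark_study` — AVG/STD of best-of-run values of OOA/MOP
  over repeated seeded runs on the analytic benchmark suite.
* :func:`split_train_test` / :func:`cross_validate` — stratified 80/20
  split and stratified 2/3/5-fold cross-validation with the full metric
  panel per fold.
* :func:`run_ablation` — the optimizer-contribution ablation: a
  budget-matched random-search baseline, OOA- and MOP-trained capsule
  networks, plus the plain model under salt-and-pepper test noise.

Every harness is deterministic given (config, seed); run seeds are
``base_seed + run`` so paired comparisons across variants share their
random numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import capsnet, imaging, metrics
from .benchmarks import get_function, list_functions
from .capsnet import (CapsNetArchitecture, FitnessEvaluator, MarginLossParams,
                      ParameterVector, train_with_optimizer)
from .optimizer import OptimizerConfig, SearchSpace, run

__all__ = [
    "BenchmarkReport",
    "FoldPlan",
    "run_benchmark_study",
    "split_train_test",
    "make_folds",
    "cross_validate",
    "random_search",
    "run_ablation",
    "CapsNetTrainer",
    "load_config",
    "configure_logging",
]

logger = logging.getLogger("ospreycaps")


def configure_logging(log_file=None, level=logging.INFO) -> None:
    """Structured logging to stderr and optionally a file."""
    handlers = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def load_config(path) -> dict:
    """Read a YAML or JSON run-configuration file into a dict."""
    import yaml

    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


# ---------------------------------------------------------------------------
# benchmark study
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-run best values plus an AVG/STD summary.

    STD is the population standard deviation (divisor R).
    """

    runs: pd.DataFrame       # columns: function, variant, run, seed, best_value, evaluations
    dimension: int
    T: int
    N: int
    seeds: list

    @property
    def summary(self) -> pd.DataFrame:
        g = self.runs.groupby(["function", "variant"])["best_value"]
        out = g.agg(AVG="mean", STD=lambda v: float(np.std(v, ddof=0)))
        return out.reset_index()

    def write(self, csv_path, json_path=None) -> None:
        self.runs.to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {
                "dimension": self.dimension,
                "T": self.T,
                "N": self.N,
                "seeds": list(map(int, self.seeds)),
                "std_definition": "population (divisor R)",
                "summary": self.summary.to_dict(orient="records"),
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def run_benchmark_study(functions=None, variants=("mop",), R: int = 20,
                        T: int = 200, N: int = 30, base_seed: int = 0,
                        dimension: int = 10) -> BenchmarkReport:
    """R independent seeded optimizer runs per (function, variant).

    Run ``r`` uses seed ``base_seed + r`` for every function and
    variant, so cross-variant comparisons are seed-paired.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if functions is None:
        functions = list_functions()
    seeds = [base_seed + r for r in range(R)]
    rows = []
    for name in functions:
        f = get_function(name, dimension)
        space = SearchSpace.cube(f.lower_bound, f.upper_bound, dimension)
        for variant in variants:
            for r, seed in enumerate(seeds):
                cfg = OptimizerConfig(N=N, T=T, variant=variant, seed=seed)
                try:
                    res = run(f, space, cfg)
                except Exception as exc:
                    raise RuntimeError(
                        f"benchmark run failed: function={name} "
                        f"variant={variant} run={r} seed={seed}"
                    ) from exc
                rows.append({
                    "function": f.name, "variant": variant, "run": r,
                    "seed": seed, "best_value": res.best_value,
                    "evaluations": res.evaluations,
                })
    runs = pd.DataFrame(rows)
    return BenchmarkReport(runs=runs, dimension=dimension, T=T, N=N, seeds=seeds)


# ---------------------------------------------------------------------------
# splits and cross-validation
# ---------------------------------------------------------------------------

def split_train_test(images: list, fraction: float = 0.8,
                     stratified: bool = True, seed: int = 0):
    """Per-class (stratified) train/test split; disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = [im.label for im in images]
    groups = (sorted(set(labels)) if stratified else [None])
    train, test = [], []
    for lab in groups:
        idx = [i for i, l in enumerate(labels) if lab is None or l == lab]
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        idx = np.array(idx)
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train += [images[i] for i in idx[:n_train]]
        test += [images[i] for i in idx[n_train:]]
    return train, test


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment: sample index -> fold id."""

    k: int
    assignments: np.ndarray
    stratified: bool = True

    def fold_indices(self, fold: int):
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def make_folds(labels, k: int, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Seeded shuffle within class, round-robin assignment to k folds."""
    labels = list(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(labels), dtype=int)
    groups = sorted(set(labels)) if stratified else [None]
    for lab in groups:
        idx = np.array([i for i, l in enumerate(labels) if lab is None or l == lab])
        if len(idx) < k:
            raise ValueError(f"class {lab!r} has fewer samples than folds")
        rng.shuffle(idx)
        assignments[idx] = np.arange(len(idx)) % k
    return FoldPlan(k=k, assignments=assignments, stratified=stratified)


def _fold_metrics(y_true, y_pred, scores) -> dict:
    """Full metric panel; undefined entries recorded as NaN."""
    cm = metrics.ConfusionMatrix.from_predictions(y_true, y_pred, k=2)
    out = {}
    for name, fn in metrics.METRIC_FUNCTIONS.items():
        try:
            out[name] = fn(cm)
        except metrics.UndefinedMetricError:
            out[name] = float("nan")
    try:
        out["auc"] = metrics.auc(scores, y_true)
    except metrics.UndefinedMetricError:
        out["auc"] = float("nan")
    return out


def cross_validate(images: list, k: int, trainer, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold (k in {2, 3, 5}) evaluation of a trainer.

    ``trainer(train_images, seed)`` must return a predictor mapping a
    list of labeled images to ``(predicted class indices,
    positive-class scores)``.  Returns one row per fold plus a
    ``"mean"`` row averaging each metric over folds.
    """
    if k not in (2, 3, 5):
        raise ValueError("k must be one of 2, 3, 5")
    labels = [im.label for im in images]
    plan = make_folds(labels, k, seed=seed)
    class_names = sorted(set(labels))
    rows = []
    for fold in range(k):
        tr_idx, te_idx = plan.fold_indices(fold)
        predictor = trainer([images[i] for i in tr_idx], seed + fold)
        test = [images[i] for i in te_idx]
        y_true = np.array([class_names.index(im.label) for im in test])
        y_pred, scores = predictor(test)
        rows.append({"fold": fold, **_fold_metrics(y_true, y_pred, scores)})
    report = pd.DataFrame(rows)
    mean = report.drop(columns="fold").mean()
    mean["fold"] = "mean"
    return pd.concat([report, mean.to_frame().T], ignore_index=True)


# ---------------------------------------------------------------------------
# capsnet trainers and the ablation
# ---------------------------------------------------------------------------

@dataclass
class CapsNetTrainer:
    """Trains the capsule net on labeled images with a chosen optimizer.

    ``method`` is ``"mop"``, ``"ooa"`` or ``"random"`` (uniform random
    search with the same evaluation budget as the metaheuristics, which
    isolates the optimizer's contribution).
    """

    arch: CapsNetArchitecture = field(default_factory=CapsNetArchitecture)
    method: str = "mop"
    N: int = 20
    T: int = 50
    weight_bound: float = 1.0
    loss_params: MarginLossParams = field(default_factory=MarginLossParams)

    def fit(self, train_images: list, seed: int):
        X, y = imaging.dataset_arrays(train_images, self.arch.input_height,
                                      self.arch.input_width)
        if self.method in ("mop", "ooa"):
            cfg = OptimizerConfig(N=self.N, T=self.T, variant=self.method,
                                  seed=seed)
            params, result = train_with_optimizer(
                self.arch, X, y, cfg, weight_bound=self.weight_bound,
                loss_params=self.loss_params)
            best_value = result.best_value
        elif self.method == "random":
            objective = FitnessEvaluator(X, y, self.arch, self.loss_params)
            space = SearchSpace.cube(-self.weight_bound, self.weight_bound,
                                     self.arch.parameter_count)
            budget = self.N + 2 * self.N * self.T  # match the optimizer
            theta, best_value = random_search(objective, space, budget, seed)
            params = ParameterVector(theta, self.arch)
        else:
            raise ValueError(f"unknown training method {self.method!r}")
        return params, best_value

    def __call__(self, train_images: list, seed: int):
        params, _ = self.fit(train_images, seed)

        def predictor(test_images):
            X, _ = imaging.dataset_arrays(test_images, self.arch.input_height,
                                          self.arch.input_width)
            lengths = capsnet.forward_batch(X, params)
            return capsnet.predict(lengths), lengths[:, 1]

        return predictor


def random_search(objective, space: SearchSpace, budget: int, seed: int):
    """Best of ``budget`` uniform draws from the box; the baseline."""
    rng = np.random.default_rng(seed)
    best_theta, best_value = None, np.inf
    for _ in range(budget):
        theta = rng.uniform(space.lb, space.ub)
        v = float(objective(theta))
        if v < best_value:
            best_theta, best_value = theta, v
    return best_theta, best_value


def _test_accuracy(params: ParameterVector, test_images: list) -> float:
    arch = params.arch
    X, y = imaging.dataset_arrays(test_images, arch.input_height,
                                  arch.input_width)
    lengths = capsnet.forward_batch(X, params)
    return float(np.mean(capsnet.predict(lengths) == y))


def run_ablation(images: list, seeds=(0, 1, 2), noise_density: float = 0.05,
                 arch: CapsNetArchitecture | None = None, N: int = 20,
                 T: int = 50, train_fraction: float = 0.8) -> pd.DataFrame:
    """Optimizer-contribution ablation on a labeled image set.

    Per seed: a stratified split, then three trainings — budget-matched
    random search (the plain capsule net), OOA and MOP — evaluated on
    the held-out images; the plain model is additionally evaluated on
    salt-and-pepper-corrupted test images.  Returns one row per model
    with the mean test accuracy (percent), mean final training margin
    loss and mean wall time over the seed list.
    """
    if arch is None:
        arch = CapsNetArchitecture()
    acc = {m: [] for m in ("capsnet_sp", "capsnet", "capsnet_ooa", "capsnet_mop")}
    loss = {m: [] for m in ("capsnet", "capsnet_ooa", "capsnet_mop")}
    wall = {m: [] for m in ("capsnet_sp", "capsnet", "capsnet_ooa", "capsnet_mop")}
    for seed in seeds:
        train, test = split_train_test(images, train_fraction, seed=seed)
        # impulse noise applied at the network's input resolution, so the
        # corruption hits exactly what the classifier sees
        rng_noise = np.random.default_rng(seed + 7919)
        noisy_test = [
            imaging.salt_pepper(
                imaging.resize_to(im, arch.input_height, arch.input_width),
                noise_density, rng_noise)
            for im in test
        ]
        for method, row in (("random", "capsnet"), ("ooa", "capsnet_ooa"),
                            ("mop", "capsnet_mop")):
            trainer = CapsNetTrainer(arch=arch, method=method, N=N, T=T)
            t0 = time.perf_counter()
            params, best_value = trainer.fit(train, seed)
            dt = time.perf_counter() - t0
            acc[row].append(_test_accuracy(params, test))
            loss[row].append(best_value)
            wall[row].append(dt)
            if row == "capsnet":  # plain model under impulse noise
                t0 = time.perf_counter()
                acc["capsnet_sp"].append(_test_accuracy(params, noisy_test))
                wall["capsnet_sp"].append(dt + time.perf_counter() - t0)
        logger.info("ablation seed %s done", seed)
    rows = []
    for model in ("capsnet_sp", "capsnet", "capsnet_ooa", "capsnet_mop"):
        rows.append({
            "model": model,
            "accuracy": 100.0 * float(np.mean(acc[model])),
            "train_margin_loss": (float(np.mean(loss[model]))
                                  if model in loss else float("nan")),
            "wall_time": float(np.mean(wall[model])),
        })
    return pd.DataFrame(rows)
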