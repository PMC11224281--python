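"""Analytic benchmark functions for validating the osprey optimizer.

Ten classical box-constrained test functions: five unimodal (Sphere,
Schwefel 2.22, Schwefel 1.2, Schwefel 2.21, Rosenbrock) probing
exploitation, and five multimodal (Ackley, Griewank, Alpine 1, Alpine 2,
Trid) probing exploration.  Each is a pure ``R^n -> R`` objective with
per-coordinate box bounds; all except Trid attain a known minimum of 0.

Notes on two non-standard definitions kept deliberately:

* Alpine 2 is implemented as ``prod |sin(x_i) * sqrt(|x_i|)|`` so that it
  is defined on the symmetric box [-10, 10] and has minimum 0 at the
  origin (the textbook form uses ``sqrt(x_i)`` and a positive domain).
* Trid is the sum ``sum (x_i - 1)^2 + sum_{i>=2} x_i x_{i-1}`` with a
  *positive* cross term; its minimum is not 0 and it is therefore
  excluded from optimum-value checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["BenchmarkFunction", "get_function", "list_functions"]

UNIMODAL = ("sphere", "schwefel222", "schwefel12", "schwefel221", "rosenbrock")
MULTIMODAL = ("ackley", "griewank", "alpine1", "alpine2", "trid")


@dataclass(frozen=True)
class BenchmarkFunction:
    """A box-constrained scalar test objective.

    Attributes
    ----------
    name : canonical registry key, e.g. ``"sphere"``.
    dimension : number of coordinates ``n``.
    lower_bound, upper_bound : per-coordinate box bounds (scalar, the box
        is a hypercube for every registered function).
    known_optimum_value : global minimum value, or ``None`` when unknown
        on the registered domain (Trid).
    modality : ``"unimodal"`` or ``"multimodal"``.
    """

    name: str
    dimension: int
    lower_bound: float
    upper_bound: float
    known_optimum_value: float | None
    modality: str
    _fn: Callable[[np.ndarray], float] = field(repr=False, compare=False, default=None)

    def evaluate(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(
                f"{self.name}: expected vector of length {self.dimension}, "
                f"got shape {x.shape}"
            )
        return float(self._fn(x))

    __call__ = evaluate


def _sphere(x):
    return np.sum(x**2)


def _schwefel222(x):
    a = np.abs(x)
    return np.sum(a) + np.prod(a)


def _schwefel12(x):
    return np.sum(np.cumsum(x) ** 2)


def _schwefel221(x):
    return np.max(np.abs(x))


def _rosenbrock(x):
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _ackley(x):
    n = x.size
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return np.sum(x**2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0


def _alpine1(x):
    return np.sum(np.abs(x * np.sin(x) + 0.1 * x))


def _alpine2(x):
    return np.prod(np.abs(np.sin(x) * np.sqrt(np.abs(x))))


def _trid(x):
    return np.sum((x - 1.0) ** 2) + np.sum(x[1:] * x[:-1])


# name -> (fn, lb, ub, optimum value, modality); aliases map F1..F10.
_REGISTRY = {
    "sphere": (_sphere, -100.0, 100.0, 0.0, "unimodal"),
    "schwefel222": (_schwefel222, -10.0, 10.0, 0.0, "unimodal"),
    "schwefel12": (_schwefel12, -100.0, 100.0, 0.0, "unimodal"),
    "schwefel221": (_schwefel221, -100.0, 100.0, 0.0, "unimodal"),
    "rosenbrock": (_rosenbrock, -30.0, 30.0, 0.0, "unimodal"),
    "ackley": (_ackley, -32.0, 32.0, 0.0, "multimodal"),
    "griewank": (_griewank, -600.0, 600.0, 0.0, "multimodal"),
    "alpine1": (_alpine1, -10.0, 10.0, 0.0, "multimodal"),
    "alpine2": (_alpine2, -10.0, 10.0, 0.0, "multimodal"),
    "trid": (_trid, -100.0, 100.0, None, "multimodal"),
}

_ALIASES = {f"f{i + 1}": name for i, name in enumerate(UNIMODAL + MULTIMODAL)}
_ALIASES.update(
    {
        "schwefel2.22": "schwefel222",
        "schwefel1.2": "schwefel12",
        "schwefel2.21": "schwefel221",
    }
)


def list_functions() -> list[str]:
    """Canonical names in F1..F10 order."""
    return list(UNIMODAL + MULTIMODAL)


def get_function(name: str, dimension: int = 10) -> BenchmarkFunction:
    """Look up a benchmark by name (case-insensitive; F1..F10 accepted).

    Parameters
    ----------
    name : registry key, alias (``"F1"``) or dotted form (``"Schwefel2.22"``).
    dimension : problem dimensionality, >= 2.
    """
    key = name.strip().lower().replace(" ", "").replace("_", "")
    key = _ALIASES.get(key, key)
    if key not in _REGISTRY:
        raise KeyError(f"no such benchmark: {name!r}")
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    fn, lb, ub, opt, modality = _REGISTRY[key]
    return BenchmarkFunction(
        name=key,
        dimension=dimension,
        lower_bound=lb,
        upper_bound=ub,
        known_optimum_value=opt,
        modality=modality,
        _fn=fn,
    )
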