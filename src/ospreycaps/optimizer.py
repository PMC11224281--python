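"""Osprey optimization algorithm (OOA) and its modified variant (MOP).

The osprey optimizer is a population metaheuristic for box-constrained
minimisation.  Each of ``N`` ospreys holds a position ``Y_i`` in the box
``[lb, ub] ⊂ R^m``.  Every iteration applies two moves per member, each
followed by greedy (strict-improvement) acceptance:

* *global phase* (hunting): the member picks a random "fish" ``SA_i``
  from the set of strictly better members plus the global best, and
  moves ``Y_i + r ⊙ (SA_i − I ⊙ Y_i)`` with ``r ∈ [0,1]^m`` and random
  integers ``I ∈ {1,2}^m``;
* *local phase* (carrying the fish): an additive perturbation
  ``(lb + r ⊙ (ub − lb)) / t`` whose envelope shrinks as ``1/t``.

The modified variant (MOP) changes two things:

* the uniform ``r`` draws of both phases are replaced by iterates of the
  sinusoidal chaos map ``p ← a·p²·sin(πp)``, one independent stream per
  (member, coordinate);
* after the two phase moves, each member attempts a third update —
  multiplicative Gaussian mutation ``Y ← Y ⊙ (1 + k·g)`` of its current
  position, with ``g ~ N(0,1)``, a randomly decreasing scale
  ``k = u·(1 − t/T)``, ``u ~ U(0,1)``, and the same greedy acceptance.

All randomness derives from a single integer seed split into named
substreams, so OOA and MOP runs with the same seed share their initial
population (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "Population",
    "OptimizerConfig",
    "OptimizationResult",
    "initialize_population",
    "fish_set",
    "phase1_update",
    "phase2_update",
    "clip_to_bounds",
    "greedy_select",
    "sinusoidal_chaos_stream",
    "gaussian_mutation",
    "run",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained continuous domain ``[lb, ub] ⊂ R^m``."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D arrays of equal length")
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def m(self) -> int:
        return self.lb.size

    @classmethod
    def cube(cls, lower: float, upper: float, m: int) -> "SearchSpace":
        return cls(np.full(m, lower), np.full(m, upper))


@dataclass
class Population:
    """Osprey positions ``Y`` (N×m) with fitness vector ``A`` and best tracking."""

    Y: np.ndarray
    A: np.ndarray

    @property
    def best_index(self) -> int:
        # lowest index on ties
        return int(np.argmin(self.A))

    @property
    def best_value(self) -> float:
        return float(self.A[self.best_index])

    @property
    def size(self) -> int:
        return self.Y.shape[0]


@dataclass(frozen=True)
class OptimizerConfig:
    """Run configuration.

    ``chaos_a``, ``chaos_p0`` and ``chaos_burn_in`` only matter for the
    ``"mop"`` variant; ``a = 2.3`` keeps the sinusoidal map's iterates
    inside (0, 1).  ``mutation`` toggles the Gaussian-mutation step of
    the modified variant (useful for ablating the two modifications
    separately); it has no effect under ``"ooa"``.
    """

    N: int = 30
    T: int = 200
    variant: str = "mop"
    seed: int = 0
    chaos_a: float = 2.3
    chaos_p0: float = 0.7
    chaos_burn_in: int = 100
    mutation: bool = True

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.T < 1:
            raise ValueError("iteration count T must be >= 1")
        if self.variant not in ("ooa", "mop"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.chaos_a <= 4.0:
            raise ValueError("chaos_a must lie in (0, 4]")
        if not 0.0 < self.chaos_p0 < 1.0:
            raise ValueError("chaos_p0 must lie strictly inside (0, 1)")
        if self.chaos_burn_in < 0:
            raise ValueError("chaos_burn_in must be non-negative")


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_value: float
    history: np.ndarray  # best-so-far value after each iteration, length T
    evaluations: int


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def initialize_population(space, N, rng, objective) -> Population:
    """Uniform positions ``Y_ij = lb_j + r_ij (ub_j − lb_j)`` with fitness."""
    if N < 2:
        raise ValueError("population size N must be >= 2")
    r = rng.random((N, space.m))
    Y = space.lb + r * (space.ub - space.lb)
    A = np.array([_checked_eval(objective, y) for y in Y])
    return Population(Y=Y, A=A)


def fish_set(pop: Population, i: int) -> np.ndarray:
    """Indices of strictly better members, united with the best index.

    Never empty: for the best member itself it is ``{best_index}``.
    """
    better = np.flatnonzero(pop.A < pop.A[i])
    return np.union1d(better, [pop.best_index]).astype(int)


def phase1_update(pop: Population, i: int, sa: np.ndarray, r: np.ndarray,
                  I: np.ndarray) -> np.ndarray:
    """Global-phase candidate ``Y_i + r ⊙ (SA − I ⊙ Y_i)`` (unclipped)."""
    return pop.Y[i] + r * (sa - I * pop.Y[i])


def phase2_update(pop: Population, i: int, r: np.ndarray, t: int,
                  space: SearchSpace) -> np.ndarray:
    """Local-phase candidate ``Y_i + (lb + r ⊙ (ub − lb)) / t`` (unclipped)."""
    if t < 1:
        raise ValueError("iteration counter t starts at 1")
    return pop.Y[i] + (space.lb + r * (space.ub - space.lb)) / t


def clip_to_bounds(x: np.ndarray, space: SearchSpace) -> np.ndarray:
    return np.clip(x, space.lb, space.ub)


def greedy_select(pop: Population, i: int, candidate: np.ndarray,
                  candidate_value: float) -> bool:
    """Replace member ``i`` iff the candidate strictly improves; in place."""
    if candidate_value < pop.A[i]:
        pop.Y[i] = candidate
        pop.A[i] = candidate_value
        return True
    return False


def sinusoidal_chaos_stream(p0: float, a: float = 2.3, length: int = 1,
                            burn_in: int = 0) -> np.ndarray:
    """Iterates of the sinusoidal chaos map ``p ← a·p²·sin(πp)``.

    Returns ``length`` values following ``burn_in`` discarded transients.
    The fixed points 0 and 1 are rejected as seeds.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("degenerate chaos seed: p0 must lie strictly in (0, 1)")
    out = np.empty(length)
    p = float(p0)
    for _ in range(burn_in):
        p = a * p * p * np.sin(np.pi * p)
    for k in range(length):
        p = a * p * p * np.sin(np.pi * p)
        out[k] = p
    return out


def gaussian_mutation(candidate: np.ndarray, k: float, rng) -> np.ndarray:
    """Multiplicative Gaussian mutation ``Y ⊙ (1 + k·g)``, ``g ~ N(0,1)``.

    Per-coordinate independent standard-normal draws; ``k = 0`` is the
    identity, as is any ``k`` on an all-zero candidate.
    """
    g = rng.standard_normal(candidate.shape)
    return candidate * (1.0 + k * g)


# ---------------------------------------------------------------------------
# chaos bookkeeping for the modified variant
# ---------------------------------------------------------------------------

class _ChaosMatrix:
    """One sinusoidal chaos stream per (member, coordinate).

    The N×m initial states are successive iterates of a single master
    stream seeded at ``p0`` (so the whole construction is deterministic
    in ``p0``), after which each stream is burnt in and advanced one map
    step per draw.
    """

    def __init__(self, N: int, m: int, a: float, p0: float, burn_in: int):
        self.a = a
        master = sinusoidal_chaos_stream(p0, a, length=N * m, burn_in=burn_in)
        P = master.reshape(N, m)
        for _ in range(burn_in):
            P = a * P * P * np.sin(np.pi * P)
        self.P = P

    def draw(self, i: int) -> np.ndarray:
        """Advance member ``i``'s streams one step; return the new iterates."""
        p = self.P[i]
        p = self.a * p * p * np.sin(np.pi * p)
        self.P[i] = p
        return p.copy()


def _checked_eval(objective, y: np.ndarray) -> float:
    v = float(objective(y))
    if not np.isfinite(v):
        raise ValueError(f"objective returned non-finite value {v} at {y!r}")
    return v


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run(objective, space: SearchSpace, config: OptimizerConfig) -> OptimizationResult:
    """Minimise ``objective`` over ``space`` with OOA or MOP.

    Each iteration sweeps the population once; every member proposes a
    global-phase candidate, then a local-phase candidate, and (under
    MOP with mutation enabled) finally a Gaussian-mutated copy of its
    current position — each clipped to the box and accepted only on
    strict improvement.  The best-so-far value is recorded after every
    iteration, so the returned history is non-increasing.
    """
    ss = np.random.SeedSequence(config.seed)
    s_init, s_fish, s_I, s_mut, s_r = ss.spawn(5)
    rng_init = np.random.default_rng(s_init)
    rng_fish = np.random.default_rng(s_fish)
    rng_I = np.random.default_rng(s_I)
    rng_mut = np.random.default_rng(s_mut)
    rng_r = np.random.default_rng(s_r)  # uniform r for the ooa variant

    mop = config.variant == "mop"
    chaos = (
        _ChaosMatrix(config.N, space.m, config.chaos_a, config.chaos_p0,
                     config.chaos_burn_in)
        if mop
        else None
    )

    pop = initialize_population(space, config.N, rng_init, objective)
    evaluations = pop.size
    best_idx = pop.best_index
    best_value = pop.best_value
    best_position = pop.Y[best_idx].copy()

    history = np.empty(config.T)
    for t in range(1, config.T + 1):
        for i in range(pop.size):
            # phase 1: locate and hunt the fish (global search)
            candidates = fish_set(pop, i)
            sa = pop.Y[candidates[rng_fish.integers(candidates.size)]]
            r1 = chaos.draw(i) if mop else rng_r.random(space.m)
            I = rng_I.integers(1, 3, size=space.m)
            cand = clip_to_bounds(phase1_update(pop, i, sa, r1, I), space)
            v = _checked_eval(objective, cand)
            evaluations += 1
            greedy_select(pop, i, cand, v)

            # phase 2: carry the fish to a suitable position (local search)
            r2 = chaos.draw(i) if mop else rng_r.random(space.m)
            cand = clip_to_bounds(phase2_update(pop, i, r2, t, space), space)
            v = _checked_eval(objective, cand)
            evaluations += 1
            greedy_select(pop, i, cand, v)

            # modified variant: multiplicative Gaussian mutation of the
            # member's position, with a randomly decreasing scale
            if mop and config.mutation:
                k_mut = rng_mut.random() * (1.0 - t / config.T)
                cand = gaussian_mutation(pop.Y[i], k_mut, rng_mut)
                cand = clip_to_bounds(cand, space)
                v = _checked_eval(objective, cand)
                evaluations += 1
                greedy_select(pop, i, cand, v)

        if pop.best_value < best_value:
            best_idx = pop.best_index
            best_value = pop.best_value
            best_position = pop.Y[best_idx].copy()
        history[t - 1] = best_value

    return OptimizationResult(
        best_position=best_position,
        best_value=best_value,
        history=history,
        evaluations=evaluations,
    )
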