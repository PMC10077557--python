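"""Artificial bee colony (ABC) optimization and its improved adaptive variant.

The colony maintains ``N`` candidate solutions ("honey sources") in a bounded
``D``-dimensional search space and cycles through three phases:

* employed bees — one local neighbourhood move per source,
* onlooker bees — fitness-proportional (roulette-wheel) re-search of good
  sources, ``N`` moves per cycle,
* scout bees — random re-initialization of sources that failed to improve for
  more than ``limit`` consecutive trials.

The improved adaptive variant ("iaabc") modifies the neighbourhood move in two
ways: an inertia weight that decays linearly from ``omega_max`` to
``omega_min`` over the run multiplies the position term of the move (so the
effective step contracts generation by generation), and a Levy-flight mutation
factor riding on the neighbour difference occasionally takes long heavy-tailed
jumps so the colony can escape local minima. With the inertia weight pinned at
1 and the Levy amplitude at 0 the variant is step-for-step identical to the
plain colony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "SearchSpace",
    "ColonyConfig",
    "HoneySource",
    "OptResult",
    "init_sources",
    "fitness_of",
    "selection_probabilities",
    "inertia_weight",
    "mantegna_sigma",
    "levy_step",
    "candidate_basic",
    "candidate_iaabc",
    "optimize",
    "griewank",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of feasible solutions.

    Parameters
    ----------
    dim : int
        Number of decision variables ``D``.
    lower, upper : array-like of shape (dim,)
        Per-dimension bounds; ``lower[j] <= upper[j]``.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if self.dim <= 0:
            raise ValueError("dim must be a positive integer")
        if lower.shape != (self.dim,) or upper.shape != (self.dim,):
            raise ValueError("lower/upper must have shape (dim,)")
        if np.any(lower > upper):
            raise ValueError("degenerate space: lower bound exceeds upper bound")

    @classmethod
    def cube(cls, dim: int, lower: float, upper: float) -> "SearchSpace":
        """Hypercube ``[lower, upper]^dim``."""
        return cls(dim, np.full(dim, float(lower)), np.full(dim, float(upper)))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class ColonyConfig:
    """Colony hyperparameters.

    Defaults follow the reference setting for the Griewank benchmark and the
    network-training application: 35 sources, 2000 cycles, retention limit 100,
    inertia bounds [0.15, 1.05], objective tolerance 1e-6.
    """

    n_sources: int = 35
    max_cycles: int = 2000
    limit: int = 100
    omega_min: float = 0.15
    omega_max: float = 1.05
    fitness_tol: float = 1e-6
    levy_beta: float = 1.5
    levy_scale: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        # equality allowed so omega can be pinned (e.g. omega == 1 reduces the
        # adaptive variant to the plain colony)
        if not (0 < self.omega_min <= self.omega_max):
            raise ValueError("require 0 < omega_min <= omega_max")
        if not (1 < self.levy_beta <= 2):
            raise ValueError("levy_beta must be in (1, 2]")


@dataclass
class HoneySource:
    """One candidate solution with its objective value, fitness and trial count."""

    position: np.ndarray
    objective: float
    fitness: float
    trials: int = 0


@dataclass
class OptResult:
    """Outcome of one optimization run."""

    best_position: np.ndarray
    best_objective: float
    trace: np.ndarray  # best-so-far objective after each cycle
    cycles_run: int


Objective = Callable[[np.ndarray], float]


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def fitness_of(objective_value: float) -> float:
    """Map an objective value to a positive fitness.

    ``fit = 1/(1+f)`` for ``f >= 0`` and ``1 + |f|`` otherwise — strictly
    positive and strictly decreasing in the objective.
    """
    f = float(objective_value)
    if not math.isfinite(f):
        raise ValueError(f"objective value must be finite, got {f!r}")
    return 1.0 / (1.0 + f) if f >= 0 else 1.0 + abs(f)


def _evaluate(objective: Objective, x: np.ndarray, where: str) -> tuple[float, float]:
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError(f"objective returned non-finite value {f!r} ({where})")
    return f, fitness_of(f)


def init_sources(
    objective: Objective,
    space: SearchSpace,
    config: ColonyConfig,
    rng: np.random.Generator,
) -> list[HoneySource]:
    """Draw ``N`` sources uniformly inside the box and evaluate them."""
    sources = []
    for i in range(config.n_sources):
        pos = space.lower + rng.random(space.dim) * (space.upper - space.lower)
        f, fit = _evaluate(objective, pos, f"initializing source {i}")
        sources.append(HoneySource(pos, f, fit, 0))
    return sources


def selection_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Roulette-wheel probabilities proportional to fitness."""
    fit = np.asarray(fitnesses, dtype=float)
    if fit.size == 0:
        raise ValueError("empty fitness vector")
    if np.any(fit <= 0):
        raise ValueError("fitnesses must be strictly positive")
    return fit / fit.sum()


def inertia_weight(cycle: int, config: ColonyConfig) -> float:
    """Linearly decayed inertia weight: omega_max at cycle 0, omega_min at max_cycles."""
    if not 0 <= cycle <= config.max_cycles:
        raise ValueError(f"cycle {cycle} outside [0, {config.max_cycles}]")
    frac = cycle / config.max_cycles
    return config.omega_max - (config.omega_max - config.omega_min) * frac


def mantegna_sigma(beta: float) -> float:
    """Scale of the numerator Gaussian in Mantegna's Levy-step algorithm."""
    if not (1 < beta <= 2):
        raise ValueError("beta must be in (1, 2]")
    num = _gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = _gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return float((num / den) ** (1 / beta))


def levy_step(rng: np.random.Generator, beta: float = 1.5) -> float:
    """One draw from a symmetric Levy-stable step via Mantegna's algorithm.

    ``L = u / |v|^(1/beta)`` with ``u ~ N(0, sigma_u^2)``, ``v ~ N(0, 1)``;
    heavy-tailed, so occasional draws are far larger than any Gaussian step.
    """
    sigma = mantegna_sigma(beta)
    u = rng.normal(0.0, sigma)
    v = rng.normal(0.0, 1.0)
    return float(u / abs(v) ** (1 / beta))


# ---------------------------------------------------------------------------
# neighbourhood moves
# ---------------------------------------------------------------------------

def candidate_basic(
    source: HoneySource,
    other: HoneySource,
    j: int,
    space: SearchSpace,
    rng: np.random.Generator | None = None,
    r: float | None = None,
) -> np.ndarray:
    """Plain neighbourhood move: ``v_ij = x_ij + r (x_ij - x_kj)``, r ~ U[-1, 1].

    Only dimension ``j`` changes; the result is clamped to the box.
    """
    if source is other:
        raise ValueError("reference source k must differ from source i")
    if r is None:
        if rng is None:
            raise ValueError("either rng or r must be given")
        r = rng.uniform(-1.0, 1.0)
    pos = np.array(source.position, dtype=float)
    pos[j] = pos[j] + r * (pos[j] - other.position[j])
    pos[j] = min(max(pos[j], space.lower[j]), space.upper[j])
    return pos


def candidate_iaabc(
    source: HoneySource,
    other: HoneySource,
    j: int,
    omega: float,
    space: SearchSpace,
    config: ColonyConfig,
    rng: np.random.Generator | None = None,
    r: float | None = None,
) -> np.ndarray:
    """Adaptive move: ``v_ij = omega x_ij + (r + levy_scale L_j) (x_ij - x_kj)``.

    The inertia weight multiplies the position term, so as omega decays below
    1 the colony contracts its coordinates cycle by cycle and the effective
    step size shrinks adaptively; at ``omega == 1`` the move is exactly the
    plain one. The Levy factor rides on the neighbour difference: its typical
    magnitude tracks the colony spread (so late-stage refinement is not
    drowned in noise) while its heavy tail still produces occasional jumps of
    many times the spread that escape local minima. With ``levy_scale == 0``
    no Levy draw is consumed and the move reduces to the plain one with
    inertia-weighted position.
    """
    if source is other:
        raise ValueError("reference source k must differ from source i")
    if not (config.omega_min <= omega <= config.omega_max):
        raise ValueError(f"omega {omega} outside [{config.omega_min}, {config.omega_max}]")
    if r is None:
        if rng is None:
            raise ValueError("either rng or r must be given")
        r = rng.uniform(-1.0, 1.0)
    coef = r
    if config.levy_scale != 0.0:
        if rng is None:
            raise ValueError("rng required when levy_scale != 0")
        coef += config.levy_scale * levy_step(rng, config.levy_beta)
    pos = np.array(source.position, dtype=float)
    pos[j] = omega * pos[j] + coef * (pos[j] - other.position[j])
    pos[j] = min(max(pos[j], space.lower[j]), space.upper[j])
    return pos


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _try_move(
    i: int,
    sources: list[HoneySource],
    variant: str,
    omega: float,
    space: SearchSpace,
    config: ColonyConfig,
    rng: np.random.Generator,
    objective: Objective,
    cycle: int,
) -> None:
    """One employed/onlooker move on source ``i`` with greedy replacement."""
    src = sources[i]
    j = int(rng.integers(space.dim))
    k = int(rng.integers(len(sources) - 1))
    if k >= i:
        k += 1
    if variant == "abc":
        pos = candidate_basic(src, sources[k], j, space, rng)
    else:
        pos = candidate_iaabc(src, sources[k], j, omega, space, config, rng)
    f, fit = _evaluate(objective, pos, f"cycle {cycle}, source {i}")
    if fit > src.fitness:  # ties keep the incumbent
        sources[i] = HoneySource(pos, f, fit, 0)
    else:
        src.trials += 1


def optimize(
    objective: Objective,
    space: SearchSpace,
    config: ColonyConfig,
    variant: str = "iaabc",
    rng: np.random.Generator | None = None,
) -> OptResult:
    """Run the colony until the objective tolerance or the cycle budget is hit.

    Parameters
    ----------
    objective : callable
        Function of a length-``D`` vector returning a finite scalar to minimize.
    variant : {"abc", "iaabc"}
        Plain colony or the adaptive/Levy-mutated one.

    Returns
    -------
    OptResult
        Best-so-far solution, its objective, the per-cycle best-objective trace
        (monotone non-increasing) and the number of cycles run.
    """
    if variant not in ("abc", "iaabc"):
        raise ValueError(f"unknown variant {variant!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    sources = init_sources(objective, space, config, rng)
    best = min(sources, key=lambda s: s.objective)
    best_pos, best_obj = best.position.copy(), best.objective

    trace: list[float] = []
    cycles_run = 0
    for cycle in range(1, config.max_cycles + 1):
        cycles_run = cycle
        omega = inertia_weight(cycle - 1, config)

        # employed phase: one move per source
        for i in range(len(sources)):
            _try_move(i, sources, variant, omega, space, config, rng, objective, cycle)

        # onlooker phase: N fitness-weighted moves
        probs = selection_probabilities([s.fitness for s in sources])
        for _ in range(len(sources)):
            i = int(rng.choice(len(sources), p=probs))
            _try_move(i, sources, variant, omega, space, config, rng, objective, cycle)

        # scout phase: abandon stagnant sources
        for i, src in enumerate(sources):
            if src.trials > config.limit:
                pos = space.lower + rng.random(space.dim) * (space.upper - space.lower)
                f, fit = _evaluate(objective, pos, f"cycle {cycle}, scout {i}")
                sources[i] = HoneySource(pos, f, fit, 0)

        # best-so-far memory survives scouting
        cand = min(sources, key=lambda s: s.objective)
        if cand.objective < best_obj:
            best_pos, best_obj = cand.position.copy(), cand.objective
        trace.append(best_obj)

        if best_obj <= config.fitness_tol:
            break

    return OptResult(best_pos, best_obj, np.asarray(trace), cycles_run)


# ---------------------------------------------------------------------------
# benchmark objective
# ---------------------------------------------------------------------------

def griewank(x: Sequence[float]) -> float:
    """Griewank benchmark: ``1 + sum(x_i^2)/4000 - prod(cos(x_i/sqrt(i)))``.

    Multimodal with a single global minimum ``f(0) = 0``; the customary domain
    is ``x_i in [-600, 600]``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("griewank requires a non-empty vector")
    idx = np.arange(1, arr.size + 1, dtype=float)
    return float(1.0 + np.sum(arr * arr) / 4000.0 - np.prod(np.cos(arr / np.sqrt(idx))))
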