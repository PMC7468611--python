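"""The SAMA search: a self-adaptive memetic algorithm over SNP pairs.

One generation applies, to every individual x_i (an unordered SNP pair):

1. hybrid crossover (HC) against the current global best pair,
2. distributed breeder mutation (DBM), an index perturbation of
   +/- round(range * delta) with delta biased toward small values,
3. with per-individual probability p_z, a self-adaptive local search
   (SLS): hill climbing over DBM proposals, accepting moves of equal or
   better chi-square fitness; p_z resets to 1 on improvement and decays
   by the switch parameter xi otherwise,
4. elitist selection (ES): the offspring replaces x_i only on a strict
   fitness improvement.

The global best is refreshed after each generation's selection, so all
individuals of a generation cross against the same best. All randomness
flows from one seeded numpy Generator; pair fitness is memoized per run.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .association import FitnessEvaluator, SnpPair
from .io import GenotypeDataset

__all__ = [
    "SamaParams",
    "MutationDelta",
    "SamaResult",
    "initialize_population",
    "hybrid_crossover",
    "breeder_delta",
    "breeder_mutation",
    "local_search_step",
    "sls_update_prob",
    "elitist_selection",
    "run_sama",
]

_DELTA_WEIGHTS = 0.5 ** np.arange(1, 16)  # 2^-1 .. 2^-15
_ALPHA_P = 1.0 / 16.0


@dataclass(frozen=True)
class SamaParams:
    """Tunable parameters of the search.

    Defaults follow the published configuration: population M = 500,
    crossover probabilities p_c1 = p_c2 = 0.8, switch parameter xi = 0.5,
    mutation range 0.1 * L.
    """

    M: int = 500
    p_c1: float = 0.8
    p_c2: float = 0.8
    xi: float = 0.5
    range_factor: float = 0.1
    max_iterations: int = 50
    max_ls_steps: int = 10
    seed: int = 0
    shared_mutation_offset: bool = False  # one delta/sign for both coordinates

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("population size M must be >= 2")
        if not (0 <= self.p_c1 <= 1 and 0 <= self.p_c2 <= 1):
            raise ValueError("crossover probabilities must lie in [0, 1]")
        if not 0 < self.xi < 1:
            raise ValueError("switch parameter xi must lie in (0, 1)")
        if self.range_factor <= 0:
            raise ValueError("range_factor must be positive")
        if self.max_iterations < 0 or self.max_ls_steps < 0:
            raise ValueError("iteration caps must be non-negative")


@dataclass(frozen=True)
class MutationDelta:
    """A breeder-mutation step size delta = sum alpha_i 2^-i with its sign."""

    delta: float
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not 0 <= self.delta <= 1 - 2**-15:
            raise ValueError(f"delta out of range: {self.delta}")


@dataclass
class SamaResult:
    """Outcome of one run: best pair found plus per-generation trace."""

    best: SnpPair
    best_fitness: float
    history: List[float]           # best fitness after init and each generation
    best_history: List[SnpPair]    # best pair at the same checkpoints
    evaluations: int               # distinct chi-square evaluations
    calls: int                     # total fitness requests (incl. cache hits)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _random_index(rng: np.random.Generator, L: int) -> int:
    """ceil(u * L) for u ~ Uniform(0, 1): uniform on {1..L} (u=0 maps to 1)."""
    return max(1, math.ceil(rng.random() * L))


def initialize_population(M: int, L: int, rng: np.random.Generator) -> List[SnpPair]:
    """M random pairs with both indices uniform on {1..L}, r_p != r_q."""
    if L < 2:
        raise ValueError("need L >= 2 to form pairs")
    population = []
    for _ in range(M):
        r_p = _random_index(rng, L)
        r_q = _random_index(rng, L)
        while r_q == r_p:
            r_q = _random_index(rng, L)
        population.append(SnpPair(r_p, r_q))
    return population


def hybrid_crossover(
    x_i: SnpPair,
    x_best: SnpPair,
    p_c1: float,
    p_c2: float,
    rng: np.random.Generator,
    L: Optional[int] = None,
) -> SnpPair:
    """Cross an individual with the current best, coordinate by coordinate.

    Draws r1, r2 ~ U(0,1); r1 < p_c1 replaces the first SNP with the best's
    first, r2 < p_c2 replaces the second with the best's second; both hits
    yield a copy of the best. A degenerate result (equal coordinates)
    redraws the second coordinate uniformly on {1..L}; L defaults to the
    larger index in play.
    """
    r1 = rng.random()
    r2 = rng.random()
    r_p = x_best.r_p if r1 < p_c1 else x_i.r_p
    r_q = x_best.r_q if r2 < p_c2 else x_i.r_q
    if L is None:
        L = max(x_i.r_p, x_i.r_q, x_best.r_p, x_best.r_q)
    while r_q == r_p:
        r_q = _random_index(rng, L)
    return SnpPair(r_p, r_q)


def breeder_delta(rng: np.random.Generator) -> MutationDelta:
    """Draw delta = sum_{i=1..15} alpha_i 2^-i and a fair-coin sign.

    Each alpha_i is 1 with probability 1/16 independently, so small deltas
    dominate; the finest step is 2^-15, the largest 1 - 2^-15.
    """
    alphas = rng.random(15) < _ALPHA_P
    delta = float(_DELTA_WEIGHTS[alphas].sum())
    sign = 1 if rng.random() < 0.5 else -1
    return MutationDelta(delta, sign)


def breeder_mutation(
    y: SnpPair,
    L: int,
    range_factor: float,
    rng: np.random.Generator,
    shared_offset: bool = False,
) -> SnpPair:
    """Perturb each coordinate by +/- ceil(range * delta), range = 0.1 L.

    Each coordinate gets its own delta and sign draw (``shared_offset``
    applies one draw to both). Offsets round upward so the smallest
    non-zero delta still moves one index — the advertised minimum step of
    range * 2^-15 precision. A mutant pushed outside [1, L] is
    reinitialized wholesale (both coordinates uniform), the search's only
    global restart; a degenerate pair redraws the second coordinate.
    """
    rng_range = round(range_factor * L)
    d1 = breeder_delta(rng)
    d2 = d1 if shared_offset else breeder_delta(rng)
    r_p = y.r_p + d1.sign * math.ceil(rng_range * d1.delta)
    r_q = y.r_q + d2.sign * math.ceil(rng_range * d2.delta)
    if not (1 <= r_p <= L and 1 <= r_q <= L):
        r_p = _random_index(rng, L)
        r_q = _random_index(rng, L)
    while r_q == r_p:
        r_q = _random_index(rng, L)
    return SnpPair(r_p, r_q)


def local_search_step(
    z: SnpPair,
    fitness: Callable[[SnpPair], float],
    L: int,
    params: SamaParams,
    rng: np.random.Generator,
) -> SnpPair:
    """Hill climb from z over breeder-mutation proposals.

    Proposes up to ``max_ls_steps`` neighbours, moving whenever the
    candidate's fitness is greater than or equal to the current one.
    """
    current = z
    current_fit = fitness(z)
    for _ in range(params.max_ls_steps):
        candidate = breeder_mutation(
            current, L, params.range_factor, rng, params.shared_mutation_offset
        )
        cand_fit = fitness(candidate)
        if cand_fit >= current_fit:
            current, current_fit = candidate, cand_fit
    return current


def sls_update_prob(p_z: float, improved: bool, xi: float) -> float:
    """Reset the local-search probability to 1 on improvement, decay by xi otherwise."""
    if not 0 < p_z <= 1:
        raise ValueError(f"p_z must lie in (0, 1], got {p_z}")
    if not 0 < xi < 1:
        raise ValueError(f"xi must lie in (0, 1), got {xi}")
    return 1.0 if improved else xi * p_z


def elitist_selection(
    x: SnpPair, w: SnpPair, fitness: Callable[[SnpPair], float]
) -> SnpPair:
    """Keep the incumbent x unless the offspring w is strictly fitter."""
    return w if fitness(w) > fitness(x) else x


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _best_of(population: List[SnpPair], fitness: Callable[[SnpPair], float]) -> Tuple[SnpPair, float]:
    """Argmax fitness; ties broken by lexicographic pair order (determinism)."""
    best, best_fit = None, -math.inf
    for pair in sorted(population, key=lambda p: p.key):
        f = fitness(pair)
        if f > best_fit:
            best, best_fit = pair, f
    return best, best_fit


def run_sama(
    dataset: GenotypeDataset,
    params: SamaParams,
    log_path: Optional[os.PathLike | str] = None,
) -> SamaResult:
    """Run the full memetic search on one dataset.

    Runs exactly ``params.max_iterations`` generations and returns the best
    pair seen, its chi-square fitness, and the per-generation trace. With
    ``log_path`` set, appends one JSON line per generation (generation
    index, best pair, best fitness, evaluation count).
    """
    rng = np.random.default_rng(params.seed)
    fitness = FitnessEvaluator(dataset)
    L = dataset.L

    population = initialize_population(params.M, L, rng)
    p_z = [1.0] * params.M
    best, best_fitness = _best_of(population, fitness)
    history = [best_fitness]
    best_history = [best]

    log_fh = open(log_path, "a", encoding="ascii") if log_path else None
    try:
        for generation in range(1, params.max_iterations + 1):
            for i in range(params.M):
                x_i = population[i]
                y_i = hybrid_crossover(x_i, best, params.p_c1, params.p_c2, rng, L)
                z_i = breeder_mutation(
                    y_i, L, params.range_factor, rng, params.shared_mutation_offset
                )
                if rng.random() < p_z[i]:
                    w_i = local_search_step(z_i, fitness, L, params, rng)
                    improved = fitness(w_i) > fitness(z_i)
                    p_z[i] = sls_update_prob(p_z[i], improved, params.xi)
                else:
                    w_i = z_i
                population[i] = elitist_selection(x_i, w_i, fitness)

            gen_best, gen_best_fit = _best_of(population, fitness)
            if gen_best_fit > best_fitness:
                best, best_fitness = gen_best, gen_best_fit
            history.append(best_fitness)
            best_history.append(best)
            if log_fh is not None:
                log_fh.write(
                    json.dumps(
                        {
                            "generation": generation,
                            "best": list(best.key),
                            "best_fitness": best_fitness,
                            "evaluations": fitness.evaluations,
                        }
                    )
                    + "\n"
                )
    finally:
        if log_fh is not None:
            log_fh.close()

    return SamaResult(
        best=best,
        best_fitness=best_fitness,
        history=history,
        best_history=best_history,
        evaluations=fitness.evaluations,
        calls=fitness.calls,
    )
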