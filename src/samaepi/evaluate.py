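"""Brute-force oracle and detection-power experiments.

Power is the fraction of replicate datasets on which the search returns
exactly the embedded causal pair: Power = #T / #G, with #G replicates per
penetrance model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .association import FitnessEvaluator, SnpPair
from .core import SamaParams, SamaResult, run_sama
from .io import GenotypeDataset
from .simulate import SimulationSpec, replicate_seed, simulate_batch

__all__ = [
    "PowerResult",
    "exhaustive_best_pair",
    "detection_success",
    "power_experiment",
]

DEFAULT_EXHAUSTIVE_CAP = 500_000  # pair budget for the brute-force scan


@dataclass
class ReplicateRecord:
    """Outcome of the search on one replicate dataset."""

    dataset_seed: int
    found: SnpPair
    truth: Tuple[int, int]
    best_fitness: float
    evaluations: int
    success: bool


@dataclass
class PowerResult:
    """Detection power over a batch of replicates: #T successes of #G."""

    successes: int
    replicates: int
    records: List[ReplicateRecord] = field(default_factory=list)

    @property
    def power(self) -> float:
        return self.successes / self.replicates

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.replicates:
            raise ValueError("need 0 <= #T <= #G")


def exhaustive_best_pair(
    dataset: GenotypeDataset, cap: int = DEFAULT_EXHAUSTIVE_CAP
) -> Tuple[SnpPair, float]:
    """Evaluate all L(L-1)/2 pairs and return the chi-square argmax.

    Ties break toward the lexicographically smallest pair. Refuses datasets
    whose pair count exceeds ``cap`` — the point of the memetic search is
    to avoid this scan at scale.
    """
    L = dataset.L
    n_pairs = L * (L - 1) // 2
    if n_pairs > cap:
        raise ValueError(
            f"exhaustive scan over {n_pairs} pairs exceeds the cap of {cap}; "
            f"raise `cap` explicitly to force it"
        )
    fitness = FitnessEvaluator(dataset)
    best, best_fit = None, -np.inf
    for p in range(1, L + 1):
        for q in range(p + 1, L + 1):
            f = fitness(SnpPair(p, q))
            if f > best_fit:
                best, best_fit = SnpPair(p, q), f
    return best, float(best_fit)


def detection_success(found: SnpPair, truth: SnpPair) -> bool:
    """True iff the found pair equals the causal pair as unordered sets."""
    return found == truth


def power_experiment(
    sim: SimulationSpec,
    params: SamaParams,
    replicates: int,
    credit_visited: bool = False,
) -> PowerResult:
    """Simulate #G datasets, search each, and score exact detections.

    A replicate counts as detected when the final best pair equals the
    embedded causal pair; with ``credit_visited`` a replicate is also
    credited if the causal pair held the best slot at any generation.
    Per-replicate search seeds derive from ``params.seed`` so the whole
    experiment reproduces from two integers.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    datasets = simulate_batch(sim, replicates)
    records: List[ReplicateRecord] = []
    successes = 0
    for rep, dataset in enumerate(datasets):
        run_params = replace(params, seed=replicate_seed(params.seed, rep))
        result: SamaResult = run_sama(dataset, run_params)
        truth = SnpPair(*dataset.truth)
        ok = detection_success(result.best, truth)
        if not ok and credit_visited:
            ok = any(detection_success(b, truth) for b in result.best_history)
        successes += ok
        records.append(
            ReplicateRecord(
                dataset_seed=replicate_seed(sim.seed, rep),
                found=result.best,
                truth=dataset.truth,
                best_fitness=result.best_fitness,
                evaluations=result.evaluations,
                success=ok,
            )
        )
    return PowerResult(successes=successes, replicates=replicates, records=records)
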