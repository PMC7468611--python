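"""Replicate case-control datasets with one embedded interacting pair.

Emulates the GAMETES-style generative design: two functional loci drawn
under Hardy-Weinberg equilibrium at the model MAF, disease status Bernoulli
with the penetrance of the joint genotype, rejection sampling until the
case and control quotas are met exactly, and independent noise SNPs each
with its own MAF. Ground truth travels with the dataset (and in a JSON
sidecar on disk), never in the column order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .io import GenotypeDataset, write_dataset
from .models import PenetranceModel, hwe_genotype_probs

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_batch", "save_simulated"]

_MAX_BATCHES = 200  # attempt budget for rejection sampling


@dataclass(frozen=True)
class SimulationSpec:
    """Design of one simulated dataset family."""

    model: PenetranceModel
    L: int = 200
    n_d: int = 1000
    n_u: int = 1000
    noise_maf_range: Tuple[float, float] = (0.05, 0.5)
    functional_indices: Optional[Tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("need L >= 2")
        if self.n_d < 1 or self.n_u < 1:
            raise ValueError("need at least one case and one control")
        lo, hi = self.noise_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"noise MAF range must sit within (0, 0.5], got {self.noise_maf_range}")
        if self.functional_indices is not None:
            i, j = self.functional_indices
            if i == j or not (1 <= i <= self.L and 1 <= j <= self.L):
                raise ValueError(f"functional indices must be distinct and within [1, {self.L}]")


def _hwe_draw(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """Sample genotype codes 0/1/2 from one genotype distribution."""
    u = rng.random(size)
    return ((u > probs[0]).astype(np.int8) + (u > probs[0] + probs[1]).astype(np.int8))


def _draw_functional(
    rng: np.random.Generator, model: PenetranceModel, spec: SimulationSpec
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample functional genotypes until both quotas are met.

    Returns (g_A, g_B, labels) with exactly n_d cases and n_u controls, in
    draw order.
    """
    probs = np.asarray(hwe_genotype_probs(model.maf).probs)
    table = model.array
    K = float((np.outer(probs, probs) * table).sum())
    need_d, need_u = spec.n_d, spec.n_u
    # expected draws to fill both quotas, padded; K near 0 or 1 inflates it
    per_batch = int(1.3 * max(need_d / max(K, 1e-6), need_u / max(1 - K, 1e-6))) + 64

    ga_parts, gb_parts, lab_parts = [], [], []
    got_d = got_u = 0
    for _ in range(_MAX_BATCHES):
        ga = _hwe_draw(rng, probs, per_batch)
        gb = _hwe_draw(rng, probs, per_batch)
        pen = table[gb, ga]  # rows = locus B
        status = (rng.random(per_batch) < pen).astype(np.int8)
        # fill each quota in draw order, dropping the surplus status
        case_idx = np.flatnonzero(status == 1)[: need_d - got_d]
        ctrl_idx = np.flatnonzero(status == 0)[: need_u - got_u]
        sel = np.sort(np.concatenate([case_idx, ctrl_idx]))
        if sel.size:
            ga_parts.append(ga[sel])
            gb_parts.append(gb[sel])
            lab_parts.append(status[sel])
            got_d += case_idx.size
            got_u += ctrl_idx.size
        if got_d >= need_d and got_u >= need_u:
            return (
                np.concatenate(ga_parts),
                np.concatenate(gb_parts),
                np.concatenate(lab_parts),
            )
    raise RuntimeError(
        f"could not fill case/control quotas for {model.name} within the attempt "
        f"budget (prevalence {K:.4f} too extreme?)"
    )


def simulate_dataset(spec: SimulationSpec) -> GenotypeDataset:
    """Generate one dataset; fully reproducible from ``spec.seed``.

    The returned dataset carries the ground-truth pair in its ``truth``
    attribute as 1-based SNP indices.
    """
    rng = np.random.default_rng(spec.seed)
    ga, gb, labels = _draw_functional(rng, spec.model, spec)
    n = labels.size

    if spec.functional_indices is not None:
        fi, fj = spec.functional_indices
    else:
        fi, fj = (int(v) + 1 for v in rng.choice(spec.L, size=2, replace=False))

    genotypes = np.empty((n, spec.L), dtype=np.int8)
    noise_cols = [c for c in range(spec.L) if c not in (fi - 1, fj - 1)]
    lo, hi = spec.noise_maf_range
    for c in noise_cols:
        q = rng.uniform(lo, hi)
        p = np.asarray(hwe_genotype_probs(q).probs)
        genotypes[:, c] = _hwe_draw(rng, p, n)
    genotypes[:, fi - 1] = ga
    genotypes[:, fj - 1] = gb

    names = [f"N{c}" for c in range(spec.L)]
    return GenotypeDataset(
        snp_names=names, genotypes=genotypes, labels=labels, truth=(fi, fj)
    )


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_batch(spec: SimulationSpec, replicates: int) -> List[GenotypeDataset]:
    """Generate ``replicates`` datasets with derived per-replicate seeds."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    return [
        simulate_dataset(replace(spec, seed=replicate_seed(spec.seed, rep)))
        for rep in range(replicates)
    ]


def save_simulated(dataset: GenotypeDataset, spec: SimulationSpec, path: os.PathLike | str) -> None:
    """Write the genotype TSV plus a JSON sidecar recording the ground truth."""
    write_dataset(dataset, path)
    sidecar = {
        "functional": list(dataset.truth) if dataset.truth else None,
        "model_id": spec.model.model_id,
        "maf": spec.model.maf,
        "seed": spec.seed,
    }
    with open(str(path) + ".json", "w", encoding="ascii") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")
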