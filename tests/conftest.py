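from __future__ import annotations

import numpy as np
import pytest

from samaepi import GenotypeDataset, SimulationSpec, get_model, simulate_dataset


class ScriptedRng:
    """Stand-in RNG yielding a scripted sequence of uniform draws.

    Lets operator tests pin the random decisions (crossover draws, mutation
    deltas, signs) to chosen values. ``random(15)`` consumes one scripted
    15-vector; ``random()`` one scalar.
    """

    def __init__(self, values):
        self._values = list(values)

    def random(self, size=None):
        v = self._values.pop(0)
        if size is None:
            return float(v)
        arr = np.asarray(v, dtype=float)
        assert arr.shape == (size,), f"scripted draw has shape {arr.shape}, wanted {size}"
        return arr


def alpha_vector(*one_positions):
    """A 15-vector of uniforms setting alpha_i = 1 exactly at the given i (1-based)."""
    v = [0.9] * 15
    for i in one_positions:
        v[i - 1] = 0.0
    return v


@pytest.fixture
def tiny_dataset():
    """Hand-written 3-sample, 2-SNP dataset (2 cases, 1 control)."""
    return GenotypeDataset(
        snp_names=["N0", "N1"],
        genotypes=np.array([[0, 1], [2, 0], [1, 1]], dtype=np.int8),
        labels=np.array([1, 0, 1], dtype=np.int8),
    )


@pytest.fixture(scope="session")
def model2_dataset():
    """One Model 2 / MAF 0.5 replicate at desk scale (L=50, n=1000)."""
    spec = SimulationSpec(
        model=get_model(2, 0.5), L=50, n_d=500, n_u=500, seed=424242
    )
    return simulate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
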