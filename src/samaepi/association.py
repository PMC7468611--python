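"""Chi-square association between a SNP pair and case/control status.

The fitness of a candidate pair is Pearson's chi-square computed on the
2 x 9 contingency table of case/control status against the nine joint
genotypes of the two loci. Larger is better; p-values are computed only
for reporting, never as the search criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .io import GenotypeDataset

__all__ = [
    "SnpPair",
    "PairContingency",
    "pair_contingency",
    "chi2_statistic",
    "pair_p_value",
    "fitness",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class SnpPair:
    """An unordered pair of distinct 1-based SNP indices.

    The pair is the `individual` of the evolutionary search; {a, b} and
    {b, a} are the same pair for equality, hashing and fitness.
    """

    r_p: int
    r_q: int

    def __post_init__(self) -> None:
        if self.r_p == self.r_q:
            raise ValueError(f"a pair needs two distinct SNPs, got ({self.r_p}, {self.r_q})")
        if self.r_p < 1 or self.r_q < 1:
            raise ValueError("SNP indices are 1-based and must be >= 1")

    @property
    def key(self) -> Tuple[int, int]:
        """Canonical (sorted) form used for hashing and equality."""
        return (self.r_p, self.r_q) if self.r_p < self.r_q else (self.r_q, self.r_p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpPair):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __iter__(self):
        return iter((self.r_p, self.r_q))


@dataclass
class PairContingency:
    """2 x 9 table of counts: rows (case, control), columns joint genotypes.

    Column ``3*g_p + g_q`` holds the count of samples whose genotypes at
    the two loci are ``(g_p, g_q)``, in row-major order (0,0), (0,1) ... (2,2).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 9):
            raise ValueError(f"expected a 2x9 table, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def _check_bounds(dataset: GenotypeDataset, pair: SnpPair) -> None:
    if not (1 <= pair.r_p <= dataset.L and 1 <= pair.r_q <= dataset.L):
        raise IndexError(
            f"pair ({pair.r_p}, {pair.r_q}) out of range for L={dataset.L} SNPs"
        )


def pair_contingency(dataset: GenotypeDataset, pair: SnpPair) -> PairContingency:
    """Tally joint genotypes of a pair, split by case/control status."""
    _check_bounds(dataset, pair)
    gp = dataset.genotypes[:, pair.r_p - 1]
    gq = dataset.genotypes[:, pair.r_q - 1]
    joint = 3 * gp.astype(np.int64) + gq
    case = dataset.labels == 1
    counts = np.stack(
        [
            np.bincount(joint[case], minlength=9),
            np.bincount(joint[~case], minlength=9),
        ]
    )
    return PairContingency(counts)


def chi2_statistic(table: PairContingency) -> float:
    """Pearson's chi-square on a 2 x 9 table, empty columns dropped.

    Columns with zero total contribute nothing (their expected counts are
    zero); no continuity correction or pseudo-counts are applied.
    """
    counts = table.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute chi-square of an all-zero table")
    col_totals = counts.sum(axis=0)
    occupied = col_totals > 0
    obs = counts[:, occupied].astype(np.float64)
    row_totals = obs.sum(axis=1)
    expected = np.outer(row_totals, col_totals[occupied]) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def occupied_columns(table: PairContingency) -> int:
    return int(np.count_nonzero(table.counts.sum(axis=0)))


def pair_p_value(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability with ``df`` degrees of freedom.

    The conventional df for a 2 x 9 genotype table is (occupied columns - 1).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(chi2, df))


def fitness(dataset: GenotypeDataset, pair: SnpPair) -> float:
    """Chi-square fitness of a pair: deterministic, symmetric in pair order."""
    return chi2_statistic(pair_contingency(dataset, pair))


class FitnessEvaluator:
    """Memoizing fitness evaluator bound to one dataset.

    Splits the genotype matrix by status once, then answers each distinct
    pair with a single bincount pass; repeat queries hit a cache keyed on
    the unordered pair. ``calls`` counts every fitness request,
    ``evaluations`` only cache misses (actual chi-square computations).
    """

    def __init__(self, dataset: GenotypeDataset) -> None:
        case = dataset.labels == 1
        self._cases = np.ascontiguousarray(dataset.genotypes[case].astype(np.int64))
        self._controls = np.ascontiguousarray(dataset.genotypes[~case].astype(np.int64))
        self.L = dataset.L
        self._cache: Dict[Tuple[int, int], float] = {}
        self.calls = 0
        self.evaluations = 0

    def __call__(self, pair: SnpPair) -> float:
        self.calls += 1
        key = pair.key
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.evaluations += 1
        p, q = key[0] - 1, key[1] - 1
        case_counts = np.bincount(3 * self._cases[:, p] + self._cases[:, q], minlength=9)
        ctrl_counts = np.bincount(
            3 * self._controls[:, p] + self._controls[:, q], minlength=9
        )
        value = chi2_statistic(PairContingency(np.stack([case_counts, ctrl_counts])))
        self._cache[key] = value
        return value
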