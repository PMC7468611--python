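"""Two-locus penetrance models and their population-genetic identities.

Twelve built-in disease models — three architectures crossed with four
minor allele frequencies — each a 3x3 penetrance table f(g_A, g_B) giving
the disease probability for every joint genotype. Model 1 is
multiplicative (risk grows multiplicatively with risk-genotype dosage),
Model 2 is a threshold model (risk jumps once both loci carry a minor
allele), Model 3 is a concrete interaction model with crossing marginal
effects. All were calibrated to population prevalence K = 0.1 and a fixed
broad-sense heritability (0.005 for Model 1, 0.02 for Models 2 and 3)
under Hardy-Weinberg equilibrium at both loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "PenetranceModel",
    "GenotypeDistribution",
    "hwe_genotype_probs",
    "prevalence",
    "heritability",
    "builtin_models",
    "get_model",
]


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities of genotype codes (0, 1, 2) at one locus."""

    probs: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"not a genotype distribution: {self.probs}")


@dataclass(frozen=True)
class PenetranceModel:
    """A 3x3 two-locus penetrance table with its design parameters.

    ``table[g_B][g_A]`` is the disease probability for genotype code g_A at
    locus A (columns AA, Aa, aa) and g_B at locus B (rows BB, Bb, bb).
    Both loci share the model's single MAF and are unlinked.
    """

    model_id: int
    maf: float
    table: tuple  # 3x3, rows = locus B genotype, columns = locus A genotype
    target_prevalence: float
    target_h2: float

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 3) or (t < 0).any() or (t > 1).any():
            raise ValueError("penetrance table must be 3x3 with entries in [0, 1]")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=float)

    @property
    def name(self) -> str:
        return f"Model {self.model_id} / MAF {self.maf:.2f}"


def hwe_genotype_probs(maf: float) -> GenotypeDistribution:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2).

    Codes (0, 1, 2) = (homozygous major, heterozygous, homozygous minor)
    for minor allele frequency q.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    q = maf
    return GenotypeDistribution(((1 - q) ** 2, 2 * q * (1 - q), q * q))


def _joint_weights(model: PenetranceModel) -> np.ndarray:
    p = np.asarray(hwe_genotype_probs(model.maf).probs)
    return np.outer(p, p)  # rows = locus B, columns = locus A


def prevalence(model: PenetranceModel) -> float:
    """Population prevalence K implied by the table under HWE at both loci."""
    return float((_joint_weights(model) * model.array).sum())


def heritability(model: PenetranceModel) -> float:
    """Broad-sense heritability in the variance-explained (GAMETES) sense.

    h^2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)), the penetrance variance
    around prevalence normalised by the binary-trait variance.
    """
    K = prevalence(model)
    if not 0 < K < 1:
        raise ValueError(f"heritability undefined at prevalence {K}")
    w = _joint_weights(model)
    return float((w * (model.array - K) ** 2).sum() / (K * (1 - K)))


# Rows BB, Bb, bb; columns AA, Aa, aa. Entries rounded to 3 decimals as
# printed; prevalence/heritability identities hold to ~5e-4.
_TABLES = {
    (1, 0.05): ((0.098, 0.098, 0.098), (0.098, 0.299, 0.522), (0.098, 0.522, 0.912)),
    (1, 0.10): ((0.096, 0.096, 0.096), (0.096, 0.197, 0.282), (0.096, 0.282, 0.408)),
    (1, 0.20): ((0.092, 0.092, 0.092), (0.092, 0.145, 0.181), (0.092, 0.181, 0.227)),
    (1, 0.50): ((0.078, 0.078, 0.078), (0.078, 0.105, 0.122), (0.078, 0.122, 0.142)),
    (2, 0.05): ((0.096, 0.096, 0.096), (0.096, 0.533, 0.533), (0.096, 0.533, 0.533)),
    (2, 0.10): ((0.092, 0.092, 0.092), (0.092, 0.319, 0.319), (0.092, 0.319, 0.319)),
    (2, 0.20): ((0.084, 0.084, 0.084), (0.084, 0.210, 0.210), (0.084, 0.210, 0.210)),
    (2, 0.50): ((0.052, 0.052, 0.052), (0.052, 0.138, 0.138), (0.052, 0.138, 0.138)),
    (3, 0.05): ((0.080, 0.192, 0.192), (0.192, 0.080, 0.080), (0.192, 0.080, 0.080)),
    (3, 0.10): ((0.072, 0.164, 0.164), (0.164, 0.072, 0.072), (0.164, 0.072, 0.072)),
    (3, 0.20): ((0.061, 0.146, 0.146), (0.146, 0.061, 0.061), (0.146, 0.061, 0.061)),
    (3, 0.50): ((0.067, 0.155, 0.155), (0.155, 0.067, 0.067), (0.155, 0.067, 0.067)),
}

_H2 = {1: 0.005, 2: 0.02, 3: 0.02}


def builtin_models() -> List[PenetranceModel]:
    """The 12 built-in models: architectures {1,2,3} x MAF {.05,.10,.20,.50}."""
    return [
        PenetranceModel(
            model_id=m,
            maf=q,
            table=table,
            target_prevalence=0.1,
            target_h2=_H2[m],
        )
        for (m, q), table in _TABLES.items()
    ]


def get_model(model_id: int, maf: float) -> PenetranceModel:
    """Look up one built-in model by architecture id and MAF."""
    for model in builtin_models():
        if model.model_id == model_id and abs(model.maf - maf) < 1e-9:
            return model
    raise KeyError(
        f"no built-in model {model_id} at MAF {maf}; "
        f"available MAFs are 0.05, 0.10, 0.20, 0.50"
    )


def gametes_model_text(model: PenetranceModel) -> str:
    """Render a model as a GAMETES-compatible text block for cross-checking."""
    lines = [
        "Attribute names:\tP0\tP1",
        f"Minor allele frequencies:\t{model.maf}\t{model.maf}",
        f"K: {prevalence(model):.6f}",
        f"Heritability: {heritability(model):.6f}",
        "Table:",
    ]
    for row in model.array:
        lines.append("\t".join(f"{v:.3f}" for v in row))
    return "\n".join(lines) + "\n"
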