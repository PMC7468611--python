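"""Case-control genotype matrices in the GAMETES tab-delimited dialect.

The on-disk format is the one GAMETES_2.0 emits: a header row of SNP names
followed by a final ``Class`` column, then one tab-separated row per sample
holding genotype codes (0 = homozygous major, 1 = heterozygous,
2 = homozygous minor) and the case/control label (1 = case, 0 = control).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["GenotypeDataset", "load_dataset", "write_dataset", "ParseError"]

CLASS_COLUMN = "Class"


class ParseError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass
class GenotypeDataset:
    """n samples x L SNPs of genotype codes plus case/control labels.

    Attributes
    ----------
    snp_names : list of str
        Unique column names, length L.
    genotypes : ndarray of shape (n, L), dtype int8
        Genotype codes in {0, 1, 2}.
    labels : ndarray of shape (n,), dtype int8
        1 = case, 0 = control.
    truth : tuple of int, optional
        Ground-truth interacting pair (1-based SNP indices) when the
        dataset came from the simulator; never written to the genotype file.
    """

    snp_names: list
    genotypes: np.ndarray
    labels: np.ndarray
    truth: Optional[Tuple[int, int]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.validate()

    # -- derived counts -------------------------------------------------
    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def L(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_d(self) -> int:
        """Number of cases."""
        return int(np.count_nonzero(self.labels == 1))

    @property
    def n_u(self) -> int:
        """Number of controls."""
        return int(self.n - self.n_d)

    def validate(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.labels.shape != (self.genotypes.shape[0],):
            raise ValueError("labels length must equal the number of samples")
        if self.L < 2:
            raise ValueError(f"need at least 2 SNPs to form a pair, got L={self.L}")
        if len(self.snp_names) != self.L:
            raise ValueError("snp_names length must equal the number of SNP columns")
        if len(set(self.snp_names)) != self.L:
            raise ValueError("snp_names must be unique")
        if self.n and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        if self.n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
        )


def load_dataset(path: os.PathLike | str) -> GenotypeDataset:
    """Read a GAMETES-style tab-delimited genotype file.

    The last header token names the class column; every other column is a
    SNP. Any token that is not a valid code raises :class:`ParseError`
    naming the offending row and column — missing genotypes are not a
    concept of this data model and are never imputed.
    """
    with open(path, "r", encoding="ascii") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file, expected a header row")
        names = header.rstrip("\n").split("\t")
        if len(names) < 3:
            raise ParseError(
                f"{path}: header has {len(names) - 1} SNP columns, need at least 2"
            )
        snp_names = names[:-1]

        geno_rows = []
        label_rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) != len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(names)} columns, got {len(tokens)}"
                )
            row = []
            for col, tok in zip(names[:-1], tokens[:-1]):
                if tok not in ("0", "1", "2"):
                    raise ParseError(
                        f"{path}:{lineno}: column {col!r}: invalid genotype code {tok!r}"
                    )
                row.append(int(tok))
            if tokens[-1] not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: column {names[-1]!r}: invalid class label "
                    f"{tokens[-1]!r}"
                )
            geno_rows.append(row)
            label_rows.append(int(tokens[-1]))

    genotypes = (
        np.array(geno_rows, dtype=np.int8)
        if geno_rows
        else np.empty((0, len(snp_names)), dtype=np.int8)
    )
    return GenotypeDataset(
        snp_names=snp_names,
        genotypes=genotypes,
        labels=np.array(label_rows, dtype=np.int8),
    )


def write_dataset(dataset: GenotypeDataset, path: os.PathLike | str) -> None:
    """Write a dataset in the same dialect :func:`load_dataset` reads."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\t".join([*dataset.snp_names, CLASS_COLUMN]) + "\n")
        for row, label in zip(dataset.genotypes, dataset.labels):
            fh.write("\t".join(str(int(g)) for g in row) + f"\t{int(label)}\n")
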