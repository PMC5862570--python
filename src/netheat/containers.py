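"""Shared in-memory containers for the pipeline stages.

Genotypes are held as a dense ``int8`` matrix (individuals x SNPs) with codes
0/1/2 counting copies of the alternate allele and -1 for a missing call.  The
binary phenotype (1 = case, 0 = control) travels with the matrix so every
stage sees a consistent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """A case/control cohort: individuals x SNPs with 0/1/2/missing codes."""

    genotypes: np.ndarray          # int8, shape (n_individuals, n_snps), -1 = missing
    phenotype: np.ndarray          # int8, shape (n_individuals,), 1 = case
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x SNPs)")
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise ValueError(
                f"{self.genotypes.shape[0]} genotype rows but "
                f"{self.phenotype.shape[0]} phenotype entries"
            )
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError(
                f"{self.genotypes.shape[1]} genotype columns but "
                f"{len(self.snp_ids)} SNP ids"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing (-1)")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be coded 0 (control) / 1 (case)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_ids.index(snp_id)]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNP columns in boolean/index ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx].copy(),
            phenotype=self.phenotype.copy(),
            snp_ids=[self.snp_ids[i] for i in idx],
        )


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for recovery tests."""

    planted_genes: set[str] = field(default_factory=set)
    causal_snps: set[str] = field(default_factory=set)
    planted_disease_drugs: set[str] = field(default_factory=set)
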