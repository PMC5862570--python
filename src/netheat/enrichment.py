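"""Hypergeometric drug-target enrichment of discovered subnetworks.

The drug universe is every drug with at least one known target (N), of which
K carry the disease indication.  A drug "hits" a gene set when any of its
targets lies in the set; with n hitting drugs of which k are disease drugs,
the enrichment P-value is the inclusive upper tail P(X >= k) of the
hypergeometric(N, K, n) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffusion import Subnetwork
from .heat import select_top_fraction


def normalize_drug_id(raw: str) -> str:
    """Case-insensitive, whitespace-trimmed drug identifier."""
    return " ".join(str(raw).split()).casefold()


@dataclass
class DrugTargetTable:
    """Validated drug-target rows with normalized drug ids."""

    frame: pd.DataFrame  # columns: drug_id, gene_id, is_disease_drug

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugTargetTable":
        df = df.copy()
        df["drug_id"] = df["drug_id"].map(normalize_drug_id)
        df["gene_id"] = df["gene_id"].astype(str).str.strip()
        df["is_disease_drug"] = df["is_disease_drug"].astype(bool)
        dup = df.duplicated(subset=["drug_id", "gene_id"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                f"duplicate (drug, target) pair: ({first['drug_id']}, {first['gene_id']})"
            )
        flags = df.groupby("drug_id")["is_disease_drug"].nunique()
        if (flags > 1).any():
            raise ValueError(
                f"inconsistent disease flag for drug {flags[flags > 1].index[0]!r}"
            )
        return cls(frame=df.reset_index(drop=True))

    @property
    def n_drugs(self) -> int:
        return self.frame["drug_id"].nunique()

    @property
    def n_disease_drugs(self) -> int:
        return self.frame.loc[self.frame["is_disease_drug"], "drug_id"].nunique()

    def disease_drugs(self) -> set[str]:
        return set(self.frame.loc[self.frame["is_disease_drug"], "drug_id"])


@dataclass
class EnrichmentResult:
    N: int   # drug universe
    K: int   # disease drugs in universe
    n: int   # drugs hitting the gene set
    k: int   # disease drugs hitting the gene set
    p: float
    drugs: list[str] = field(default_factory=list)


def drugs_hitting_genes(
    table: DrugTargetTable, genes: set[str]
) -> tuple[int, int, list[str]]:
    """(n, k, hitting drugs): a drug counts once if any target is in ``genes``."""
    hits = table.frame[table.frame["gene_id"].isin(genes)]
    drugs = sorted(hits["drug_id"].unique())
    disease = table.disease_drugs()
    k = sum(1 for d in drugs if d in disease)
    return len(drugs), k, drugs


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k) of hypergeometric(N, K, n), in log space."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    if j.size == 0:
        return 0.0

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    logpmf = logc(K, j) + logc(N - K, n - j) - logc(N, n)
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def subnetwork_enrichment(
    subnetworks: list[Subnetwork], table: DrugTargetTable
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Enrichment of the pooled subnetwork gene set, plus a per-subnetwork listing.

    The listing has one row per (subnetwork, drug, target-in-subnetwork) hit,
    mirroring a drugs-by-subnetwork table.
    """
    if not subnetworks:
        raise ValueError("need at least one subnetwork")
    pooled: set[str] = set()
    rows = []
    for sub in subnetworks:
        genes = set(sub.genes)
        pooled |= genes
        hits = table.frame[table.frame["gene_id"].isin(genes)]
        for _, r in hits.sort_values(["gene_id", "drug_id"]).iterrows():
            rows.append(
                {
                    "subnetwork": sub.index,
                    "drug_id": r["drug_id"],
                    "gene_id": r["gene_id"],
                    "is_disease_drug": r["is_disease_drug"],
                }
            )
    n, k, drugs = drugs_hitting_genes(table, pooled)
    result = EnrichmentResult(
        N=table.n_drugs,
        K=table.n_disease_drugs,
        n=n,
        k=k,
        p=hypergeom_upper_tail(table.n_drugs, table.n_disease_drugs, n, k),
        drugs=drugs,
    )
    listing = pd.DataFrame(
        rows, columns=["subnetwork", "drug_id", "gene_id", "is_disease_drug"]
    )
    return result, listing


def single_locus_baseline(
    gene_heat: pd.DataFrame, table: DrugTargetTable, top_n: int
) -> EnrichmentResult:
    """Enrichment of the ``top_n`` heat-ranked genes (single-locus comparator)."""
    if top_n < 0 or top_n > len(gene_heat):
        raise ValueError("top_n must lie in [0, number of genes]")
    if top_n == 0:
        return EnrichmentResult(
            N=table.n_drugs, K=table.n_disease_drugs, n=0, k=0, p=1.0
        )
    ranked = select_top_fraction(gene_heat, fraction=1.0)  # full heat ranking
    genes = set(ranked.head(top_n)["gene_id"])
    n, k, drugs = drugs_hitting_genes(table, genes)
    return EnrichmentResult(
        N=table.n_drugs,
        K=table.n_disease_drugs,
        n=n,
        k=k,
        p=hypergeom_upper_tail(table.n_drugs, table.n_disease_drugs, n, k),
        drugs=drugs,
    )
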