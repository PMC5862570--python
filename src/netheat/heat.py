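"""Gene-level heat scores from SNP association P-values.

A gene's score is the minimum P-value over its assigned SNPs; the diffusion
heat is -log10 of that minimum.  The hottest fraction of genes (default 20%)
is selected as diffusion input; everything else enters with heat 0 so the
network node set stays fixed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


def aggregate_min_p(assoc: pd.DataFrame, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Per-gene minimum P and heat = -log10(min P).

    ``assoc`` needs columns snp_id and p; ``snp_map`` maps snp_id -> gene_id.
    Genes whose mapped SNPs all failed testing (NA p) are omitted and counted
    in the log.  ``n_snps`` counts the tested (non-NA) SNPs per gene.
    """
    if snp_map.empty:
        raise ValueError("empty SNP-to-gene mapping")
    merged = snp_map[["snp_id", "gene_id"]].merge(
        assoc[["snp_id", "p"]], on="snp_id", how="left"
    )
    tested = merged.dropna(subset=["p"])
    n_genes_all = merged["gene_id"].nunique()
    out = (
        tested.groupby("gene_id")["p"]
        .agg(min_p="min", n_snps="size")
        .reset_index()
    )
    dropped = n_genes_all - len(out)
    if dropped:
        logger.info("%d gene(s) had no testable SNP and were omitted", dropped)
    # floor min_p at the smallest positive double so heat stays finite
    out["heat"] = -np.log10(np.clip(out["min_p"], np.finfo(float).tiny, None))
    return out[["gene_id", "min_p", "heat", "n_snps"]].sort_values(
        "gene_id", kind="mergesort"
    ).reset_index(drop=True)


def select_top_fraction(gene_heat: pd.DataFrame, fraction: float = 0.2) -> pd.DataFrame:
    """The floor(fraction * n) hottest genes.

    Ties at the cutoff are broken by lexicographic gene id, so the selection
    is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if gene_heat.empty:
        raise ValueError("empty gene-heat table")
    k = int(np.floor(fraction * len(gene_heat)))
    ranked = gene_heat.sort_values(
        ["heat", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)


def mutation_heat_correlation(gene_heat: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between per-gene SNP count and heat (diagnostic).

    Returns (rho, p); (nan, nan) with a warning when either variable is
    constant.
    """
    if len(gene_heat) < 3:
        raise ValueError("need at least 3 genes")
    n_snps = gene_heat["n_snps"].to_numpy(float)
    heat = gene_heat["heat"].to_numpy(float)
    if np.ptp(n_snps) == 0 or np.ptp(heat) == 0:
        warnings.warn("constant variable: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = spearmanr(n_snps, heat)
    return float(rho), float(p)


def heat_vector(
    gene_heat: pd.DataFrame, nodes: list[str], fraction: float = 0.2
) -> np.ndarray:
    """Diffusion input aligned to ``nodes``: top-fraction heat, 0 elsewhere.

    Heat-scored genes absent from the network are dropped (logged); network
    genes without a score get 0.
    """
    top = select_top_fraction(gene_heat, fraction)
    lookup = dict(zip(top["gene_id"], top["heat"]))
    node_set = set(nodes)
    outside = [g for g in top["gene_id"] if g not in node_set]
    if outside:
        logger.info("%d hot gene(s) not in the network were dropped", len(outside))
    return np.array([lookup.get(g, 0.0) for g in nodes])
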