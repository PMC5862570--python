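"""Synthetic cohort generator with ground truth for recovery tests.

Emulates a small-breed case/control genotyping study: an imbalanced cohort
(default 34 cases / 168 controls), SNPs grouped into genes, a gene-interaction
network with a planted connected "hot" module whose SNPs carry a genuine
phenotype effect, and a drug-target table in which some disease-indicated
drugs target the planted module.

Genotypes are drawn from the same cumulative-logit model the association
stage fits — the genotype is the ordinal outcome of the binary phenotype —
so parameter recovery is exact for the matched estimator.  Control-group
intercepts are chosen so that the control allele frequency equals the drawn
MAF under Hardy-Weinberg proportions:

    alpha1 = logit((1-f)^2),  alpha2 = logit(1 - f^2)

and causal SNPs add ``causal_effect`` to both linear predictors for cases.

Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import GenotypeMatrix, GroundTruth
from .diffusion import InteractionNetwork

N_CHROMOSOMES = 38  # canine autosomes


@dataclass
class SimulationConfig:
    n_cases: int = 34
    n_controls: int = 168
    n_genes: int = 500
    snps_per_gene: int | tuple[int, int] = 5          # fixed count or (lo, hi) uniform
    planted_module_size: int = 8
    causal_effect: float = 1.2                        # log-odds shift for causal SNPs
    maf_range: tuple[float, float] = (0.10, 0.50)
    network_model: str = "scale-free"                 # or "erdos-renyi"
    ba_m: int = 2                                     # preferential-attachment edges per node
    er_p: float = 0.02                                # Erdos-Renyi edge probability
    edge_score_range: tuple[int, int] = (150, 1000)   # STRING-style combined scores
    planted_score_floor: int = 400                    # internal module edges score >= this
    n_drugs: int = 100
    n_disease_drugs: int = 10
    planted_drug_count: int = 4
    targets_per_drug: tuple[int, int] = (1, 3)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module cannot exceed the gene count")
        if self.planted_module_size < 2:
            raise ValueError("planted module needs at least 2 genes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        slo, shi = self.edge_score_range
        if not (0 <= slo <= shi <= 1000):
            raise ValueError("edge_score_range must lie within [0, 1000]")
        if not (self.planted_drug_count <= self.n_disease_drugs <= self.n_drugs):
            raise ValueError(
                "need planted_drug_count <= n_disease_drugs <= n_drugs"
            )
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.network_model not in ("scale-free", "erdos-renyi"):
            raise ValueError(f"unknown network model {self.network_model!r}")


@dataclass
class Cohort:
    """Everything one simulated study produces."""

    config: SimulationConfig
    network: InteractionNetwork
    snp_map: pd.DataFrame              # snp_id, chrom, pos, gene_id
    genotypes: GenotypeMatrix
    drug_targets: pd.DataFrame         # drug_id, gene_id, is_disease_drug
    truth: GroundTruth = field(default_factory=GroundTruth)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def simulate_network(config: SimulationConfig) -> tuple[InteractionNetwork, set[str]]:
    """Generate the interaction graph and the planted connected module.

    Base topology: Barabasi-Albert preferential attachment with ``ba_m`` edges
    per arriving node (edge count exactly ``ba_m * (n_genes - ba_m)`` when
    ``n_genes > ba_m``, otherwise empty), or G(n, p).  The planted module is a
    uniform node sample made connected by adding a random spanning tree among
    its members; the extra tree edges (0 to module_size - 1 of them) are
    recorded in ``network.meta``.  Edges internal to the module score at least
    ``planted_score_floor`` so the module survives downstream thresholding;
    all other edges score uniformly in ``edge_score_range``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_genes

    if config.network_model == "scale-free":
        if n > config.ba_m:
            base = nx.barabasi_albert_graph(
                n, config.ba_m, seed=int(rng.integers(2**31))
            )
        else:
            base = nx.empty_graph(n)
    else:
        base = nx.gnp_random_graph(n, config.er_p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(base, dict(enumerate(genes)))
    n_base_edges = g.number_of_edges()

    planted = sorted(
        str(g) for g in rng.choice(genes, size=config.planted_module_size, replace=False)
    )
    # random spanning tree over the planted nodes guarantees connectivity
    order = list(rng.permutation(planted))
    n_added = 0
    for i in range(1, len(order)):
        partner = order[int(rng.integers(i))]
        if not g.has_edge(order[i], partner):
            g.add_edge(order[i], partner)
            n_added += 1

    slo, shi = config.edge_score_range
    planted_set = set(planted)
    floor = max(config.planted_score_floor, slo)
    for a, b in g.edges:
        if a in planted_set and b in planted_set:
            g[a][b]["score"] = int(rng.integers(floor, shi + 1))
        else:
            g[a][b]["score"] = int(rng.integers(slo, shi + 1))

    net = InteractionNetwork(
        graph=g,
        score_threshold=0,  # unfiltered; downstream build_network applies the cutoff
        meta={"n_base_edges": n_base_edges, "n_added_edges": n_added},
    )
    return net, planted_set


def simulate_snp_map(config: SimulationConfig) -> pd.DataFrame:
    """Assign SNPs to genes; genes are laid out round-robin over autosomes."""
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_genes)
    rows = []
    snp_no = 0
    for gi, gene in enumerate(genes):
        if isinstance(config.snps_per_gene, int):
            k = config.snps_per_gene
        else:
            lo, hi = config.snps_per_gene
            k = int(rng.integers(lo, hi + 1))
        chrom = gi % N_CHROMOSOMES + 1
        for s in range(k):
            snp_no += 1
            rows.append(
                {
                    "snp_id": f"snp{snp_no:06d}",
                    "chrom": chrom,
                    "pos": (gi // N_CHROMOSOMES) * 100_000 + s * 1_000 + 1,
                    "gene_id": gene,
                }
            )
    return pd.DataFrame(rows)


def _hwe_intercepts(f: float) -> tuple[float, float]:
    """Cumulative-logit intercepts giving HWE genotype proportions at allele freq f."""
    if not (0 < f < 1):
        raise ValueError("degenerate allele frequency")
    return float(logit((1 - f) ** 2)), float(logit(1 - f**2))


def simulate_genotypes(
    config: SimulationConfig,
    planted_genes: set[str],
    snp_map: pd.DataFrame,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotypes from the cumulative-logit model given phenotype.

    Every SNP mapped to a planted gene is causal with slope
    ``causal_effect``; all other SNPs have slope 0, so case and control
    genotype distributions coincide for them.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_ind = config.n_cases + config.n_controls
    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8), np.zeros(config.n_controls, dtype=np.int8)]
    )
    snp_ids = list(snp_map["snp_id"])
    snp_gene = dict(zip(snp_map["snp_id"], snp_map["gene_id"]))
    causal = {s for s in snp_ids if snp_gene[s] in planted_genes}

    lo, hi = config.maf_range
    geno = np.empty((n_ind, len(snp_ids)), dtype=np.int8)
    x = phenotype.astype(float)
    for j, snp in enumerate(snp_ids):
        f = float(rng.uniform(lo, hi))
        a1, a2 = _hwe_intercepts(f)
        beta = config.causal_effect if snp in causal else 0.0
        q1 = expit(a1 + beta * x)
        q2 = expit(a2 + beta * x)
        u = rng.random(n_ind)
        geno[:, j] = np.where(u < q1, 0, np.where(u < q2, 1, 2)).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = -1

    gm = GenotypeMatrix(genotypes=geno, phenotype=phenotype, snp_ids=snp_ids)
    truth = GroundTruth(planted_genes=set(planted_genes), causal_snps=causal)
    return gm, truth


def simulate_drug_targets(
    config: SimulationConfig,
    planted_genes: set[str],
    all_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Drug-target table; the planted disease drugs are guaranteed a module target.

    One row per (drug, target).  Disease drugs are the first
    ``n_disease_drugs`` ids; of those, the first ``planted_drug_count`` have
    at least one target inside the planted module.  All remaining target
    assignments are uniform over the gene universe.
    """
    if not planted_genes:
        raise ValueError("planted module is empty")
    rng = np.random.default_rng(config.seed + 3)
    genes = all_genes if all_genes is not None else _gene_ids(config.n_genes)
    planted_sorted = sorted(planted_genes)
    width = len(str(config.n_drugs))
    tlo, thi = config.targets_per_drug
    rows = []
    planted_drugs: set[str] = set()
    for d in range(config.n_drugs):
        drug = f"drug{d + 1:0{width}d}"
        is_disease = d < config.n_disease_drugs
        k = int(rng.integers(tlo, thi + 1))
        targets = [str(g) for g in rng.choice(genes, size=min(k, len(genes)), replace=False)]
        if is_disease and d < config.planted_drug_count:
            if not any(t in planted_genes for t in targets):
                targets[0] = planted_sorted[int(rng.integers(len(planted_sorted)))]
            planted_drugs.add(drug)
        for t in sorted(set(targets)):
            rows.append({"drug_id": drug, "gene_id": t, "is_disease_drug": is_disease})
    return pd.DataFrame(rows), planted_drugs


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run all three generators under one seed and bundle the results."""
    network, planted = simulate_network(config)
    snp_map = simulate_snp_map(config)
    gm, truth = simulate_genotypes(config, planted, snp_map)
    drug_targets, planted_drugs = simulate_drug_targets(
        config, planted, _gene_ids(config.n_genes)
    )
    truth.planted_disease_drugs = planted_drugs
    return Cohort(
        config=config,
        network=network,
        snp_map=snp_map,
        genotypes=gm,
        drug_targets=drug_targets,
        truth=truth,
    )
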