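"""Generate a synthetic case/control cohort with a planted hot module.

The design mirrors a small within-breed genotyping study: 34 cases, 168
controls, 2,500 SNPs in 500 genes, a scale-free interaction network with a
connected 8-gene module whose SNPs carry a real phenotype effect, and a
drug-target table in which 4 disease drugs target the module.
"""

import netheat as nh

cohort = nh.simulate_cohort(nh.SimulationConfig(seed=11))

gm = cohort.genotypes
print(f"cohort: {gm.n_cases} cases / {gm.n_individuals - gm.n_cases} controls, "
      f"{gm.n_snps} SNPs in {cohort.snp_map['gene_id'].nunique()} genes")
print(f"network: {cohort.network.n_nodes} genes, {cohort.network.n_edges} scored edges")
print(f"planted module: {sorted(cohort.truth.planted_genes)}")
print(f"causal SNPs: {len(cohort.truth.causal_snps)} "
      f"(all in planted genes, log-odds effect {cohort.config.causal_effect})")
print(f"disease drugs targeting the module: {sorted(cohort.truth.planted_disease_drugs)}")
# Downstream stages must rediscover the planted module and drugs from the
# genotypes alone; the ground truth exists only to score that recovery.
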