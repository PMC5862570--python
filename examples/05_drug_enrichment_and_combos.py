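"""Drug-target enrichment of discovered subnetworks and combination proposal.

Disease-drug over-representation among drugs hitting the subnetwork genes is
tested with an inclusive upper-tail hypergeometric; disease drugs sharing a
subnetwork through different targets become combination candidates.
"""

import netheat as nh
from netheat.heat import heat_vector

SEED = 11
cohort = nh.simulate_cohort(nh.SimulationConfig(seed=SEED))
gm_qc, _ = nh.apply_qc(cohort.genotypes)
assoc = nh.run_gwas(gm_qc, cohort.snp_map)
gene_heat = nh.aggregate_min_p(assoc, cohort.snp_map)
network = nh.build_network(cohort.network.edge_list(), 400)
kernel = nh.diffusion_kernel(network, 0.4)
hvec = heat_vector(gene_heat, kernel.nodes, 0.2)
delta = nh.choose_delta(network, hvec, n_perm=60, seed=SEED, kernel=kernel)
subs = nh.extract_subnetworks(nh.exchanged_heat(kernel, hvec), delta, kernel.nodes, 3)

table = nh.DrugTargetTable.from_frame(cohort.drug_targets)
result, listing = nh.subnetwork_enrichment(subs, table)
print(f"universe: {result.N} drugs, {result.K} disease-indicated")
print(f"subnetwork genes hit by {result.n} drugs, {result.k} disease drugs "
      f"-> hypergeometric p = {result.p:.3g}")

baseline = nh.single_locus_baseline(gene_heat, table, top_n=sum(s.size for s in subs))
print(f"single-locus baseline (same gene count): {baseline.k}/{baseline.n} "
      f"-> p = {baseline.p:.3g}")

pairs = nh.propose_combinations(listing)
print(f"candidate drug combinations (same subnetwork, disjoint targets): {len(pairs)}")
for p in pairs[:5]:
    print(f"  subnetwork {p.subnetwork}: {p.drug_a} + {p.drug_b} "
          f"({','.join(sorted(p.targets_a))} vs {','.join(sorted(p.targets_b))})")
recovered = {d for p in pairs for d in (p.drug_a, p.drug_b)}
print(f"planted disease drugs among proposed: "
      f"{sorted(recovered & cohort.truth.planted_disease_drugs)}")
# A smaller subnetwork p than baseline p is the module-level gain: network
# structure concentrates disease-drug targets beyond what single hot loci do.
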