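# Methods

## Association model

The association stage regresses the ordinal genotype on the binary
phenotype — a proportional-odds cumulative logit with cumulative
probabilities Q₁ = P(y=0|x) = σ(α₁ + βx) and Q₂ = P(y≤1|x) = σ(α₂ + βx),
category probabilities p₁ = Q₁, p₂ = Q₂ − Q₁ and p₃ computed as the
complement 1 − Q₂ so the three always sum to one exactly. This direction
(genotype as outcome) is unusual relative to the conventional
phenotype-on-dosage logistic regression, but it is the model the pipeline is
built around, and the synthetic generator draws genotypes from exactly this
law so that the fitter is the matched maximum-likelihood estimator; a
conventional binary-logistic mode (`model="binlogit"`) is available for
comparison. The two orderings agree closely in P-value ranking on simulated
cohorts (rank correlation > 0.8 in the test suite).

Because the covariate is binary, the likelihood depends on the data only
through the 2×3 genotype-by-phenotype count table, so each marker is fitted
by a three-parameter Newton–Raphson on that table: analytic gradient and
Hessian, at most 50 iterations, gradient tolerance 1e-8, step-halving on any
step that decreases the likelihood or violates α₁ < α₂, and divergence of
any parameter beyond ±40 treated as separation (reported as non-converged
with NA statistics, never an exception). Standard errors come from the
inverse observed information at the optimum. When only two genotype
categories are observed the model collapses to its single-intercept binary
form (α₂ reported as +∞); a monomorphic marker is untestable and reported
with a reason code. Missing genotypes are dropped per marker
(complete-case). The Wald P uses the erfc-based normal survival function,
which keeps relative accuracy far beyond |z| = 8.

## Quality control

MAF is min(f, 1−f) with f the alternate-allele frequency over non-missing
calls. The Hardy–Weinberg test is the exact conditional test: given the
allele counts, the heterozygote count under random mating has a known
distribution, and the two-sided P sums the probabilities of all
configurations no more probable than the observed one (computed in log
space; a relative tolerance of 1e-12 guards tie comparisons against float
round-off). A χ² variant is available behind `hwe_method="chisq"`. Markers
are retained when MAF > 0.05 **and** HWE P ≥ 0.001; both statistics use all
individuals, cases and controls together, matching common preprocessing
practice. Whether the original preprocessing applied HWE in controls only
is not documented; the all-samples convention is a deliberate choice here.

## Heat and diffusion

Gene heat is −log₁₀ of the minimum association P over the gene's assigned
SNPs (assignment is an explicit input table; no positional windowing). The
hottest floor(0.2·n) genes carry their heat into diffusion; the floor
convention is chosen because it is conservative and reproduces the
published 12,355 × 0.2 = 2,471 arithmetic. Ties at the cutoff break by
lexicographic gene id so selection is deterministic. Genes outside the top
fraction enter the diffusion with heat 0 rather than being dropped, keeping
the node set fixed; heat-scored genes absent from the network are dropped
with a logged count.

The network keeps STRING-style edges with combined score ≥ 400 (inclusive,
documented for bit-reproducibility), drops self-loops and isolated nodes,
and treats surviving edges as unweighted. Per connected component the
insulated diffusion kernel is F = β(I − (1−β)W)⁻¹ with β = 0.4 and W the
column-degree-normalised adjacency; columns of F sum to one (asserted to
1e-9), so the exchanged heat E = F·diag(h) conserves each gene's heat over
its column. Components are solved densely; at the package's intended desk
scale (≤ a few thousand nodes per component) this is faster and simpler
than an iterative solver.

Subnetworks are the strongly connected components of the digraph with an
arc j → i wherever E_ij ≥ δ (diagonal excluded), keeping components of size
≥ 3 by default (the floor is configurable down to 2; the method's reported
modules are typically ≥ 8 genes and a floor of 3 suppresses pair noise).

### Choosing δ and scoring significance

δ is selected from heat permutations: for each of `n_perm` random
reassignments of the heat values to genes, binary-search the sorted distinct
positive off-diagonal exchanged-heat values for the smallest δ at which the
largest strongly connected component falls below `target_max_size`
(default 10). The selected δ is the **largest** of these per-permutation
values — the smallest cutoff at which *no* permuted assignment retains a
component of the target size. This choice is what gives the permutation
test its power: with a central summary (say the median) half of all fresh
permutations would retain a target-size component and an observed module
could never look unusual, whereas with the max rule a fresh permutation
exceeds the cutoff with probability roughly 1/(n_perm+1).

Significance permutes the heat-to-gene assignment (the appropriate null
when heat is a per-gene scalar) and, for every size threshold s from 2 to
the largest observed component, compares the observed count of components
of size ≥ s with the permuted counts; the add-one estimator
p = (1 + #{perm ≥ observed}) / (n_perm + 1) bounds every p below by
1/(n_perm+1). The pipeline defaults are 60 δ-permutations and 100
significance permutations: with 100 significance permutations the expected
p for a genuinely unusual component is ≈ (1 + 100/(δ-perms+1))/101, which
is above 0.05 at 20 δ-permutations and ≈ 0.026 at 60 — the δ-permutation
count must therefore be large enough for the α = 0.05 report to be
attainable at all. The **reported discovery set** is the components at the
tightest significant scale: the largest s with p ≤ 0.05, all components of
size ≥ s.

## Drug enrichment and combinations

The drug universe N is every drug with at least one known target; K of them
carry the disease indication. A drug hits a gene set when any of its
targets lies in it (counted once regardless of multiplicity). With n
hitting drugs, k of them disease drugs, the P-value is the inclusive upper
tail P(X ≥ k) of hypergeometric(N, K, n), summed in log space; the
inclusive convention reproduces the published tail probabilities digit for
digit, which the test suite demonstrates (the strict tail does not). Drug
identifiers are case-insensitive and whitespace-normalised, since curated
tables mix spellings of the same agent. The single-locus baseline applies
the identical test to the top-n heat-ranked genes, with n matched to the
subnetwork gene-union size ("first n genes" is read as heat-ranked, the
only ordering the pipeline defines).

Combination candidates are unordered pairs of disease drugs enriched in the
same subnetwork whose within-subnetwork target sets are **disjoint**; a
relaxed "not identical" rule is available behind a flag because the strict
rule is the one consistent with the published pairing of two
non-overlapping target classes (11 × 2 = 22 pairs), and no partially
overlapping case arises there to disambiguate. Pairs are deduplicated
across subnetworks and ordered deterministically.

## Synthetic cohorts

The generator emulates the motivating study design, scaled to desk size:
34 cases / 168 controls, 500 genes × 5 SNPs = 2,500 markers, a scale-free
(Barabási–Albert, m = 2) interaction network with scores drawn uniformly in
150–1000, a planted connected module of 8 genes whose internal edges score
≥ 400 (so the module survives thresholding), all module SNPs causal with
β = 1.2, and a drug table of 100 drugs (10 disease-indicated, 4 guaranteed
a target inside the module, 1–3 targets per drug — the published universe
averages ≈ 2.9 targets per disease drug). Genotypes are drawn from the
cumulative-logit model itself: control-group intercepts are set from the
drawn MAF under Hardy–Weinberg proportions, α₁ = logit((1−f)²),
α₂ = logit(1−f²), and causal SNPs add β to both linear predictors for
cases. The default MAF range is 0.10–0.50 so that simulated markers
comfortably clear the MAF > 0.05 QC gate and sampling noise cannot silently
delete planted signal. The planted module is made connected by adding a
random spanning tree among its members; the edge count therefore equals
m(n−m) base edges plus 0 to (module−1) additions, both recorded in the
network metadata. Every output is reproducible bit-exactly from the
configuration and seed.

What the generator does **not** emulate: linkage disequilibrium between
markers, population/breed stratification, genotyping batch effects, and
realistic clustering coefficients of curated interactomes. Passing
recovery tests therefore show that the pipeline's stages compose correctly
and have power against the planted alternative under clean sampling — not
that the method is robust to confounding in real cohorts.

## Measured behaviour at the default design

(Computed by the test suite and `scripts/acceptance.py`; problem sizes were
chosen to keep a full run in minutes on one CPU.)

- Null calibration: over 5,000 no-effect SNPs at the 34/168 design, the
  fraction with Wald P < 0.05 is ≈ 0.05 and the P distribution is uniform
  (Kolmogorov–Smirnov).
- Effect recovery: β̂ within ±0.1 of the true 1.0 at 10,000 + 10,000
  individuals.
- Module recovery: the reported significant subnetworks reach Jaccard ≥ 0.5
  with the planted module in ~84% of 50 seeds.
- Planted drug enrichment: with only 4 planted disease drugs in a 100-drug
  universe the hypergeometric tail has a hard floor near
  P(X ≥ 4 | N=100, K=10, n=4) = 5.4e-5, and each chance background hit
  (≈ Binomial(96, 0.03) of them) multiplies the tail by roughly 5; the
  median tail over seeds is ≈ 7e-4 and sits close to 1e-3 by construction
  of the scaled-down design. Comparisons against the single-locus baseline
  are the informative readout at this scale.

## Known limitations

- The cumulative-logit Wald test loses calibration at very low minor-allele
  counts (separation is detected and reported, not corrected); no
  small-sample correction such as Firth penalisation is implemented.
- Diffusion treats edges as unweighted; STRING confidence scores gate edge
  existence but do not modulate transition probabilities.
- Subnetwork membership is a hard threshold on exchanged heat: linker genes
  adjacent to a hot module are routinely co-reported (the Jaccard ceiling
  in recovery tests), and a module containing a high-degree hub can
  fragment at large δ because its heat spreads thin.
- The permutation P is bounded below by 1/(n_perm+1); reporting smaller
  values requires proportionally more permutations.
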