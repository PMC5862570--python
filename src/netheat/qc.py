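"""Marker quality control: minor-allele-frequency and Hardy-Weinberg filters.

SNPs are retained when MAF > ``maf_min`` and the exact Hardy-Weinberg test
P-value is >= ``hwe_alpha``; both statistics are computed on all genotyped
individuals with missing calls excluded per marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import MISSING, GenotypeMatrix

# relative tolerance when deciding whether a heterozygote configuration is
# "no more probable than observed" — guards against float round-off ties
_HWE_REL_TOL = 1e-12


@dataclass
class QcReport:
    n_input_snps: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    maf: np.ndarray        # per input SNP
    hwe_p: np.ndarray      # per input SNP
    retained: np.ndarray   # boolean mask over input SNPs

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "n_retained": self.n_retained,
        }


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one genotype column (codes 0/1/2, -1 missing).

    Returns min(f, 1-f) where f is the alternate-allele frequency among
    non-missing calls.  All-missing columns are an error.
    """
    g = np.asarray(column)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    f = float(obs.sum()) / (2.0 * obs.size)
    return min(f, 1.0 - f)


def _hwe_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every feasible heterozygote count.

    Given ``n`` diploid individuals and ``n_rare`` copies of the rarer allele,
    the heterozygote count h under Hardy-Weinberg random mating, conditional on
    the allele counts, takes values with the parity of ``n_rare`` in
    ``[h_min, n_rare]``.  Unnormalized log-weight of h:
    ``h*log(2) - lgamma-terms`` of the genotype multinomial.
    """
    n_common = 2 * n - n_rare
    h_min = max(n_rare % 2, n_rare - n_common)
    hs = np.arange(h_min, n_rare + 1, 2)
    rare_hom = (n_rare - hs) // 2
    common_hom = (n_common - hs) // 2
    logw = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    return hs, logw - logsumexp(logw)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Sums the conditional probabilities (given the allele counts) of every
    heterozygote configuration no more probable than the observed one.
    Symmetric in the major/minor labelling; returns a value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_rare = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    hs, logp = _hwe_log_probs(n, n_rare)
    probs = np.exp(logp)
    p_obs = probs[np.flatnonzero(hs == n_het)[0]]
    p = float(probs[probs <= p_obs * (1.0 + _HWE_REL_TOL)].sum())
    return min(p, 1.0)


def hwe_chisq_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test (no continuity correction)."""
    from scipy.stats import chi2

    counts = np.array((n_hom_major, n_het, n_hom_minor), dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    f = (2 * counts[2] + counts[1]) / (2 * n)
    expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    if (expected == 0).any():  # monomorphic: no deviation possible
        return 1.0
    stat = float(((counts - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    g = np.asarray(column)
    obs = g[g != MISSING]
    n0 = int((obs == 0).sum())
    n1 = int((obs == 1).sum())
    n2 = int((obs == 2).sum())
    # orient so the first count is the major homozygote
    if 2 * n2 + n1 > 2 * n0 + n1:
        n0, n2 = n2, n0
    return n0, n1, n2


def apply_qc(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs: keep MAF > ``maf_min`` and HWE P >= ``hwe_alpha``.

    Deterministic and idempotent.  An empty retained set triggers a warning,
    not an error, so callers can inspect the report.
    """
    if not (0 < maf_min < 1) or not (0 < hwe_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    test = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[hwe_method]

    m = gm.n_snps
    maf = np.empty(m)
    hwe_p = np.empty(m)
    for j in range(m):
        col = gm.genotypes[:, j]
        maf[j] = compute_maf(col)
        hwe_p[j] = test(*_genotype_counts(col))

    pass_maf = maf > maf_min
    pass_hwe = hwe_p >= hwe_alpha
    retained = pass_maf & pass_hwe
    report = QcReport(
        n_input_snps=m,
        n_removed_maf=int((~pass_maf).sum()),
        n_removed_hwe=int((~pass_hwe).sum()),
        n_retained=int(retained.sum()),
        maf=maf,
        hwe_p=hwe_p,
        retained=retained,
    )
    if report.n_retained == 0:
        warnings.warn("QC removed every SNP", stacklevel=2)
    return gm.subset_snps(retained), report
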