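"""Candidate synergistic drug pairs from shared subnetworks.

Two disease drugs become a combination candidate when they are enriched in
the same subnetwork but act through different targets there.  "Different" is
strict by default — their within-subnetwork target sets must be disjoint —
with an optional relaxation to merely non-identical sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass
class DrugPair:
    subnetwork: int
    drug_a: str
    drug_b: str
    targets_a: frozenset[str]
    targets_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.drug_a >= self.drug_b:
            raise ValueError("pair must be in canonical order drug_a < drug_b")


def propose_combinations(
    listing: pd.DataFrame, strict_disjoint: bool = True
) -> list[DrugPair]:
    """Enumerate disease-drug pairs with different targets in a shared subnetwork.

    ``listing`` is the per-subnetwork drug/target table from
    ``subnetwork_enrichment`` (columns subnetwork, drug_id, gene_id,
    is_disease_drug).  Pairs are deduplicated across subnetworks (first
    subnetwork wins) and ordered by (subnetwork index, drug_a, drug_b).
    """
    pairs: list[DrugPair] = []
    seen: set[tuple[str, str]] = set()
    if listing.empty:
        return pairs
    disease = listing[listing["is_disease_drug"]]
    for sub_idx in sorted(disease["subnetwork"].unique()):
        block = disease[disease["subnetwork"] == sub_idx]
        targets = {
            drug: frozenset(g["gene_id"])
            for drug, g in block.groupby("drug_id")
        }
        for a, b in combinations(sorted(targets), 2):
            ta, tb = targets[a], targets[b]
            different = ta.isdisjoint(tb) if strict_disjoint else ta != tb
            if not different or (a, b) in seen:
                continue
            seen.add((a, b))
            pairs.append(DrugPair(int(sub_idx), a, b, ta, tb))
    return pairs


def pair_count(
    class_counts: list[int],
    disjoint: list[list[bool]] | None = None,
) -> int:
    """Closed-form pair total: sum of count_i * count_j over disjoint class pairs.

    Classes are groups of drugs sharing one distinct target set; ``disjoint``
    gives the pairwise disjointness (all-pairs-disjoint when omitted).
    """
    total = 0
    for i, j in combinations(range(len(class_counts)), 2):
        if disjoint is None or disjoint[i][j]:
            total += class_counts[i] * class_counts[j]
    return total


def combos_frame(pairs: list[DrugPair]) -> pd.DataFrame:
    """Tabular view of proposed pairs (target sets as comma-joined ids)."""
    return pd.DataFrame(
        {
            "subnetwork": [p.subnetwork for p in pairs],
            "drug_a": [p.drug_a for p in pairs],
            "drug_b": [p.drug_b for p in pairs],
            "targets_a": [",".join(sorted(p.targets_a)) for p in pairs],
            "targets_b": [",".join(sorted(p.targets_b)) for p in pairs],
        }
    )


def pubmed_query_strings(pairs: list[DrugPair], keyword: str = "epilepsy") -> list[str]:
    """Co-occurrence query strings for manual literature lookup (no fetching)."""
    return [f'"{p.drug_a}" AND "{p.drug_b}" AND "{keyword}"' for p in pairs]
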