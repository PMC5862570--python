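"""Readers and writers for the pipeline's plain-text formats.

All files are UTF-8, tab-separated, with an optional provenance header of
``# key=value`` comment lines before the column header.  Writers emit
canonical files (sorted where an order is documented, floats via ``repr``) so
that write(read(x)) is byte-identical; readers raise errors that name the
offending line.

Genotype TSV: first column ``phenotype`` (0 control / 1 case), then one
column per SNP with codes 0/1/2/NA; ``-9`` and ``.`` are accepted as missing
on read and normalized to ``NA`` on write.  PLINK .ped/.map import codes each
marker as copies of its minor allele (ties broken toward the
lexicographically larger allele); ``0`` alleles are missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GroundTruth
from .diffusion import InteractionNetwork, SignificanceReport, Subnetwork, build_network
from .enrichment import EnrichmentResult

_NA_IN = {"NA", "-9", "."}


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}={provenance[k]}" for k in provenance]


def read_provenance(path) -> dict:
    """Parse the ``# key=value`` comment header of any pipeline file."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                out[k.strip()] = v.strip()
    return out


def _read_table(path, expected_header: list[str]) -> list[tuple[int, list[str]]]:
    """Rows of a headered TSV as (lineno, fields), comments skipped."""
    rows = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != expected_header:
                    raise ParseError(
                        path, lineno,
                        f"expected header {expected_header}, got {fields}",
                    )
                header_seen = True
                continue
            if len(fields) != len(expected_header):
                raise ParseError(
                    path, lineno,
                    f"expected {len(expected_header)} fields, got {len(fields)}",
                )
            rows.append((lineno, fields))
    if not header_seen:
        raise ParseError(path, 1, "missing header line")
    return rows


def _write_lines(path, lines: list[str]) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- genotypes

def write_genotypes(path, gm: GenotypeMatrix, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("\t".join(["phenotype"] + gm.snp_ids))
    for i in range(gm.n_individuals):
        codes = [
            "NA" if c == -1 else str(int(c)) for c in gm.genotypes[i]
        ]
        lines.append("\t".join([str(int(gm.phenotype[i]))] + codes))
    _write_lines(path, lines)


def read_genotypes(path) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [
            (no, ln.rstrip("\n"))
            for no, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise ParseError(path, 1, "empty genotype file")
    header = lines[0][1].split("\t")
    if header[0] != "phenotype":
        raise ParseError(path, lines[0][0], "first column must be 'phenotype'")
    snp_ids = header[1:]
    phenos, rows = [], []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                path, lineno, f"expected {len(header)} fields, got {len(fields)}"
            )
        if fields[0] not in ("0", "1"):
            raise ParseError(path, lineno, f"phenotype must be 0/1, got {fields[0]!r}")
        phenos.append(int(fields[0]))
        row = np.empty(len(snp_ids), dtype=np.int8)
        for j, tok in enumerate(fields[1:]):
            if tok in _NA_IN:
                row[j] = -1
            elif tok in ("0", "1", "2"):
                row[j] = int(tok)
            else:
                raise ParseError(
                    path, lineno, f"bad genotype code {tok!r} in column {snp_ids[j]}"
                )
        rows.append(row)
    return GenotypeMatrix(
        genotypes=np.vstack(rows),
        phenotype=np.array(phenos, dtype=np.int8),
        snp_ids=snp_ids,
    )


# ------------------------------------------------------------- PLINK import

def read_ped(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Import PLINK .ped/.map text files.

    Phenotype column must be 1 (control) or 2 (case).  Genotype codes count
    the minor allele per marker; allele ``0`` marks a missing call.  Returns
    the matrix and a map frame (snp_id, chrom, pos) — gene assignment comes
    from a separate table.
    """
    snps = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(map_path, lineno, "expected 4 columns (chrom id cM pos)")
            snps.append((fields[1], fields[0], int(fields[3])))
    m = len(snps)

    phenos, allele_rows = [], []
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    ped_path, lineno,
                    f"expected {6 + 2 * m} fields for {m} markers, got {len(fields)}",
                )
            if fields[5] not in ("1", "2"):
                raise ParseError(
                    ped_path, lineno, f"phenotype must be 1/2, got {fields[5]!r}"
                )
            phenos.append(int(fields[5]) - 1)
            allele_rows.append(fields[6:])

    n = len(allele_rows)
    geno = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        counts: dict[str, int] = {}
        for a, b in pairs:
            for al in (a, b):
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise ParseError(ped_path, 1, f"marker {snps[j][0]} has >2 alleles")
        if len(counts) == 2:
            # count the rarer allele; ties toward the lexicographically larger
            minor = min(counts, key=lambda al: (counts[al], [-ord(c) for c in al]))
        else:
            minor = None  # monomorphic: minor allele absent, every call codes 0
        for i, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                geno[i, j] = -1
            else:
                geno[i, j] = (a == minor) + (b == minor)
    gm = GenotypeMatrix(
        genotypes=geno,
        phenotype=np.array(phenos, dtype=np.int8),
        snp_ids=[s[0] for s in snps],
    )
    snp_map = pd.DataFrame(
        {"snp_id": [s[0] for s in snps],
         "chrom": [s[1] for s in snps],
         "pos": [s[2] for s in snps]}
    )
    return gm, snp_map


def write_ped(ped_path, map_path, gm: GenotypeMatrix, snp_map: pd.DataFrame) -> None:
    """Export to PLINK .ped/.map (alleles A/C; missing 0 0; phenotype 1/2)."""
    pos = snp_map.set_index("snp_id")
    with open(map_path, "w", encoding="utf-8") as fh:
        for snp in gm.snp_ids:
            row = pos.loc[snp]
            fh.write(f"{row['chrom']}\t{snp}\t0\t{row['pos']}\n")
    alleles = {0: "A A", 1: "A C", 2: "C C", -1: "0 0"}
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i in range(gm.n_individuals):
            lead = f"fam{i + 1} ind{i + 1} 0 0 0 {int(gm.phenotype[i]) + 1}"
            body = " ".join(alleles[int(c)] for c in gm.genotypes[i])
            fh.write(f"{lead} {body}\n")


# ------------------------------------------------------------- small tables

def write_snp_map(path, snp_map: pd.DataFrame, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("snp_id\tchrom\tpos\tgene_id")
    for r in snp_map.itertuples(index=False):
        lines.append(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.gene_id}")
    _write_lines(path, lines)


def read_snp_map(path) -> pd.DataFrame:
    rows = _read_table(path, ["snp_id", "chrom", "pos", "gene_id"])
    seen: set[str] = set()
    out = []
    for lineno, (snp, chrom, pos, gene) in rows:
        if snp in seen:
            raise ParseError(path, lineno, f"duplicate snp_id {snp!r}")
        seen.add(snp)
        try:
            out.append({"snp_id": snp, "chrom": int(chrom), "pos": int(pos), "gene_id": gene})
        except ValueError:
            raise ParseError(path, lineno, f"non-integer chrom/pos {chrom!r}/{pos!r}") from None
    return pd.DataFrame(out)


def write_edges(path, network: InteractionNetwork, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("gene_a\tgene_b\tcombined_score")
    for a, b, score in network.edge_list():
        lines.append(f"{a}\t{b}\t{score}")
    _write_lines(path, lines)


def read_edges(path) -> list[tuple[str, str, int]]:
    rows = _read_table(path, ["gene_a", "gene_b", "combined_score"])
    out = []
    for lineno, (a, b, score) in rows:
        try:
            s = int(score)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer combined_score {score!r}") from None
        if not (0 <= s <= 1000):
            raise ParseError(path, lineno, f"combined_score {s} outside [0, 1000]")
        out.append((a, b, s))
    return out


def read_network(path, score_threshold: int = 400) -> InteractionNetwork:
    return build_network(read_edges(path), score_threshold)


def write_drug_targets(path, table: pd.DataFrame, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("drug_id\tgene_id\tis_disease_drug")
    df = table.sort_values(["drug_id", "gene_id"], kind="mergesort")
    for r in df.itertuples(index=False):
        lines.append(f"{r.drug_id}\t{r.gene_id}\t{int(r.is_disease_drug)}")
    _write_lines(path, lines)


def read_drug_targets(path) -> pd.DataFrame:
    rows = _read_table(path, ["drug_id", "gene_id", "is_disease_drug"])
    seen: set[tuple[str, str]] = set()
    out = []
    for lineno, (drug, gene, flag) in rows:
        if flag not in ("0", "1"):
            raise ParseError(path, lineno, f"is_disease_drug must be 0/1, got {flag!r}")
        key = (drug, gene)
        if key in seen:
            raise ParseError(path, lineno, f"duplicate (drug, target) row {key}")
        seen.add(key)
        out.append({"drug_id": drug, "gene_id": gene, "is_disease_drug": bool(int(flag))})
    return pd.DataFrame(out)


# ------------------------------------------------------ association / heat

_ASSOC_COLS = ["snp_id", "chrom", "pos", "beta", "se", "z", "p", "n_used", "status"]


def write_assoc(path, assoc: pd.DataFrame, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("\t".join(_ASSOC_COLS))
    for r in assoc.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    _fmt(r.chrom if r.chrom is not pd.NA else None),
                    _fmt(r.pos if r.pos is not pd.NA else None),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.z),
                    _fmt(r.p),
                    str(int(r.n_used)),
                    r.status,
                ]
            )
        )
    _write_lines(path, lines)


def read_assoc(path) -> pd.DataFrame:
    rows = _read_table(path, _ASSOC_COLS)
    out = []
    for lineno, fields in rows:
        rec = dict(zip(_ASSOC_COLS, fields))
        try:
            for key in ("beta", "se", "z", "p"):
                rec[key] = np.nan if rec[key] == "NA" else float(rec[key])
            for key in ("chrom", "pos"):
                rec[key] = pd.NA if rec[key] == "NA" else int(rec[key])
            rec["n_used"] = int(rec["n_used"])
        except ValueError:
            raise ParseError(path, lineno, "malformed numeric field") from None
        out.append(rec)
    return pd.DataFrame(out, columns=_ASSOC_COLS)


def write_gene_heat(path, gene_heat: pd.DataFrame, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("gene_id\tmin_p\theat\tn_snps")
    for r in gene_heat.itertuples(index=False):
        lines.append(f"{r.gene_id}\t{_fmt(r.min_p)}\t{_fmt(r.heat)}\t{int(r.n_snps)}")
    _write_lines(path, lines)


def read_gene_heat(path) -> pd.DataFrame:
    rows = _read_table(path, ["gene_id", "min_p", "heat", "n_snps"])
    out = []
    for lineno, (gene, min_p, heat, n_snps) in rows:
        try:
            out.append(
                {"gene_id": gene, "min_p": float(min_p),
                 "heat": float(heat), "n_snps": int(n_snps)}
            )
        except ValueError:
            raise ParseError(path, lineno, "malformed numeric field") from None
    return pd.DataFrame(out)


# ------------------------------------------------------------------- JSONs

def write_subnetworks(
    path,
    subnetworks: list[Subnetwork],
    report: SignificanceReport | None = None,
    provenance: dict | None = None,
) -> None:
    payload = {
        "provenance": provenance or {},
        "delta": report.delta if report else None,
        "significance": (
            report.table.to_dict(orient="records") if report is not None else []
        ),
        "subnetworks": [
            {"index": s.index, "genes": s.genes, "size": s.size} for s in subnetworks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_subnetworks(path) -> tuple[list[Subnetwork], dict]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    subs = [
        Subnetwork(index=s["index"], genes=list(s["genes"]), size=s["size"])
        for s in payload["subnetworks"]
    ]
    return subs, payload


def write_enrichment(
    path,
    subnetwork_result: EnrichmentResult,
    baseline_result: EnrichmentResult | None,
    listing: pd.DataFrame,
    provenance: dict | None = None,
) -> None:
    def as_dict(r: EnrichmentResult | None):
        if r is None:
            return None
        return {"N": r.N, "K": r.K, "n": r.n, "k": r.k, "p": r.p, "drugs": r.drugs}

    payload = {
        "provenance": provenance or {},
        "subnetwork_enrichment": as_dict(subnetwork_result),
        "single_locus_baseline": as_dict(baseline_result),
        "listing": listing.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_enrichment(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_combos(path, combos: pd.DataFrame, provenance: dict | None = None) -> None:
    lines = _provenance_lines(provenance)
    lines.append("subnetwork\tdrug_a\tdrug_b\ttargets_a\ttargets_b")
    for r in combos.itertuples(index=False):
        lines.append(f"{r.subnetwork}\t{r.drug_a}\t{r.drug_b}\t{r.targets_a}\t{r.targets_b}")
    _write_lines(path, lines)


def read_combos(path) -> pd.DataFrame:
    rows = _read_table(path, ["subnetwork", "drug_a", "drug_b", "targets_a", "targets_b"])
    return pd.DataFrame(
        [
            {"subnetwork": int(s), "drug_a": a, "drug_b": b, "targets_a": ta, "targets_b": tb}
            for _, (s, a, b, ta, tb) in rows
        ],
        columns=["subnetwork", "drug_a", "drug_b", "targets_a", "targets_b"],
    )


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "planted_genes": sorted(truth.planted_genes),
        "causal_snps": sorted(truth.causal_snps),
        "planted_disease_drugs": sorted(truth.planted_disease_drugs),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        planted_genes=set(payload["planted_genes"]),
        causal_snps=set(payload["causal_snps"]),
        planted_disease_drugs=set(payload["planted_disease_drugs"]),
    )
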