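"""End-to-end orchestration: QC -> GWAS -> heat -> subnetworks -> drugs -> combos.

Every stage output carries a provenance header (config hash + seed) and the
run manifest records parameter values, per-stage row counts and output file
hashes, so reruns with the same seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, combos, diffusion, enrichment, gwas, heat, io, qc

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genotypes: str
    snp_map: str
    network: str
    drug_targets: str
    outdir: str
    maf_min: float = 0.05
    hwe_alpha: float = 0.001
    model: str = "cumlogit"
    fraction: float = 0.2
    beta: float = 0.4
    score_threshold: int = 400
    n_perm: int = 100
    delta_perm: int = 60
    target_max_size: int = 10
    min_size: int = 3
    baseline_n: int | str = "auto"
    seed: int = 7

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat key=value config file; later command-line overrides win."""
        values: dict = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, raw = line.partition("=")
                values[key.strip()] = raw.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        coerced = {}
        for key, raw in values.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("maf_min", "hwe_alpha", "fraction", "beta"):
                coerced[key] = float(raw)
            elif key in ("score_threshold", "n_perm", "delta_perm",
                         "target_max_size", "min_size", "seed"):
                coerced[key] = int(raw)
            elif key == "baseline_n":
                coerced[key] = raw if raw == "auto" else int(raw)
            else:
                coerced[key] = raw
        return cls(**coerced)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        params = {
            k: v for k, v in asdict(self).items()
            if k not in ("genotypes", "snp_map", "network", "drug_targets", "outdir")
        }
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Manifest:
    version: str
    seed: int
    config: dict
    config_hash: str
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # file -> sha256

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> Manifest:
    """Execute the full pipeline; stage failure halts with the stage name."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"netheat": __version__, "seed": cfg.seed, "config_hash": cfg.config_hash()}
    manifest = Manifest(
        version=__version__, seed=cfg.seed, config=asdict(cfg),
        config_hash=cfg.config_hash(),
    )

    def record(name: str, path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    stage = "qc"
    try:
        gm = io.read_genotypes(cfg.genotypes)
        snp_map = io.read_snp_map(cfg.snp_map)
        gm_qc, report = qc.apply_qc(gm, cfg.maf_min, cfg.hwe_alpha)
        path = outdir / "genotypes.qc.tsv"
        io.write_genotypes(path, gm_qc, prov)
        record(stage, path)
        (outdir / "qc_report.json").write_text(
            json.dumps({**prov, **report.to_dict()}, indent=2) + "\n", encoding="utf-8"
        )
        record(stage, outdir / "qc_report.json")
        manifest.counts["snps_input"] = report.n_input_snps
        manifest.counts["snps_after_qc"] = report.n_retained
        logger.info("QC: %d of %d SNPs retained", report.n_retained, report.n_input_snps)

        stage = "gwas"
        assoc = gwas.run_gwas(gm_qc, snp_map, model=cfg.model)
        path = outdir / "assoc.tsv"
        io.write_assoc(path, assoc, prov)
        record(stage, path)
        manifest.counts["snps_tested"] = int((assoc["status"] == "ok").sum())

        stage = "heat"
        gene_heat = heat.aggregate_min_p(assoc, snp_map)
        path = outdir / "geneheat.tsv"
        io.write_gene_heat(path, gene_heat, prov)
        record(stage, path)
        manifest.counts["genes_scored"] = len(gene_heat)
        manifest.counts["genes_top_fraction"] = len(
            heat.select_top_fraction(gene_heat, cfg.fraction)
        )

        stage = "subnetworks"
        network = io.read_network(cfg.network, cfg.score_threshold)
        kernel = diffusion.diffusion_kernel(network, cfg.beta)
        hvec = heat.heat_vector(gene_heat, kernel.nodes, cfg.fraction)
        delta = diffusion.choose_delta(
            network, hvec, cfg.beta, n_perm=cfg.delta_perm,
            target_max_size=cfg.target_max_size, seed=cfg.seed, kernel=kernel,
        )
        E = diffusion.exchanged_heat(kernel, hvec)
        subs = diffusion.extract_subnetworks(E, delta, kernel.nodes, cfg.min_size)
        sig = diffusion.permutation_significance(
            network, hvec, delta, cfg.beta, n_perm=cfg.n_perm,
            seed=cfg.seed, kernel=kernel,
        )
        path = outdir / "subnetworks.json"
        io.write_subnetworks(path, subs, sig, prov)
        record(stage, path)
        manifest.counts["subnetworks"] = len(subs)
        manifest.counts["subnetwork_genes"] = sum(s.size for s in subs)
        logger.info("subnetworks: %d (delta=%.3g)", len(subs), delta)

        stage = "drugs"
        table = enrichment.DrugTargetTable.from_frame(io.read_drug_targets(cfg.drug_targets))
        if subs:
            sub_res, listing = enrichment.subnetwork_enrichment(subs, table)
            top_n = (
                manifest.counts["subnetwork_genes"]
                if cfg.baseline_n == "auto" else int(cfg.baseline_n)
            )
            top_n = min(top_n, manifest.counts["genes_scored"])
            base_res = enrichment.single_locus_baseline(gene_heat, table, top_n)
        else:
            sub_res, listing = None, None
            base_res = None
        path = outdir / "enrichment.json"
        if sub_res is not None:
            io.write_enrichment(path, sub_res, base_res, listing, prov)
            record(stage, path)
            manifest.counts["drugs_enriched"] = sub_res.n
            manifest.counts["disease_drugs_enriched"] = sub_res.k

        stage = "combos"
        if sub_res is not None:
            pairs = combos.propose_combinations(listing)
            frame = combos.combos_frame(pairs)
            path = outdir / "combos.tsv"
            io.write_combos(path, frame, prov)
            record(stage, path)
            manifest.counts["drug_pairs"] = len(pairs)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "manifest.json")
    return manifest
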