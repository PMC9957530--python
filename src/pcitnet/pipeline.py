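"""End-to-end pipeline driver: filter -> DE -> networks -> comparison.

The stages mirror the analysis workflow: low-expression filtering of the
count matrix, NB Wald differential expression with DEG calling, per-group
PCIT co-expression networks anchored on the DEGs, hub identification,
union reference network and differential-connectivity z-scores, plus
optional over-representation analysis (given a GMT file) and qPCR
validation (given a Ct table). Every intermediate table is written with a
provenance header, and identical configuration + inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .connectivity import compare_networks
from .diffexpr import de_analysis, deg_set
from .enrichment import hypergeom_ora, read_gmt
from .errors import ConfigurationError, PipelineError
from .io import read_counts, read_ct, write_counts, write_table
from .network import build_group_network, write_sif
from .preprocess import GROUPS, cpm, filter_low_expression
from .qpcr import validate_targets

logger = logging.getLogger("pcitnet")


@dataclass(frozen=True)
class PipelineConfig:
    """All paths, thresholds and conventions of one pipeline run."""

    counts: str = ""
    metadata: str = ""
    out_dir: str = "pcitnet_out"
    gmt: str | None = None
    ct_table: str | None = None
    qpcr_targets: tuple[str, ...] = ()
    qpcr_reference: str = "GAPDH"

    cpm_threshold: float = 1.0
    min_fraction: float = 0.5
    padj_max: float = 0.05
    lfc_min: float = 0.5
    r_min: float = 0.95
    p_max: float = 0.05
    hub_sd_mult: float = 2.0
    dk_z: float = 1.96

    lfc_sign: str = "SFH"  # positive log2fc = higher in this group
    sd_denominator: str = "n-1"  # hub SD convention: "n-1" or "n"
    correlation_scale: str = "cpm"  # "cpm" or "log2cpm"
    seed: int = 0
    force_large: bool = False

    def __post_init__(self) -> None:
        checks = [
            ("cpm_threshold", self.cpm_threshold >= 0),
            ("min_fraction", 0.0 <= self.min_fraction <= 1.0),
            ("padj_max", 0.0 <= self.padj_max <= 1.0),
            ("lfc_min", self.lfc_min >= 0),
            ("r_min", 0.0 <= self.r_min <= 1.0),
            ("p_max", 0.0 <= self.p_max <= 1.0),
            ("hub_sd_mult", self.hub_sd_mult >= 0),
            ("dk_z", self.dk_z >= 0),
            ("lfc_sign", self.lfc_sign in GROUPS),
            ("sd_denominator", self.sd_denominator in ("n-1", "n")),
            ("correlation_scale", self.correlation_scale in ("cpm", "log2cpm")),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(
                    f"configuration field {name!r} out of range: "
                    f"{getattr(self, name)!r}"
                )
        object.__setattr__(self, "qpcr_targets", tuple(self.qpcr_targets))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of keys")
        return cls.from_dict(data)

    @property
    def hub_ddof(self) -> int:
        return 1 if self.sd_denominator == "n-1" else 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short digest of the analysis parameters (the output location
        does not alter what is computed and is excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, hint: str):
    """Decorator-free stage wrapper: re-raise with stage name and hint."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc} ({hint})") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all result tables plus a manifest.

    Returns a dict with the in-memory results (filtered counts, DE table,
    both networks, connectivity table, union network, optional enrichment
    and qPCR tables) and the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    counts_stage: dict[str, int] = {}
    results: dict = {}

    with _stage("load", "check the counts/metadata TSV schemas"):
        cm = read_counts(config.counts, config.metadata)
        counts_stage["input_genes"] = cm.n_genes
        counts_stage["input_samples"] = cm.n_samples

    with _stage("filter", "adjust cpm_threshold/min_fraction"):
        filtered, report = filter_low_expression(
            cm, cpm_threshold=config.cpm_threshold, min_fraction=config.min_fraction
        )
        write_table(report, out / "filter_report.tsv", "filter", chash)
        write_counts(filtered, out / "filtered_counts.tsv", out / "sample_metadata.tsv")
        counts_stage["filtered_genes"] = filtered.n_genes
        results["filtered"] = filtered

    with _stage("de", "differential expression needs >= 2 samples per group"):
        de = de_analysis(
            filtered,
            padj_max=config.padj_max,
            lfc_min=config.lfc_min,
            positive_group=config.lfc_sign,
        )
        write_table(de, out / "de_results.tsv", "de", chash)
        degs = deg_set(de)
        counts_stage["degs"] = len(degs)
        results["de"] = de

    with _stage("network", "PCIT is O(p^3); reduce genes or set force_large"):
        expr = cpm(filtered)
        nets = {}
        for group in GROUPS:
            net = build_group_network(
                expr,
                group,
                degs,
                r_min=config.r_min,
                p_max=config.p_max,
                scale=config.correlation_scale,
                force=config.force_large,
            )
            write_table(
                net.edges, out / f"network_{group}.tsv", f"network_{group}", chash,
                index=False,
            )
            write_sif(net, out / f"network_{group}.sif")
            counts_stage[f"edges_{group}"] = net.n_edges
            nets[group] = net
        results["networks"] = nets

    with _stage("compare", "both group networks must share the gene namespace"):
        table, union = compare_networks(
            nets["FH"],
            nets["SFH"],
            z_threshold=config.dk_z,
            hub_sd_mult=config.hub_sd_mult,
            hub_ddof=config.hub_ddof,
        )
        node_attrs = union.nodes.copy()
        node_attrs["hub_class"] = table["hub_class"].reindex(
            node_attrs.index, fill_value="none"
        )
        node_attrs["is_deg"] = [g in degs for g in node_attrs.index]
        write_table(table, out / "connectivity.tsv", "compare", chash)
        write_table(union.edges, out / "union_edges.tsv", "compare", chash, index=False)
        write_table(node_attrs, out / "union_nodes.tsv", "compare", chash)
        counts_stage["union_nodes"] = union.n_nodes
        counts_stage["union_edges"] = union.n_edges
        counts_stage["dk_significant"] = int(table["dk_significant"].sum())
        results["connectivity"] = table
        results["union"] = union

    if config.gmt:
        with _stage("enrich", "query genes must overlap the universe"):
            collection = read_gmt(config.gmt)
            universe = set(filtered.gene_ids)
            ora = hypergeom_ora(degs, collection, universe=universe)
            write_table(ora, out / "enrichment_degs.tsv", "enrich", chash)
            counts_stage["enriched_sets"] = int(
                (ora["padj_bonferroni"] <= 0.05).sum()
            )
            results["enrichment"] = ora

    if config.ct_table:
        with _stage("qpcr", "Ct table needs sample_id, group, gene, ct columns"):
            ct = read_ct(config.ct_table)
            targets = list(config.qpcr_targets) or sorted(
                set(ct["gene"]) - {config.qpcr_reference}
            )
            qv = validate_targets(ct, targets, config.qpcr_reference)
            write_table(qv, out / "qpcr_validation.tsv", "qpcr", chash)
            counts_stage["qpcr_targets"] = len(qv)
            results["qpcr"] = qv

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "stage_counts": counts_stage,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
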