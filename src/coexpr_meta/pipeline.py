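"""Config-driven orchestration: ingest -> QC -> meta-analysis -> optional
GSEA -> optional network stage, with a log and a machine-readable manifest.

Configuration is TOML or YAML. Minimal example::

    target = "NNAT"
    output_dir = "out"

    [[datasets]]
    name = "sim1"
    expression = "sim1_expression.tsv"
    calls = "sim1_calls.tsv"          # optional
    annotation = "sim1_annotation.tsv"

Optional ``[filter]``, ``[meta]``, ``[gsea]`` and ``[network]`` tables
override the defaults (intensity filter 100, |r| filter 0.2, present
fraction 0.30, alpha 0.05, 1000 permutations, network expression
threshold 200). A single ``seed`` governs every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from coexpr_meta import __version__
from coexpr_meta.errors import ValidationError
from coexpr_meta.expression_io import (
    read_annotation,
    read_calls,
    read_expression_matrix,
    write_results_table,
)
from coexpr_meta.qc_filter import FilterConfig
from coexpr_meta.correlation_meta import MetaConfig, run_meta
from coexpr_meta.gsea_lite import (
    filter_gene_sets,
    permutation_test,
    rank_by_correlation,
    read_gmt,
    write_enrichment_table,
)
from coexpr_meta.ppi_neighbors import (
    expression_filter,
    first_neighbor_subgraph,
    read_edge_list,
    subgraph_stats,
    write_edge_table,
    write_node_table,
)

logger = logging.getLogger(__name__)

_FILTER_KEYS = {"expr_min", "abs_r_min", "present_frac_min"}
_META_KEYS = {"method", "denominator", "t_to_z_mode", "universe_m", "alpha"}
_GSEA_KEYS = {"gmt", "n_perm", "exponent", "min_size", "max_size", "dataset"}
_NETWORK_KEYS = {"edge_list", "format", "expression_table", "threshold"}
_DATASET_KEYS = {"name", "expression", "calls", "annotation"}
_TOP_KEYS = {
    "target", "output_dir", "seed", "datasets", "exclusions",
    "filter", "meta", "gsea", "network",
}


@dataclass(frozen=True)
class DatasetEntry:
    name: str
    expression: Path
    annotation: Path
    calls: Path | None = None


@dataclass(frozen=True)
class GseaConfig:
    gmt: Path
    n_perm: int = 1000
    exponent: float = 1.0
    min_size: int = 15
    max_size: int = 500
    dataset: str | None = None  # defaults to the first dataset


@dataclass(frozen=True)
class NetworkConfig:
    edge_list: Path
    format: str = "SIF"
    expression_table: Path | None = None
    threshold: float = 200.0


@dataclass(frozen=True)
class PipelineConfig:
    target: str
    output_dir: Path
    datasets: tuple[DatasetEntry, ...]
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    meta_cfg: MetaConfig = field(default_factory=MetaConfig)
    exclusions: Path | None = None
    gsea: GseaConfig | None = None
    network: NetworkConfig | None = None
    seed: int = 0


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def _existing(path, base: Path, key: str) -> Path:
    p = Path(path)
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        raise ValidationError(f"{key}: path {p} does not exist")
    return p


def validate_config(path) -> PipelineConfig:
    """Parse and fully validate a TOML/YAML pipeline config."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    base = path.parent
    _check_keys(raw, _TOP_KEYS, "config")
    target = str(raw.get("target", "")).strip()
    if not target:
        raise ValidationError("missing required key 'target'")
    entries_raw = raw.get("datasets") or []
    if not entries_raw:
        raise ValidationError("need at least one [[datasets]] entry")
    entries = []
    for i, entry in enumerate(entries_raw):
        _check_keys(entry, _DATASET_KEYS, f"datasets[{i}]")
        for key in ("name", "expression", "annotation"):
            if key not in entry:
                raise ValidationError(f"datasets[{i}]: missing key {key!r}")
        entries.append(
            DatasetEntry(
                name=str(entry["name"]),
                expression=_existing(entry["expression"], base, "expression"),
                annotation=_existing(entry["annotation"], base, "annotation"),
                calls=(
                    _existing(entry["calls"], base, "calls")
                    if entry.get("calls")
                    else None
                ),
            )
        )
    filt = raw.get("filter", {})
    _check_keys(filt, _FILTER_KEYS, "[filter]")
    filter_cfg = FilterConfig(**filt)
    meta = raw.get("meta", {})
    _check_keys(meta, _META_KEYS, "[meta]")
    meta_cfg = MetaConfig(**meta)
    gsea_cfg = None
    if "gsea" in raw:
        g = dict(raw["gsea"])
        _check_keys(g, _GSEA_KEYS, "[gsea]")
        if "gmt" not in g:
            raise ValidationError("[gsea]: missing key 'gmt'")
        g["gmt"] = _existing(g["gmt"], base, "gmt")
        gsea_cfg = GseaConfig(**g)
        if gsea_cfg.n_perm < 1:
            raise ValidationError("[gsea]: n_perm must be >= 1")
    net_cfg = None
    if "network" in raw:
        n = dict(raw["network"])
        _check_keys(n, _NETWORK_KEYS, "[network]")
        if "edge_list" not in n:
            raise ValidationError("[network]: missing key 'edge_list'")
        n["edge_list"] = _existing(n["edge_list"], base, "edge_list")
        if n.get("expression_table"):
            n["expression_table"] = _existing(
                n["expression_table"], base, "expression_table"
            )
        net_cfg = NetworkConfig(**n)
    exclusions = None
    if raw.get("exclusions"):
        exclusions = _existing(raw["exclusions"], base, "exclusions")
    out_dir = Path(raw.get("output_dir", "coexpr_meta_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return PipelineConfig(
        target=target,
        output_dir=out_dir,
        datasets=tuple(entries),
        filter_cfg=filter_cfg,
        meta_cfg=meta_cfg,
        exclusions=exclusions,
        gsea=gsea_cfg,
        network=net_cfg,
        seed=int(raw.get("seed", 0)),
    )


def _load_datasets(config: PipelineConfig):
    datasets = []
    for entry in config.datasets:
        ds = read_expression_matrix(entry.expression, entry.name)
        if entry.calls is not None:
            ds = read_calls(entry.calls, ds)
        ds = ds.with_annotation(read_annotation(entry.annotation))
        datasets.append(ds)
    return datasets


def _read_symbol_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def _read_expression_table(path) -> dict[str, float]:
    expr: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"line {lineno}: expression table needs 2 columns"
                )
            if lineno == 1 and not _is_number(parts[1]):
                continue  # header row
            expr[parts[0].upper()] = float(parts[1])
    return expr


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Writes ``meta_results.tsv`` (and optionally ``gsea_results.tsv``,
    ``network_stats.tsv`` plus node/edge tables and GraphML), a
    ``run.log`` with per-stage counts, and ``manifest.json``. Re-running
    with the same config and seed reproduces all numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        datasets = _load_datasets(config)
        exclusions = (
            _read_symbol_list(config.exclusions) if config.exclusions else None
        )
        analysis = run_meta(
            datasets,
            config.target,
            filter_cfg=config.filter_cfg,
            meta_cfg=config.meta_cfg,
            exclusions=exclusions,
        )
    except Exception as exc:
        raise ValidationError(f"meta-analysis stage failed: {exc}") from exc
    for summary in analysis.dataset_summaries:
        log(
            f"dataset {summary.name}: {summary.n_samples} samples, "
            f"{summary.n_probesets} probesets, "
            f"{summary.n_retained_probesets} retained after QC, "
            f"{summary.n_genes} genes (target probeset {summary.target_probeset})"
        )
    log(f"universe m = {analysis.universe_m}")
    log(
        f"significant genes at Bonferroni alpha {analysis.alpha}: "
        f"{analysis.pre_exclusion_count} before exclusions, "
        f"{len(analysis)} after ({len(analysis.excluded_hits)} excluded)"
    )
    dataset_names = [ds.name for ds in datasets]
    write_results_table(
        analysis.results, out / "meta_results.tsv", dataset_names=dataset_names
    )

    if config.gsea is not None:
        g = config.gsea
        try:
            ds_name = g.dataset or datasets[0].name
            dataset = next(d for d in datasets if d.name == ds_name)
            sets = read_gmt(g.gmt)
            ranked = rank_by_correlation(dataset, config.target, config.filter_cfg)
            kept = filter_gene_sets(sets, g.min_size, g.max_size, ranked.genes)
            log(
                f"gsea: {len(sets)} sets read, {len(kept)} within size bounds "
                f"({g.min_size}, {g.max_size}) on {len(ranked)} ranked genes"
            )
            results = permutation_test(
                dataset,
                config.target,
                kept,
                n_perm=g.n_perm,
                exponent=g.exponent,
                seed=config.seed,
                filter_cfg=config.filter_cfg,
            )
            write_enrichment_table(results, out / "gsea_results.tsv")
        except Exception as exc:
            raise ValidationError(f"gsea stage failed: {exc}") from exc

    if config.network is not None:
        n = config.network
        try:
            graph = read_edge_list(n.edge_list, n.format)
            seeds = analysis.genes
            sub, mapped = first_neighbor_subgraph(graph, seeds)
            log(
                f"network: {graph.number_of_nodes()} nodes / "
                f"{graph.number_of_edges()} edges; {mapped} of {len(seeds)} "
                f"seeds mapped; first-neighbor subgraph "
                f"{sub.number_of_nodes()} nodes / {sub.number_of_edges()} edges"
            )
            if n.expression_table is not None:
                expr = _read_expression_table(n.expression_table)
                sub = expression_filter(sub, expr, n.threshold)
                log(
                    f"network: after expression > {n.threshold} filter: "
                    f"{sub.number_of_nodes()} nodes / {sub.number_of_edges()} edges"
                )
            stats = subgraph_stats(sub, seeds)
            with open(out / "network_stats.tsv", "w") as fh:
                fh.write("metric\tvalue\n")
                fh.write(f"nodes\t{stats.node_count}\n")
                fh.write(f"edges\t{stats.edge_count}\n")
                fh.write(f"mapped_seeds\t{mapped}\n")
                for seed_gene, count in stats.neighbor_counts.items():
                    fh.write(f"neighbors:{seed_gene}\t{count}\n")
            write_node_table(sub, out / "network_nodes.tsv")
            write_edge_table(sub, out / "network_edges.tsv")
            nx.write_graphml(sub, out / "network.graphml")
        except ValidationError:
            raise
        except Exception as exc:
            raise ValidationError(f"network stage failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "target": config.target,
        "universe_m": analysis.universe_m,
        "significant_pre_exclusion": analysis.pre_exclusion_count,
        "significant": len(analysis),
        "datasets": {
            s.name: {"n_samples": s.n_samples, "n_genes": s.n_genes}
            for s in analysis.dataset_summaries
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
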