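"""End-to-end orchestration: simulate → de → cerna → topology → enrich.

Stages hand artifacts to each other through plain files (TSV / GraphML /
SIF) inside the configured output directory, so every intermediate is
inspectable and each stage can equally be run standalone. A JSON manifest
records the config snapshot and a SHA-256 digest of every written file;
identical config + seed reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .datatypes import ValidationError
from .diffexpr import DEParams, de_sets, differential_expression
from .enrichment import gsea_permutation_p, ora_collection, rank_by_correlation
from .network import (
    CeRNAParams,
    build_triple_network,
    call_cerna_pairs,
    pearson_filter,
)
from .synthetic import SyntheticConfig, generate, truth_recovery_report, write_dataset
from .topology import fitness_report

log = logging.getLogger("cernaforge")

STAGE_ORDER = ["simulate", "de", "cerna", "topology", "enrich", "validate"]

#: Published reference values for the four topology-fit R² panels
#: (degree distribution, topological coefficient, closeness, betweenness).
REFERENCE_R_SQUARED = {
    "degree": 0.827,
    "topological_coefficient": 0.936,
    "closeness": 0.690,
    "betweenness": 0.688,
}


@dataclass
class PipelineConfig:
    """Everything one run needs: stage list, per-stage params, seed, paths."""

    outdir: Path
    stages: list[str] = field(default_factory=lambda: STAGE_ORDER[:])
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    de_params: DEParams = field(default_factory=DEParams)
    cerna_params: CeRNAParams = field(default_factory=CeRNAParams)
    topology_mode: str = "per_node"
    hub_genes: list[str] = field(default_factory=list)
    gmt_path: Path | None = None
    n_perm: int = 1000
    gsea_weight: float = 1.0
    inputs: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        self.outdir = Path(self.outdir)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.get("synthetic")
    cfg = PipelineConfig(
        outdir=Path(raw.get("outdir", "cernaforge_out")),
        stages=raw.get("stages", STAGE_ORDER[:]),
        seed=int(raw.get("seed", 0)),
        synthetic=SyntheticConfig(**syn) if syn is not None else None,
        de_params=DEParams(**raw.get("de", {})),
        cerna_params=CeRNAParams(**raw.get("cerna", {})),
        topology_mode=raw.get("topology", {}).get("mode", "per_node"),
        hub_genes=list(raw.get("enrich", {}).get("hubs", [])),
        gmt_path=Path(raw["enrich"]["gmt"]) if raw.get("enrich", {}).get("gmt") else None,
        n_perm=int(raw.get("enrich", {}).get("n_perm", 1000)),
        gsea_weight=float(raw.get("enrich", {}).get("weight", 1.0)),
        inputs={k: Path(v) for k, v in raw.get("inputs", {}).items()},
    )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def _read_design(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].values, index=df["sample"].values, dtype=object)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; return the manifest dict.

    A stage failure raises with the failing stage named; files written up
    to that point are flagged ``partial`` in the manifest (also written to
    disk on failure).
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "config": _config_snapshot(cfg),
        "stages": {},
        "status": "partial",
    }
    written: dict[str, Path] = {}

    def emit(stage: str, name: str, path: Path) -> None:
        written[f"{stage}/{name}"] = path

    dataset = None
    try:
        for stage in cfg.stages:
            log.info("stage %s started", stage)
            if stage == "simulate":
                syn = cfg.synthetic if cfg.synthetic is not None else SyntheticConfig(seed=cfg.seed)
                dataset = generate(syn)
                paths = write_dataset(dataset, cfg.outdir / "data")
                for name, p in paths.items():
                    emit(stage, name, p)
                # stages downstream read the files we just wrote
                cfg.inputs.update(
                    {
                        "expr_mrna": paths["expr_mrna"],
                        "expr_lncrna": paths["expr_lncrna"],
                        "expr_mirna": paths["expr_mirna"],
                        "design": paths["design"],
                        "mrna_targets": paths["mrna_targets"],
                        "lncrna_targets": paths["lncrna_targets"],
                    }
                )
            elif stage == "de":
                design = _read_design(cfg.inputs["design"])
                for cls, key in (
                    ("mRNA", "expr_mrna"), ("lncRNA", "expr_lncrna"), ("miRNA", "expr_mirna"),
                ):
                    m = cio.read_expression_matrix(cfg.inputs[key], cls, design)
                    table = differential_expression(m, cfg.de_params)
                    p = cfg.outdir / f"de_{key.split('_')[1]}.tsv"
                    cio.write_de_table(table, p)
                    emit(stage, p.name, p)
            elif stage == "cerna":
                design = _read_design(cfg.inputs["design"])
                mrna_m = cio.read_expression_matrix(cfg.inputs["expr_mrna"], "mRNA", design)
                lnc_m = cio.read_expression_matrix(cfg.inputs["expr_lncrna"], "lncRNA", design)
                de_tabs = {
                    cls: cio.read_de_table(cfg.outdir / f"de_{cls}.tsv")
                    for cls in ("mrna", "lncrna", "mirna")
                }
                mir_sets = de_sets(de_tabs["mirna"])
                de_mirnas = mir_sets["up"] | mir_sets["down"]
                mrna_tbl = cio.read_interaction_table(cfg.inputs["mrna_targets"], "mRNA")
                lnc_tbl = cio.read_interaction_table(cfg.inputs["lncrna_targets"], "lncRNA")
                net = build_triple_network(de_mirnas, mrna_tbl, lnc_tbl, cfg.cerna_params)
                de_mr = de_tabs["mrna"].index[de_tabs["mrna"]["is_de"]]
                de_ln = de_tabs["lncrna"].index[de_tabs["lncrna"]["is_de"]]
                cand = [
                    (mr, ln)
                    for mr in de_mr if mr in net.graph
                    for ln in de_ln if ln in net.graph
                ]
                corr = pearson_filter(
                    cand, mrna_m, lnc_m,
                    r_threshold=cfg.cerna_params.r_threshold,
                    use_abs=cfg.cerna_params.use_abs_r,
                )
                universe = len(mrna_tbl.mirnas() | lnc_tbl.mirnas())
                cerna = call_cerna_pairs(net, corr, cfg.cerna_params, mirna_universe=universe)
                pairs_p = cfg.outdir / "cerna_pairs.tsv"
                triples_p = cfg.outdir / "cerna_triples.tsv"
                cio.write_cerna_tables(cerna, pairs_p, triples_p)
                emit(stage, pairs_p.name, pairs_p)
                emit(stage, triples_p.name, triples_p)
                g = cerna.to_graph()
                if g.number_of_nodes():
                    for fmt, ext in (("sif", "sif"), ("graphml", "graphml")):
                        p = cfg.outdir / f"cerna_network.{ext}"
                        cio.export_network(g, p, fmt)
                        emit(stage, p.name, p)
                if dataset is not None:
                    rep = truth_recovery_report(dataset, cerna)
                    p = cfg.outdir / "recovery.tsv"
                    pd.DataFrame([dataclasses.asdict(rep)]).to_csv(p, sep="\t", index=False)
                    emit(stage, p.name, p)
            elif stage == "topology":
                g = _topology_input_graph(cfg)
                rep = fitness_report(g, mode=cfg.topology_mode)
                nm = pd.DataFrame.from_dict(rep.node_metrics, orient="index")
                nm.index.name = "node"
                p = cfg.outdir / "topology_node_metrics.tsv"
                nm.sort_index().to_csv(p, sep="\t")
                emit(stage, p.name, p)
                rows = [
                    {
                        "metric": m, "a": f.a, "b": f.b,
                        "r_squared": f.r_squared, "n_points": f.n_points,
                    }
                    for m, f in rep.fits.items()
                ]
                for m, err in rep.errors.items():
                    rows.append({"metric": m, "a": float("nan"), "b": float("nan"),
                                 "r_squared": float("nan"), "n_points": 0})
                p = cfg.outdir / "topology_fit_summary.tsv"
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                emit(stage, p.name, p)
            elif stage == "enrich":
                design = _read_design(cfg.inputs["design"])
                mrna_m = cio.read_expression_matrix(cfg.inputs["expr_mrna"], "mRNA", design)
                gmt = cio.read_gmt(cfg.gmt_path or cio.packaged_gmt_path())
                de_tab = cio.read_de_table(cfg.outdir / "de_mrna.tsv")
                sets = de_sets(de_tab)
                hits = sets["up"] | sets["down"]
                ora = ora_collection(hits, gmt, set(de_tab.index))
                p = cfg.outdir / "enrich_ora.tsv"
                ora.to_csv(p, sep="\t", index=False)
                emit(stage, p.name, p)
                rows = []
                for hub in cfg.hub_genes:
                    ranked = rank_by_correlation(hub, mrna_m)
                    for name, members in sorted(gmt.items()):
                        overlap = members & set(ranked.genes)
                        if not overlap or len(overlap) == len(ranked):
                            continue
                        res = gsea_permutation_p(
                            ranked, members, n_perm=cfg.n_perm,
                            seed=cfg.seed, weight_p=cfg.gsea_weight,
                        )
                        rows.append(
                            {
                                "hub": hub, "set": name, "es": res.es,
                                "p": res.p_value, "n_hits": res.n_hits,
                                "direction": res.direction,
                            }
                        )
                p = cfg.outdir / "enrich_gsea.tsv"
                pd.DataFrame(
                    rows, columns=["hub", "set", "es", "p", "n_hits", "direction"]
                ).to_csv(p, sep="\t", index=False)
                emit(stage, p.name, p)
            elif stage == "validate":
                rep = validate_against_fixture()
                p = cfg.outdir / "fixture_validation.tsv"
                rep["fits"].to_csv(p, sep="\t", index=False)
                emit(stage, p.name, p)
            manifest["stages"][stage] = "ok"
            log.info("stage %s finished", stage)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _finalise_manifest(cfg, manifest, written)
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["status"] = "ok"
    _finalise_manifest(cfg, manifest, written)
    log.removeHandler(handler)
    return manifest


def _finalise_manifest(cfg: PipelineConfig, manifest: dict, written: dict[str, Path]) -> None:
    manifest["files"] = {
        key: {"path": str(p), "sha256": _sha256(p)} for key, p in sorted(written.items())
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _topology_input_graph(cfg: PipelineConfig):
    graphml = cfg.inputs.get("network", cfg.outdir / "cerna_network.graphml")
    if Path(graphml).exists():
        return cio.import_graphml(graphml)
    # fall back to the packaged published network
    return cio.load_table2_fixture().to_graph()


def validate_against_fixture() -> dict:
    """Build the packaged 99-triple network, check its composition, and
    compare its four topology R² values with the published ones.

    Returns a dict with the node-class counts, the triple count and a
    DataFrame of fits (metric, mode, r_squared, reference, abs_delta).
    """
    net = cio.load_table2_fixture()
    counts = {
        "n_triples": len(net),
        "n_mrna": len(net.mrnas),
        "n_lncrna": len(net.lncrnas),
        "n_mirna": len(net.mirnas),
    }
    expected = {"n_triples": 99, "n_mrna": 27, "n_lncrna": 15, "n_mirna": 25}
    if counts != expected:
        raise ValidationError(f"fixture composition {counts} != expected {expected}")
    g = net.to_graph()
    rows = []
    for mode in ("per_node", "per_degree"):
        rep = fitness_report(g, mode=mode)
        for metric, ref in REFERENCE_R_SQUARED.items():
            r2 = rep.fits[metric].r_squared
            rows.append(
                {
                    "metric": metric,
                    "mode": mode,
                    "r_squared": r2,
                    "reference": ref,
                    "abs_delta": abs(r2 - ref),
                }
            )
    return {"counts": counts, "fits": pd.DataFrame(rows)}


def format_validation_report(rep: dict) -> str:
    lines = [
        "network composition: "
        + ", ".join(f"{k}={v}" for k, v in rep["counts"].items()),
        "",
        rep["fits"].to_string(index=False, float_format=lambda v: f"{v:.4f}"),
    ]
    return "\n".join(lines)
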