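"""End-to-end orchestration: filter -> PCIT x2 -> combine -> RIF -> networks.

A run is driven by a :class:`PipelineConfig` (flat key-value YAML). Stages
execute in order, each writing TSV outputs into the run directory; a
manifest (JSON) records per-stage outputs, parameters and input checksums so
unchanged stages can be skipped on a rerun. All randomness is owned by the
synthetic-data generator — the pipeline itself is deterministic, and two
runs from the same config and seed produce byte-identical data outputs (the
run log, which carries timing, is not part of that guarantee).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import AttributeTable, CountMatrix, ExpressionMatrix, GEBVMatrix
from .network import (build_network, detect_hubs, final_regulator_network,
                      integrate_with_degs, select_regulatory_edges)
from .pcit import (combine_feature_trait_edges, correlated_features_per_trait,
                   run_pcit_general, run_pcit_mirna)
from .preprocess import align_samples, filter_low_expression
from .rif import rif_overall, rif_per_trait

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, constants and output location for one pipeline run.

    The numeric defaults are the method's standard operating values: a
    low-expression cut at 22 samples, 15-sample contrast groups, |z| >= 1.96
    for RIF significance and a hub threshold of mean + 2 sd.
    """

    genes_path: str = ""
    mirnas_path: str = ""
    gebv_path: str = ""
    gene_counts_path: str = ""
    mirna_counts_path: str = ""
    attributes_path: str = ""
    pathway_members_path: str = ""
    output_dir: str = "gebvnet_run"
    group_size: int = 15
    min_samples: int = 22
    rif_z_cutoff: float = 1.96
    hub_sd_multiplier: float = 2.0
    pca_variance_weight: str = "proportion"
    rank_transform: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Bookkeeping for one pipeline execution (manifest + skip logic)."""

    def __init__(self, outdir: Path, cfg: PipelineConfig):
        self.outdir = outdir
        self.cfg = cfg
        self.manifest_path = outdir / "manifest.json"
        self.previous = {}
        if self.manifest_path.exists():
            try:
                self.previous = json.loads(self.manifest_path.read_text()).get("stages", {})
            except json.JSONDecodeError:
                self.previous = {}
        self.stages: dict = {}

    def stage_current(self, name: str, input_paths) -> bool:
        """True when the stage ran before on identical inputs and outputs exist."""
        prev = self.previous.get(name)
        if not prev:
            return False
        checksums = {str(p): _sha256(Path(p)) for p in input_paths if Path(p).exists()}
        if prev.get("input_checksums") != checksums:
            return False
        return all((self.outdir / f).exists() for f in prev.get("outputs", []))

    def record(self, name: str, outputs, input_paths, **params) -> None:
        self.stages[name] = {
            "outputs": [str(o) for o in outputs],
            "input_checksums": {str(p): _sha256(Path(p))
                                for p in input_paths if Path(p).exists()},
            "params": params,
        }

    def write(self) -> None:
        doc = {"config": dataclasses.asdict(self.cfg), "stages": self.stages}
        self.manifest_path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    Stage order: low-expression filter (optional, needs count matrices) ->
    PCIT general -> PCIT miRNA -> combine -> PCA score + contrasts ->
    RIF per trait + overall -> association network with attributes + hubs ->
    DEG integration per trait (optional, needs DEG attribute rows) ->
    regulatory-edge selection -> final regulator network.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir, cfg)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("gebvnet")
    root.addHandler(log_handler)
    try:
        manifest = _run_stages(cfg, outdir, run)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return manifest


def _load_inputs(cfg: PipelineConfig):
    genes = ExpressionMatrix.from_tsv(cfg.genes_path, "gene") if cfg.genes_path else None
    mirnas = ExpressionMatrix.from_tsv(cfg.mirnas_path, "mirna") if cfg.mirnas_path \
        else _empty_expr(genes)
    if genes is None:
        genes = _empty_expr(mirnas)
    gebv = GEBVMatrix.from_tsv(cfg.gebv_path)
    attributes = AttributeTable.from_tsv(cfg.attributes_path) \
        if cfg.attributes_path else AttributeTable()
    pathway_members = []
    if cfg.pathway_members_path:
        pm = pd.read_csv(cfg.pathway_members_path, sep="\t")
        pathway_members = pm.iloc[:, 0].astype(str).tolist()
    return genes, mirnas, gebv, attributes, pathway_members


def _empty_expr(like) -> ExpressionMatrix:
    cols = like.data.columns if like is not None else pd.Index([])
    return ExpressionMatrix(pd.DataFrame(index=pd.Index([]), columns=cols, dtype=float))


def _run_stages(cfg: PipelineConfig, outdir: Path, run: _Run) -> dict:
    cfg.to_yaml(outdir / "config.resolved.yaml")
    genes, mirnas, gebv, attributes, pathway_members = _load_inputs(cfg)

    # -- stage: low-expression filter ---------------------------------
    for label, counts_path, mat in (("gene", cfg.gene_counts_path, genes),
                                    ("mirna", cfg.mirna_counts_path, mirnas)):
        if not counts_path:
            continue
        counts = CountMatrix.from_tsv(counts_path, label)
        kept = filter_low_expression(counts, cfg.min_samples)
        out = outdir / f"filter_{label}.tsv"
        pd.DataFrame({"feature_id": kept}).to_csv(out, sep="\t", index=False)
        if mat.n_features:
            sub = mat.subset_features(kept)
            mat.data = sub.data
            mat.feature_role = sub.feature_role
        run.record(f"filter_{label}", [out.name], [counts_path],
                   min_samples=cfg.min_samples, kept=len(kept))
        logger.info("filter[%s]: kept %d features", label, len(kept))

    merged_expr = _concat_expr(genes, mirnas)
    merged_expr, gebv = align_samples(merged_expr, gebv)
    genes = merged_expr.subset_features(
        merged_expr.feature_role.index[merged_expr.feature_role == "gene"])
    mirnas = merged_expr.subset_features(
        merged_expr.feature_role.index[merged_expr.feature_role == "mirna"])

    # -- stage: the two PCIT runs (resumable; these dominate run time) --
    from .pcit import PCITResults

    gen_inputs = [p for p in (cfg.genes_path, cfg.mirnas_path, cfg.gebv_path) if p]
    if run.stage_current("pcit_general", gen_inputs):
        logger.info("pcit_general unchanged; resuming from existing outputs")
        general = PCITResults.from_tsv(outdir / "pcit_general_edges.tsv",
                                       outdir / "pcit_general_nodes.tsv")
    else:
        general = run_pcit_general(genes, mirnas, gebv,
                                   rank_transform=cfg.rank_transform)
        general.to_tsv(outdir / "pcit_general_edges.tsv",
                       outdir / "pcit_general_nodes.tsv")
    run.record("pcit_general", ["pcit_general_edges.tsv", "pcit_general_nodes.tsv"],
               gen_inputs, n_nodes=general.n_nodes,
               n_significant=int(len(general.significant_edges())))

    mirna_res = None
    if mirnas.n_features >= 1 and mirnas.n_features + gebv.n_traits >= 3:
        mir_inputs = [p for p in (cfg.mirnas_path, cfg.gebv_path) if p]
        if run.stage_current("pcit_mirna", mir_inputs):
            logger.info("pcit_mirna unchanged; resuming from existing outputs")
            mirna_res = PCITResults.from_tsv(outdir / "pcit_mirna_edges.tsv",
                                             outdir / "pcit_mirna_nodes.tsv")
        else:
            mirna_res = run_pcit_mirna(mirnas, gebv, rank_transform=cfg.rank_transform)
            mirna_res.to_tsv(outdir / "pcit_mirna_edges.tsv",
                             outdir / "pcit_mirna_nodes.tsv")
        run.record("pcit_mirna", ["pcit_mirna_edges.tsv", "pcit_mirna_nodes.tsv"],
                   mir_inputs, n_nodes=mirna_res.n_nodes,
                   n_significant=int(len(mirna_res.significant_edges())))

    combined = combine_feature_trait_edges(general, mirna_res)
    combined.to_csv(outdir / "correlated_features.tsv", sep="\t", index=False)
    per_trait = correlated_features_per_trait(combined)
    run.record("combine", ["correlated_features.tsv"], [],
               n_feature_trait_edges=int(len(combined)))
    logger.info("combine: %d feature-trait records across %d traits",
                len(combined), len(per_trait))

    # -- stage: RIF ----------------------------------------------------
    rif_tables = rif_per_trait(per_trait, merged_expr, gebv,
                               group_size=cfg.group_size, z_cutoff=cfg.rif_z_cutoff)
    for trait, res in rif_tables.items():
        res.to_tsv(outdir / f"rif_{trait}.tsv")
    all_candidates = list(dict.fromkeys(combined["feature_id"]))
    overall_res, scores, overall_design = rif_overall(
        all_candidates, merged_expr, gebv, group_size=cfg.group_size,
        z_cutoff=cfg.rif_z_cutoff, variance_weight=cfg.pca_variance_weight)
    scores.to_frame("score").to_csv(outdir / "pca_scores.tsv", sep="\t",
                                    index_label="sample_id")
    overall_design.to_tsv(outdir / "contrast_overall.tsv")
    overall_res.to_tsv(outdir / "rif_overall.tsv")
    rif_all = dict(rif_tables)
    rif_all["overall"] = overall_res
    run.record("rif", [f"rif_{t}.tsv" for t in rif_tables] +
               ["rif_overall.tsv", "pca_scores.tsv", "contrast_overall.tsv"], [],
               group_size=cfg.group_size, z_cutoff=cfg.rif_z_cutoff,
               n_overall_significant=len(overall_res.significant_ids))

    # -- stage: primary association network ---------------------------
    roles = pd.concat([merged_expr.feature_role,
                       pd.Series("trait", index=gebv.trait_ids, dtype=object)])
    edge_pool = [general.significant_edges()]
    if mirna_res is not None:
        medges = mirna_res.significant_edges()
        seen = set(map(frozenset, zip(edge_pool[0]["node_a"], edge_pool[0]["node_b"])))
        medges = medges[[frozenset(p) not in seen
                         for p in zip(medges["node_a"], medges["node_b"])]]
        edge_pool.append(medges)
    edges = pd.concat(edge_pool, ignore_index=True)
    net = build_network(edges, roles, attributes=attributes, rif_results=rif_all)
    hub_summary = detect_hubs(net, cfg.hub_sd_multiplier)
    net.to_tsv(outdir / "network_edges.tsv", outdir / "network_nodes.tsv")
    hub_summary.to_csv(outdir / "network_degrees.tsv", sep="\t", index=False)
    run.record("network", ["network_edges.tsv", "network_nodes.tsv",
                           "network_degrees.tsv"],
               [cfg.attributes_path] if cfg.attributes_path else [],
               n_nodes=net.n_nodes, n_edges=net.n_edges,
               n_hubs=len(net.hubs()))

    # -- stage: DEG integration (optional) -----------------------------
    integration_hubs: dict = {}
    has_degs = len(attributes.rows_of_kind("DEG")) > 0
    if has_degs:
        for trait in gebv.trait_ids:
            deg_ids = attributes.deg_ids(trait)
            corr_ids = per_trait.get(trait, [])
            union = set(deg_ids) | set(corr_ids)
            if len([f for f in merged_expr.feature_ids if f in union]) < 3:
                logger.info("integration[%s]: fewer than 3 features; skipped", trait)
                continue
            inet, isummary, _ = integrate_with_degs(
                trait, corr_ids, deg_ids, merged_expr,
                attributes=attributes, rif_results=rif_all)
            inet.to_tsv(outdir / f"integration_{trait}_edges.tsv",
                        outdir / f"integration_{trait}_nodes.tsv")
            isummary.to_csv(outdir / f"integration_{trait}_degrees.tsv",
                            sep="\t", index=False)
            integration_hubs[trait] = inet.hubs()
        run.record("integration",
                   sorted(p.name for p in outdir.glob("integration_*")), [],
                   traits=len(integration_hubs))
    else:
        logger.info("no DEG attribute rows; DEG-integration stage skipped")

    # -- stage: regulatory edge selection ------------------------------
    sel_edges, candidate_ids = select_regulatory_edges(net)
    sel_edges.to_csv(outdir / "regulatory_edges.tsv", sep="\t", index=False)
    run.record("select_regulatory", ["regulatory_edges.tsv"], [],
               n_edges=int(len(sel_edges)), n_candidates=len(candidate_ids))

    # -- stage: final regulator network --------------------------------
    rif_sig_ids = set()
    for res in rif_all.values():
        rif_sig_ids.update(res.significant_ids)
    hub_ids = set(net.hubs()) | {h for hs in integration_hubs.values() for h in hs}
    tf_ids = set(attributes.rows_of_kind("TF")["feature_id"])
    selection = (set(pathway_members) | hub_ids | rif_sig_ids
                 | (tf_ids & set(merged_expr.feature_ids))
                 | set(mirnas.feature_ids))
    selection &= set(merged_expr.feature_ids)
    if len(selection) >= 3:
        fnet, fres = final_regulator_network(
            selection, merged_expr, attributes=attributes, rif_results=rif_all,
            pathway_member_ids=pathway_members)
        fnet.to_tsv(outdir / "final_network_edges.tsv",
                    outdir / "final_network_nodes.tsv")
        run.record("final_network",
                   ["final_network_edges.tsv", "final_network_nodes.tsv"],
                   [cfg.pathway_members_path] if cfg.pathway_members_path else [],
                   n_nodes=fnet.n_nodes, n_edges=fnet.n_edges)
    else:
        logger.info("final network skipped: only %d selected features", len(selection))

    run.write()
    return json.loads(run.manifest_path.read_text())


def _concat_expr(genes: ExpressionMatrix, mirnas: ExpressionMatrix) -> ExpressionMatrix:
    frames, roles = [], []
    for m in (genes, mirnas):
        if m.n_features:
            frames.append(m.data)
            roles.append(m.feature_role)
    if not frames:
        raise ValueError("no expression features supplied")
    if len(frames) == 1:
        return ExpressionMatrix(frames[0], roles[0])
    common = [s for s in frames[0].columns if s in set(frames[1].columns)]
    if not common:
        raise ValueError("gene and miRNA matrices share no samples")
    return ExpressionMatrix(pd.concat([f[common] for f in frames]),
                            pd.concat(roles))
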