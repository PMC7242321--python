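"""Attribute-annotated association networks, hub detection, regulator selection.

Networks are undirected :class:`networkx.Graph` objects wrapped with typed
node attributes (role, DEG/TF/eQTL annotations, RIF significance, hub flag,
pathway membership) and edge attributes (Pearson r, source run, and a marker
for edges incident to a RIF-significant node). Hub nodes are those whose
degree strictly exceeds the network's mean degree plus twice its population
standard deviation.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .data import AttributeTable, ExpressionMatrix
from .pcit import PCIT, PCITResults

logger = logging.getLogger(__name__)

HUB_SD_MULTIPLIER = 2.0

__all__ = [
    "AssociationNetwork",
    "build_network",
    "detect_hubs",
    "integrate_with_degs",
    "select_regulatory_edges",
    "final_regulator_network",
]

_NODE_ROLES = ("gene", "mirna", "trait")


class AssociationNetwork:
    """Undirected association network with attribute layers.

    Node attributes: ``role``, ``deg`` (dict trait_id -> direction), ``tf``,
    ``cis_eqtl``, ``trans_eqtl``, ``rif_significant`` (list of contrast
    labels), ``hub``, ``in_enriched_pathway``.
    Edge attributes: ``r``, ``source_run``, ``rif_marked``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node_id, role: str) -> None:
        if role not in _NODE_ROLES:
            raise ValueError(f"unknown role {role!r} for node {node_id!r}")
        if node_id not in self.graph:
            self.graph.add_node(node_id, role=role, deg={}, tf=False,
                                cis_eqtl=False, trans_eqtl=False,
                                rif_significant=[], hub=False,
                                in_enriched_pathway=False)

    def add_edge(self, a, b, r: float, source_run: str = "pcit") -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        for node in (a, b):
            if node not in self.graph:
                raise KeyError(f"edge references unknown node {node!r}")
        self.graph.add_edge(a, b, r=float(r), source_run=source_run,
                            rif_marked=False)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_with(self, flag: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get(flag)]

    def hubs(self) -> list:
        return self.nodes_with("hub")

    # -- attribute overlay --------------------------------------------
    def apply_attributes(self, attributes: AttributeTable) -> None:
        """Overlay DEG/TF/eQTL annotations; unmatched rows logged and ignored."""
        unmatched = 0
        for row in attributes.data.itertuples(index=False):
            if row.feature_id not in self.graph:
                unmatched += 1
                continue
            node = self.graph.nodes[row.feature_id]
            if row.kind == "DEG":
                node["deg"][row.trait_id] = row.direction
            elif row.kind == "TF":
                node["tf"] = True
            elif row.kind == "cis_eqtl":
                node["cis_eqtl"] = True
            elif row.kind == "trans_eqtl":
                node["trans_eqtl"] = True
        if unmatched:
            logger.info("attribute overlay: %d row(s) matched no network node", unmatched)

    def apply_rif(self, label: str, significant_ids) -> None:
        """Flag RIF-significant nodes and mark their incident edges."""
        sig = set(significant_ids)
        for node in sig & set(self.graph.nodes):
            flags = self.graph.nodes[node]["rif_significant"]
            if label not in flags:
                flags.append(label)
        for a, b, d in self.graph.edges(data=True):
            if (self.graph.nodes[a]["rif_significant"]
                    or self.graph.nodes[b]["rif_significant"]):
                d["rif_marked"] = True

    def apply_pathway_membership(self, member_ids) -> None:
        for node in set(member_ids) & set(self.graph.nodes):
            self.graph.nodes[node]["in_enriched_pathway"] = True

    # -- I/O -----------------------------------------------------------
    def edge_frame(self) -> pd.DataFrame:
        rows = [{"source": a, "target": b, "r": d["r"],
                 "significant": True, "rif_marked": d["rif_marked"],
                 "source_run": d["source_run"]}
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "r", "significant",
                                           "rif_marked", "source_run"])

    def node_frame(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            deg_traits = ";".join(f"{t}:{dirn}" for t, dirn in sorted(d["deg"].items()))
            rows.append({"node_id": n, "role": d["role"], "deg": deg_traits,
                         "tf": d["tf"], "cis_eqtl": d["cis_eqtl"],
                         "trans_eqtl": d["trans_eqtl"],
                         "rif_significant": ";".join(d["rif_significant"]),
                         "hub": d["hub"],
                         "in_enriched_pathway": d["in_enriched_pathway"]})
        return pd.DataFrame(rows, columns=["node_id", "role", "deg", "tf",
                                           "cis_eqtl", "trans_eqtl",
                                           "rif_significant", "hub",
                                           "in_enriched_pathway"])

    def to_tsv(self, edge_path, node_path) -> None:
        self.edge_frame().to_csv(edge_path, sep="\t", index=False)
        self.node_frame().to_csv(node_path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for _, row in self.node_frame().iterrows():
            g.add_node(row["node_id"], **row.drop("node_id").to_dict())
        for _, row in self.edge_frame().iterrows():
            g.add_edge(row["source"], row["target"],
                       **row.drop(["source", "target"]).to_dict())
        nx.write_graphml(g, path)

    @classmethod
    def from_tsv(cls, edge_path, node_path) -> "AssociationNetwork":
        nodes = pd.read_csv(node_path, sep="\t", keep_default_na=False)
        edges = pd.read_csv(edge_path, sep="\t", keep_default_na=False)
        net = cls()
        for _, row in nodes.iterrows():
            net.add_node(row["node_id"], row["role"])
            d = net.graph.nodes[row["node_id"]]
            if row["deg"]:
                d["deg"] = dict(item.split(":") for item in str(row["deg"]).split(";"))
            d["tf"] = _as_bool(row["tf"])
            d["cis_eqtl"] = _as_bool(row["cis_eqtl"])
            d["trans_eqtl"] = _as_bool(row["trans_eqtl"])
            if row["rif_significant"]:
                d["rif_significant"] = str(row["rif_significant"]).split(";")
            d["hub"] = _as_bool(row["hub"])
            d["in_enriched_pathway"] = _as_bool(row["in_enriched_pathway"])
        for _, row in edges.iterrows():
            net.add_edge(row["source"], row["target"], row["r"], row["source_run"])
            net.graph.edges[row["source"], row["target"]]["rif_marked"] = _as_bool(
                row["rif_marked"])
        return net


def _as_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "1")


def build_network(edges: pd.DataFrame, roles: pd.Series,
                  attributes: AttributeTable | None = None,
                  rif_results: dict | None = None) -> AssociationNetwork:
    """Assemble a network from a significant-edge table plus attribute layers.

    ``edges`` needs columns ``node_a, node_b, r`` (``source_run`` optional);
    ``roles`` maps every referenced node id to gene/mirna/trait.
    ``rif_results`` maps a contrast label to a RIFResults (or an id list).
    """
    net = AssociationNetwork()
    for _, row in edges.iterrows():
        for node in (row["node_a"], row["node_b"]):
            if node not in net.graph:
                if node not in roles.index:
                    raise ValueError(f"edge references node {node!r} with unknown role")
                net.add_node(node, roles[node])
        net.add_edge(row["node_a"], row["node_b"], row["r"],
                     row.get("source_run", "pcit"))
    if attributes is not None:
        net.apply_attributes(attributes)
    if rif_results is not None:
        for label, res in rif_results.items():
            ids = res.significant_ids if hasattr(res, "significant_ids") else list(res)
            net.apply_rif(label, ids)
    return net


def detect_hubs(net: AssociationNetwork,
                sd_multiplier: float = HUB_SD_MULTIPLIER) -> pd.DataFrame:
    """Degree summary with hub calls: degree > mean + sd_multiplier * sd.

    The standard deviation is the population sd of the degree sequence over
    all nodes of the analyzed network; the inequality is strict, so a
    network with uniform degree (complete or edgeless) has no hubs. Hub
    flags are also written back onto the network's nodes.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot detect hubs in an empty network")
    nodes = list(net.graph.nodes)
    degrees = np.array([net.graph.degree[n] for n in nodes], dtype=float)
    mean = degrees.mean()
    sd = degrees.std()  # population sd
    threshold = mean + sd_multiplier * sd
    is_hub = degrees > threshold
    for n, h in zip(nodes, is_hub):
        net.graph.nodes[n]["hub"] = bool(h)
    return pd.DataFrame({"node_id": nodes, "degree": degrees.astype(int),
                         "mean_degree": mean, "sd_degree": sd,
                         "hub_threshold": threshold, "hub": is_hub})


def integrate_with_degs(trait: str, correlated_ids, deg_ids,
                        expr: ExpressionMatrix,
                        attributes: AttributeTable | None = None,
                        rif_results: dict | None = None) -> tuple:
    """Expression-only PCIT over a trait's correlated features plus its DEGs.

    This is the classical co-expression use of the trio test (no trait
    nodes): the node set is the union of the features associated to the
    trait and the differentially expressed genes reported for it. Returns
    ``(AssociationNetwork, degree-summary DataFrame, PCITResults)``.
    """
    wanted = list(dict.fromkeys(list(correlated_ids) + list(deg_ids)))
    have = [f for f in expr.feature_ids if f in set(wanted)]
    missing = set(wanted) - set(have)
    if missing:
        logger.warning("integration for %r: %d feature(s) lack expression",
                       trait, len(missing))
    if len(have) < 3:
        raise ValueError(
            f"integration for {trait!r}: need >= 3 features with expression, "
            f"got {len(have)}")
    res = PCIT(expr.data.loc[have], expr.feature_role.loc[have],
               source_run=f"integration_{trait}").fit()
    net = build_network(res.significant_edges(), res.roles,
                        attributes=attributes, rif_results=rif_results)
    # features isolated by PCIT still belong to the analyzed network
    for node in res.node_ids:
        if node not in net.graph:
            net.add_node(node, res.roles[node])
    summary = detect_hubs(net)
    return net, summary, res


def select_regulatory_edges(net: AssociationNetwork) -> tuple:
    """Edges with at least one hub or RIF-significant endpoint.

    Returns ``(edge DataFrame, candidate node-id list)`` — the endpoints of
    the kept edges form the candidate set handed to external enrichment.
    """
    keep = []
    candidates: list = []
    for a, b, d in net.graph.edges(data=True):
        flagged = any(net.graph.nodes[n]["hub"] or net.graph.nodes[n]["rif_significant"]
                      for n in (a, b))
        if flagged:
            keep.append({"source": a, "target": b, "r": d["r"],
                         "source_run": d["source_run"]})
            for n in (a, b):
                if n not in candidates:
                    candidates.append(n)
    return pd.DataFrame(keep, columns=["source", "target", "r", "source_run"]), candidates


def final_regulator_network(selected_ids, expr: ExpressionMatrix,
                            attributes: AttributeTable | None = None,
                            rif_results: dict | None = None,
                            pathway_member_ids=None,
                            source_run: str = "final") -> tuple:
    """Last PCIT round over the selected elements' expression.

    ``selected_ids`` is the union of pathway members, hubs, TFs, miRNAs and
    RIF-significant features chosen upstream. Edges incident to a
    RIF-significant node carry the ``rif_marked`` attribute so they can be
    highlighted when the network is drawn.
    """
    have = [f for f in expr.feature_ids if f in set(selected_ids)]
    if len(have) < 3:
        raise ValueError(f"final network: need >= 3 selected features with "
                         f"expression, got {len(have)}")
    res = PCIT(expr.data.loc[have], expr.feature_role.loc[have],
               source_run=source_run).fit()
    net = build_network(res.significant_edges(), res.roles,
                        attributes=attributes, rif_results=rif_results)
    for node in res.node_ids:
        if node not in net.graph:
            net.add_node(node, res.roles[node])
    if pathway_member_ids is not None:
        net.apply_pathway_membership(pathway_member_ids)
    detect_hubs(net)
    return net, res
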