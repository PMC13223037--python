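"""Integrative sensitivity network: module -> pathways -> drug classes -> cells.

The network condenses the pipeline's evidence into a typed directed graph:

* module -> pathway edges for gene sets passing the enrichment thresholds
  (weight |NES|, evidence ``enrichment``; or |r| when built from correlation
  profiles),
* pathway -> drug-class edges for classes whose mean delta-AUC is negative
  with a confidence interval excluding zero (weight |mean delta-AUC|,
  evidence ``delta_auc``),
* drug-class -> cell edges for signature-high cells, weighted by the cell's
  mean AUC deficit relative to the panel mean for that class (positive =
  more sensitive than the panel average), from observed responses
  (``delta_auc``) or model predictions (``model_prediction``).

Construction is a pure function of its input tables; edge counts shrink
monotonically as thresholds tighten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .signature import StratumAssignment

logger = logging.getLogger("rair_axis")

NODE_TYPES = ("module", "pathway", "drug_class", "cell_model")
EDGE_EVIDENCE = ("enrichment", "correlation", "delta_auc", "model_prediction")
_ALLOWED_LAYERS = {("module", "pathway"), ("pathway", "drug_class"),
                   ("drug_class", "cell_model")}


@dataclass
class SensitivityNetwork:
    """Typed weighted digraph with layer constraints enforced on build."""

    graph: nx.DiGraph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("node_type") == node_type]

    def node_table(self) -> pd.DataFrame:
        rows = [{"node": n, "node_type": d["node_type"]}
                for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows, columns=["node", "node_type"])

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "weight": d["weight"],
                 "evidence": d["evidence"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "evidence"])

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            tu = self.graph.nodes[u]["node_type"]
            tv = self.graph.nodes[v]["node_type"]
            if (tu, tv) not in _ALLOWED_LAYERS:
                raise ValueError(f"edge {u}->{v} violates layer order ({tu}->{tv})")
            if u == v:
                raise ValueError(f"self edge on {u}")
            if not pd.notna(d["weight"]):
                raise ValueError(f"non-finite weight on {u}->{v}")


def build_network(enrichment: pd.DataFrame, class_summaries: pd.DataFrame,
                  assignment: StratumAssignment, response: pd.DataFrame,
                  drug_classes: pd.Series, module_name: str = "module",
                  q_thresh: float = 0.05, delta_thresh: float = 0.0,
                  require_ci: bool = True, nes_thresh: float = 0.0,
                  predicted: pd.DataFrame | None = None) -> SensitivityNetwork:
    """Assemble the sensitivity network from stage outputs.

    Parameters
    ----------
    enrichment
        Per-set table indexed by set name with ``nes`` and ``p_adj`` columns.
    class_summaries
        Per-class table indexed by class with ``mean_delta``, ``ci_high``,
        ``ci_defined``.
    assignment
        Cell stratification; only high-stratum cells become nodes.
    response
        Long (cell_id, drug_id, auc) table of observed responses.
    drug_classes
        drug_id -> class label; must cover the response table's drugs.
    predicted
        Optional long table of predicted AUCs with the same columns; when
        given, class->cell edges additionally carry model predictions.
    """
    unmatched = sorted(set(response["drug_id"]) - set(drug_classes.index))
    if unmatched:
        raise ValueError(f"drugs without class labels: {unmatched[:5]}")
    g = nx.DiGraph()
    g.add_node(module_name, node_type="module")

    passing = enrichment[(enrichment["p_adj"] < q_thresh)
                         & (enrichment["nes"].abs() > nes_thresh)]
    for set_name, row in passing.iterrows():
        g.add_node(set_name, node_type="pathway")
        g.add_edge(module_name, set_name, weight=float(abs(row["nes"])),
                   evidence="enrichment")

    ok = class_summaries["mean_delta"] < delta_thresh
    if require_ci:
        ok &= class_summaries["ci_defined"] & (class_summaries["ci_high"] < 0)
    sensitive = class_summaries[ok]
    for cls, row in sensitive.iterrows():
        g.add_node(cls, node_type="drug_class")
        for set_name in passing.index:
            g.add_edge(set_name, cls, weight=float(abs(row["mean_delta"])),
                       evidence="delta_auc")

    high_cells = assignment.samples("high")
    labelled = response.assign(
        drug_class=response["drug_id"].map(drug_classes))
    for cls in sensitive.index:
        sub = labelled[labelled["drug_class"] == cls]
        if sub.empty:
            continue
        cell_mean = sub.groupby("cell_id")["auc"].mean()
        panel_mean = float(cell_mean.mean())
        for cell in high_cells:
            if cell not in cell_mean.index:
                continue
            g.add_node(cell, node_type="cell_model")
            g.add_edge(cls, cell, weight=float(panel_mean - cell_mean[cell]),
                       evidence="delta_auc")
    if predicted is not None:
        plabelled = predicted.assign(
            drug_class=predicted["drug_id"].map(drug_classes))
        for cls in sensitive.index:
            sub = plabelled[plabelled["drug_class"] == cls]
            if sub.empty:
                continue
            cell_mean = sub.groupby("cell_id")["auc"].mean()
            panel_mean = float(cell_mean.mean())
            for cell in high_cells:
                if cell not in cell_mean.index or not g.has_edge(cls, cell):
                    continue
                g[cls][cell]["predicted_weight"] = float(panel_mean - cell_mean[cell])
                g[cls][cell]["evidence"] = "model_prediction"

    net = SensitivityNetwork(graph=g)
    net.validate()
    logger.info("build_network: %d nodes, %d edges (%d pathways, %d classes)",
                g.number_of_nodes(), g.number_of_edges(),
                len(passing), len(sensitive))
    return net


def export_network(net: SensitivityNetwork, out_dir, graphml: bool = False) -> None:
    """Write node and edge tables as TSV (and optionally GraphML)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net.node_table().to_csv(out / "network_nodes.tsv", sep="\t", index=False)
    net.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    if graphml:
        nx.write_graphml(net.graph, out / "network.graphml")


def read_network(out_dir) -> SensitivityNetwork:
    """Rebuild a network from exported node/edge tables."""
    from pathlib import Path

    out = Path(out_dir)
    nodes = pd.read_csv(out / "network_nodes.tsv", sep="\t")
    edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    g = nx.DiGraph()
    for _, row in nodes.iterrows():
        g.add_node(row["node"], node_type=row["node_type"])
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], weight=float(row["weight"]),
                   evidence=row["evidence"])
    return SensitivityNetwork(graph=g)
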