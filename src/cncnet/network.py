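"""Coding-noncoding coexpression networks and differential connectivity.

One network per group: nodes are the differentially expressed lncRNAs and
mRNAs, and an edge joins two genes whose Pearson correlation across that
group's samples passes the threshold (default ``|r| >= 0.97``, sign kept as
an edge attribute).  Genes left with no edge are not network members.

Per node and network: degree, k-core index (largest k surviving iterative
pruning of degree < k nodes), and normalized connectivity ``K`` (degree over
the network's maximum degree by default).  Differential connectivity
``diffK = K_disease - K_control`` (``K = 0`` where the gene is absent) ranks
candidate core regulators: a gene tightly connected in the disease network
but isolated in the control network scores near +1.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Mapping, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import BIOTYPE_LNC, BIOTYPE_MRNA, ExpressionMatrix

logger = logging.getLogger(__name__)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def build_cnc_network(matrix: ExpressionMatrix, group: str,
                      de_lnc: List[str], de_mrna: List[str],
                      config: PipelineConfig) -> nx.Graph:
    """Coexpression network for one group's samples.

    Candidate nodes are the DE lncRNAs and mRNAs; every unordered candidate
    pair whose correlation passes ``corr_threshold`` becomes an edge with
    attributes ``r`` and ``sign``.  With ``corr_use_absolute=False`` only
    positive correlations qualify (the literal signed reading); with
    ``bipartite_only=True`` same-biotype edges are not considered.
    Zero-degree candidates are dropped.  Constant-expression genes have no
    defined correlation; they are skipped with a logged count.
    """
    samples = matrix.samples_of(group)
    if len(samples) < 3:
        raise ValueError(
            f"group {group!r} has {len(samples)} samples; "
            "correlation needs >= 3")
    candidates = list(dict.fromkeys(list(de_lnc) + list(de_mrna)))
    biotype = {g: BIOTYPE_LNC for g in de_lnc}
    biotype.update({g: BIOTYPE_MRNA for g in de_mrna})
    graph = nx.Graph(group=group)
    if not candidates:
        return graph

    sub = matrix.values.loc[candidates, samples].to_numpy()
    sd = sub.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("%d constant genes skipped in %s network",
                    int(constant.sum()), group)
    keep = np.flatnonzero(~constant)
    ids = [candidates[i] for i in keep]
    if len(ids) >= 2:
        r = np.corrcoef(sub[keep])
        r = np.clip(r, -1.0, 1.0)
        iu, ju = np.triu_indices(len(ids), k=1)
        strength = np.abs(r[iu, ju]) if config.corr_use_absolute else r[iu, ju]
        hits = strength >= config.corr_threshold
        for i, j in zip(iu[hits], ju[hits]):
            a, b = ids[i], ids[j]
            if config.bipartite_only and biotype[a] == biotype[b]:
                continue
            rij = float(r[i, j])
            graph.add_node(a, biotype=biotype[a])
            graph.add_node(b, biotype=biotype[b])
            graph.add_edge(a, b, r=rij, sign="+" if rij >= 0 else "-")
    return graph


def k_core_decomposition(graph: nx.Graph) -> Dict[str, int]:
    """Core index per node: the largest k at which the node survives
    repeated deletion of nodes with degree < k."""
    if graph.number_of_nodes() == 0:
        return {}
    return nx.core_number(graph)


def _normalized_connectivity(graph: nx.Graph,
                             normalization: str) -> Dict[str, float]:
    if graph.number_of_nodes() == 0:
        return {}
    degrees = dict(graph.degree())
    if normalization == "max_degree":
        denom = max(degrees.values())
    else:  # 'n_minus_1'
        denom = max(1, graph.number_of_nodes() - 1)
    if denom == 0:
        return {n: 0.0 for n in degrees}
    return {n: d / denom for n, d in degrees.items()}


def diffk(net_disease: nx.Graph, net_control: nx.Graph,
          config: PipelineConfig) -> pd.DataFrame:
    """Node statistics of both networks ranked by |diffK| (descending).

    Columns: biotype, degree and core index and K per network, diffK, rank.
    Nodes absent from a network contribute K = 0 there.  Ties in |diffK| are
    broken by node id so the ranking is deterministic.
    """
    if net_disease.number_of_nodes() == 0 and net_control.number_of_nodes() == 0:
        warnings.warn("both networks are empty; diffK table is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=[
            "node", "biotype", "degree_disease", "degree_control",
            "core_disease", "core_control", "K_disease", "K_control",
            "diffK", "rank"]).set_index("node")

    k_d = _normalized_connectivity(net_disease, config.k_normalization)
    k_c = _normalized_connectivity(net_control, config.k_normalization)
    core_d = k_core_decomposition(net_disease)
    core_c = k_core_decomposition(net_control)
    nodes = sorted(set(net_disease.nodes) | set(net_control.nodes))
    rows = []
    for node in nodes:
        bt = (net_disease.nodes[node].get("biotype")
              if node in net_disease else net_control.nodes[node].get("biotype"))
        rows.append({
            "node": node,
            "biotype": bt,
            "degree_disease": net_disease.degree(node) if node in net_disease else 0,
            "degree_control": net_control.degree(node) if node in net_control else 0,
            "core_disease": core_d.get(node, 0),
            "core_control": core_c.get(node, 0),
            "K_disease": k_d.get(node, 0.0),
            "K_control": k_c.get(node, 0.0),
        })
    table = pd.DataFrame(rows).set_index("node")
    table["diffK"] = table["K_disease"] - table["K_control"]
    # order by |diffK| descending, ties broken by node id
    order = sorted(table.index, key=lambda n: (-abs(table.at[n, "diffK"]), n))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def export_network(graph: nx.Graph, stats: pd.DataFrame | None,
                   sif_path, graphml_path) -> None:
    """Write SIF (interaction pos/neg) and GraphML with node statistics."""
    g = nx.Graph()
    g.graph.update(graph.graph)
    for node in sorted(graph.nodes):
        attrs = {"biotype": graph.nodes[node].get("biotype", "")}
        if stats is not None and node in stats.index:
            row = stats.loc[node]
            suffix = "_disease" if graph.graph.get("group") == "disease" else "_control"
            attrs.update({
                "degree": int(row[f"degree{suffix}"]),
                "core_index": int(row[f"core{suffix}"]),
                "K": float(row[f"K{suffix}"]),
                "diffK": float(row["diffK"]),
            })
        else:
            attrs["degree"] = graph.degree(node)
        g.add_node(node, **attrs)
    for a, b in sorted(map(lambda e: tuple(sorted(e)), graph.edges)):
        data = graph.get_edge_data(a, b)
        g.add_edge(a, b, r=float(data["r"]), sign=data["sign"])

    with open(sif_path, "w") as fh:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
            kind = "pos" if g.edges[a, b]["sign"] == "+" else "neg"
            fh.write(f"{a}\t{kind}\t{b}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")
    nx.write_graphml(g, graphml_path)
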