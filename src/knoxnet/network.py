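"""Significance-filtered Pearson co-expression networks and their topology.

Edges connect probe pairs whose replicate-level log2(x+1) expression
correlates with |r| >= r_min at two-sided p <= alpha (t-test on n-2
degrees of freedom, no multiple-testing correction).  Topology metrics
follow the common network-analyzer conventions: local clustering
coefficient 0 for degree < 2, averaged over all nodes; characteristic
path length averaged over connected ordered pairs only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from knoxnet.expression_io import ExpressionMatrix
from knoxnet.preprocess import log_transform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    """Undirected correlation edge; probe_a < probe_b lexicographically."""

    probe_a: str
    probe_b: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.probe_a >= self.probe_b:
            raise ValueError("edge endpoints must satisfy probe_a < probe_b")


@dataclass
class CoexpressionNetwork:
    """Undirected simple graph of significance-filtered correlations.

    Isolated candidate nodes (no surviving edge) are dropped at build time
    and recorded in ``dropped_nodes``; every stored node has degree >= 1.
    """

    nodes: list[str]
    edges: list[CorrelationEdge]
    r_min: float
    alpha: float
    dropped_nodes: list[str] = field(default_factory=list)
    excluded_constant: list[str] = field(default_factory=list)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.probe_a, e.probe_b, {"r": e.r, "p": e.p}) for e in self.edges
        )
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_a": [e.probe_a for e in self.edges],
                "probe_b": [e.probe_b for e in self.edges],
                "r": [e.r for e in self.edges],
                "p": [e.p for e in self.edges],
                "n": [e.n for e in self.edges],
            }
        )

    def write_edges_tsv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def write_sif(self, path: str | Path) -> None:
        """Cytoscape simple-interaction format: ``a pp b`` per edge."""
        with open(path, "w") as fh:
            for e in self.edges:
                fh.write(f"{e.probe_a}\tpp\t{e.probe_b}\n")


@dataclass
class TopologyReport:
    degree: dict[str, int]
    local_cc: dict[str, float]
    avg_clustering_coefficient: float
    characteristic_path_length: float
    n_components: int
    n_nodes: int
    n_edges: int

    def hub_table(self) -> pd.DataFrame:
        """Nodes ranked by descending degree, ties broken by probe id."""
        rows = sorted(self.degree.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "probe_id": [p for p, _ in rows],
                "degree": [d for _, d in rows],
                "local_cc": [self.local_cc[p] for p, _ in rows],
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_clustering_coefficient": self.avg_clustering_coefficient,
            "characteristic_path_length": self.characteristic_path_length,
            "n_components": self.n_components,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length 1-d series, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant series")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(
        np.clip((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0)
    )


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise ValueError("correlation test requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_network(
    matrix: ExpressionMatrix,
    node_set,
    r_min: float = 0.6,
    alpha: float = 0.05,
    log: bool = True,
    sample_ids=None,
) -> CoexpressionNetwork:
    """All-pairs correlation network over ``node_set`` probes.

    Correlations use replicate-level values (optionally restricted to
    ``sample_ids``), log2(x+1)-transformed when ``log``.  Probes with
    constant expression are excluded from edge candidates with a log
    record; candidates left without any surviving edge are dropped.
    """
    node_list = list(dict.fromkeys(node_set))
    missing = [p for p in node_list if p not in set(matrix.probe_ids)]
    if missing:
        raise KeyError(f"node(s) absent from expression matrix: {missing}")
    sub = matrix.subset(node_list)
    values = sub.values
    if sample_ids is not None:
        keep = [j for j, s in enumerate(sub.samples) if s.sample_id in set(sample_ids)]
        values = values[:, keep]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    if log:
        values = log_transform(values)
    n_samples = values.shape[1]

    sd = values.std(axis=1)
    constant = [p for p, s in zip(sub.probe_ids, sd) if s == 0]
    if constant:
        logger.info("excluding %d constant probe(s): %s", len(constant), constant[:10])
    keep_idx = [i for i, s in enumerate(sd) if s > 0]
    probes = [sub.probe_ids[i] for i in keep_idx]
    vals = values[keep_idx]

    if len(probes) >= 2:
        corr = np.corrcoef(vals)
        corr = np.clip(corr, -1.0, 1.0)
    else:
        corr = np.ones((len(probes), len(probes)))
    edges: list[CorrelationEdge] = []
    for i, j in combinations(range(len(probes)), 2):
        r = float(corr[i, j])
        if abs(r) < r_min:
            continue
        p = correlation_pvalue(r, n_samples)
        if p > alpha:
            continue
        a, b = sorted((probes[i], probes[j]))
        edges.append(CorrelationEdge(a, b, r, p, n_samples))

    connected = {e.probe_a for e in edges} | {e.probe_b for e in edges}
    dropped = [p for p in probes if p not in connected]
    if dropped:
        logger.info(
            "dropping %d isolated candidate node(s) of %d: %s",
            len(dropped), len(probes), dropped[:10],
        )
    return CoexpressionNetwork(
        nodes=[p for p in probes if p in connected],
        edges=edges,
        r_min=r_min,
        alpha=alpha,
        dropped_nodes=dropped,
        excluded_constant=constant,
    )


def topology(network: CoexpressionNetwork) -> TopologyReport:
    """Degree, clustering coefficients and characteristic path length.

    CPL is the mean shortest-path length over all connected ordered node
    pairs (unweighted BFS); disconnected pairs are ignored.
    """
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = {v: int(d) for v, d in g.degree()}
    local_cc = {v: float(c) for v, c in nx.clustering(g).items()}
    avg_cc = float(np.mean(list(local_cc.values())))
    total, npairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if dist > 0:
                total += dist
                npairs += 1
    cpl = total / npairs if npairs else float("nan")
    return TopologyReport(
        degree=degree,
        local_cc=local_cc,
        avg_clustering_coefficient=avg_cc,
        characteristic_path_length=float(cpl),
        n_components=nx.number_connected_components(g),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
    )


def shared_neighbors(
    network: CoexpressionNetwork, seeds
) -> dict:
    """Shared-connection counts among seed genes.

    For every seed pair, the size of the intersection of their neighbor
    sets is reported twice: with the seeds removed from each other's
    neighborhoods (``pairwise``, the headline convention -- "connections
    shared" as common partners) and without removal
    (``pairwise_with_seeds``).  ``common_all`` is the set of nodes adjacent
    to every seed (seeds excluded).
    """
    g = network.to_graph()
    present = []
    for s in seeds:
        if s in g:
            present.append(s)
        else:
            logger.warning("seed %r not in network; skipped", s)
    seed_set = set(present)
    nbrs = {s: set(g.neighbors(s)) for s in present}
    pairwise = {}
    pairwise_with_seeds = {}
    for a, b in combinations(present, 2):
        pairwise[(a, b)] = len((nbrs[a] - seed_set) & (nbrs[b] - seed_set))
        pairwise_with_seeds[(a, b)] = len(nbrs[a] & nbrs[b])
    common = (
        set.intersection(*(nbrs[s] for s in present)) - seed_set
        if present
        else set()
    )
    return {
        "seeds": present,
        "pairwise": pairwise,
        "pairwise_with_seeds": pairwise_with_seeds,
        "common_all": sorted(common),
    }


def extract_subnetwork(
    network: CoexpressionNetwork, seeds
) -> CoexpressionNetwork:
    """Induced subgraph on the seeds and their direct neighbors."""
    g = network.to_graph()
    keep: set[str] = set()
    for s in seeds:
        if s not in g:
            logger.warning("seed %r not in network; skipped", s)
            continue
        keep.add(s)
        keep.update(g.neighbors(s))
    if not keep:
        raise ValueError("no seed present in the network")
    edges = [e for e in network.edges if e.probe_a in keep and e.probe_b in keep]
    connected = {e.probe_a for e in edges} | {e.probe_b for e in edges}
    return CoexpressionNetwork(
        nodes=sorted(keep & connected, key=network.nodes.index),
        edges=edges,
        r_min=network.r_min,
        alpha=network.alpha,
    )


def write_node_table(
    network: CoexpressionNetwork,
    report: TopologyReport,
    path: str | Path,
    gene_ids: dict[str, str] | None = None,
    clusters: dict[str, int] | None = None,
    scores: dict[str, float] | None = None,
) -> None:
    gene_ids = gene_ids or {}
    clusters = clusters or {}
    scores = scores or {}
    pd.DataFrame(
        {
            "probe_id": network.nodes,
            "gene_id": [gene_ids.get(p, "") for p in network.nodes],
            "cluster": [clusters.get(p, "") for p in network.nodes],
            "score": [scores.get(p, float("nan")) for p in network.nodes],
            "degree": [report.degree[p] for p in network.nodes],
            "local_cc": [report.local_cc[p] for p in network.nodes],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
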