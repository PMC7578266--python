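"""Protein-interaction network construction, centralities and comparison.

Builds undirected simple graphs from STRING-export-style edge lists
(optionally restricted to a node whitelist), computes degree,
betweenness and closeness per node, selects top-decile nodes per
metric, and partitions two networks' node sets into A-only / shared /
B-only.  Also formats the substrate/site input table for an external
kinase-site predictor and parses its output.

Conventions: betweenness is normalized by (n-1)(n-2)/2 with endpoints
excluded; closeness is computed within each connected component
(NetworkAnalyzer-style), not harmonically over the whole graph; the
"upper 10th percentile" threshold uses linear interpolation and keeps
ties at the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from osteoblast.diffphos import DifferentialRecord, Direction

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "closeness")


class EdgeListError(ValueError):
    """Malformed edge-list row."""


@dataclass(frozen=True)
class SiteKinasePrediction:
    """One predicted kinase/domain -> substrate-site interaction."""

    substrate_symbol: str
    site_position: int
    predicted_interactor: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.site_position < 1:
            raise ValueError("site_position must be >= 1")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass
class Ppin:
    """Undirected simple protein network with optional per-node metrics."""

    graph: nx.Graph
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def metrics_frame(self) -> pd.DataFrame:
        """Per-node metric table sorted by symbol."""
        nodes = sorted(self.graph.nodes)
        data = {"symbol": nodes}
        for m in METRICS:
            if m in self.metrics:
                data[m] = [self.metrics[m][n] for n in nodes]
        return pd.DataFrame(data)


def export_networkin_input(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Substrate/site rows for the external kinase-site predictor.

    One row per (accession, phospho position) pair over the significant
    (non-``ns``) records; records without an accession are skipped with
    a warning.
    """
    rows = []
    for rec in records:
        if rec.direction is Direction.NS:
            continue
        ann = rec.annotation
        if ann is None or not ann.uniprot_accession:
            logger.warning("record %s lacks an accession; skipped", rec.spot_id)
            continue
        for pos in ann.phospho_positions:
            rows.append(
                {
                    "substrate": ann.uniprot_accession,
                    "position": pos,
                    "residue": "Y",
                    "symbol": ann.symbol,
                }
            )
    return pd.DataFrame(rows, columns=["substrate", "position", "residue", "symbol"])


def read_predictions(path: str | Path, sep: str = "\t") -> list[SiteKinasePrediction]:
    """Parse a predictor-output-style TSV into site-kinase predictions.

    Expects columns substrate/symbol, position, kinase/interactor and an
    optional score column (extra columns ignored).
    """
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}

    def pick(*names: str) -> str | None:
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sub = pick("substrate", "symbol", "substrate_symbol", "#name", "name")
    pos = pick("position", "site", "site_position")
    kin = pick("kinase", "interactor", "predicted_interactor", "id", "kinase_id")
    score = pick("score", "networkin_score", "combined_score")
    if sub is None or pos is None or kin is None:
        raise EdgeListError(
            f"{path}: cannot identify substrate/position/kinase columns in {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            SiteKinasePrediction(
                substrate_symbol=str(row[sub]),
                site_position=int(row[pos]),
                predicted_interactor=str(row[kin]),
                score=float(row[score]) if score is not None else 0.0,
            )
        )
    return out


def build_ppin(
    edge_list: pd.DataFrame | str | Path,
    node_whitelist: set[str] | None = None,
    symbol_columns: tuple[str, str] | None = None,
) -> Ppin:
    """Undirected simple graph from a two-symbol-column edge table.

    Duplicate and reversed edges collapse to one; self-loops are
    dropped.  With a whitelist, only edges between whitelisted symbols
    survive (isolated whitelist nodes are not added).  Any extra
    columns (e.g. a combined score) are ignored - filtering by score is
    the caller's responsibility at export time.
    """
    if not isinstance(edge_list, pd.DataFrame):
        edge_list = pd.read_csv(edge_list, sep=None, engine="python")
    if symbol_columns is None:
        if edge_list.shape[1] < 2:
            raise EdgeListError("edge list needs at least two symbol columns")
        symbol_columns = (edge_list.columns[0], edge_list.columns[1])
    pairs = edge_list[list(symbol_columns)]
    graph = nx.Graph()
    for lineno, row in enumerate(pairs.itertuples(index=False), start=2):
        u, v = row[0], row[1]
        if pd.isna(u) or pd.isna(v) or not str(u).strip() or not str(v).strip():
            raise EdgeListError(f"malformed edge-list row at line {lineno}: {row}")
        u, v = str(u).strip(), str(v).strip()
        if u == v:
            continue
        if node_whitelist is not None and (u not in node_whitelist or v not in node_whitelist):
            continue
        graph.add_edge(u, v)
    return Ppin(graph=graph)


def centrality_metrics(ppin: Ppin) -> Ppin:
    """Attach degree, betweenness and closeness to every node (in place).

    Degree is the raw incident-edge count.  Betweenness uses the
    standard normalization for undirected graphs.  Closeness is the
    within-component convention: (n_comp - 1) / sum of distances to the
    node's component.
    """
    g = ppin.graph
    ppin.metrics["degree"] = {n: float(d) for n, d in g.degree()}
    ppin.metrics["betweenness"] = nx.betweenness_centrality(g, normalized=True)
    ppin.metrics["closeness"] = nx.closeness_centrality(g, wf_improved=False)
    return ppin


def top_decile(ppin: Ppin, metric: str) -> set[str]:
    """Nodes at or above the 90th percentile of a metric's distribution.

    The threshold uses linear-interpolation percentiles; ties at the
    threshold are all included.  An empty graph gives an empty set.
    """
    if metric not in ppin.metrics:
        raise KeyError(
            f"metric {metric!r} not computed; available: {sorted(ppin.metrics)}"
        )
    values = ppin.metrics[metric]
    if not values:
        return set()
    threshold = float(np.percentile(list(values.values()), 90))
    return {n for n, v in values.items() if v >= threshold}


def compare_networks(
    ppin_a: Ppin, ppin_b: Ppin, metric: str = "all_nodes"
) -> tuple[set[str], set[str], set[str]]:
    """Partition two networks' (top-decile or full) node sets.

    Returns ``(only_a, shared, only_b)`` - three disjoint sets whose
    union is the union of the two input sets.
    """
    if metric == "all_nodes":
        set_a, set_b = ppin_a.nodes, ppin_b.nodes
    else:
        set_a, set_b = top_decile(ppin_a, metric), top_decile(ppin_b, metric)
    return set_a - set_b, set_a & set_b, set_b - set_a
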