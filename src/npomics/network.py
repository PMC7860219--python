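"""Condition-specific co-expression networks with k-core hub ranking.

For one condition's samples, Pearson correlation is computed for every
unordered feature pair; each r gets a p-value from the t transform
``t = r * sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom (two-sided) and
a BH q-value across all pairs. Edges pass ``q < q_threshold`` and
``|r| >= r_threshold``; isolated nodes are retained. Node importance
combines the k-core index (the largest k such that the node survives in a
subgraph of minimum degree k) with plain degree; contrasting the
degenerated (IDD) network against the normal (IVD) one quantifies the
condensed-versus-scattered topology difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .diffexpr import bh_adjust
from .exceptions import ValidationError
from .matrix import ExpressionMatrix

DEFAULT_R_THRESHOLD = 0.95
DEFAULT_Q_THRESHOLD = 0.05


def pairwise_pearson(data: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson r and p over rows of a features x samples table.

    Zero-variance features are excluded with a warning (their correlation is
    undefined). Requires at least 3 samples so the t-transform p-value has
    positive degrees of freedom.
    """
    n = data.shape[1]
    if n < 3:
        raise ValidationError("pairwise_pearson needs >= 3 samples")
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        dropped = list(data.index[~keep])
        warnings.warn(f"excluding zero-variance features: {dropped[:5]}", stacklevel=2)
    ids = list(data.index[keep])
    values = values[keep]
    if len(ids) < 2:
        return pd.DataFrame(columns=["feature_a", "feature_b", "r", "p"])
    corr = np.corrcoef(values)
    iu = np.triu_indices(len(ids), k=1)
    r = np.clip(corr[iu], -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame(
        {
            "feature_a": [ids[i] for i in iu[0]],
            "feature_b": [ids[j] for j in iu[1]],
            "r": r,
            "p": p,
        }
    )


def build_network(
    correlations: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    node_layers: dict[str, str] | None = None,
    condition: str | None = None,
) -> nx.Graph:
    """Threshold correlations into a simple undirected graph.

    Edges satisfy ``q < q_threshold`` and ``|r| >= r_threshold``. All nodes
    present in the correlation table (or in ``node_layers``) are retained,
    isolated or not. Node attribute ``layer`` marks protein / mrna / both;
    k-core indices and degrees are attached by :func:`kcore_decompose`.
    """
    if not 0 <= r_threshold <= 1:
        raise ValidationError("r_threshold must lie in [0, 1]")
    if q_threshold <= 0:
        raise ValidationError("q_threshold must be > 0")
    corr = correlations.copy()
    corr["q"] = bh_adjust(corr["p"].to_numpy()) if len(corr) else []
    G = nx.Graph()
    if condition is not None:
        G.graph["condition"] = condition
    nodes = set(corr["feature_a"]) | set(corr["feature_b"])
    if node_layers:
        nodes |= set(node_layers)
    for node in sorted(nodes):
        G.add_node(node, layer=(node_layers or {}).get(node, "unknown"))
    passed = corr.loc[(corr["q"] < q_threshold) & (corr["r"].abs() >= r_threshold)]
    for row in passed.itertuples(index=False):
        G.add_edge(row.feature_a, row.feature_b, r=float(row.r), p=float(row.p), q=float(row.q))
    return kcore_decompose(G)


def kcore_decompose(network: nx.Graph) -> nx.Graph:
    """Attach ``kcore`` and ``degree`` attributes to every node in place."""
    core = nx.core_number(network)
    for node in network.nodes:
        network.nodes[node]["kcore"] = int(core[node])
        network.nodes[node]["degree"] = int(network.degree[node])
    return network


def rank_hubs(network: nx.Graph, top_n: int | None = None) -> list[str]:
    """Nodes sorted by (k-core desc, degree desc, id asc)."""
    nodes = sorted(
        network.nodes,
        key=lambda v: (-network.nodes[v]["kcore"], -network.nodes[v]["degree"], str(v)),
    )
    return nodes if top_n is None else nodes[:top_n]


@dataclass
class NetworkContrast:
    """Topology summary per condition plus IDD-minus-IVD differences."""

    idd: dict[str, float]
    ivd: dict[str, float]
    difference: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def topology_summary(network: nx.Graph) -> dict[str, float]:
    n = network.number_of_nodes()
    components = list(nx.connected_components(network)) if n else []
    largest = max((len(c) for c in components), default=0)
    degrees = [d for _, d in network.degree]
    return {
        "n_nodes": n,
        "n_edges": network.number_of_edges(),
        "density": float(nx.density(network)) if n > 1 else 0.0,
        "n_components": len(components),
        "largest_component_size": largest,
        "largest_component_fraction": largest / n if n else 0.0,
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "max_kcore": max((network.nodes[v].get("kcore", 0) for v in network.nodes), default=0),
    }


def contrast_networks(net_idd: nx.Graph, net_ivd: nx.Graph) -> NetworkContrast:
    """Per-condition topology summaries and their IDD - IVD differences."""
    idd, ivd = topology_summary(net_idd), topology_summary(net_ivd)
    diff = {k: idd[k] - ivd[k] for k in idd}
    return NetworkContrast(idd=idd, ivd=ivd, difference=diff)


class CoexpressionNetworkBuilder(BaseEstimator):
    """Estimator wrapper: fit a thresholded co-expression graph to samples.

    ``fit(X)`` takes X of shape (n_samples, n_features) — typically the
    samples of a single condition — and exposes ``correlations_`` (pair
    table with r, p) and ``graph_`` (the thresholded graph with k-core and
    degree attributes).
    """

    def __init__(
        self,
        q_threshold: float = DEFAULT_Q_THRESHOLD,
        r_threshold: float = DEFAULT_R_THRESHOLD,
        node_layers: dict[str, str] | None = None,
        condition: str | None = None,
    ):
        self.q_threshold = q_threshold
        self.r_threshold = r_threshold
        self.node_layers = node_layers
        self.condition = condition

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            data = X.T  # back to features x samples
        else:
            X = np.asarray(X, dtype=float)
            data = pd.DataFrame(X.T, index=[f"f{i}" for i in range(X.shape[1])])
        self.correlations_ = pairwise_pearson(data)
        self.graph_ = build_network(
            self.correlations_,
            q_threshold=self.q_threshold,
            r_threshold=self.r_threshold,
            node_layers=self.node_layers,
            condition=self.condition,
        )
        return self


def condition_network(
    matrix: ExpressionMatrix | pd.DataFrame,
    condition: str,
    groups: dict[str, str] | None = None,
    node_layers: dict[str, str] | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> nx.Graph:
    """Build the co-expression network over one condition's samples."""
    if isinstance(matrix, ExpressionMatrix):
        data = matrix.data
        groups = matrix.groups
    else:
        data = matrix
        if groups is None:
            raise ValidationError("groups mapping required with a plain DataFrame")
    samples = [s for s in data.columns if groups[s] == condition]
    corr = pairwise_pearson(data[samples])
    return build_network(
        corr,
        q_threshold=q_threshold,
        r_threshold=r_threshold,
        node_layers=node_layers,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        (a, b, d.get("r", np.nan), d.get("p", np.nan), d.get("q", np.nan))
        for a, b, d in sorted(network.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p", "q"])


def node_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        (v, d.get("layer", "unknown"), d.get("kcore", 0), d.get("degree", 0))
        for v, d in sorted(network.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["node", "layer", "kcore", "degree"])
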