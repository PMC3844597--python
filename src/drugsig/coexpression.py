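"""Transcriptome co-expression map and drug-responsive network extraction.

All-pairs Spearman correlations between transcript drug-response
profiles define a correlation distance d = 1 - rho.  A minimal spanning
tree over this distance is the co-expression map; walk-length (number of
edges on the unique tree path) is the metric used to cut the selected
drug-responsive transcripts into networks by single-linkage clustering,
which at a fixed cut height is the same as taking connected components
of the graph joining selected pairs within that walk-length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .scoring import FoldChangeTable

UNASSIGNED = "unassigned"


def expression_profiles(fct: FoldChangeTable) -> pd.DataFrame:
    """Probe × (drug, time) matrix of group-mean log2 fold changes.

    These drug-response curves are the "expression profiles" correlated
    to build the co-expression map.
    """
    return fct.per_cell["log2fc"].unstack(["drug", "time_h"])


def spearman_distance(profiles: pd.DataFrame, transcripts=None) -> pd.DataFrame:
    """Pairwise Spearman correlation distance d = 1 - rho between profiles.

    Constant profiles have undefined rank correlation; their distances
    are set to the neutral sentinel 1.0 with a warning.
    """
    if transcripts is not None:
        profiles = profiles.loc[pd.Index(transcripts)]
    if profiles.shape[1] < 3:
        raise ValueError("need >= 3 observations per profile for rank correlation")
    X = profiles.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    # Spearman = Pearson on average-tied ranks; row-wise rank transform
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
    d = 1.0 - rho
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profiles; their correlations are "
            "undefined, distance set to 1.0"
        )
        d[constant, :] = 1.0
        d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def build_mst(distances: pd.DataFrame) -> nx.Graph:
    """Minimal spanning tree of the full pairwise distance matrix.

    Kruskal's algorithm with edges pre-sorted lexicographically, so ties
    between equal-weight edges resolve to the lexicographically smallest
    pair and the tree is reproducible.
    """
    D = distances.to_numpy(dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distances contain NaN/inf")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    nodes = list(distances.index)
    n = len(nodes)
    order = sorted(range(n), key=lambda i: str(nodes[i]))
    perm = np.array(order)
    Dp = D[np.ix_(perm, perm)]
    iu, ju = np.triu_indices(n, k=1)
    # stable sort on weight keeps the lexicographic (iu, ju) order at ties
    rank = np.argsort(Dp[iu, ju], kind="stable")
    G = nx.Graph()
    G.add_nodes_from(nodes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    added = 0
    for e in rank:
        a, b = int(iu[e]), int(ju[e])
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            G.add_edge(
                nodes[perm[a]], nodes[perm[b]], weight=float(Dp[a, b])
            )
            added += 1
            if added == n - 1:
                break
    return G


def walk_length(tree: nx.Graph, node_pairs) -> list[int]:
    """Number of edges on the unique tree path between each node pair."""
    out = []
    for u, v in node_pairs:
        if u not in tree or v not in tree:
            missing = u if u not in tree else v
            raise KeyError(f"node {missing!r} not in tree")
        out.append(nx.shortest_path_length(tree, u, v))
    return out


@dataclass
class NetworkAssignment:
    """Partition of the selected transcripts into co-expression networks."""

    labels: pd.Series  # transcript -> net_k or "unassigned"
    networks: dict[str, list]  # label -> member list, decreasing size

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.networks.items()}

    def write(self, path) -> None:
        self.labels.rename("network_label").rename_axis("probe_id").to_csv(
            path, sep="\t"
        )


def extract_networks(
    tree: nx.Graph,
    selected_transcripts,
    cutoff: int = 4,
    min_network_size: int = 10,
) -> NetworkAssignment:
    """Single-linkage networks of selected transcripts under walk-length.

    Two selected transcripts belong to the same network when they are
    linked by a chain of selected transcripts with consecutive
    walk-lengths <= ``cutoff`` (equivalently: connected components of
    the thresholded walk-length graph).  Components smaller than
    ``min_network_size`` are labelled unassigned.  Networks are named
    net_1, net_2, ... in decreasing size order (ties broken by the
    smallest member id).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    selected = list(dict.fromkeys(selected_transcripts))
    missing = [t for t in selected if t not in tree]
    if missing:
        raise KeyError(f"selected transcripts not in tree: {missing[:5]}")

    sel_set = set(selected)
    H = nx.Graph()
    H.add_nodes_from(selected)
    # BFS from each selected node out to `cutoff` edges on the tree
    for s in selected:
        lengths = nx.single_source_shortest_path_length(tree, s, cutoff=cutoff)
        for v in lengths:
            if v != s and v in sel_set:
                H.add_edge(s, v)

    comps = sorted(
        (sorted(c, key=str) for c in nx.connected_components(H)),
        key=lambda c: (-len(c), str(c[0])),
    )
    labels = pd.Series(UNASSIGNED, index=pd.Index(selected, name="probe_id"))
    networks: dict[str, list] = {}
    k = 0
    for comp in comps:
        if len(comp) >= min_network_size:
            k += 1
            name = f"net_{k}"
            networks[name] = comp
            labels.loc[comp] = name
    return NetworkAssignment(labels=labels, networks=networks)


def write_tree(tree: nx.Graph, edgelist_path, graphml_path=None) -> None:
    """Export the co-expression tree as an edge-list TSV (and GraphML)."""
    rows = [
        (u, v, d.get("weight", 1.0))
        for u, v, d in sorted(tree.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight"]).to_csv(
        edgelist_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(tree, graphml_path)
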