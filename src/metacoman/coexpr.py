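"""Co-expression networks over the most varied functional groups.

Within one condition, pairwise Spearman correlations of feature expression
profiles define a network: an edge joins two features when |rho| meets the
threshold (default 0.7). Communities are found by short-random-walk
agglomeration (Walktrap, walk length 4) on |rho| edge weights, cutting the
dendrogram at maximum modularity; every detected community with fewer than
3 members is then merged into one residual module. Hubs are the nodes in
the top degree fraction. A condition must contribute more than 4 samples;
more than 8 is recommended for lower false-positive rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_tab import SampleMetadata
from .profiling import AbundanceProfile

DEFAULT_RHO = 0.7
DEFAULT_WALK_STEPS = 4
MIN_SAMPLES = 4  # strict floor: need strictly more than this
RECOMMENDED_SAMPLES = 8
RESIDUAL_LABEL = -1


@dataclass
class CoexprNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns u, v, rho (u < v)
    community_of: dict[str, int] = field(default_factory=dict)
    hubs: set[str] = field(default_factory=set)
    hub_degenerate: bool = False

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=pd.Index(self.nodes, name="feature"))
        for u, v in zip(self.edges["u"], self.edges["v"]):
            deg[u] += 1
            deg[v] += 1
        return deg

    def modularity(self) -> float:
        g = _to_igraph(self)
        labels = [self.community_of[n] for n in self.nodes]
        return g.modularity(_relabel(labels), weights=g.es["weight"] if g.ecount() else None)


def _relabel(labels: list[int]) -> list[int]:
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
        out.append(seen[lab])
    return out


def _to_igraph(net: CoexprNetwork) -> ig.Graph:
    index = {n: i for i, n in enumerate(net.nodes)}
    g = ig.Graph(len(net.nodes))
    g.vs["name"] = net.nodes
    if len(net.edges):
        g.add_edges([(index[u], index[v]) for u, v in zip(net.edges["u"], net.edges["v"])])
        g.es["weight"] = [abs(r) for r in net.edges["rho"]]
    return g


def build_network(
    profile: AbundanceProfile,
    meta: SampleMetadata,
    condition: str,
    features: list[str] | None = None,
    rho_threshold: float = DEFAULT_RHO,
) -> CoexprNetwork:
    """Spearman co-expression network from one condition's samples.

    An edge is kept when |rho| >= ``rho_threshold``; isolated nodes are
    retained. Errors when the condition has 4 or fewer samples (the
    analysis needs more than four); warns below the recommended more-than-
    eight. Feature pairs where either profile is constant have undefined
    rho and get no edge.
    """
    if condition not in meta.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    samples = [s for s in meta.samples_of(condition) if s in profile.samples]
    if len(samples) <= MIN_SAMPLES:
        raise ValueError(
            f"co-expression analysis needs more than {MIN_SAMPLES} samples in one "
            f"condition; {condition!r} has {len(samples)}"
        )
    if len(samples) <= RECOMMENDED_SAMPLES:
        warnings.warn(
            f"condition {condition!r} has {len(samples)} samples; more than "
            f"{RECOMMENDED_SAMPLES} is recommended to limit false positives",
            stacklevel=2,
        )
    nodes = sorted(features) if features is not None else sorted(profile.features)
    if len(nodes) < 2:
        raise ValueError("need at least 2 features to build a network")
    data = profile.data.loc[nodes, samples].to_numpy(dtype=float)
    # constant features have undefined rho; exclude them up front (scipy
    # collapses the whole matrix to a scalar NaN when its first or second
    # variable is constant)
    constant = np.array([len(np.unique(row)) == 1 for row in data])
    active = np.flatnonzero(~constant)
    rho = np.full((len(nodes), len(nodes)), np.nan)
    if len(active) >= 2:
        sub = spearmanr(data[active], axis=1).statistic
        if np.ndim(sub) == 0:  # scipy returns a scalar for exactly 2 variables
            sub = np.array([[1.0, float(sub)], [float(sub), 1.0]])
        rho[np.ix_(active, active)] = sub
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = float(rho[i, j])
            if not math.isnan(r) and abs(r) >= rho_threshold:
                rows.append((nodes[i], nodes[j], r))
    edges = pd.DataFrame(rows, columns=["u", "v", "rho"])
    return CoexprNetwork(nodes=nodes, edges=edges)


def detect_communities(
    net: CoexprNetwork,
    walk_steps: int = DEFAULT_WALK_STEPS,
    seed: int | None = None,
    min_community_size: int = 3,
) -> CoexprNetwork:
    """Random-walk (Walktrap) communities on |rho| weights, then residual merge.

    The agglomerative dendrogram is cut at maximum modularity. Every
    community smaller than ``min_community_size`` is merged into one
    residual module (label -1). ``seed`` is accepted for interface
    stability; the walk-distance agglomeration itself is deterministic.
    Returns the same network with ``community_of`` filled in.
    """
    if not net.nodes:
        net.community_of = {}
        return net
    g = _to_igraph(net)
    if g.ecount() == 0:
        membership = list(range(len(net.nodes)))
    else:
        dendrogram = g.community_walktrap(weights=g.es["weight"], steps=walk_steps)
        membership = list(dendrogram.as_clustering().membership)
    sizes: dict[int, int] = {}
    for lab in membership:
        sizes[lab] = sizes.get(lab, 0) + 1
    merged = [
        lab if sizes[lab] >= min_community_size else RESIDUAL_LABEL for lab in membership
    ]
    # compact positive labels, keep residual at -1
    compact: dict[int, int] = {}
    final = []
    for lab in merged:
        if lab == RESIDUAL_LABEL:
            final.append(RESIDUAL_LABEL)
            continue
        if lab not in compact:
            compact[lab] = len(compact)
        final.append(compact[lab])
    net.community_of = dict(zip(net.nodes, final))
    return net


def find_hubs(net: CoexprNetwork, top_fraction: float = 0.05) -> CoexprNetwork:
    """Nodes whose degree lies in the top ``top_fraction`` (ties included).

    At least one node is returned for any network with an edge; an edgeless
    network has no hubs. When every node ties on degree the whole node set
    is returned and the result is flagged degenerate.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(net.edges) == 0:
        net.hubs = set()
        net.hub_degenerate = False
        return net
    deg = net.degree()
    k = max(1, math.ceil(top_fraction * len(net.nodes)))
    cutoff = deg.sort_values(ascending=False).iloc[k - 1]
    hubs = set(deg.index[deg >= cutoff])
    net.hubs = hubs
    net.hub_degenerate = len(set(deg.values)) == 1
    return net


def network_tables(net: CoexprNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge table) for TSV export."""
    deg = net.degree()
    node_table = pd.DataFrame(
        {
            "degree": deg,
            "community": [net.community_of.get(n, np.nan) for n in net.nodes],
            "hub": [n in net.hubs for n in net.nodes],
        },
        index=pd.Index(net.nodes, name="feature"),
    )
    edge_table = net.edges.sort_values(["u", "v"], kind="mergesort").reset_index(drop=True)
    return node_table, edge_table
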