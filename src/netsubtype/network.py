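"""Per-group co-expression networks: Pearson correlation, the PCIT trio
significance filter, pruning, label-propagation communities, and node
centralities.

PCIT examines every gene trio (x, y, z): the three first-order partial
correlations define a local tolerance (the average absolute ratio of
partial to direct correlation), and the edge (x, y) is eliminated whenever
some z renders |r_xy| smaller than tolerance * |r_xz| and
tolerance * |r_yz| simultaneously.  Surviving pairs keep their raw Pearson
correlation as edge weight.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netsubtype.matrix import ExprMatrix
from netsubtype.stats_util import zscore

logger = logging.getLogger(__name__)

_DENOM_GUARD = 1e-12


def pearson_matrix(E: ExprMatrix) -> np.ndarray:
    """Pairwise Pearson correlations across samples (genes as variables).

    Zero-variance genes get correlation 0 with a warning.
    """
    if E.n_samples < 4:
        raise ValueError("need >= 4 samples")
    if E.n_genes < 3:
        raise ValueError("need >= 3 genes")
    X = E.values
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance genes: correlations set to 0", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def pcit_mask(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCIT significance mask and masked weights for a correlation matrix."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if np.abs(R).max() > 1 + 1e-8:
        raise ValueError("|r| > 1")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("R must have unit diagonal")
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)

    absR = np.abs(R)
    eliminated = np.zeros((n, n), dtype=bool)
    one_minus_sq = np.maximum(1.0 - R**2, 0.0)
    for z in range(n):
        rz = R[:, z]                       # r_xz as column, r_yz as row
        omz = one_minus_sq[:, z]
        # partial r_xy.z
        den_xy = np.sqrt(np.maximum(np.outer(omz, omz), _DENOM_GUARD))
        p_xy = (R - np.outer(rz, rz)) / den_xy
        # partial r_xz.y  (condition the x-z pair on y)
        den_xz = np.sqrt(np.maximum(one_minus_sq * omz[None, :], _DENOM_GUARD))
        p_xz = (rz[:, None] - R * rz[None, :]) / den_xz
        # partial r_yz.x  (condition the y-z pair on x)
        den_yz = np.sqrt(np.maximum(one_minus_sq * omz[:, None], _DENOM_GUARD))
        p_yz = (rz[None, :] - R * rz[:, None]) / den_yz

        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_xy = np.where(absR > 0, np.abs(p_xy) / absR, 0.0)
            ratio_xz = np.where(
                np.abs(rz[:, None]) > 0, np.abs(p_xz) / np.abs(rz)[:, None], 0.0
            )
            ratio_yz = np.where(
                np.abs(rz[None, :]) > 0, np.abs(p_yz) / np.abs(rz)[None, :], 0.0
            )
        eps = (ratio_xy + ratio_xz + ratio_yz) / 3.0
        cond = (absR < eps * np.abs(rz)[:, None]) & (absR < eps * np.abs(rz)[None, :])
        # trios require three distinct genes
        cond[z, :] = False
        cond[:, z] = False
        np.fill_diagonal(cond, False)
        eliminated |= cond

    mask = ~eliminated
    np.fill_diagonal(mask, False)
    mask &= mask.T
    mask &= absR > 0  # an exactly-zero correlation is never an edge
    weights = np.where(mask, R, 0.0)
    return mask, weights


@dataclass
class GeneNetwork:
    """Weighted undirected co-expression network over gene nodes."""

    nodes: np.ndarray
    weights: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    group: str = ""
    pruned_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=object)
        n = len(self.nodes)
        if self.weights.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("matrix shapes must match nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.mask, 1).sum())

    def edges(self) -> list[tuple[str, str, float]]:
        iu = np.triu_indices(self.n_nodes, 1)
        out = []
        for i, j in zip(*iu):
            if self.mask[i, j]:
                out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w, length=1.0 / max(abs(w), _DENOM_GUARD))
        return g

    def write_edgelist(self, path: str | Path) -> None:
        rows = [{"gene1": a, "gene2": b, "weight": w, "group": self.group}
                for a, b, w in self.edges()]
        pd.DataFrame(rows, columns=["gene1", "gene2", "weight", "group"]).to_csv(
            path, sep="\t", index=False
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


def build_network(
    nodes, mask: np.ndarray, weights: np.ndarray, group: str = "",
    prune_isolated: bool = True,
) -> GeneNetwork:
    """Assemble a network: drop self-loops, symmetrize, prune degree-0 nodes."""
    nodes = np.asarray(nodes, dtype=object)
    mask = np.asarray(mask, dtype=bool).copy()
    weights = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(mask, False)
    mask = mask | mask.T  # symmetric storage; duplicate directed entries collapse
    np.fill_diagonal(mask, False)
    weights = np.where(mask, 0.5 * (weights + weights.T), 0.0)
    degree = mask.sum(axis=1)
    if prune_isolated:
        keep = degree > 0
        pruned = nodes[~keep]
        if len(pruned):
            logger.info("pruned %d isolated nodes", len(pruned))
        net = GeneNetwork(
            nodes[keep], weights[np.ix_(keep, keep)], mask[np.ix_(keep, keep)],
            group=group, pruned_nodes=pruned,
        )
    else:
        net = GeneNetwork(nodes, weights, mask, group=group)
    if net.n_nodes == 0:
        logger.warning("empty network for group %r", group)
    return net


@dataclass
class CommunityAssignment:
    communities: dict[str, int]
    n_communities: int
    converged: bool
    seed: int
    restart_counts: Counter = field(default_factory=Counter)


def _label_propagation_once(
    adj: list[list[int]], n: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, bool]:
    labels = np.arange(n)
    order = np.arange(n)
    for _ in range(max_iter):
        rng.shuffle(order)
        changed = False
        for i in order:
            if not adj[i]:
                continue
            counts = Counter(labels[j] for j in adj[i])
            top = max(counts.values())
            modes = [lab for lab, c in counts.items() if c == top]
            if labels[i] in modes:
                continue
            labels[i] = modes[int(rng.integers(len(modes)))]
            changed = True
        if not changed:
            return labels, True
    return labels, False


def _canonical(labels: np.ndarray) -> tuple[int, ...]:
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def detect_communities(
    net: GeneNetwork, seed: int = 12345, max_iter: int = 100, n_restarts: int = 20
) -> CommunityAssignment:
    """Asynchronous label propagation on the unweighted mask, with seeded
    restarts; the modal partition across restarts is reported."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    n = net.n_nodes
    adj = [list(np.flatnonzero(net.mask[i])) for i in range(n)]
    results: Counter = Counter()
    details: dict[tuple[int, ...], bool] = {}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        labels, converged = _label_propagation_once(adj, n, rng, max_iter)
        canon = _canonical(labels)
        results[canon] += 1
        details[canon] = converged
    modal, _count = results.most_common(1)[0]
    communities = {net.nodes[i]: lab + 1 for i, lab in enumerate(modal)}
    return CommunityAssignment(
        communities, len(set(modal)), details[modal], seed, restart_counts=results
    )


@dataclass
class CentralityTable:
    table: pd.DataFrame = field(repr=False)

    def betweenness_z(self) -> pd.Series:
        return self.table.set_index("gene")["betweenness_z"]

    def authority(self) -> pd.Series:
        return self.table.set_index("gene")["authority"]


def centralities(net: GeneNetwork, weighted: bool = True) -> CentralityTable:
    """Betweenness (shortest paths with edge length 1/|weight| by default)
    and authority (principal eigenvector of |W|, power iteration)."""
    if net.n_nodes == 0 or net.n_edges == 0:
        raise ValueError("cannot compute centralities on an empty network")
    g = net.to_graph()
    btw = nx.betweenness_centrality(
        g, normalized=False, weight="length" if weighted else None
    )
    raw = np.array([btw[node] for node in net.nodes])
    z = zscore(raw)

    A = np.abs(net.weights)
    # small diagonal shift: breaks power-iteration oscillation on bipartite
    # graphs (paired +/- leading eigenvalues) without changing eigenvectors
    shift = 0.05 * max(A.max(), _DENOM_GUARD)
    A = A + shift * np.eye(net.n_nodes)
    v = np.ones(net.n_nodes)
    for _ in range(100_000):
        v_new = A @ v
        norm = np.linalg.norm(v_new)
        if norm == 0:
            v_new = v
            break
        v_new /= norm
        if np.abs(v_new - v).max() < 1e-10:
            v = v_new
            break
        v = v_new
    authority = np.abs(v)
    if authority.max() > 0:
        authority = authority / authority.max()

    table = pd.DataFrame(
        {
            "gene": net.nodes,
            "betweenness": raw,
            "betweenness_z": z,
            "authority": authority,
        }
    )
    return CentralityTable(table)


def delta_betweenness(
    net1: GeneNetwork, net2: GeneNetwork, weighted: bool = True
) -> pd.Series:
    """Per-node difference of standardized betweenness (net1 - net2) over
    the union node set, sorted by |delta| descending.  Nodes absent from a
    network contribute raw betweenness 0 before standardization."""
    union = sorted(set(net1.nodes) | set(net2.nodes))

    def z_over_union(net: GeneNetwork) -> pd.Series:
        raw = pd.Series(0.0, index=union)
        if net.n_nodes and net.n_edges:
            ct = centralities(net, weighted=weighted)
            raw.loc[ct.table["gene"].tolist()] = ct.table["betweenness"].to_numpy()
        return pd.Series(zscore(raw.to_numpy()), index=union)

    delta = z_over_union(net1) - z_over_union(net2)
    return delta.reindex(delta.abs().sort_values(ascending=False, kind="stable").index)
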