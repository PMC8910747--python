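"""Permutation network comparison between two sample groups.

The observed networks are built by a caller-supplied network function
(default: Pearson correlation -> PCIT mask -> pruning).  Sample-to-group
assignments are permuted (group sizes preserved) and both networks rebuilt
per permutation, giving null distributions for the global strength
difference, the maximum edge difference, and every per-edge difference.
The plus-one convention keeps Monte-Carlo p-values strictly positive; when
the number of distinct assignments is small enough, the full assignment set
is enumerated instead and p-values are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from netsubtype.matrix import ExprMatrix
from netsubtype.network import GeneNetwork, build_network, pcit_mask, pearson_matrix
from netsubtype.stats_util import bh_adjust

logger = logging.getLogger(__name__)


def default_network_fn(E: ExprMatrix, group: str = "") -> GeneNetwork:
    """Pearson -> PCIT -> prune, keeping the full node set unpruned so edge
    matrices stay aligned across permutations."""
    R = pearson_matrix(E)
    mask, weights = pcit_mask(R)
    return build_network(E.gene_ids, mask, weights, group=group, prune_isolated=False)


def global_strength(net: GeneNetwork) -> float:
    """Sum of |weights| over unique undirected edges."""
    return float(np.abs(np.triu(np.where(net.mask, net.weights, 0.0), 1)).sum())


@dataclass
class NCTResult:
    S_obs: float
    p_S: float
    M_obs: float
    p_M: float
    edge_table: pd.DataFrame = field(repr=False)
    n_perm: int
    seed: int
    exact: bool = False
    nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def _edge_weight_matrix(net: GeneNetwork) -> np.ndarray:
    return np.where(net.mask, net.weights, 0.0)


def nct(
    E1: ExprMatrix,
    E2: ExprMatrix,
    n_perm: int = 1000,
    seed: int = 12345,
    network_fn=default_network_fn,
) -> NCTResult:
    """Permutation test of global strength, structure (max edge difference)
    and per-edge strength invariance between two group networks."""
    if list(E1.gene_ids) != list(E2.gene_ids):
        raise ValueError("both groups must share the same gene set")
    n1, n2 = E1.n_samples, E2.n_samples
    if min(n1, n2) < 4:
        raise ValueError("both groups need >= 4 samples")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")

    net1 = network_fn(E1, group="group1")
    net2 = network_fn(E2, group="group2")
    W1, W2 = _edge_weight_matrix(net1), _edge_weight_matrix(net2)
    diff = W1 - W2
    iu = np.triu_indices(len(E1.gene_ids), 1)
    union_edges = (net1.mask | net2.mask)[iu]
    obs_edge = np.abs(diff[iu])
    S_obs = float(abs(np.abs(W1[iu]).sum() - np.abs(W2[iu]).sum()))
    M_obs = float(obs_edge.max()) if obs_edge.size else 0.0

    pooled = np.hstack([E1.values, E2.values])
    samples = np.concatenate([E1.sample_ids, E2.sample_ids])
    n = n1 + n2

    def stat_for(idx1: np.ndarray) -> tuple[float, float, np.ndarray]:
        mask1 = np.zeros(n, dtype=bool)
        mask1[idx1] = True
        P1 = ExprMatrix(E1.gene_ids, samples[mask1], pooled[:, mask1])
        P2 = ExprMatrix(E1.gene_ids, samples[~mask1], pooled[:, ~mask1])
        g1, g2 = network_fn(P1), network_fn(P2)
        A1, A2 = _edge_weight_matrix(g1), _edge_weight_matrix(g2)
        d = np.abs((A1 - A2)[iu])
        s = abs(np.abs(A1[iu]).sum() - np.abs(A2[iu]).sum())
        return s, (d.max() if d.size else 0.0), d

    total_assignments = comb(n, n1)
    exact = total_assignments <= n_perm
    s_ge = m_ge = 0
    edge_ge = np.zeros(len(obs_edge))
    if exact:
        count = 0
        for idx1 in combinations(range(n), n1):
            s, m, d = stat_for(np.array(idx1))
            s_ge += s >= S_obs - 1e-12
            m_ge += m >= M_obs - 1e-12
            edge_ge += d >= obs_edge - 1e-12
            count += 1
        p_S = s_ge / count
        p_M = m_ge / count
        p_edge = edge_ge / count
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            idx1 = rng.choice(n, size=n1, replace=False)
            s, m, d = stat_for(idx1)
            s_ge += s >= S_obs - 1e-12
            m_ge += m >= M_obs - 1e-12
            edge_ge += d >= obs_edge - 1e-12
        p_S = (1 + s_ge) / (1 + n_perm)
        p_M = (1 + m_ge) / (1 + n_perm)
        p_edge = (1 + edge_ge) / (1 + n_perm)

    rows = pd.DataFrame(
        {
            "gene1": np.asarray(E1.gene_ids)[iu[0]],
            "gene2": np.asarray(E1.gene_ids)[iu[1]],
            "diff": diff[iu],
            "p": p_edge,
        }
    )
    rows = rows[union_edges].reset_index(drop=True)
    if len(rows):
        rows["q"] = bh_adjust(rows["p"].to_numpy())
    else:
        rows["q"] = pd.Series(dtype=float)
    return NCTResult(
        S_obs, float(p_S), M_obs, float(p_M), rows, n_perm, seed, exact=exact,
        nodes=np.asarray(E1.gene_ids, dtype=object),
    )


def differential_network(result: NCTResult, q_threshold: float = 0.01) -> GeneNetwork:
    """Network of edges with BH-adjusted permutation p <= threshold; edge
    weight = observed difference; isolated nodes pruned."""
    nodes = result.nodes
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    mask = np.zeros((n, n), dtype=bool)
    weights = np.zeros((n, n))
    hits = result.edge_table[result.edge_table["q"] <= q_threshold]
    for row in hits.itertuples(index=False):
        i, j = index[row.gene1], index[row.gene2]
        mask[i, j] = mask[j, i] = True
        weights[i, j] = weights[j, i] = row.diff
    net = build_network(nodes, mask, weights, group="differential")
    if net.n_edges == 0:
        logger.warning("differential network is empty at q <= %g", q_threshold)
    return net
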