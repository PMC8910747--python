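"""Subtype discovery: clusterability assessment (Hopkins), best-k
estimation by an internal-validity index ensemble, a clustering-algorithm
portfolio over distance metrics, internal validation (silhouette / Dunn),
model selection, and clinical comparison between clusters.

All algorithms operate on samples as rows.  Hierarchical methods are built
on a generalized Lance-Williams agglomeration so centroid linkage can be
combined with Manhattan distances (a formally heterodox but documented
pairing); the hybrid "hierarchical k-means" cuts that tree at k and refines
the induced partition with Lloyd's algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "kmeans",
    "hierarchical_kmeans",
    "pam",
    "clara",
    "agnes",
    "diana",
    "fuzzy",
    "hclust",
)
METRICS = ("euclidean", "manhattan")
DUNN_SENTINEL = 1e12

# algorithm/metric pairs that are skipped (centroid-based updates assume
# Euclidean geometry and no distance-matrix variant is provided)
_UNSUPPORTED = {("kmeans", "manhattan"), ("fuzzy", "manhattan")}


# ---------------------------------------------------------------------------
# distances and clusterability
# ---------------------------------------------------------------------------


def distance_matrix(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise sample distances with zero diagonal."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if metric == "euclidean":
        D = cdist(X, X, metric="euclidean")
    elif metric == "manhattan":
        D = cdist(X, X, metric="cityblock")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def pca_scores(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Principal-component scores (SVD on centered data)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ Vt[: min(n_components, Vt.shape[0])].T


@dataclass
class ClusterabilityReport:
    H: float
    m: int
    seed: int
    threshold: float = 0.5

    @property
    def clusterable(self) -> bool:
        return self.H < self.threshold


def hopkins(X: np.ndarray, m: int = 50, seed: int = 12345, threshold: float = 0.5) -> ClusterabilityReport:
    """Hopkins clusterability statistic, H = sum(w) / (sum(u) + sum(w)).

    w: nearest-neighbor distances of m sampled data points to the remaining
    data; u: nearest-neighbor distances of m uniform points (drawn in the
    data bounding box) to the data.  Values near 0 indicate cluster
    structure under this convention.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= n:
        raise ValueError("m must be smaller than the number of samples")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate (zero-extent) bounding box")
    # spawn-keyed stream: a caller who built X from default_rng(seed) must
    # not see the reference points replay the data stream
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x486F,)))
    idx = rng.choice(n, size=m, replace=False)
    # distance of each sampled point to its nearest other data point
    dw = cdist(X[idx], X, metric="euclidean")
    dw[np.arange(m), idx] = np.inf
    w = dw.min(axis=1)
    U = rng.uniform(lo, hi, size=(m, X.shape[1]))
    u = cdist(U, X, metric="euclidean").min(axis=1)
    H = float(w.sum() / (u.sum() + w.sum()))
    return ClusterabilityReport(H, m, seed, threshold)


# ---------------------------------------------------------------------------
# generalized agglomerative clustering (Lance-Williams)
# ---------------------------------------------------------------------------


def agglomerative_labels(D: np.ndarray, k: int, linkage: str = "average") -> np.ndarray:
    """Cut a Lance-Williams agglomerative tree at k clusters.

    ``centroid`` linkage uses the squared-distance update
    d2(k, ij) = (ni*d2(k,i) + nj*d2(k,j))/(ni+nj) - ni*nj*d2(i,j)/(ni+nj)^2,
    applied to the squared input distances whatever the metric.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    if linkage == "centroid":
        W = D.astype(float) ** 2
    else:
        W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    while len(active) > k:
        sub = W[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        i, j = active[ai], active[aj]
        if i > j:
            i, j = j, i
        ni, nj = sizes[i], sizes[j]
        dij = W[i, j]
        for c in active:
            if c in (i, j):
                continue
            if linkage == "average":
                new = (ni * W[c, i] + nj * W[c, j]) / (ni + nj)
            elif linkage == "complete":
                new = max(W[c, i], W[c, j])
            elif linkage == "single":
                new = min(W[c, i], W[c, j])
            elif linkage == "centroid":
                new = (ni * W[c, i] + nj * W[c, j]) / (ni + nj) - ni * nj * dij / (ni + nj) ** 2
            else:
                raise ValueError(f"unknown linkage {linkage!r}")
            W[c, i] = W[i, c] = new
        members[i] = members[i] + members[j]
        sizes[i] = ni + nj
        del members[j], sizes[j]
        active.remove(j)
        W[j, :] = np.inf
        W[:, j] = np.inf
    labels = np.empty(n, dtype=int)
    for lab, root in enumerate(sorted(active)):
        labels[members[root]] = lab
    return labels


def _diana_labels(D: np.ndarray, k: int) -> np.ndarray:
    """Divisive hierarchical clustering (splinter-group heuristic)."""
    n = D.shape[0]
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        ci = int(np.argmax(diams))
        if diams[ci] == 0:
            break
        cluster = clusters.pop(ci)
        sub = D[np.ix_(cluster, cluster)]
        avg = sub.sum(axis=1) / (len(cluster) - 1)
        splinter = [int(np.argmax(avg))]
        rest = [i for i in range(len(cluster)) if i not in splinter]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            best_gain, best_i = 0.0, None
            for i in rest:
                d_rest = sub[i, [r for r in rest if r != i]].mean()
                d_spl = sub[i, splinter].mean()
                gain = d_rest - d_spl
                if gain > best_gain:
                    best_gain, best_i = gain, i
            if best_i is not None:
                splinter.append(best_i)
                rest.remove(best_i)
                moved = True
        clusters.append([cluster[i] for i in splinter])
        clusters.append([cluster[i] for i in rest])
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(clusters):
        labels[c] = lab
    return labels


# ---------------------------------------------------------------------------
# PAM / CLARA / fuzzy c-means / k-means helpers
# ---------------------------------------------------------------------------


def _pam_labels(D: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Classic PAM: greedy BUILD then SWAP on a distance matrix."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(cur - D[:, c], 0).sum() if c not in medoids else -np.inf for c in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        cost = D[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = D[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(base, D[:, h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, np.array(medoids)


def _clara_labels(
    X: np.ndarray, k: int, metric: str, rng: np.random.Generator,
    n_subsamples: int = 5,
) -> np.ndarray:
    """CLARA: PAM on subsamples, best medoid set kept by full-data cost."""
    n = X.shape[0]
    size = min(n, max(40 + 2 * k, n // 5))
    best_cost, best_medoids = np.inf, None
    mfun = "cityblock" if metric == "manhattan" else metric
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        Dsub = cdist(X[idx], X[idx], metric=mfun)
        _, med_local = _pam_labels(Dsub, k)
        medoids = idx[med_local]
        dist_all = cdist(X, X[medoids], metric=mfun)
        cost = dist_all.min(axis=1).sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    dist_all = cdist(X, X[best_medoids], metric=mfun)
    return np.argmin(dist_all, axis=1)


def _kmeans_labels(
    X: np.ndarray, k: int, rng: np.random.Generator, init: np.ndarray | None = None,
    max_iter: int = 300,
) -> np.ndarray:
    """Lloyd's algorithm (Euclidean); ``init`` gives starting centers."""
    n = X.shape[0]
    if init is None:
        centers = X[rng.choice(n, size=k, replace=False)].copy()
    else:
        centers = np.asarray(init, dtype=float).copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = cdist(X, centers)
        new_labels = np.argmin(d, axis=1)
        for c in range(k):
            if not (new_labels == c).any():  # re-seed an empty cluster
                far = int(np.argmax(d.min(axis=1)))
                centers[c] = X[far]
                new_labels[far] = c
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    return labels


def _kmedians_labels(
    X: np.ndarray, k: int, rng: np.random.Generator, init: np.ndarray | None = None,
    max_iter: int = 300,
) -> np.ndarray:
    """k-medians with Manhattan assignment (exact L1 alternative)."""
    n = X.shape[0]
    centers = (X[rng.choice(n, size=k, replace=False)] if init is None else np.asarray(init)).copy()
    labels = np.zeros(n, dtype=int)
    for it in range(max_iter):
        d = cdist(X, centers, metric="cityblock")
        new_labels = np.argmin(d, axis=1)
        for c in range(k):
            if not (new_labels == c).any():
                far = int(np.argmax(d.min(axis=1)))
                centers[c] = X[far]
                new_labels[far] = c
        if (new_labels == labels).all() and it > 0:
            break
        labels = new_labels
        for c in range(k):
            centers[c] = np.median(X[labels == c], axis=0)
    return labels


def _fuzzy_cmeans_labels(
    X: np.ndarray, k: int, rng: np.random.Generator, m: float = 2.0,
    max_iter: int = 300, tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy c-means (fanny-style), memberships hardened by argmax."""
    n = X.shape[0]
    U = rng.dirichlet(np.ones(k), size=n)
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d = np.maximum(cdist(X, centers), 1e-12)
        inv = d ** (-2.0 / (m - 1))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    return np.argmax(U, axis=1)


# ---------------------------------------------------------------------------
# internal validation
# ---------------------------------------------------------------------------


def internal_validation(labels: np.ndarray, D: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(average silhouette, Dunn index, per-sample silhouettes) from a
    distance matrix.  Singleton clusters receive silhouette 0; a zero
    maximum intra-cluster diameter maps the Dunn index to a large sentinel.
    """
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    n = len(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            sil[i] = 0.0
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    min_between = np.inf
    max_diam = 0.0
    for c in uniq:
        mask = labels == c
        if mask.sum() > 1:
            max_diam = max(max_diam, D[np.ix_(mask, mask)].max())
    for c1, c2 in combinations(uniq, 2):
        min_between = min(min_between, D[np.ix_(labels == c1, labels == c2)].min())
    dunn = min_between / max_diam if max_diam > 0 else DUNN_SENTINEL
    return float(sil.mean()), float(min(dunn, DUNN_SENTINEL)), sil


# ---------------------------------------------------------------------------
# best-k estimation
# ---------------------------------------------------------------------------

DEFAULT_INDICES = ("silhouette", "calinski_harabasz", "dunn", "davies_bouldin", "hartigan")


@dataclass
class BestKReport:
    k_range: tuple[int, ...]
    votes: dict[str, int]
    best_k: int
    tie_break: str = "smallest k"


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return total


def estimate_best_k(
    X: np.ndarray,
    k_range=range(2, 11),
    indices=DEFAULT_INDICES,
    seed: int = 12345,
) -> BestKReport:
    """Majority vote over internal-validity indices, each scored on
    agglomerative (average linkage, Euclidean) reference clusterings."""
    from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate k")
    D = distance_matrix(X, "euclidean")
    if D.max() == 0:
        raise ValueError("degenerate geometry: all rows identical")
    labelings = {k: agglomerative_labels(D, k, "average") for k in ks}
    wss = {k: _within_ss(X, labelings[k]) for k in ks}
    wss[ks[-1] + 1] = _within_ss(X, agglomerative_labels(D, ks[-1] + 1, "average"))

    votes: dict[str, int] = {}
    for index in indices:
        if index == "silhouette":
            scores = {k: internal_validation(labelings[k], D)[0] for k in ks}
            votes[index] = max(ks, key=lambda k: scores[k])
        elif index == "dunn":
            scores = {k: internal_validation(labelings[k], D)[1] for k in ks}
            votes[index] = max(ks, key=lambda k: scores[k])
        elif index == "calinski_harabasz":
            scores = {k: calinski_harabasz_score(X, labelings[k]) for k in ks}
            votes[index] = max(ks, key=lambda k: scores[k])
        elif index == "davies_bouldin":
            scores = {k: davies_bouldin_score(X, labelings[k]) for k in ks}
            votes[index] = min(ks, key=lambda k: scores[k])
        elif index == "hartigan":
            # H(k) = (W_k / W_{k+1} - 1) (n - k - 1); smallest k with H <= 10
            hvals = {
                k: (wss[k] / wss[k + 1] - 1) * (n - k - 1) if wss[k + 1] > 0 else 0.0
                for k in ks
            }
            ok = [k for k in ks if hvals[k] <= 10]
            votes[index] = min(ok) if ok else min(ks, key=lambda k: hvals[k])
        else:
            raise ValueError(f"unknown index {index!r}")
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    best = min(k for k, c in counts.items() if c == top)
    return BestKReport(tuple(ks), votes, best)


# ---------------------------------------------------------------------------
# portfolio
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    algorithm: str
    metric: str
    k: int
    labels: np.ndarray = field(repr=False)
    silhouette_avg: float
    dunn: float
    linkage: str | None = None
    seed: int = 12345

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels)
        if len(uniq) != self.k:
            raise ValueError(f"{len(uniq)} non-empty clusters, expected k={self.k}")

    @property
    def name(self) -> str:
        link = f"/{self.linkage}" if self.linkage else ""
        return f"{self.algorithm}{link}/{self.metric}"


def _fit_one(
    X: np.ndarray,
    D: np.ndarray,
    algorithm: str,
    metric: str,
    k: int,
    rng: np.random.Generator,
    linkage: str,
    exact_kmedians: bool,
) -> tuple[np.ndarray, str | None]:
    if algorithm == "kmeans":
        return _kmeans_labels(X, k, rng), None
    if algorithm == "hierarchical_kmeans":
        tree_labels = agglomerative_labels(D, k, linkage)
        centers = np.stack([X[tree_labels == c].mean(axis=0) for c in range(k)])
        if metric == "manhattan" and exact_kmedians:
            return _kmedians_labels(X, k, rng, init=centers), linkage
        return _kmeans_labels(X, k, rng, init=centers), linkage
    if algorithm == "pam":
        return _pam_labels(D, k)[0], None
    if algorithm == "clara":
        return _clara_labels(X, k, metric, rng), None
    if algorithm == "agnes":
        return agglomerative_labels(D, k, "average"), "average"
    if algorithm == "hclust":
        return agglomerative_labels(D, k, "complete"), "complete"
    if algorithm == "diana":
        return _diana_labels(D, k), None
    if algorithm == "fuzzy":
        return _fuzzy_cmeans_labels(X, k, rng), None
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_portfolio(
    X: np.ndarray,
    k: int,
    algorithms=ALGORITHMS,
    metrics=METRICS,
    seed: int = 12345,
    linkage: str = "centroid",
    exact_kmedians: bool = False,
) -> list[ClusterModel]:
    """Fit every supported algorithm/metric pair at the given k; unsupported
    pairs are skipped with a log entry, models that collapse to fewer than
    k clusters are re-seeded once then reported as failed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    models: list[ClusterModel] = []
    for metric in metrics:
        D = distance_matrix(X, metric)
        for algorithm in algorithms:
            if (algorithm, metric) in _UNSUPPORTED:
                logger.info("skipping unsupported pair %s/%s", algorithm, metric)
                continue
            labels = link = None
            for attempt in range(2):
                rng = np.random.default_rng(seed + attempt)
                cand, link = _fit_one(X, D, algorithm, metric, k, rng, linkage, exact_kmedians)
                cand = _relabel(cand)
                if len(np.unique(cand)) == k:
                    labels = cand
                    break
            if labels is None:
                logger.warning("model %s/%s failed: empty cluster", algorithm, metric)
                continue
            sil, dunn, _ = internal_validation(labels, D)
            models.append(
                ClusterModel(algorithm, metric, k, labels, sil, dunn, linkage=link, seed=seed)
            )
    return models


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map labels to contiguous integers, ordered by first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def select_best_model(models: list[ClusterModel]) -> ClusterModel:
    """Maximum average silhouette; ties broken by larger Dunn, then
    lexicographic model name (deterministic)."""
    if not models:
        raise ValueError("no successful models")
    return max(models, key=lambda m: (m.silhouette_avg, m.dunn, [-ord(c) for c in m.name]))


# ---------------------------------------------------------------------------
# clinical comparison
# ---------------------------------------------------------------------------


@dataclass
class ClinicalComparison:
    wilcoxon: dict[str, dict]
    fisher: dict[str, dict]
    cluster_summaries: dict


def _fisher_2xr_exact_or_mc(
    table: np.ndarray, seed: int = 12345, max_tables: int = 200_000, n_mc: int = 100_000
) -> tuple[float, str]:
    """Two-sided Fisher test for a 2 x R table: exact enumeration over all
    tables with the observed margins when feasible, else seeded Monte Carlo
    with >= 1e5 draws."""
    table = np.asarray(table, dtype=int)
    row1 = int(table[0].sum())
    cols = table.sum(axis=0)
    n = int(table.sum())

    def log_prob(r: np.ndarray) -> float:
        lp = -math.lgamma(n + 1) + math.lgamma(row1 + 1) + math.lgamma(n - row1 + 1)
        for rj, cj in zip(r, cols):
            lp += (
                math.lgamma(cj + 1)
                - math.lgamma(rj + 1)
                - math.lgamma(cj - rj + 1)
            )
        return lp

    lp_obs = log_prob(table[0])
    # count tables by DP over columns
    counts = {0: 1}
    for cj in cols:
        new: dict[int, int] = {}
        for s, c in counts.items():
            for rj in range(0, min(cj, row1 - s) + 1):
                new[s + rj] = new.get(s + rj, 0) + c
        counts = new
    n_tables = counts.get(row1, 0)
    if n_tables <= max_tables:
        total = 0.0

        def recurse(j: int, remaining: int, partial: list[int]):
            nonlocal total
            if j == len(cols) - 1:
                if remaining <= cols[j]:
                    r = np.array(partial + [remaining])
                    lp = log_prob(r)
                    if lp <= lp_obs + 1e-7:
                        total += math.exp(lp)
                return
            hi = min(cols[j], remaining)
            for rj in range(0, hi + 1):
                recurse(j + 1, remaining - rj, partial + [rj])

        recurse(0, row1, [])
        return min(total, 1.0), "exact"
    # Monte Carlo: permute group membership, recompute first-row vector
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_mc):
        pick = rng.choice(pool, size=row1, replace=False)
        r = np.bincount(pick, minlength=len(cols))
        if log_prob(r) <= lp_obs + 1e-7:
            hits += 1
    return (hits + 1) / (n_mc + 1), "monte_carlo"


def compare_clinical(meta, labels, seed: int = 12345) -> ClinicalComparison:
    """Wilcoxon rank-sum on age at death and Fisher exact tests on sex
    (2x2) and Braak stage (2xR) between two clusters."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("compare_clinical requires exactly 2 clusters")
    df = meta.table
    wilcoxon: dict[str, dict] = {}
    fisher: dict[str, dict] = {}
    summaries: dict = {}

    if "age_death" in df.columns and df["age_death"].notna().sum() >= 6:
        x = df.loc[labels == uniq[0], "age_death"].dropna().to_numpy(float)
        y = df.loc[labels == uniq[1], "age_death"].dropna().to_numpy(float)
        if len(x) >= 3 and len(y) >= 3:
            has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if (len(x) + len(y) <= 50 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            wilcoxon["age_death"] = {"W": float(res.statistic), "p": float(res.pvalue),
                                     "method": method}
            summaries["age_death"] = {str(uniq[0]): float(np.median(x)),
                                      str(uniq[1]): float(np.median(y))}
    else:
        logger.info("age_death unavailable; Wilcoxon test skipped")

    if "sex" in df.columns and df["sex"].notna().sum() >= 6:
        tab = np.array(
            [
                [(df["sex"][labels == c] == s).sum() for s in ("M", "F")]
                for c in uniq
            ]
        )
        if tab.sum(axis=1).min() >= 3:
            _, p = stats.fisher_exact(tab, alternative="two-sided")
            fisher["sex"] = {"table": tab.tolist(), "p": float(p), "method": "exact"}

    if "braak" in df.columns and df["braak"].notna().sum() >= 6:
        stages = np.sort(df["braak"].dropna().unique())
        tab = np.array(
            [[(df["braak"][labels == c] == s).sum() for s in stages] for c in uniq]
        )
        tab = tab[:, tab.sum(axis=0) > 0]
        if tab.shape[1] >= 2 and tab.sum(axis=1).min() >= 3:
            p, method = _fisher_2xr_exact_or_mc(tab, seed=seed)
            fisher["braak"] = {"table": tab.tolist(), "p": float(p), "method": method}

    return ClinicalComparison(wilcoxon, fisher, summaries)
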