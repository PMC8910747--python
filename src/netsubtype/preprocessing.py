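"""Count preprocessing: integration by gene, demographic outlier screening
(Grubbs), low-count filtering, NB-regression quantile-mapping batch
adjustment, and log2-CPM transformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from netsubtype.matrix import CountMatrix, ExprMatrix

logger = logging.getLogger(__name__)


def integrate_by_gene(matrices: list[CountMatrix]) -> CountMatrix:
    """Concatenate cohorts column-wise on the intersection of their genes.

    Gene order follows the first input; sample ids must be globally unique.
    """
    if not matrices:
        raise ValueError("need at least one count matrix")
    if len(matrices) == 1:
        return matrices[0]
    all_samples = np.concatenate([m.sample_ids for m in matrices])
    if len(np.unique(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across input matrices")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("empty gene intersection")
    genes = np.array([g for g in matrices[0].gene_ids if g in common], dtype=object)
    blocks = []
    for m in matrices:
        index = {g: i for i, g in enumerate(m.gene_ids)}
        rows = np.array([index[g] for g in genes])
        blocks.append(m.counts[rows])
    return CountMatrix(genes, all_samples, np.hstack(blocks))


@dataclass
class GrubbsResult:
    G: float
    G_crit: float
    outlier_index: int | None
    alpha: float
    n: int
    zero_variance: bool = False

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Single-pass two-sided Grubbs test for one outlier.

    G = max_i |x_i - mean| / sd (n-1 denominator); the critical value is
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper alpha/(2n)
    quantile of Student's t on n-2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: no outlier detectable")
        return GrubbsResult(0.0, np.inf, None, alpha, n, zero_variance=True)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    G_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))
    return GrubbsResult(G, G_crit, i if G > G_crit else None, alpha, n)


def grubbs_screen(values, alpha: float = 0.05, iterative: bool = False) -> list[int]:
    """Indices of detected outliers; single pass by default, optionally
    repeated until no further outlier is found."""
    x = np.asarray(values, dtype=float)
    active = list(range(len(x)))
    out: list[int] = []
    while len(active) >= 3:
        res = grubbs_test(x[active], alpha=alpha)
        if not res.is_outlier:
            break
        out.append(active.pop(res.outlier_index))
        if not iterative:
            break
    return out


def filter_low_counts(cm: CountMatrix, percentile: float = 15.0) -> CountMatrix:
    """Drop genes whose total count falls strictly below the given
    percentile (linear-interpolation / type-7 convention) of per-gene totals."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    totals = cm.counts.sum(axis=1)
    threshold = np.percentile(totals, percentile)  # numpy default = linear (type 7)
    keep = totals >= threshold
    if not keep.any():
        raise ValueError("low-count filter removed all genes")
    logger.info("low-count filter: threshold %.3f, removed %d/%d genes",
                threshold, int((~keep).sum()), cm.n_genes)
    return cm.subset_genes(keep)


# ---------------------------------------------------------------------------
# NB quantile-mapping batch adjustment
# ---------------------------------------------------------------------------

_PHI_FLOOR = 1e-8
_POISSON_PHI = 1e-6


def _nb_cdf(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB CDF at y for mean mu, dispersion phi (var = mu + phi mu^2),
    falling back to Poisson for near-zero dispersion."""
    out = np.empty(np.broadcast(y, mu, phi).shape)
    y, mu, phi = np.broadcast_arrays(y, mu, phi)
    pois = phi < _POISSON_PHI
    if pois.any():
        out[pois] = stats.poisson.cdf(y[pois], np.maximum(mu[pois], 1e-12))
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + np.maximum(mu[nb], 1e-12))
        out[nb] = stats.nbinom.cdf(y[nb], r, p)
    return out


def _nb_ppf(u: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.empty(np.broadcast(u, mu, phi).shape)
    u, mu, phi = np.broadcast_arrays(u, mu, phi)
    pois = phi < _POISSON_PHI
    if pois.any():
        out[pois] = stats.poisson.ppf(u[pois], np.maximum(mu[pois], 1e-12))
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + np.maximum(mu[nb], 1e-12))
        out[nb] = stats.nbinom.ppf(u[nb], r, p)
    return out


def _fit_offset_model(
    counts: np.ndarray,
    libsize: np.ndarray,
    batch_codes: np.ndarray,
    group_codes: np.ndarray | None,
    n_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Moment/IPF fit of mu_gs = l_s * exp(a_g + beta_{g,batch} + gamma_{g,group}).

    Returns (a, beta, gamma); beta is library-size-weighted to mean zero so
    removing it preserves overall abundance.  All arrays are per gene.
    """
    G, S = counts.shape
    n_batch = batch_codes.max() + 1
    n_group = group_codes.max() + 1 if group_codes is not None else 0
    a = np.log(np.maximum(counts.sum(axis=1), 0.5) / libsize.sum())
    beta = np.zeros((G, n_batch))
    gamma = np.zeros((G, n_group)) if group_codes is not None else None
    l = libsize[None, :]
    y_batch = np.stack([counts[:, batch_codes == b].sum(axis=1) for b in range(n_batch)], axis=1)
    if group_codes is not None:
        y_group = np.stack(
            [counts[:, group_codes == g].sum(axis=1) for g in range(n_group)], axis=1
        )
    for _ in range(n_iter):
        eta = a[:, None] + beta[:, batch_codes]
        if gamma is not None:
            eta = eta + gamma[:, group_codes]
        mu = l * np.exp(np.clip(eta, -50, 50))
        # batch step
        for b in range(n_batch):
            denom = mu[:, batch_codes == b].sum(axis=1)
            beta[:, b] += np.log(np.maximum(y_batch[:, b], 0.5) / np.maximum(denom, 1e-12))
        beta = np.clip(beta, -10, 10)
        # center beta (library-size weighted) and fold the shift into a
        w = np.array([libsize[batch_codes == b].sum() for b in range(n_batch)])
        shift = (beta * w[None, :]).sum(axis=1) / w.sum()
        beta -= shift[:, None]
        a += shift
        if gamma is not None:
            eta = a[:, None] + beta[:, batch_codes] + gamma[:, group_codes]
            mu = l * np.exp(np.clip(eta, -50, 50))
            for g in range(n_group):
                denom = mu[:, group_codes == g].sum(axis=1)
                gamma[:, g] += np.log(np.maximum(y_group[:, g], 0.5) / np.maximum(denom, 1e-12))
            gamma = np.clip(gamma, -10, 10)
            # identifiability: absorb the first group level into the intercept
            a += gamma[:, 0]
            gamma -= gamma[:, [0]]
    return a, beta, gamma


def _moment_dispersion(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion phi = sum((y-mu)^2 - mu) / sum(mu^2),
    floored at 1e-8, computed per gene across the given samples."""
    num = ((counts - mu) ** 2 - mu).sum(axis=1)
    den = np.maximum((mu**2).sum(axis=1), 1e-12)
    return np.maximum(num / den, _PHI_FLOOR)


def batch_adjust(
    cm: CountMatrix,
    batch,
    group=None,
) -> CountMatrix:
    """Remove multiplicative batch effects by NB quantile mapping.

    Per gene, an NB model with library-size offset, batch effect and an
    optional group covariate is fitted by iterative moment matching; each
    count is then carried from its batch-specific NB distribution to the
    batch-free (group-preserving) target via its CDF midpoint quantile.
    Single-batch input is returned unchanged; a batch/group 1:1 confound is
    refused.
    """
    batch = np.asarray(batch)
    if len(batch) != cm.n_samples:
        raise ValueError("batch labels must match samples")
    levels, batch_codes = np.unique(batch, return_inverse=True)
    if len(levels) == 1:
        return cm
    counts_per_batch = np.bincount(batch_codes)
    if (counts_per_batch < 2).any():
        raise ValueError("every batch needs at least 2 samples")
    group_codes = None
    if group is not None:
        group = np.asarray(group)
        glevels, group_codes = np.unique(group, return_inverse=True)
        if len(glevels) == 1:
            group_codes = None
        else:
            # refuse a 1:1 confound: batch determines group and vice versa
            pairs = {(b, g) for b, g in zip(batch_codes, group_codes)}
            b_pure = len({b for b, _ in pairs}) == len(pairs)
            g_pure = len({g for _, g in pairs}) == len(pairs)
            if b_pure and g_pure:
                raise ValueError("batch is confounded 1:1 with group; cannot adjust")

    counts = cm.counts.astype(float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    nonzero = counts.sum(axis=1) > 0
    adjusted = counts.copy()

    y = counts[nonzero]
    a, beta, gamma = _fit_offset_model(y, libsize, batch_codes, group_codes)
    eta_batch = a[:, None] + beta[:, batch_codes]
    eta_free = np.tile(a[:, None], (1, cm.n_samples))
    if gamma is not None:
        eta_batch = eta_batch + gamma[:, group_codes]
        eta_free = eta_free + gamma[:, group_codes]
    mu_batch = libsize[None, :] * np.exp(np.clip(eta_batch, -50, 50))
    mu_free = libsize[None, :] * np.exp(np.clip(eta_free, -50, 50))

    # per-(gene, batch) dispersion for the source; pooled residual dispersion
    # for the batch-free target
    phi_batch = np.empty_like(mu_batch)
    for b in range(len(levels)):
        cols = batch_codes == b
        phi_b = _moment_dispersion(y[:, cols], mu_batch[:, cols])
        phi_batch[:, cols] = phi_b[:, None]
        logger.info("batch %r: median mu scale %.3f, median dispersion %.4g",
                    levels[b], float(np.median(np.exp(beta[:, b]))), float(np.median(phi_b)))
    phi_free = _moment_dispersion(y, mu_batch)[:, None]

    upper = _nb_cdf(y, mu_batch, phi_batch)
    lower = _nb_cdf(y - 1.0, mu_batch, phi_batch)
    u = np.clip(0.5 * (upper + lower), 1e-12, 1 - 1e-12)
    mapped = _nb_ppf(u, mu_free, np.broadcast_to(phi_free, mu_free.shape))
    adjusted[nonzero] = np.maximum(np.rint(mapped), 0)
    return CountMatrix(cm.gene_ids, cm.sample_ids, adjusted.astype(np.int64))


def log2_cpm(cm: CountMatrix, prior: float = 0.5) -> ExprMatrix:
    """log2 counts-per-million with a pseudocount:
    log2((count + prior) / (libsize + 2*prior) * 1e6)."""
    libsize = cm.counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    values = np.log2((cm.counts + prior) / (libsize + 2 * prior)[None, :] * 1e6)
    return ExprMatrix(cm.gene_ids, cm.sample_ids, values)
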