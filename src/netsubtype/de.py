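"""Moderated-t differential expression on log2-CPM.

Per-gene ordinary least squares is followed by empirical-Bayes moderation
of the residual variances: (d0, s0^2) are estimated by matching the moments
of log s_g^2 to a scaled-F prior (digamma/trigamma inversion), posterior
variances are the df-weighted blend, and the moderated t is referenced to
d0 + d_g degrees of freedom.  DEGs are called at BH-adjusted p <= alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from netsubtype.matrix import ExprMatrix
from netsubtype.stats_util import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    gene_ids: np.ndarray
    coef: np.ndarray          # per-gene contrast coefficient (log2 fold change)
    sigma2: np.ndarray        # residual variances
    df_residual: int
    v_unscaled: float         # (X'X)^-1 diagonal entry for the contrast column


@dataclass
class DEResult:
    contrast: str
    table: pd.DataFrame = field(repr=False)
    d0: float = np.inf
    s02: float = 0.0
    alpha: float = 0.01

    @property
    def degs(self) -> set[str]:
        return set(self.table.loc[self.table["deg"], "gene"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"logFC": "logFC", "t": "t", "p": "P.Value", "q": "adj.P.Val", "B": "B"}
        )
        out[["gene", "logFC", "t", "P.Value", "adj.P.Val", "B", "deg"]].to_csv(
            path, sep="\t", index=False
        )


def design_two_group(group_indicator: np.ndarray) -> np.ndarray:
    """Intercept + group-indicator design matrix."""
    g = np.asarray(group_indicator, dtype=float)
    return np.column_stack([np.ones(len(g)), g])


def fit_linear_model(
    E: ExprMatrix, design: np.ndarray, contrast_col: int = -1
) -> LinearFit:
    """Per-gene OLS against a shared design; extracts the contrast column
    coefficient and residual variance."""
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n != E.n_samples:
        raise ValueError("design rows must match samples")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("more covariates than samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    Y = E.values  # genes x samples
    beta = Y @ pinv.T  # genes x p
    resid = Y - beta @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    j = contrast_col % p
    return LinearFit(E.gene_ids, beta[:, j], sigma2, df, float(xtx_inv[j, j]))


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the inverse)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment estimation of the scaled-F prior (d0, s0^2) for residual
    variances, following the standard log-variance moment equations.
    Returns d0 = inf (pooled variance) when the between-gene spread does
    not exceed the chi-square sampling spread."""
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        if not (np.isfinite(d0) and np.isfinite(s02) and d0 > 0 and s02 > 0):
            warnings.warn("prior estimation failed; using pooled variance (d0 = inf)")
            return np.inf, float(np.exp(emean))
        return float(d0), s02
    return np.inf, float(np.exp(emean))


def _tmixture_v0(
    tstat: np.ndarray, v_unscaled: float, df_total: float, proportion: float
) -> float:
    """Estimate the prior variance of the contrast coefficient from the
    top |t| quantiles (used only for the log-odds B column)."""
    ngenes = len(tstat)
    ntarget = int(np.ceil(proportion / 2 * ngenes))
    if ntarget < 1:
        return 0.0
    p = max(ntarget / ngenes, proportion)
    t_abs = np.sort(np.abs(tstat))[::-1][:ntarget]
    ranks = np.arange(1, ntarget + 1)
    p0 = 2 * stats.t.sf(t_abs, df_total)
    ptarget = ((ranks - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2, df_total)
        v0[pos] = v_unscaled * (t_abs[pos] ** 2 / np.maximum(qtarget**2, 1e-12) - 1.0)
    return float(np.maximum(v0, 0.0).mean())


def ebayes(
    fit: LinearFit, contrast: str = "contrast", alpha: float = 0.01,
    proportion: float = 0.01,
) -> DEResult:
    """Empirical-Bayes moderated t-test for the fitted contrast."""
    d0, s02 = estimate_prior(fit.sigma2, fit.df_residual)
    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * fit.sigma2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * fit.v_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.coef / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
        df_for_b = 1e6
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
        df_for_b = df_total
    q = bh_adjust(p)

    v0 = _tmixture_v0(t, fit.v_unscaled, df_for_b, proportion)
    r = (fit.v_unscaled + v0) / fit.v_unscaled
    t2 = t**2
    if np.isinf(df_total):
        kernel = t2 * (1 - 1 / r) / 2
    else:
        kernel = (1 + df_total) / 2 * np.log((t2 + df_total) / (t2 / r + df_total))
    B = np.log(proportion / (1 - proportion)) - np.log(r) / 2 + kernel

    table = pd.DataFrame(
        {
            "gene": fit.gene_ids,
            "logFC": fit.coef,
            "s2": fit.sigma2,
            "t": t,
            "p": p,
            "q": q,
            "B": B,
            "deg": q <= alpha,
        }
    )
    return DEResult(contrast, table, d0=d0, s02=s02, alpha=alpha)


def run_contrast(
    E: ExprMatrix, group_indicator: np.ndarray, contrast: str, alpha: float = 0.01,
    covariates: np.ndarray | None = None,
) -> DEResult:
    """Convenience wrapper: two-group design (optionally with extra
    covariate columns), OLS, moderation, BH adjustment."""
    design = design_two_group(group_indicator)
    contrast_col = 1
    if covariates is not None:
        design = np.column_stack([design, np.asarray(covariates, dtype=float)])
    fit = fit_linear_model(E, design, contrast_col=contrast_col)
    return ebayes(fit, contrast=contrast, alpha=alpha)


def call_degs(result: DEResult, alpha: float | None = None) -> set[str]:
    """Genes with BH-adjusted p <= alpha."""
    a = result.alpha if alpha is None else alpha
    return set(result.table.loc[result.table["q"] <= a, "gene"])


def venn_partition(set_a, set_b) -> tuple[set, set, set]:
    """(unique to A, unique to B, common)."""
    a, b = set(set_a), set(set_b)
    return a - b, b - a, a & b
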