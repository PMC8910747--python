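"""Regulator ranking: TF identification among DEGs, phenotypic impact
factors (PIF), regulatory impact factors (RIF1 / RIF2), and top-regulator
selection for drug repurposing.

With e1_j / e2_j the mean expression of DE gene j in each group and r1_ij /
r2_ij the within-group Pearson correlation of TF i with DE gene j:

    PIF_j  = ((e1_j + e2_j) / 2) * (e1_j - e2_j)
    RIF1_i = (1/n_de) * sum_j PIF_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_de) * sum_j [ (e1_j * r1_ij)^2 - (e2_j * r2_ij)^2 ]

Both RIF columns are z-standardized across TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netsubtype.matrix import ExprMatrix
from netsubtype.stats_util import zscore

logger = logging.getLogger(__name__)


def identify_tfs(genes, tf_list) -> set[str]:
    """Genes that appear in the TF list, case-normalized on symbols;
    original-case ids from ``genes`` are returned."""
    if not tf_list:
        raise ValueError("empty TF list")
    wanted = {str(t).upper() for t in tf_list}
    return {g for g in genes if str(g).upper() in wanted}


@dataclass
class RegulatorTable:
    """Per-TF RIF scores and per-gene PIF values."""

    rif: pd.DataFrame = field(repr=False)  # tf, rif1, rif2, rif1_z, rif2_z
    pif: pd.Series = field(repr=False)     # indexed by DE gene

    def rif1_z(self) -> pd.Series:
        return self.rif.set_index("tf")["rif1_z"]

    def rif2_z(self) -> pd.Series:
        return self.rif.set_index("tf")["rif2_z"]


def _group_corr(E: ExprMatrix, tfs: list[str], de_genes: list[str]) -> np.ndarray:
    """TF x DE-gene Pearson correlation within one group; zero-variance
    TFs or genes give correlation 0 with a warning."""
    T = E.restrict(tfs).values
    D = E.restrict(de_genes).values
    ts = T.std(axis=1)
    ds = D.std(axis=1)
    if (ts == 0).any():
        logger.warning("%d zero-variance TFs: correlations set to 0", int((ts == 0).sum()))
    Tc = T - T.mean(axis=1, keepdims=True)
    Dc = D - D.mean(axis=1, keepdims=True)
    denom = np.outer(np.where(ts == 0, np.inf, ts), np.where(ds == 0, np.inf, ds))
    r = (Tc @ Dc.T) / (T.shape[1] * denom)
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


def rif_scores(
    E1: ExprMatrix, E2: ExprMatrix, tfs, de_genes
) -> RegulatorTable:
    """PIF-weighted RIF1 and RIF2 scores for each TF (see module docstring)."""
    tfs = sorted(set(tfs))
    de_genes = sorted(set(de_genes))
    if not tfs or not de_genes:
        raise ValueError("tfs and de_genes must be nonempty")
    if E1.n_samples < 4 or E2.n_samples < 4:
        raise ValueError("both groups need >= 4 samples")
    e1 = E1.restrict(de_genes).values.mean(axis=1)
    e2 = E2.restrict(de_genes).values.mean(axis=1)
    pif = ((e1 + e2) / 2.0) * (e1 - e2)
    r1 = _group_corr(E1, tfs, de_genes)
    r2 = _group_corr(E2, tfs, de_genes)
    n_de = len(de_genes)
    rif1 = (pif[None, :] * (r1 - r2) ** 2).sum(axis=1) / n_de
    rif2 = (((e1[None, :] * r1) ** 2) - ((e2[None, :] * r2) ** 2)).sum(axis=1) / n_de
    table = pd.DataFrame(
        {
            "tf": tfs,
            "rif1": rif1,
            "rif2": rif2,
            "rif1_z": zscore(rif1),
            "rif2_z": zscore(rif2),
        }
    )
    return RegulatorTable(table, pd.Series(pif, index=de_genes, name="pif"))


def top_regulators(
    authority: pd.Series,
    delta_b: pd.Series,
    rif: RegulatorTable,
    k: int = 5,
) -> set[str]:
    """Union of the top-k genes by authority, |RIF1 z|, |RIF2 z| and
    |delta standardized betweenness|; ties resolved by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def top(series: pd.Series, absolute: bool) -> list[str]:
        s = series.abs() if absolute else series
        ranked = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
        return [g for g, _ in ranked[:k]]

    selected: set[str] = set()
    selected.update(top(authority, absolute=False))
    selected.update(top(delta_b, absolute=True))
    selected.update(top(rif.rif1_z(), absolute=True))
    selected.update(top(rif.rif2_z(), absolute=True))
    return selected
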