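"""Core data containers: gene x sample count matrices, expression matrices,
and per-sample metadata tables, with plain-text round-trip I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample", "diagnosis", "batch", "age_death", "sex", "braak"]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with ordered, unique identifiers."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Subset by boolean mask or index array over genes."""
        keep = np.asarray(keep)
        return CountMatrix(self.gene_ids[keep], self.sample_ids, self.counts[keep])

    def subset_samples(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(self.gene_ids, self.sample_ids[keep], self.counts[:, keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy())

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)


@dataclass
class ExprMatrix:
    """Real-valued gene x sample expression matrix (log2-CPM scale)."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExprMatrix":
        keep = np.asarray(keep)
        return ExprMatrix(self.gene_ids[keep], self.sample_ids, self.values[keep])

    def subset_samples(self, keep: np.ndarray) -> "ExprMatrix":
        keep = np.asarray(keep)
        return ExprMatrix(self.gene_ids, self.sample_ids[keep], self.values[:, keep])

    def restrict(self, genes) -> "ExprMatrix":
        """Restrict to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = np.array([index[g] for g in genes], dtype=int)
        return self.subset_genes(idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExprMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy())


@dataclass
class SampleTable:
    """Per-sample metadata aligned (by id) with a CountMatrix."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "sample" not in self.table.columns:
            raise ValueError("metadata requires a 'sample' column")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.table.get("diagnosis", pd.Series(dtype=object)).dropna()) - {"PD", "NC"}
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample"].to_numpy(object)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def aligned_to(self, sample_ids) -> "SampleTable":
        """Reorder/subset rows to match the given sample id order."""
        df = self.table.set_index("sample").loc[list(sample_ids)].reset_index()
        return SampleTable(df)

    def check_paired(self, cm: CountMatrix) -> None:
        if set(self.sample_ids) != set(cm.sample_ids):
            raise ValueError("metadata sample ids do not match count matrix")

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path))
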