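"""Over-representation analysis against local gene-set collections (GMT)
and disease-gene overlap summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from netsubtype.stats_util import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag, serializable to GMT."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = "custom"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path: str | Path, source: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    The description is field 2 verbatim; member fields follow.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            if not members:
                raise ValueError(f"empty gene set {name!r} at line {lineno}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=source)


def ora(
    query,
    collection: GeneSetCollection,
    universe,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation analysis.

    For each set, p = P(X >= k) where X ~ Hypergeom(N, K, n) with N the
    universe size, K the set size (after intersecting with the universe),
    n the query size and k the observed overlap.  BH adjustment is applied
    across all tested sets.  Query genes outside the universe are dropped
    with a warning; sets smaller than ``min_set_size`` (after intersection)
    are skipped.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside the universe dropped")
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection:
        members = members & universe
        K = len(members)
        if K < min_set_size:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p", "genes"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def gda_overlap(degs, disease_genes) -> float:
    """Fraction of DEGs present in a disease-gene list."""
    degs = set(degs)
    if not degs:
        raise ValueError("empty DEG set")
    return len(degs & set(disease_genes)) / len(degs)
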