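"""Synthetic cohort, gene-set and drug-table generators with known ground
truth.

Counts are negative binomial per gene: the mean for gene g in sample s is

    mu_gs = mu_g * 2**(lfc_g * I[s in affected group]) * b_{batch(s), g} * 2**(latent_gs)

where ``log2 b`` is Normal(0, batch_effect_sd) per (batch, gene) and
``latent_gs`` carries block-structured correlation: genes in a declared
correlation block share a per-sample standard-normal factor with the given
loading (plus independent noise completing unit variance), inducing
within-block co-expression on the log-mean scale.  Genes outside every
block receive no latent term, so their marginal count moments are exactly
negative binomial (var = mu + phi * mu**2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netsubtype.drugs import InteractionRecord
from netsubtype.enrichment import GeneSetCollection
from netsubtype.matrix import CountMatrix, SampleTable

GROUPS = ("PDC1", "PDC2", "NC")


@dataclass(frozen=True)
class CorrBlock:
    """A latent-factor correlation block: ``genes`` share one factor with
    the given loading, active only in ``group`` ('PDC1'/'PDC2'/'NC'/'all')."""

    genes: tuple[str, ...]
    group: str
    loading: float

    def __post_init__(self) -> None:
        if self.group not in (*GROUPS, "all"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= abs(self.loading) <= 1:
            raise ValueError("loading must be in [-1, 1]")


@dataclass
class SimulationConfig:
    n_genes: int = 600
    n_pd1: int = 40
    n_pd2: int = 50
    n_nc: int = 60
    n_batches: int = 2
    batch_effect_sd: float = 0.25
    n_de_subtype: int = 50
    n_de_disease: int = 50
    lfc_mean: float = 2.0
    lfc_sd: float = 0.25
    nb_mu_log_mean: float = 6.0
    nb_mu_log_sd: float = 1.5
    nb_dispersion: float | np.ndarray = 0.1
    corr_block_spec: list[CorrBlock] = field(default_factory=list)
    # SD (log2 scale) of the latent block contribution; large enough that NB
    # sampling noise does not dilute planted correlations below their target
    latent_scale: float = 2.0
    tf_fraction: float = 0.1
    age_mean: float = 75.0
    age_sd: float = 6.0
    age_shift: float = 5.0
    braak_shift: float = 1.0
    seed: int = 12345
    batch_dispersion_factors: np.ndarray | None = None  # stress flag: per-batch phi scaling

    def gene_ids(self) -> np.ndarray:
        width = max(4, len(str(self.n_genes)))
        return np.array([f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)], dtype=object)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in ("n_pd1", "n_pd2", "n_nc"):
            if getattr(self, name) < 2:
                raise ValueError(f"group size {name} must be >= 2")
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be non-negative")
        if not 0 < self.tf_fraction < 1:
            raise ValueError("tf_fraction must be in (0, 1)")
        if self.n_de_subtype + self.n_de_disease > self.n_genes:
            raise ValueError("DE blocks exceed gene count (blocks must be disjoint)")
        phi = np.asarray(self.nb_dispersion, dtype=float)
        if (phi <= 0).any():
            raise ValueError("nb_dispersion must be positive")
        known = set(self.gene_ids())
        for block in self.corr_block_spec:
            missing = set(block.genes) - known
            if missing:
                raise ValueError(f"corr block references unknown genes: {sorted(missing)[:5]}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated cohort."""

    subtype_labels: dict[str, str]
    de_genes_subtype: dict[str, float]
    de_genes_disease: dict[str, float]
    batch_assignment: dict[str, int]
    true_edges_per_group: dict[str, list[tuple[str, str, float]]]
    tf_ids: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels,
            "de_genes_subtype": self.de_genes_subtype,
            "de_genes_disease": self.de_genes_disease,
            "batch_assignment": self.batch_assignment,
            "true_edges_per_group": {
                g: [list(e) for e in edges] for g, edges in self.true_edges_per_group.items()
            },
            "tf_ids": sorted(self.tf_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            subtype_labels=d["subtype_labels"],
            de_genes_subtype=d["de_genes_subtype"],
            de_genes_disease=d["de_genes_disease"],
            batch_assignment={k: int(v) for k, v in d["batch_assignment"].items()},
            true_edges_per_group={
                g: [(a, b, float(w)) for a, b, w in edges]
                for g, edges in d["true_edges_per_group"].items()
            },
            tf_ids=set(d["tf_ids"]),
        )


def simulate_cohort(config: SimulationConfig) -> tuple[CountMatrix, SampleTable, SyntheticTruth]:
    """Simulate a cohort of NB counts with planted subtypes, batches and
    correlation blocks.  Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    G = config.n_genes

    groups = (
        ["PDC1"] * config.n_pd1 + ["PDC2"] * config.n_pd2 + ["NC"] * config.n_nc
    )
    n = len(groups)
    samples = np.array([f"S{i:04d}" for i in range(1, n + 1)], dtype=object)
    # round-robin within each group so batches are never confounded with group
    batch = np.empty(n, dtype=int)
    for grp in GROUPS:
        idx = [i for i, g in enumerate(groups) if g == grp]
        batch[idx] = np.arange(len(idx)) % config.n_batches

    # baseline abundance and dispersion
    mu0 = 2.0 ** rng.normal(config.nb_mu_log_mean, config.nb_mu_log_sd, size=G)
    phi = np.broadcast_to(np.asarray(config.nb_dispersion, dtype=float), (G,)).copy()

    # planted DE: subtype block first, then disjoint disease block
    sub_idx = np.arange(config.n_de_subtype)
    dis_idx = np.arange(config.n_de_subtype, config.n_de_subtype + config.n_de_disease)
    lfc_sub = rng.normal(config.lfc_mean, config.lfc_sd, size=len(sub_idx)) * rng.choice(
        [-1.0, 1.0], size=len(sub_idx)
    )
    lfc_dis = rng.normal(config.lfc_mean, config.lfc_sd, size=len(dis_idx)) * rng.choice(
        [-1.0, 1.0], size=len(dis_idx)
    )

    log2_mu = np.tile(np.log2(mu0)[:, None], (1, n))
    is_pd = np.array([g in ("PDC1", "PDC2") for g in groups])
    is_pd1 = np.array([g == "PDC1" for g in groups])
    log2_mu[np.ix_(sub_idx, np.flatnonzero(is_pd1))] += lfc_sub[:, None]
    log2_mu[np.ix_(dis_idx, np.flatnonzero(is_pd))] += lfc_dis[:, None]

    # multiplicative batch effect, per (batch, gene)
    if config.batch_effect_sd > 0:
        log2_b = rng.normal(0.0, config.batch_effect_sd, size=(config.n_batches, G))
    else:
        log2_b = np.zeros((config.n_batches, G))
    log2_mu += log2_b[batch, :].T

    # latent-factor correlation blocks (log2-mean scale, unit total variance)
    gene_index = {g: i for i, g in enumerate(genes)}
    edges: dict[str, list[tuple[str, str, float]]] = {g: [] for g in GROUPS}
    for block in config.corr_block_spec:
        gi = np.array([gene_index[g] for g in block.genes])
        target = (
            np.ones(n, dtype=bool)
            if block.group == "all"
            else np.array([g == block.group for g in groups])
        )
        f = rng.normal(size=target.sum())
        eps = rng.normal(size=(len(gi), target.sum()))
        lam = block.loading
        log2_mu[np.ix_(gi, np.flatnonzero(target))] += config.latent_scale * (
            lam * f[None, :] + np.sqrt(max(0.0, 1 - lam**2)) * eps
        )
        block_groups = GROUPS if block.group == "all" else (block.group,)
        for grp in block_groups:
            for a in range(len(gi)):
                for b in range(a + 1, len(gi)):
                    edges[grp].append((block.genes[a], block.genes[b], lam))

    mu = 2.0**log2_mu
    phi_mat = np.tile(phi[:, None], (1, n))
    if config.batch_dispersion_factors is not None:
        factors = np.asarray(config.batch_dispersion_factors, dtype=float)
        phi_mat *= factors[batch][None, :]
    # NB parameterization: size r = 1/phi, p = r / (r + mu)
    r = 1.0 / phi_mat
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(genes, samples, counts)

    # TFs: prefer genes wired into correlation blocks, then the rest
    n_tf = int(round(config.tf_fraction * G))
    block_genes = []
    seen: set[str] = set()
    for block in config.corr_block_spec:
        for g in block.genes:
            if g not in seen:
                seen.add(g)
                block_genes.append(g)
    rest = [g for g in genes if g not in seen]
    rng.shuffle(rest)
    tf_ids = set((block_genes + rest)[:n_tf])

    # clinical metadata: subtype-shifted age at death and Braak stage
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age[is_pd1] -= config.age_shift
    braak_base = np.where(is_pd, 4.0, 1.0) + rng.normal(0, 0.8, size=n)
    braak_base[is_pd1] += config.braak_shift
    braak = np.clip(np.rint(braak_base), 0, 6).astype(int)
    sex = rng.choice(["M", "F"], size=n)

    meta = SampleTable(
        pd.DataFrame(
            {
                "sample": samples,
                "diagnosis": np.where(is_pd, "PD", "NC"),
                "batch": batch,
                "age_death": np.round(age, 1),
                "sex": sex,
                "braak": braak,
            }
        )
    )

    truth = SyntheticTruth(
        subtype_labels={s: g for s, g in zip(samples, groups) if g != "NC"},
        de_genes_subtype={genes[i]: float(l) for i, l in zip(sub_idx, lfc_sub)},
        de_genes_disease={genes[i]: float(l) for i, l in zip(dis_idx, lfc_dis)},
        batch_assignment={s: int(b) for s, b in zip(samples, batch)},
        true_edges_per_group=edges,
        tf_ids=tf_ids,
    )
    return cm, meta, truth


def make_drug_fixture(
    total: int,
    duplicated: int = 0,
    inefficacious: int = 0,
    side_effect: int = 0,
    unknown_moa: int = 0,
    genes: tuple[str, ...] = ("NEUROD1", "GRM2"),
    overlap_duplicate_unknown: int = 0,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Build a drug-gene interaction table with controlled filter outcomes.

    ``duplicated`` records are exact repeats of existing (compound, gene)
    pairs; the remaining categories are flagged on distinct unique records
    so the sequential filter removes exactly the requested counts.  Set
    ``overlap_duplicate_unknown`` to also blank the modality of action on
    that many duplicate records (stress-testing first-failing-stage
    disposition).
    """
    for name, v in {
        "total": total,
        "duplicated": duplicated,
        "inefficacious": inefficacious,
        "side_effect": side_effect,
        "unknown_moa": unknown_moa,
    }.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if duplicated + inefficacious + side_effect + unknown_moa > total:
        raise ValueError("category counts exceed total")
    if overlap_duplicate_unknown > duplicated:
        raise ValueError("overlap count exceeds duplicate count")

    rng = np.random.default_rng(seed)
    n_unique = total - duplicated
    moas = ("receptor agonist", "pathway inhibitor", "allosteric modulator", "iron chelator")
    phases = ("Preclinical", "Phase 1", "Phase 2", "Launched")
    uniques: list[InteractionRecord] = []
    for i in range(n_unique):
        flags = {"efficacious": True, "side_effect_memory": False, "moa": moas[i % len(moas)]}
        if i < inefficacious:
            flags["efficacious"] = False
        elif i < inefficacious + side_effect:
            flags["side_effect_memory"] = True
        elif i < inefficacious + side_effect + unknown_moa:
            flags["moa"] = ""
        uniques.append(
            InteractionRecord(
                compound_id=f"CHEMBL{10000 + i}",
                compound_name=f"CPD-{i + 1:03d}",
                gene=genes[i % len(genes)],
                moa=flags["moa"],
                phase=phases[i % len(phases)],
                efficacious=flags["efficacious"],
                side_effect_memory=flags["side_effect_memory"],
            )
        )
    # duplicates repeat clean records so categories stay non-overlapping
    clean = [u for u in uniques if u.efficacious and not u.side_effect_memory and u.moa]
    pool = clean if clean else uniques
    dupes: list[InteractionRecord] = []
    for j in range(duplicated):
        src = pool[j % len(pool)] if pool else None
        if src is None:
            raise ValueError("cannot create duplicates from an empty table")
        moa = "" if j < overlap_duplicate_unknown else src.moa
        dupes.append(
            InteractionRecord(
                compound_id=src.compound_id,
                compound_name=src.compound_name,
                gene=src.gene,
                moa=moa,
                phase=src.phase,
            )
        )
    # duplicates are placed after their originals so dedup disposes the copy
    order = rng.permutation(len(dupes))
    return uniques + [dupes[i] for i in order]


def make_gene_set_fixture(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe,
    planted_query=None,
    tf_fraction: float = 0.1,
    disease_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str], list[str]]:
    """Random gene-set collection over ``universe``; optionally plant one
    set equal to ``planted_query`` so its ORA p-value is minimal.  Also
    returns a TF list and a disease-gene list drawn from the universe."""
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = set(members.tolist())
    if planted_query is not None:
        planted = set(planted_query)
        if not planted <= set(universe):
            raise ValueError("planted query must lie in the universe")
        sets["PLANTED"] = planted
    collection = GeneSetCollection(sets, source="fixture")
    n_tf = int(round(tf_fraction * len(universe)))
    n_dis = int(round(disease_fraction * len(universe)))
    perm = rng.permutation(len(universe))
    tf_list = [universe[i] for i in perm[:n_tf]]
    disease = [universe[i] for i in rng.permutation(len(universe))[:n_dis]]
    return collection, tf_list, disease
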