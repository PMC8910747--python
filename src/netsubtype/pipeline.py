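"""End-to-end pipeline orchestration from a single declarative config.

Stage order: integrate -> Grubbs screen -> low-count filter -> batch
adjustment -> log2-CPM -> Hopkins -> best-k -> clustering portfolio ->
model selection -> clinical comparison -> differential expression (three
contrasts) -> Venn partition -> per-cluster PCIT networks -> communities ->
centralities -> NCT -> differential network -> TF identification -> RIF ->
top regulators -> ORA / GDA -> drug filter.  All stage seeds derive
deterministically from the master seed; artifacts plus a checksum manifest
are written to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from netsubtype import clustering, de, drugs, enrichment, network, nct, preprocessing, rif
from netsubtype import synthetic
from netsubtype.matrix import CountMatrix, SampleTable

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_BAD_CONFIG = 2
EXIT_NO_STRUCTURE = 3
EXIT_STAGE_FAILURE = 4


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 12345
    simulate: synthetic.SimulationConfig | None = None
    counts_paths: list[Path] = field(default_factory=list)
    metadata_path: Path | None = None
    gmt_path: Path | None = None
    tf_list_path: Path | None = None
    disease_list_path: Path | None = None
    drug_table_path: Path | None = None
    low_count_percentile: float = 15.0
    grubbs_alpha: float = 0.05
    # 0.35 rather than 0.5: with a uniform-bounding-box reference, even
    # structureless Gaussian-like expression data scores ~0.4, so 0.5 would
    # never gate; ~0.22 is typical for genuinely clustered cohorts
    hopkins_threshold: float = 0.35
    hopkins_pcs: int = 2
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 10)
    metrics: tuple[str, ...] = clustering.METRICS
    algorithms: tuple[str, ...] = clustering.ALGORITHMS
    linkage: str = "centroid"
    de_alpha: float = 0.01
    n_perm: int = 200
    nct_q: float = 0.01
    top_k: int = 5
    ora_q: float = 0.05
    min_set_size: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        sim = raw.pop("simulate", None)
        outdir = Path(raw.pop("outdir", "netsubtype_out"))
        if not outdir.is_absolute():
            outdir = base / outdir
        cfg = cls(outdir=outdir)
        if sim is not None:
            blocks = [
                synthetic.CorrBlock(tuple(b["genes"]), b.get("group", "all"), float(b["loading"]))
                for b in sim.pop("corr_block_spec", [])
            ]
            cfg.simulate = synthetic.SimulationConfig(**sim, corr_block_spec=blocks)
        for key in ("counts_paths",):
            if key in raw:
                cfg.counts_paths = [base / p for p in raw.pop(key)]
        for key in ("metadata_path", "gmt_path", "tf_list_path",
                    "disease_list_path", "drug_table_path"):
            if key in raw:
                setattr(cfg, key, base / raw.pop(key))
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and not self.counts_paths:
            raise ValueError("config needs either a simulate block or counts_paths")
        if self.simulate is None and self.metadata_path is None:
            raise ValueError("metadata_path required with counts_paths")
        if not 0 <= self.low_count_percentile < 100:
            raise ValueError("low_count_percentile out of range")
        for name in ("de_alpha", "nct_q", "ora_q"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")


@dataclass
class ReportBundle:
    outdir: Path
    status: str
    summary: dict
    manifest: dict[str, str] = field(default_factory=dict)

    def path(self, name: str) -> Path:
        return self.outdir / name


class PipelineStop(Exception):
    """Raised when the clusterability gate halts the pipeline."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)}


_STAGE_NAMES = [
    "simulate", "hopkins", "best_k", "portfolio", "clinical", "nct",
    "communities", "fixtures",
]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed, _STAGE_NAMES)
    summary: dict = {"seed": config.seed}
    emitted: list[Path] = []
    bundle = ReportBundle(outdir, "running", summary)

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        emitted.append(path)
        return path

    try:
        # ---- inputs -------------------------------------------------------
        truth = None
        if config.simulate is not None:
            sim = config.simulate
            sim.seed = seeds["simulate"] if sim.seed is None else sim.seed
            cm, meta, truth = synthetic.simulate_cohort(sim)
            emit("counts.tsv", cm.write_tsv)
            emit("metadata.csv", meta.write_csv)
            emit("truth.json", truth.to_json)
        else:
            matrices = [CountMatrix.read_tsv(p) for p in config.counts_paths]
            cm = preprocessing.integrate_by_gene(matrices)
            meta = SampleTable.read_csv(config.metadata_path)
        meta = meta.aligned_to(cm.sample_ids)
        meta.check_paired(cm)

        # ---- preprocessing ------------------------------------------------
        diagnosis = meta.column("diagnosis")
        age = meta.table.get("age_death")
        if age is not None and age.notna().sum() >= 3:
            pd_idx = np.flatnonzero(diagnosis == "PD")
            pd_out = preprocessing.grubbs_screen(
                age.to_numpy(float)[pd_idx], alpha=config.grubbs_alpha
            )
            drop = set(pd_idx[pd_out])
            if drop:
                keep = np.array([i not in drop for i in range(cm.n_samples)])
                logger.info("Grubbs screen removed %d sample(s)", len(drop))
                cm = cm.subset_samples(keep)
                meta = SampleTable(meta.table.loc[keep].reset_index(drop=True))
                diagnosis = meta.column("diagnosis")
        cm = preprocessing.filter_low_counts(cm, config.low_count_percentile)
        batch = meta.column("batch")
        if len(np.unique(batch)) > 1:
            cm = preprocessing.batch_adjust(cm, batch, group=diagnosis)
        expr = preprocessing.log2_cpm(cm)
        emit("expression.tsv", expr.write_tsv)
        universe = list(cm.gene_ids)

        # ---- subtype discovery (PD samples only) --------------------------
        is_pd = diagnosis == "PD"
        X = expr.values[:, is_pd].T  # samples x genes
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        # clusterability is judged on low-dimensional PC scores; in the full
        # gene space nearest-neighbor distances are noise-dominated and the
        # statistic cannot distinguish structure from its absence
        X_hop = clustering.pca_scores(X, config.hopkins_pcs)
        hop = clustering.hopkins(
            X_hop, m=min(50, max(1, (is_pd.sum()) // 4)), seed=seeds["hopkins"],
            threshold=config.hopkins_threshold,
        )
        summary["hopkins"] = {"H": hop.H, "clusterable": hop.clusterable}
        if not hop.clusterable:
            bundle.status = "no_cluster_structure"
            raise PipelineStop

        if config.k == "auto":
            lo, hi = config.k_range
            bk = clustering.estimate_best_k(
                X, range(lo, min(hi, X.shape[0] - 2) + 1), seed=seeds["best_k"]
            )
            k = bk.best_k
            summary["best_k"] = {"k": k, "votes": {i: int(v) for i, v in bk.votes.items()}}
        else:
            k = int(config.k)
            summary["best_k"] = {"k": k, "votes": {}}

        models = clustering.run_portfolio(
            X, k, algorithms=config.algorithms, metrics=config.metrics,
            seed=seeds["portfolio"], linkage=config.linkage,
        )
        best = clustering.select_best_model(models)
        summary["cluster_model"] = {
            "name": best.name, "k": best.k,
            "silhouette_avg": best.silhouette_avg, "dunn": best.dunn,
            "sizes": np.bincount(best.labels).tolist(),
        }
        pd_samples = cm.sample_ids[is_pd]
        labels_df = pd.DataFrame({"sample": pd_samples, "cluster": best.labels + 1})
        emit("cluster_labels.csv", lambda p: labels_df.to_csv(p, index=False))

        if k == 2:
            meta_pd = SampleTable(meta.table.loc[is_pd].reset_index(drop=True))
            clin = clustering.compare_clinical(meta_pd, best.labels, seed=seeds["clinical"])
            summary["clinical"] = {"wilcoxon": clin.wilcoxon, "fisher": clin.fisher}

        # ---- differential expression --------------------------------------
        cluster_of = dict(zip(pd_samples, best.labels))
        group1 = np.array([cluster_of.get(s) == 0 for s in cm.sample_ids])
        group2 = np.array([cluster_of.get(s) == 1 for s in cm.sample_ids])
        is_nc = ~is_pd
        contrasts = {}
        subtype_degs: set[str] = set()
        if k == 2:
            pair_defs = {
                "PDC1_vs_PDC2": (group1, group2),
                "PDC1_vs_NC": (group1, is_nc),
                "PDC2_vs_NC": (group2, is_nc),
            }
            for name, (ga, gb) in pair_defs.items():
                sel = ga | gb
                sub = expr.subset_samples(sel)
                indicator = ga[sel].astype(float)
                res = de.run_contrast(sub, indicator, name, alpha=config.de_alpha)
                contrasts[name] = res
                emit(f"de_{name}.tsv", res.write_tsv)
            subtype_degs = contrasts["PDC1_vs_PDC2"].degs
            ua, ub, common = de.venn_partition(
                contrasts["PDC1_vs_NC"].degs, contrasts["PDC2_vs_NC"].degs
            )
            summary["degs"] = {
                "PDC1_vs_PDC2": len(subtype_degs),
                "PDC1_vs_NC_unique": len(ua),
                "PDC2_vs_NC_unique": len(ub),
                "common": len(common),
            }

        # ---- networks -----------------------------------------------------
        deg_nodes = sorted(subtype_degs)
        nets: dict[str, network.GeneNetwork] = {}
        if len(deg_nodes) >= 3 and k == 2:
            for name, gmask in (("PDC1", group1), ("PDC2", group2)):
                sub = expr.subset_samples(gmask).restrict(deg_nodes)
                R = network.pearson_matrix(sub)
                mask, weights = network.pcit_mask(R)
                net = network.build_network(deg_nodes, mask, weights, group=name)
                nets[name] = net
                emit(f"network_{name}.tsv", net.write_edgelist)
            comm_summary = {}
            for name, net in nets.items():
                if net.n_edges > 0:
                    ca = network.detect_communities(net, seed=seeds["communities"])
                    comm_summary[name] = ca.n_communities
            summary["communities"] = comm_summary
            cents = {
                name: network.centralities(net)
                for name, net in nets.items() if net.n_edges > 0
            }
            delta_b = network.delta_betweenness(nets["PDC1"], nets["PDC2"])

            E1 = expr.subset_samples(group1).restrict(deg_nodes)
            E2 = expr.subset_samples(group2).restrict(deg_nodes)
            res_nct = nct.nct(E1, E2, n_perm=config.n_perm, seed=config.seed)
            summary["nct"] = {
                "S_obs": res_nct.S_obs, "p_S": res_nct.p_S,
                "M_obs": res_nct.M_obs, "p_M": res_nct.p_M,
                "n_perm": res_nct.n_perm, "exact": res_nct.exact,
            }
            diff_net = nct.differential_network(res_nct, q_threshold=config.nct_q)
            summary["differential_network_edges"] = diff_net.n_edges
            emit("nct_edges.tsv",
                 lambda p: res_nct.edge_table.to_csv(p, sep="\t", index=False))

            # ---- regulators -----------------------------------------------
            tf_list, disease_list, gene_sets, drug_table = _load_annotations(
                config, universe, seeds["fixtures"]
            )
            tfs = rif.identify_tfs(deg_nodes, tf_list)
            summary["n_tfs"] = len(tfs)
            top = set()
            if tfs and cents:
                reg = rif.rif_scores(E1, E2, tfs, deg_nodes)
                emit("rif.csv", lambda p: reg.rif.to_csv(p, index=False))
                auth = cents.get("PDC1", next(iter(cents.values()))).authority()
                top = rif.top_regulators(auth, delta_b, reg, k=config.top_k)
                summary["top_regulators"] = sorted(top)

            # ---- enrichment / GDA -----------------------------------------
            if gene_sets is not None and deg_nodes:
                ora_table = enrichment.ora(
                    deg_nodes, gene_sets, universe, min_set_size=config.min_set_size
                )
                emit("ora.csv", lambda p: ora_table.to_csv(p, index=False))
                summary["ora_significant"] = int((ora_table["q"] <= config.ora_q).sum())
            if disease_list and deg_nodes:
                summary["gda_fraction"] = enrichment.gda_overlap(deg_nodes, disease_list)

            # ---- drugs ----------------------------------------------------
            if drug_table is None and config.simulate is not None and top:
                drug_table = synthetic.make_drug_fixture(
                    42, 16, 5, 2, 10, genes=tuple(sorted(top)), seed=seeds["fixtures"]
                )
            if drug_table is not None and top:
                candidates = drugs.query_interactions(top, drug_table)
                final, flog = drugs.filter_compounds(candidates)
                report = drugs.drug_report(final)
                emit("drug_report.csv", lambda p: report.to_csv(p, index=False))
                summary["drugs"] = flog.to_dict()

        if truth is not None and k == 2:
            from sklearn.metrics import adjusted_rand_score

            true_labels = [truth.subtype_labels[s] for s in pd_samples]
            summary["ari_vs_truth"] = float(
                adjusted_rand_score(true_labels, best.labels)
            )
        bundle.status = "ok"
    except PipelineStop:
        pass
    except Exception as exc:  # partial failure: keep artifacts + error manifest
        bundle.status = "failed"
        summary["error"] = f"{type(exc).__name__}: {exc}"
        logger.exception("pipeline stage failed")

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, default=_json_default))
    emitted.append(summary_path)
    bundle.manifest = {p.name: _checksum(p) for p in emitted if p.exists()}
    (outdir / "manifest.json").write_text(json.dumps(
        {"seed": config.seed, "status": bundle.status, "files": bundle.manifest},
        indent=1,
    ))
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_annotations(config: PipelineConfig, universe: list[str], seed: int):
    """Load user-supplied annotation tables, or generate fixtures tied to
    the simulated universe."""
    tf_list = disease_list = None
    gene_sets = None
    drug_table = None
    if config.tf_list_path is not None:
        tf_list = [l.strip() for l in Path(config.tf_list_path).read_text().splitlines() if l.strip()]
    if config.disease_list_path is not None:
        disease_list = [
            l.strip() for l in Path(config.disease_list_path).read_text().splitlines() if l.strip()
        ]
    if config.gmt_path is not None:
        gene_sets = enrichment.read_gmt(config.gmt_path)
    if config.drug_table_path is not None:
        drug_table = drugs.read_interaction_csv(config.drug_table_path)
    if config.simulate is not None:
        fix_sets, fix_tfs, fix_disease = synthetic.make_gene_set_fixture(
            n_sets=10, set_size_range=(5, 20), universe=universe, seed=seed
        )
        gene_sets = gene_sets or fix_sets
        tf_list = tf_list or fix_tfs
        disease_list = disease_list or fix_disease
    return tf_list or [], disease_list or [], gene_sets, drug_table
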