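import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from netsubtype.clustering import (
    DUNN_SENTINEL,
    ClusterModel,
    agglomerative_labels,
    compare_clinical,
    distance_matrix,
    estimate_best_k,
    hopkins,
    internal_validation,
    run_portfolio,
    select_best_model,
)
from netsubtype.matrix import SampleTable
import pandas as pd


class TestDistanceMatrix:
    def test_hand_values(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert distance_matrix(X, "euclidean")[0, 1] == pytest.approx(5.0)
        assert distance_matrix(X, "manhattan")[0, 1] == pytest.approx(7.0)

    def test_identical_rows_zero(self):
        D = distance_matrix(np.ones((3, 4)))
        assert (D == 0).all()

    def test_triangle_inequality(self, rng):
        X = rng.normal(size=(30, 5))
        for metric in ("euclidean", "manhattan"):
            D = distance_matrix(X, metric)
            for _ in range(200):
                i, j, k = rng.integers(0, 30, size=3)
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            distance_matrix(np.zeros((2, 2)), "cosine")


class TestHopkins:
    def test_uniform_null_near_half(self):
        hs = []
        for seed in range(50):
            X = np.random.default_rng(seed).uniform(size=(500, 2))
            hs.append(hopkins(X, m=50, seed=seed).H)
        assert abs(np.mean(hs) - 0.5) < 0.1

    def test_separated_blobs_low(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
            if hopkins(X, m=40, seed=seed).H < 0.25:
                low += 1
        assert low >= 19

    def test_errors(self):
        with pytest.raises(ValueError):
            hopkins(np.zeros((10, 2)), m=0)
        with pytest.raises(ValueError):
            hopkins(np.random.default_rng(0).uniform(size=(5, 2)), m=10)
        with pytest.raises(ValueError):
            hopkins(np.ones((10, 2)), m=3)


class TestInternalValidation:
    def brute_silhouette(self, labels, D):
        n = len(labels)
        out = np.zeros(n)
        for i in range(n):
            same = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not same:
                continue
            a = np.mean([D[i, j] for j in same])
            b = min(
                np.mean([D[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i]
            )
            out[i] = (b - a) / max(a, b)
        return out

    def brute_dunn(self, labels, D):
        labels = np.asarray(labels)
        inter = min(
            D[i, j]
            for i in range(len(labels)) for j in range(len(labels))
            if labels[i] != labels[j]
        )
        intra = max(
            (D[i, j] for i in range(len(labels)) for j in range(len(labels))
             if labels[i] == labels[j]), default=0.0,
        )
        return inter / intra if intra > 0 else DUNN_SENTINEL

    def test_hand_example(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        D = distance_matrix(X)
        labels = np.array([0, 0, 1, 1])
        sil_avg, dunn, sil = internal_validation(labels, D)
        assert np.allclose(sil, [9 / 11, 7 / 9, 7 / 9, 9 / 11], atol=1e-3)
        assert sil_avg == pytest.approx((9 / 11 + 7 / 9) / 2, abs=1e-6)
        assert dunn == pytest.approx(4.0)

    def test_limit_case(self):
        X = np.array([[0.0], [0.0], [9.0], [9.0]])
        sil_avg, dunn, _ = internal_validation([0, 0, 1, 1], distance_matrix(X))
        assert sil_avg == pytest.approx(1.0)
        assert dunn == DUNN_SENTINEL

    def test_random_labels_near_zero(self):
        avgs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(40, 3))
            labels = rng.integers(0, 2, size=40)
            if len(set(labels)) < 2:
                continue
            avgs.append(internal_validation(labels, distance_matrix(X))[0])
        assert abs(np.mean(avgs)) < 0.1

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            X = rng.normal(size=(rng.integers(8, 20), 3))
            labels = rng.integers(0, 3, size=X.shape[0])
            if len(set(labels.tolist())) < 2:
                continue
            D = distance_matrix(X)
            sil_avg, dunn, sil = internal_validation(labels, D)
            brute = self.brute_silhouette(labels, D)
            assert np.allclose(sil, brute, atol=1e-12)
            assert dunn == pytest.approx(self.brute_dunn(labels, D), abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            internal_validation([0, 0, 0], np.zeros((3, 3)))


class TestBestK:
    def test_two_blobs(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(8, 1, (30, 4))])
        report = estimate_best_k(X, range(2, 8))
        assert report.best_k == 2
        assert sum(1 for v in report.votes.values() if v == 2) >= 4

    def test_three_blobs(self, rng):
        X = np.vstack([
            rng.normal(0, 1, (25, 4)),
            rng.normal(8, 1, (25, 4)),
            rng.normal([0, 16, 0, 16], 1, (25, 4)),
        ])
        assert estimate_best_k(X, range(2, 8)).best_k == 3

    def test_identical_rows_error(self):
        with pytest.raises(ValueError):
            estimate_best_k(np.ones((20, 3)), range(2, 5))

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            estimate_best_k(np.random.default_rng(0).normal(size=(4, 2)), [2])


class TestPortfolio:
    def test_separable_recovered_by_all(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (15, 3)), rng.normal(10, 0.5, (20, 3))])
        truth = np.array([0] * 15 + [1] * 20)
        models = run_portfolio(X, 2, seed=1)
        assert len(models) == 14  # 8 + 8 algorithms minus 2 unsupported pairs
        for m in models:
            assert adjusted_rand_score(truth, m.labels) == pytest.approx(1.0), m.name

    def test_determinism(self, rng):
        X = rng.normal(size=(30, 4))
        m1 = run_portfolio(X, 2, algorithms=("kmeans", "fuzzy", "clara"), seed=9)
        m2 = run_portfolio(X, 2, algorithms=("kmeans", "fuzzy", "clara"), seed=9)
        for a, b in zip(m1, m2):
            assert (a.labels == b.labels).all()

    def test_labels_cover_k_clusters(self, rng):
        X = rng.normal(size=(25, 3))
        for m in run_portfolio(X, 3, seed=4):
            assert len(np.unique(m.labels)) == 3

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            run_portfolio(np.zeros((5, 2)), 1)


class TestSelectBestModel:
    def _model(self, sil, dunn, name="kmeans"):
        return ClusterModel(name, "euclidean", 2, np.array([0, 1]), sil, dunn)

    def test_max_silhouette(self):
        models = [self._model(0.2, 1), self._model(0.4, 1), self._model(0.3, 1)]
        assert select_best_model(models).silhouette_avg == 0.4

    def test_tie_broken_by_dunn(self):
        models = [self._model(0.3, 0.05), self._model(0.3, 0.10)]
        assert select_best_model(models).dunn == 0.10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


class TestAgglomerative:
    def test_matches_average_linkage_structure(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(10, 1, (10, 2))])
        D = distance_matrix(X)
        for linkage in ("average", "complete", "single", "centroid"):
            labels = agglomerative_labels(D, 2, linkage)
            assert adjusted_rand_score([0] * 10 + [1] * 10, labels) == 1.0


class TestCompareClinical:
    def _meta(self, age, sex, braak):
        n = len(age)
        return SampleTable(pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "diagnosis": ["PD"] * n,
            "batch": [0] * n,
            "age_death": age,
            "sex": sex,
            "braak": braak,
        }))

    def test_wilcoxon_exact_small(self):
        meta = self._meta([1, 2, 3, 4, 70, 71, 72, 73],
                          ["M"] * 8, [1] * 8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = compare_clinical(meta, labels)
        # exhaustive: 2/C(8,4) two-sided
        assert out.wilcoxon["age_death"]["p"] == pytest.approx(2 / 70, rel=1e-6)

    def test_wilcoxon_enumeration_oracle(self):
        meta = self._meta([1.0, 2.0, 3.0, 4.0, 10.0, 20.0],
                          ["M"] * 6, [1] * 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = compare_clinical(meta, labels)
        # brute-force enumeration of C(6,3) assignments for rank-sum
        from itertools import combinations
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 20.0])
        ranks = np.argsort(np.argsort(vals)) + 1
        obs = ranks[:3].sum()
        total = list(combinations(range(6), 3))
        stat = [ranks[list(c)].sum() for c in total]
        mean = np.mean(stat)
        p_oracle = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stat])
        assert out.wilcoxon["age_death"]["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_fisher_2x2_hand_value(self):
        meta = self._meta([60.0] * 8, ["M", "M", "M", "F", "M", "F", "F", "F"],
                          [1] * 8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = compare_clinical(meta, labels)
        assert out.fisher["sex"]["p"] == pytest.approx(34 / 70, rel=1e-9)

    def test_identical_groups_p_one(self):
        meta = self._meta([1, 2, 3, 1, 2, 3], ["M", "F", "M", "M", "F", "M"],
                          [1, 2, 3, 1, 2, 3])
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = compare_clinical(meta, labels)
        assert out.wilcoxon["age_death"]["p"] == pytest.approx(1.0)
        assert out.fisher["sex"]["p"] == pytest.approx(1.0)
        assert out.fisher["braak"]["p"] == pytest.approx(1.0)

    def test_braak_2xr_exact_vs_monte_carlo(self):
        rng = np.random.default_rng(3)
        braak = rng.integers(1, 5, size=40)
        meta = self._meta([60.0] * 40, ["M"] * 40, braak)
        labels = np.array([0] * 20 + [1] * 20)
        out = compare_clinical(meta, labels)
        from netsubtype.clustering import _fisher_2xr_exact_or_mc
        stages = np.sort(np.unique(braak))
        tab = np.array([[(braak[labels == c] == s).sum() for s in stages]
                        for c in (0, 1)])
        p_mc, method = _fisher_2xr_exact_or_mc(tab, seed=1, max_tables=0)
        assert method == "monte_carlo"
        assert out.fisher["braak"]["p"] == pytest.approx(p_mc, abs=0.02)

    def test_requires_two_clusters(self):
        meta = self._meta([1, 2, 3], ["M"] * 3, [1] * 3)
        with pytest.raises(ValueError):
            compare_clinical(meta, np.array([0, 0, 0]))


def test_portfolio_recovers_planted_subtypes():
    """Planted two-subtype recovery across seeds (scaled-down cohort)."""
    from netsubtype import preprocessing, synthetic

    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = synthetic.SimulationConfig(
            n_genes=150, n_pd1=40, n_pd2=40, n_nc=4, n_batches=1,
            batch_effect_sd=0.0, n_de_subtype=50, n_de_disease=0,
            lfc_mean=1.5, seed=seed,
        )
        cm, meta, truth = synthetic.simulate_cohort(cfg)
        expr = preprocessing.log2_cpm(cm)
        is_pd = meta.column("diagnosis") == "PD"
        X = expr.values[:, is_pd].T
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1, sd)
        models = run_portfolio(X, 2, seed=12345)
        best = select_best_model(models)
        true = [truth.subtype_labels[s] for s in cm.sample_ids[is_pd]]
        if adjusted_rand_score(true, best.labels) >= 0.9:
            wins += 1
    assert wins >= int(0.9 * n_seeds)
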