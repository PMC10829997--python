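import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from meavocab.similarity import PairwiseSimilarity
from meavocab.vocabulary import (SimilarityGraph, build_graph, fit_thresholds,
                                 percent_explained, spectral_cluster, Vocabulary)


def synthetic_pairwise(b=80, frac_similar=0.5, seed=0):
    """Pairwise tables with a planted two-group structure.

    Within-group pairs draw high correlations (N(0.9, 0.03)) and low
    distances; across-group pairs low correlations (N(0.3, 0.1)) and high
    distances — a clean bimodal ensemble with known pair labels.
    """
    rng = np.random.default_rng(seed)
    groups = (np.arange(b) >= b * (1 - frac_similar)).astype(int)
    same = groups[:, None] == groups[None, :]
    c2 = np.where(same, rng.normal(0.9, 0.03, (b, b)), rng.normal(0.3, 0.1, (b, b)))
    sp = np.where(same, rng.normal(0.92, 0.03, (b, b)), rng.normal(0.35, 0.1, (b, b)))
    ic = np.where(same, rng.normal(0.7, 0.08, (b, b)), rng.normal(0.05, 0.12, (b, b)))
    cd = np.where(same, rng.lognormal(2.3, 0.25, (b, b)), rng.lognormal(4.4, 0.25, (b, b)))
    for m in (c2, sp, ic, cd):
        m[:] = (m + m.T) / 2
    np.fill_diagonal(c2, 1); np.fill_diagonal(sp, 1); np.fill_diagonal(ic, 1)
    np.fill_diagonal(cd, 0)
    return PairwiseSimilarity(corr2=np.clip(c2, -1, 1), com_distance=cd,
                              spatial_corr=np.clip(sp, -1, 1),
                              initial_corr=np.clip(ic, -1, 1)), same


class TestPercentExplained:
    def test_worked_example(self):
        assert percent_explained(n_bursts=1017, n_unclassified=151) \
            == pytest.approx(85.15, abs=0.01)

    def test_boundaries(self):
        assert percent_explained(n_bursts=10, n_unclassified=0) == 100.0
        assert percent_explained(n_bursts=10, n_unclassified=10) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_explained(n_bursts=0, n_unclassified=0)


class TestFitThresholds:
    def test_threshold_in_valley_and_separates_modes(self):
        """The corr2 threshold from the known two-mode mixture lands in
        (0.55, 0.8) and misclassifies < 2% of the pair labels."""
        pw, same = synthetic_pairwise(seed=1)
        thr = fit_thresholds(pw)
        assert 0.55 < thr.theta < 0.8
        iu, ju = np.triu_indices(pw.n_bursts, k=1)
        pred = pw.corr2[iu, ju] >= thr.theta
        assert (pred != same[iu, ju]).mean() < 0.02
        # com_distance is an upper bound separating the two lognormal modes
        cd = thr.metric_thresholds["com_distance"]
        assert np.exp(2.3) < cd < np.exp(4.4)

    def test_degenerate_sample_refused(self):
        pw, _ = synthetic_pairwise()
        for name in ("corr2", "com_distance", "spatial_corr", "initial_corr"):
            getattr(pw, name)[:] = 0.5 if name != "com_distance" else 10.0
        with pytest.raises(ValueError):
            fit_thresholds(pw)

    def test_unimodal_sample_refused(self):
        rng = np.random.default_rng(2)
        b = 60
        m = rng.normal(0.4, 0.05, (b, b))
        m = (m + m.T) / 2
        pw = PairwiseSimilarity(corr2=m, com_distance=np.abs(m) * 100,
                                spatial_corr=m, initial_corr=m)
        with pytest.raises(ValueError, match="bimodal"):
            fit_thresholds(pw)

    def test_override_verbatim(self):
        pw, _ = synthetic_pairwise()
        thr = fit_thresholds(pw, overrides={"corr2": 0.77, "com_distance": 33.0,
                                            "spatial_corr": 0.5, "initial": 0.4})
        assert thr.theta == 0.77
        assert thr.metric_thresholds["com_distance"] == 33.0
        assert thr.initial_thresholds["corr2"] == 0.4


class TestBuildGraph:
    def test_weights_by_bruteforce_recount(self):
        pw, _ = synthetic_pairwise(seed=3)
        thr = fit_thresholds(pw)
        g = build_graph(pw, thr)
        assert set(np.unique(g.weights)) <= {0, 1, 2, 3}
        assert (np.diag(g.weights) == 0).all()
        assert np.array_equal(g.weights, g.weights.T)
        # independent recount on a sample of pairs
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j = rng.integers(0, pw.n_bursts, 2)
            if i == j:
                continue
            w = 0
            init_ok = pw.initial_corr[i, j] >= thr.initial_thresholds["corr2"]
            if init_ok and pw.corr2[i, j] >= thr.metric_thresholds["corr2"]:
                w += 1
            if init_ok and pw.com_distance[i, j] <= thr.metric_thresholds["com_distance"]:
                w += 1
            if init_ok and pw.spatial_corr[i, j] >= thr.metric_thresholds["spatial_corr"]:
                w += 1
            assert g.weights[i, j] == w

    def test_and_condition_with_initial_threshold(self):
        pw, _ = synthetic_pairwise(seed=4)
        thr = fit_thresholds(pw)
        pw.initial_corr[:] = -1.0   # nothing passes the initial gate
        np.fill_diagonal(pw.initial_corr, 1.0)
        g = build_graph(pw, thr)
        assert not g.weights.any()

    def test_nan_never_passes(self):
        pw, _ = synthetic_pairwise(seed=5)
        thr = fit_thresholds(pw)
        pw.corr2[2, 3] = pw.corr2[3, 2] = np.nan
        g = build_graph(pw, thr)
        g2 = build_graph(pw, thr)
        assert g.weights[2, 3] <= 2


def two_clique_graph(n1=30, n2=20):
    b = n1 + n2
    w = np.zeros((b, b), dtype=int)
    w[:n1, :n1] = 3
    w[n1:, n1:] = 3
    np.fill_diagonal(w, 0)
    return SimilarityGraph(weights=w)


class TestSpectralCluster:
    def test_two_cliques_exact_split(self):
        g = two_clique_graph()
        v = spectral_cluster(g, k=2, seed=0)
        assert len(v.cluster_ids) == 2
        assert percent_explained(v) == 100.0
        assert len(set(v.labels[:30])) == 1 and len(set(v.labels[30:])) == 1
        assert v.labels[0] != v.labels[-1]

    def test_eigengap_selects_two(self):
        v = spectral_cluster(two_clique_graph(), k="auto", seed=0)
        assert v.k == 2

    def test_zero_degree_nodes_unclassified(self):
        g = two_clique_graph()
        g.weights[10, :] = 0
        g.weights[:, 10] = 0
        v = spectral_cluster(g, k=2, seed=0)
        assert v.labels[10] == -1
        assert v.n_unclassified == 1

    def test_small_clusters_dissolved(self):
        b = 100
        w = np.zeros((b, b), dtype=int)
        w[:98, :98] = 3
        w[98:, 98:] = 3     # a 2-node clique, < 2% of 100 once split
        np.fill_diagonal(w, 0)
        v = spectral_cluster(SimilarityGraph(weights=w), k=2, seed=0, min_frac=0.05)
        assert (v.labels[98:] == -1).all()
        assert percent_explained(v) == pytest.approx(98.0)

    def test_label_permutation_invariance(self):
        g = two_clique_graph()
        rng = np.random.default_rng(11)
        perm = rng.permutation(g.n_nodes)
        g2 = SimilarityGraph(weights=g.weights[np.ix_(perm, perm)])
        v1 = spectral_cluster(g, k=2, seed=0)
        v2 = spectral_cluster(g2, k=2, seed=0)
        assert adjusted_rand_score(v1.labels[perm], v2.labels) == 1.0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            spectral_cluster(two_clique_graph(), k=60, seed=0)

    def test_partition_integrity(self):
        v = spectral_cluster(two_clique_graph(), k=2, seed=0)
        assert sum(v.cluster_sizes.values()) + v.n_unclassified == v.n_bursts


def test_ari_degrades_with_noise(geometry, templates3):
    """Vocabulary recovery worsens monotonically (within tolerance) as the
    realization-noise scale grows."""
    from helpers import render_bursts
    from meavocab.pipeline import build_vocabulary
    aris = []
    for scale in (0.5, 2.0, 6.0):
        rng = np.random.default_rng(100)
        bursts, labels = [], []
        for t in templates3:
            bursts.extend(render_bursts(t, geometry, rng, 25, noise_scale=scale))
            labels.extend([t.template_id] * 25)
        try:
            fit = build_vocabulary(bursts, geometry, k=3, seed=0)
            aris.append(adjusted_rand_score(labels, fit.vocabulary.labels))
        except ValueError:   # thresholds unfittable: recovery has collapsed
            aris.append(0.0)
    assert aris[0] >= 0.9
    assert aris[0] >= aris[1] - 0.05 >= aris[2] - 0.10
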