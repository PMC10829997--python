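"""Burst vocabulary: bimodal thresholds, similarity graph, spectral clustering.

The joint distribution of initial-state correlation vs. each full-burst
metric is bimodal across pairs: one mode for pairs converging to the same
pattern, one for pairs converging to different patterns.  For each metric a
pair of thresholds is fitted at the valley between the modes (two-component
Gaussian mixture, equal-posterior point).  A pair of bursts is linked under
a metric when it passes both that metric's threshold and the initial-state
threshold; summing the three binary graphs yields an integer-weighted
(0-3) similarity graph.  Spectral clustering of this graph — normalized
symmetric Laplacian L_s = D^{-1/2} L D^{-1/2}, k smallest eigenvectors,
row-normalized, k-medoids — produces the network's vocabulary.  Clusters
holding fewer than 2% of bursts are dissolved; their members, along with
zero-degree bursts, are left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .similarity import PairwiseSimilarity

METRICS = ("corr2", "com_distance", "spatial_corr")


@dataclass
class ThresholdSet:
    """Dual thresholds per metric plus the network similarity threshold theta.

    ``metric_thresholds[m]`` is a lower bound for the correlation metrics
    and an upper bound for ``com_distance``; ``initial_thresholds[m]`` is
    the initial-state-correlation lower bound paired with metric ``m``.
    ``theta`` is the corr2 threshold — the network-specific line separating
    same-attractor from different-attractor burst pairs.
    """

    metric_thresholds: dict[str, float]
    initial_thresholds: dict[str, float]

    @property
    def theta(self) -> float:
        return self.metric_thresholds["corr2"]


@dataclass
class SimilarityGraph:
    """Symmetric integer-weighted (0-3) graph over bursts; zero diagonal."""

    weights: np.ndarray  # (B, B) int

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class Vocabulary:
    """Cluster labels over spontaneous bursts.

    ``labels[i]`` is the cluster id of burst ``i`` or -1 for unclassified.
    Retained clusters each hold at least ``min_frac`` of all bursts.
    """

    labels: np.ndarray             # (B,) int, -1 = unclassified
    k: int                         # clusters requested of the embedding
    theta: float
    thresholds: ThresholdSet | None = None
    medoids: dict[int, int] = field(default_factory=dict)  # cluster -> burst id
    min_frac: float = 0.02

    @property
    def n_bursts(self) -> int:
        return len(self.labels)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(c for c in np.unique(self.labels) if c >= 0)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in self.cluster_ids}

    @property
    def n_unclassified(self) -> int:
        return int((self.labels < 0).sum())

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def percent_explained(vocab: Vocabulary | None = None, *,
                      n_bursts: int | None = None,
                      n_unclassified: int | None = None) -> float:
    """Percentage of bursts captured by the retained clusters.

    ``100 * (B - unclassified) / B``; accepts either a fitted vocabulary or
    the two counts directly.
    """
    if vocab is not None:
        n_bursts = vocab.n_bursts
        n_unclassified = vocab.n_unclassified
    if not n_bursts:
        raise ValueError("percent explained undefined for an empty burst set")
    return 100.0 * (n_bursts - n_unclassified) / n_bursts


def _gmm_threshold(values: np.ndarray, lower_is_similar: bool,
                   separability: float = 1.0, seed: int = 0) -> float:
    """Equal-posterior valley point of a bimodal sample.

    Fits a Gaussian mixture and solves for the point between the "similar"
    mode (low for distances, high for correlations) and the rest where the
    posteriors are equal.  Refuses (raises) when the similar component is
    not separated from its neighbour by at least ``separability`` times
    their pooled standard deviation — the marginal is then effectively
    unimodal and an automatic threshold would be arbitrary.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 100:
        raise ValueError(f"need >= 100 finite pairs to fit a threshold, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("all pairwise values identical; supply a manual threshold")

    # The same-attractor mode holds only ~1/k of the pairs, and the
    # different-attractor bulk is structured (one shoulder per template
    # pair), so an unguided two-component fit can split the bulk instead of
    # isolating the minority mode.  Components are initialized at sample
    # quantiles and a three-component fit is allowed when BIC prefers it.
    x = values.reshape(-1, 1)
    fits = []
    for q in (((0.01, 0.75), (0.25, 0.99))[not lower_is_similar],
              ((0.01, 0.4, 0.8), (0.2, 0.6, 0.99))[not lower_is_similar]):
        init = np.quantile(values, q).reshape(-1, 1)
        gm = GaussianMixture(n_components=len(q), random_state=seed,
                             n_init=1, means_init=init).fit(x)
        fits.append((gm.bic(x), gm))
    gm = min(fits, key=lambda t: t[0])[1]

    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    # components are split into a similar and a dissimilar group at the
    # largest gap between adjacent means (a wide mode may be modelled by
    # two components); the threshold lies in that gap
    gap = int(np.argmax(np.diff(mu)))
    lo_grp = list(range(gap + 1))
    hi_grp = list(range(gap + 1, len(mu)))
    sim_grp, rest_grp = (lo_grp, hi_grp) if lower_is_similar else (hi_grp, lo_grp)
    if abs(mu[gap + 1] - mu[gap]) < separability * (sd[gap] + sd[gap + 1]):
        raise ValueError(
            "metric marginal is not separably bimodal "
            f"(means {mu[gap]:.3g}/{mu[gap + 1]:.3g}, "
            f"sds {sd[gap]:.3g}/{sd[gap + 1]:.3g}); "
            "supply a manual threshold override")

    def group_logpdf(t, grp):
        lp = np.array([np.log(w[i]) + norm.logpdf(t, mu[i], sd[i]) for i in grp])
        m = lp.max()
        return m + np.log(np.exp(lp - m).sum())

    def logpost_diff(t):
        return group_logpdf(t, sim_grp) - group_logpdf(t, rest_grp)

    try:
        thr = brentq(logpost_diff, mu[gap], mu[gap + 1])
    except ValueError:
        # no sign change in the gap (rare, very unequal weights): fall back
        # to the mixture-density minimum on a grid
        grid = np.linspace(mu[gap], mu[gap + 1], 512)
        dens = sum(w[i] * norm.pdf(grid, mu[i], sd[i]) for i in range(len(mu)))
        thr = float(grid[np.argmin(dens)])
    return float(thr)


def fit_thresholds(pairwise: PairwiseSimilarity,
                   overrides: dict | None = None,
                   separability: float = 1.0,
                   seed: int = 0) -> ThresholdSet:
    """Fit the dual thresholds for all three metrics from the pair tables.

    Each metric's marginal over burst pairs is fitted with a two-component
    Gaussian mixture; the threshold is the equal-posterior valley point.
    The initial-state-correlation threshold is fitted once from its own
    bimodal marginal and paired with every metric.  ``overrides`` may pin
    any threshold verbatim: keys among ``corr2``, ``com_distance``,
    ``spatial_corr``, ``initial``.
    """
    overrides = dict(overrides or {})
    metric_thr: dict[str, float] = {}
    for m in METRICS:
        if m in overrides:
            metric_thr[m] = float(overrides[m])
        elif m == "com_distance":
            # distances are positive with a right-skewed different-attractor
            # bulk; the mixture is fitted on the log scale where both modes
            # are near-Gaussian
            vals = pairwise.upper_values(m)
            with np.errstate(divide="ignore"):
                logvals = np.log(vals[vals > 0])
            metric_thr[m] = float(np.exp(_gmm_threshold(
                logvals, lower_is_similar=True,
                separability=separability, seed=seed)))
        else:
            metric_thr[m] = _gmm_threshold(pairwise.upper_values(m),
                                           lower_is_similar=False,
                                           separability=separability, seed=seed)
    if "initial" in overrides:
        init_thr = float(overrides["initial"])
    else:
        init_thr = _gmm_threshold(pairwise.upper_values("initial_corr"),
                                  lower_is_similar=False,
                                  separability=separability, seed=seed)
    return ThresholdSet(metric_thresholds=metric_thr,
                        initial_thresholds={m: init_thr for m in METRICS})


def build_graph(pairwise: PairwiseSimilarity,
                thresholds: ThresholdSet) -> SimilarityGraph:
    """Sum the three thresholded metric graphs into one 0-3 weighted graph.

    Per metric, a pair is linked iff its initial-state correlation passes
    that metric's initial threshold AND the metric itself passes (>= for
    correlations, <= for the COM distance).  NaN (undefined) values never
    pass.  Diagonal is zero by convention.
    """
    b = pairwise.n_bursts
    w = np.zeros((b, b), dtype=np.int8)
    for m in METRICS:
        vals = getattr(pairwise, m)
        thr = thresholds.metric_thresholds[m]
        with np.errstate(invalid="ignore"):
            passes = (vals <= thr) if m == "com_distance" else (vals >= thr)
            init_ok = pairwise.initial_corr >= thresholds.initial_thresholds[m]
        passes &= ~np.isnan(vals) & ~np.isnan(pairwise.initial_corr)
        w += (passes & init_ok).astype(np.int8)
    np.fill_diagonal(w, 0)
    return SimilarityGraph(weights=w)


def _kmedoids(points: np.ndarray, k: int, rng: np.random.Generator,
              n_restarts: int = 20, max_iter: int = 100) -> np.ndarray:
    """Alternating (Voronoi) k-medoids on Euclidean distances.

    Deterministic under the supplied generator; keeps the best of
    ``n_restarts`` random initialisations by total within-cluster distance.
    Returns integer labels 0..k-1.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    best_cost = np.inf
    best_labels = np.zeros(n, dtype=int)
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(d[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if len(members) == 0:
                    # re-seed an empty cluster at the point farthest from
                    # its medoid (deterministic)
                    far = np.argmax(d[np.arange(n), medoids[labels]])
                    new_medoids[c] = far
                    continue
                sub = d[np.ix_(members, members)]
                new_medoids[c] = members[np.argmin(sub.sum(axis=1))]
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        labels = np.argmin(d[:, medoids], axis=1)
        cost = d[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_labels = labels.copy()
            best_medoids = medoids.copy()
    return best_labels, best_medoids, d


def select_k_eigengap(eigenvalues: np.ndarray, k_max: int = 25) -> int:
    """Eigengap heuristic: k = position of the largest gap in the sorted
    Laplacian spectrum (restricted to the first ``k_max`` eigenvalues)."""
    lam = np.sort(np.asarray(eigenvalues))[:k_max + 1]
    gaps = np.diff(lam)
    if len(gaps) == 0:
        return 1
    return int(np.argmax(gaps)) + 1


def spectral_cluster(graph: SimilarityGraph, k: int | str = "auto",
                     seed: int = 0, min_frac: float = 0.02,
                     thresholds: ThresholdSet | None = None,
                     k_max: int = 25) -> Vocabulary:
    """Cluster the similarity graph into the network's burst vocabulary.

    Zero-degree bursts are unclassified a priori.  On the remaining graph,
    the spectral embedding uses the k eigenvectors of the normalized
    symmetric Laplacian ``L_s = D^{-1/2} (D - S) D^{-1/2}`` with the
    smallest eigenvalues, rows normalized to unit length, followed by
    seeded k-medoids.  Clusters holding fewer than ``min_frac`` (2%) of all
    bursts are dissolved into the unclassified set.

    ``k='auto'`` chooses k by the eigengap heuristic, capped at ``k_max``.
    """
    b = graph.n_nodes
    if b == 0:
        raise ValueError("empty similarity graph")
    labels = np.full(b, -1, dtype=int)
    deg = graph.degrees()
    active = np.flatnonzero(deg > 0)
    if len(active) == 0:
        warnings.warn("similarity graph has no edges; all bursts unclassified")
        return Vocabulary(labels=labels, k=0,
                          theta=thresholds.theta if thresholds else np.nan,
                          thresholds=thresholds, min_frac=min_frac)

    s = graph.weights[np.ix_(active, active)].astype(float)
    d = s.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    ls = np.eye(len(active)) - (inv_sqrt[:, None] * s * inv_sqrt[None, :])
    n_eig = min(len(active), k_max + 1) if k == "auto" else min(len(active), int(k))
    lam, vec = eigh(ls, subset_by_index=[0, n_eig - 1])

    if k == "auto":
        k_use = select_k_eigengap(lam, k_max=min(k_max, len(lam) - 1))
    else:
        k_use = int(k)
        if k_use < 1 or k_use > len(active):
            raise ValueError(f"k={k_use} outside 1..{len(active)}")
    emb = vec[:, :k_use]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = np.where(norms > 0, emb / norms, 0.0)

    rng = np.random.default_rng(seed)
    sub_labels, sub_medoids, _ = _kmedoids(emb, k_use, rng)
    labels[active] = sub_labels

    # dissolve clusters below the size floor, relabel compactly by size
    keep: list[int] = []
    for c in range(k_use):
        if (labels == c).sum() < min_frac * b:
            labels[labels == c] = -1
        else:
            keep.append(c)
    keep.sort(key=lambda c: -(labels == c).sum())
    remap = {c: i for i, c in enumerate(keep)}
    medoids: dict[int, int] = {}
    new_labels = np.full(b, -1, dtype=int)
    for c, i in remap.items():
        new_labels[labels == c] = i
        medoids[i] = int(active[sub_medoids[c]])

    return Vocabulary(labels=new_labels, k=k_use,
                      theta=thresholds.theta if thresholds else np.nan,
                      thresholds=thresholds, medoids=medoids, min_frac=min_frac)
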