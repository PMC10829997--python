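"""Evoked responses: stimulation sites, the "explains" relation, robustness,
existence, site selection, and stimulated/non-stimulated cluster labeling.

The array is tiled by 20 stimulation sites of 6 adjacent electrodes (3 rows
x 2 columns, disjoint).  Each probed site is pulsed 30 times; the evoked
bursts are compared to the spontaneous vocabulary with the stimulating
electrodes excluded from every correlation.  A spontaneous cluster
*explains* one evoked repetition when enough spontaneous bursts are similar
to it (corr2 above the reduced threshold ``f_th * theta``) and the
plurality of those similar bursts belong to that cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .bursts import Burst
from .geometry import ElectrodeGeometry
from .similarity import corr2
from .vocabulary import Vocabulary

SITE_ROWS = 3   # electrode rows per stimulation site
SITE_COLS = 2   # electrode columns per stimulation site


@dataclass(frozen=True)
class StimulationSite:
    """Block of 6 adjacent electrodes pulsed simultaneously (id 1..20)."""

    site_id: int
    electrodes: tuple[int, ...]


@dataclass
class ExplainParams:
    """Parameters of the explains relation.

    f_th reduces the spontaneous similarity threshold theta when comparing
    evoked to spontaneous bursts (their initial states differ by design);
    m is the minimum percentage of all spontaneous bursts that must be
    similar before a repetition counts as explained at all.
    """

    f_th: float = 0.88
    m: float = 0.5   # percent

    def __post_init__(self):
        if not 0 < self.f_th <= 1:
            raise ValueError("f_th must be in (0, 1]")
        if not 0 < self.m < 100:
            raise ValueError("m must be a percentage in (0, 100)")


@dataclass
class SiteSummary:
    """Robustness / existence summary of one probed site."""

    site_id: int
    robustness: float                 # median pairwise corr2 of the responses
    existence: float                  # clusters needed to explain 50%; inf if unreachable
    explaining: list[int | None]      # per-repetition explaining cluster
    within_corr: np.ndarray = field(default=None, repr=False)
    across_corr: np.ndarray = field(default=None, repr=False)
    uniqueness_p: float = np.nan      # within > across, one-sided


def define_sites(geometry: ElectrodeGeometry) -> list[StimulationSite]:
    """Tile the array into 3x2 stimulation-site blocks.

    Sites are numbered 1..n column-major over blocks (all blocks of the
    first block-column first, top to bottom).  Raises if the grid is not an
    exact multiple of 3 rows x 2 columns.
    """
    if geometry.rows % SITE_ROWS or geometry.cols % SITE_COLS:
        raise ValueError(
            f"{geometry.rows}x{geometry.cols} grid is not tileable by "
            f"{SITE_ROWS}x{SITE_COLS} blocks")
    n_br = geometry.rows // SITE_ROWS
    n_bc = geometry.cols // SITE_COLS
    sites = []
    for bc in range(n_bc):
        for br in range(n_br):
            elecs = tuple(geometry.rowcol_to_index(br * SITE_ROWS + r, bc * SITE_COLS + c)
                          for r in range(SITE_ROWS) for c in range(SITE_COLS))
            sites.append(StimulationSite(site_id=bc * n_br + br + 1, electrodes=elecs))
    return sites


def _valid_rows(n_electrodes: int, excluded: tuple[int, ...]) -> np.ndarray:
    valid = np.ones(n_electrodes, dtype=bool)
    valid[list(excluded)] = False
    return valid


def response_corr2(response: Burst, other: Burst,
                   excluded_electrodes: tuple[int, ...]) -> float:
    """corr2 between two bursts with the stimulating electrodes excluded."""
    valid = _valid_rows(response.matrix.shape[0], excluded_electrodes)
    return corr2(response.matrix, other.matrix,
                 valid=np.broadcast_to(valid[:, None], response.matrix.shape))


def explain_response(response: Burst, spontaneous: list[Burst],
                     vocab: Vocabulary, params: ExplainParams | None = None,
                     excluded_electrodes: tuple[int, ...] = (),
                     _corr_cache: np.ndarray | None = None) -> int | None:
    """Which spontaneous cluster, if any, explains this evoked repetition.

    Similar set = spontaneous bursts with corr2 > f_th * theta (stimulating
    electrodes excluded).  The repetition is explained only if the similar
    set holds at least m% of all spontaneous bursts; the explaining cluster
    is the one owning the plurality of the similar set (unclassified bursts
    do not vote; ties break toward the cluster with higher mean corr2 to
    the response).
    """
    params = params or ExplainParams()
    if vocab.n_bursts == 0 or not spontaneous:
        import warnings
        warnings.warn("empty vocabulary; response cannot be explained")
        return None
    if _corr_cache is not None:
        cors = _corr_cache
    else:
        cors = np.array([response_corr2(response, s, excluded_electrodes)
                         for s in spontaneous])
    with np.errstate(invalid="ignore"):
        similar = cors > params.f_th * vocab.theta
    if similar.sum() < params.m / 100.0 * len(spontaneous):
        return None
    labels = vocab.labels[np.flatnonzero(similar)]
    labels = labels[labels >= 0]
    if len(labels) == 0:
        return None
    counts = np.bincount(labels)
    best = np.flatnonzero(counts == counts.max())
    if len(best) == 1:
        return int(best[0])
    # tie: higher mean corr2 to the response wins
    means = [np.nanmean(cors[similar & (vocab.labels == c)]) for c in best]
    return int(best[int(np.argmax(means))])


def _pairwise_response_corr(responses: list[Burst],
                            excluded: tuple[int, ...]) -> np.ndarray:
    vals = []
    for i in range(len(responses)):
        for j in range(i + 1, len(responses)):
            vals.append(response_corr2(responses[i], responses[j], excluded))
    return np.asarray(vals)


def site_summary(site: StimulationSite, responses: list[Burst],
                 spontaneous: list[Burst], vocab: Vocabulary,
                 params: ExplainParams | None = None,
                 across_responses: list[Burst] | None = None) -> SiteSummary:
    """Robustness, existence, and per-repetition explain labels for a site.

    Robustness is the median of all pairwise corr2 among the responses.
    Existence is the size of the smallest set of clusters (greedy, by
    explained count) jointly explaining at least 50% of the repetitions,
    or infinity if even all clusters fall short.  If responses of the other
    sites are supplied, their cross-correlations feed the uniqueness test
    (one-sided Mann-Whitney: within-site > across-site).
    """
    if len(responses) < 2:
        raise ValueError("site summary needs at least 2 repetitions")
    params = params or ExplainParams()
    excl = site.electrodes
    within = _pairwise_response_corr(responses, excl)
    robustness = float(np.nanmedian(within))

    # precompute the evoked-vs-spontaneous correlation matrix once
    valid = _valid_rows(responses[0].matrix.shape[0], excl)
    vmask = np.broadcast_to(valid[:, None], responses[0].matrix.shape)
    explaining = []
    for r in responses:
        cors = np.array([corr2(r.matrix, s.matrix, valid=vmask) for s in spontaneous])
        explaining.append(explain_response(r, spontaneous, vocab, params,
                                           excluded_electrodes=excl,
                                           _corr_cache=cors))

    counts: dict[int, int] = {}
    for c in explaining:
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    need = 0.5 * len(responses)
    total, n_clusters = 0, 0
    existence: float = np.inf
    for c in sorted(counts, key=lambda c: -counts[c]):
        total += counts[c]
        n_clusters += 1
        if total >= need:
            existence = n_clusters
            break

    across = None
    p = np.nan
    if across_responses:
        across = np.array([response_corr2(r, o, excl)
                           for r in responses for o in across_responses])
        w = within[np.isfinite(within)]
        a = across[np.isfinite(across)]
        if len(w) and len(a):
            p = float(mannwhitneyu(w, a, alternative="greater").pvalue)

    return SiteSummary(site_id=site.site_id, robustness=robustness,
                       existence=existence, explaining=explaining,
                       within_corr=within, across_corr=across, uniqueness_p=p)


@dataclass
class SiteSelection:
    selected: list[int]          # site ids, best first
    complete: bool               # n sites satisfied all criteria
    dendrogram_labels: dict[int, int] = field(default_factory=dict)


def select_sites(summaries: list[SiteSummary], n: int = 3,
                 uniqueness_alpha: float = 0.05,
                 cross_site_corr: dict[tuple[int, int], float] | None = None,
                 dendrogram_cut: float = 0.3) -> SiteSelection:
    """Pick the n most robust sites with unique, mutually distinct responses.

    Quantitative stand-in for the visual selection procedure: sites are
    ranked by robustness; a site qualifies only if its within-site
    correlations stochastically dominate its across-site correlations
    (one-sided rank test at ``uniqueness_alpha``).  When median cross-site
    correlations are supplied, average-linkage clustering of
    ``1 - median corr`` at ``dendrogram_cut`` must place every chosen site
    in a distinct branch.
    """
    if len(summaries) < n:
        raise ValueError(f"need at least {n} probed sites, got {len(summaries)}")
    branch: dict[int, int] = {}
    if cross_site_corr is not None:
        ids = sorted({s.site_id for s in summaries})
        idx = {sid: i for i, sid in enumerate(ids)}
        dm = np.zeros((len(ids), len(ids)))
        for (a, b), v in cross_site_corr.items():
            if a in idx and b in idx and a != b:
                dm[idx[a], idx[b]] = dm[idx[b], idx[a]] = 1.0 - v
        link = average(squareform(dm, checks=False))
        labels = fcluster(link, t=dendrogram_cut, criterion="distance")
        branch = {sid: int(labels[idx[sid]]) for sid in ids}

    ranked = sorted(summaries, key=lambda s: -s.robustness)
    chosen: list[int] = []
    used_branches: set[int] = set()
    for s in ranked:
        if len(chosen) == n:
            break
        if np.isfinite(s.uniqueness_p) and s.uniqueness_p >= uniqueness_alpha:
            continue
        if np.isnan(s.uniqueness_p) and s.within_corr is not None and s.across_corr is not None:
            continue
        if branch:
            b = branch.get(s.site_id)
            if b in used_branches:
                continue
            used_branches.add(b)
        chosen.append(s.site_id)
    return SiteSelection(selected=chosen, complete=len(chosen) == n,
                         dendrogram_labels=branch)


def label_clusters(summaries: list[SiteSummary], vocab: Vocabulary,
                   min_robustness: float = 0.8,
                   max_existence: float = 2) -> tuple[set[int], set[int]]:
    """Split the vocabulary into stimulated and non-stimulated clusters.

    Only sites passing the robust-and-existing qualification (robustness >=
    ``min_robustness`` and existence <= ``max_existence``) contribute.  Per
    qualifying site, the stimulated cluster is the one explaining the most
    repetitions.  Non-stimulated clusters are those explaining zero
    repetitions of *all* probed sites in ``summaries``.  Clusters in
    neither set are excluded from group statistics.
    """
    qualifying = [s for s in summaries
                  if s.robustness >= min_robustness and s.existence <= max_existence]
    stimulated: set[int] = set()
    for s in qualifying:
        counts: dict[int, int] = {}
        for c in s.explaining:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            stimulated.add(max(counts, key=lambda c: counts[c]))
    ever_explaining: set[int] = set()
    for s in summaries:
        ever_explaining.update(c for c in s.explaining if c is not None)
    non_stimulated = {c for c in vocab.cluster_ids if c not in ever_explaining}
    return stimulated, non_stimulated
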