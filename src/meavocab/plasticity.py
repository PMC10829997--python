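"""Stimulation-induced vocabulary changes.

The central statistic is the empirical-CDF shift

    dCDF(alpha) = alpha - CDF_after(x_alpha),   x_alpha = Q_before(alpha)

computed on correlation samples between a reference pattern and the
spontaneous bursts of each epoch, over a grid of high quantiles
(alpha in [0.75, 0.95]).  Negative values mean the high-correlation tail
shrank after stimulation — the pattern is disappearing from the
spontaneous vocabulary.  Supporting analyses: per-network z-scoring and
group comparisons (stimulated vs non-stimulated clusters, stimulation vs
control networks), evoked-response variability in 30-minute windows, and
the initial-state basin analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, permutation_test

from .bursts import Burst
from .similarity import corr2, initial_state_corr
from .vocabulary import Vocabulary

DEFAULT_ALPHA_GRID = np.round(np.arange(0.75, 0.95 + 1e-9, 0.025), 4)


@dataclass
class DeltaCDFResult:
    """dCDF of one reference pattern between two epochs."""

    pattern: int | str
    alphas: np.ndarray
    delta_cdf: np.ndarray
    before_samples: np.ndarray = field(repr=False, default=None)
    after_samples: np.ndarray = field(repr=False, default=None)
    z_scored: np.ndarray | None = None
    network: str | int | None = None
    insufficient: bool = False


def empirical_cdf_at(samples: np.ndarray, x: float) -> float:
    """Right-continuous empirical CDF: P(sample <= x)."""
    samples = np.asarray(samples, dtype=float)
    return float(np.count_nonzero(samples <= x) / len(samples))


def delta_cdf(before: np.ndarray, after: np.ndarray,
              alphas: np.ndarray | None = None,
              pattern: int | str = 0) -> DeltaCDFResult:
    """Empirical-CDF shift between two correlation samples.

    For each alpha: ``x_alpha`` is the inverse-CDF (type-1) empirical
    alpha-quantile of the before sample; the statistic is
    ``alpha - CDF_after(x_alpha)`` with a right-continuous after-CDF.
    Values lie in ``[alpha - 1, alpha]``; identical samples give 0 up to
    the empirical-CDF step resolution (1/n).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) == 0 or len(after) == 0:
        raise ValueError("before and after samples must be nonempty")
    alphas = DEFAULT_ALPHA_GRID if alphas is None else np.asarray(alphas, dtype=float)
    x_a = np.quantile(before, alphas, method="inverted_cdf")
    d = np.array([a - empirical_cdf_at(after, x) for a, x in zip(alphas, x_a)])
    return DeltaCDFResult(pattern=pattern, alphas=alphas, delta_cdf=d,
                          before_samples=before, after_samples=after)


def _cross_corr_samples(reference: list[Burst], population: list[Burst]) -> np.ndarray:
    """corr2 of every (reference, population) pair, self-pairs excluded.

    Self-pairs are identified by object identity, so a reference burst
    drawn from the population never contributes its trivial 1.0.
    """
    ref_ids = {id(r) for r in reference}
    vals = []
    for r in reference:
        for p in population:
            if id(p) in ref_ids:
                continue
            vals.append(corr2(r.matrix, p.matrix))
    return np.asarray(vals)


def pattern_existence_change(reference: list[Burst],
                             spont_before: list[Burst],
                             spont_after: list[Burst],
                             alphas: np.ndarray | None = None,
                             pattern: int | str = 0) -> DeltaCDFResult:
    """dCDF of a cluster's similarity to the spontaneous population.

    The before/after samples are all corr2 values between the reference
    bursts (e.g. one cluster's members before stimulation) and the
    respective epoch's spontaneous bursts, reference self-pairs excluded.
    """
    if not reference:
        raise ValueError("reference burst set is empty")
    if not spont_before or not spont_after:
        raise ValueError("both epochs need at least one spontaneous burst")
    before = _cross_corr_samples(reference, spont_before)
    after = _cross_corr_samples(reference, spont_after)
    res = delta_cdf(before[np.isfinite(before)], after[np.isfinite(after)],
                    alphas, pattern=pattern)
    return res


def z_score_within_network(results: list[DeltaCDFResult]) -> None:
    """Z-score dCDF values within each network, in place.

    All (pattern, alpha) values of one network are pooled to estimate the
    network's mean and sd, removing between-network differences in
    correlation scale and baseline drift before pooling across networks.
    Networks contributing a single value cannot be z-scored and are
    excluded (z left None) with a warning.
    """
    by_net: dict = {}
    for r in results:
        by_net.setdefault(r.network, []).append(r)
    for net, rs in by_net.items():
        vals = np.concatenate([r.delta_cdf for r in rs])
        if len(vals) < 2 or np.std(vals) == 0:
            warnings.warn(f"network {net!r} has too few dCDF values to z-score; excluded")
            continue
        mu, sd = vals.mean(), vals.std()
        for r in rs:
            r.z_scored = (r.delta_cdf - mu) / sd


@dataclass
class GroupComparison:
    alphas: np.ndarray
    group_a: dict[float, np.ndarray]
    group_b: dict[float, np.ndarray]
    p_values: np.ndarray       # per alpha, one-sided: effect in A larger (more negative)


def group_compare(results_a: list[DeltaCDFResult],
                  results_b: list[DeltaCDFResult],
                  z_score: bool = False,
                  exact_max_n: int = 12,
                  seed: int = 0) -> GroupComparison:
    """Per-alpha one-sided comparison of two groups of dCDF results.

    Tests, at each alpha, whether group A's effect is larger — i.e. its
    dCDF values are more negative — than group B's.  With ``z_score`` the
    values are first z-scored within network across both groups.  The test
    is a one-sided Mann-Whitney U; for small samples (both groups at most
    ``exact_max_n``) an exact permutation test on the difference of means
    is used instead.
    """
    for g in (results_a, results_b):
        if len(g) < 2:
            raise ValueError("each group needs at least 2 dCDF results")
    if z_score:
        z_score_within_network(results_a + results_b)
        take = lambda r: r.z_scored
    else:
        take = lambda r: r.delta_cdf
    alphas = results_a[0].alphas
    ga, gb, ps = {}, {}, []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(alphas):
        va = np.array([take(r)[i] for r in results_a if take(r) is not None])
        vb = np.array([take(r)[i] for r in results_b if take(r) is not None])
        ga[float(a)] = va
        gb[float(a)] = vb
        if len(va) <= exact_max_n and len(vb) <= exact_max_n:
            res = permutation_test(
                (va, vb), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
                alternative="less", permutation_type="independent",
                n_resamples=20000, rng=rng)
            ps.append(float(res.pvalue))
        else:
            ps.append(float(mannwhitneyu(va, vb, alternative="less").pvalue))
    return GroupComparison(alphas=alphas, group_a=ga, group_b=gb,
                           p_values=np.asarray(ps))


@dataclass
class EvokedVariability:
    """Evoked-response variability in chronological fixed-length windows."""

    window_min: float
    window_times_min: np.ndarray      # window start, minutes from session start
    deviations: np.ndarray            # mean Euclidean deviation from window mean
    normalized: np.ndarray            # deviations / first finite window's value
    degenerate: bool = False          # all-zero deviations (0/0 convention -> ones)


def evoked_variability(responses: list[Burst], times_ms: np.ndarray,
                       window_min: float = 30.0) -> EvokedVariability:
    """Mean deviation from the window-mean response, per 30-minute window.

    In each window the mean flattened response is computed and the mean
    Euclidean distance of the window's responses from it is recorded; the
    series is normalized by the first window's value.  Empty windows yield
    NaN gaps.  If every deviation is zero (identical responses), the
    normalized series is defined as all ones and flagged degenerate.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if len(times_ms) != len(responses):
        raise ValueError("one timestamp per response required")
    w_ms = window_min * 60e3
    t0 = times_ms.min()
    span = times_ms.max() - t0
    n_win = int(np.floor(span / w_ms)) + 1
    if n_win < 2:
        raise ValueError("responses must span at least 2 windows")
    flat = np.stack([r.matrix.ravel() for r in responses])
    devs = np.full(n_win, np.nan)
    for w in range(n_win):
        sel = (times_ms >= t0 + w * w_ms) & (times_ms < t0 + (w + 1) * w_ms)
        if not sel.any():
            continue
        mean = flat[sel].mean(axis=0)
        devs[w] = float(np.linalg.norm(flat[sel] - mean, axis=1).mean())
    finite = np.flatnonzero(np.isfinite(devs))
    first = devs[finite[0]] if len(finite) else np.nan
    # identical responses: deviations are zero up to float rounding
    tol = 1e-9 * float(np.linalg.norm(flat.mean(axis=0)))
    degenerate = bool(np.nanmax(devs) <= tol) if len(finite) else True
    if degenerate:
        normalized = np.where(np.isfinite(devs), 1.0, np.nan)
    else:
        normalized = devs / first
    return EvokedVariability(window_min=window_min,
                             window_times_min=np.arange(n_win) * window_min,
                             deviations=devs, normalized=normalized,
                             degenerate=degenerate)


def basin_analysis(bursts_before: list[Burst], bursts_after: list[Burst],
                   reference: list[Burst], initial_threshold: float,
                   vocab: Vocabulary | None = None,
                   reference_cluster: int | None = None,
                   criterion: str = "medoid",
                   alphas: np.ndarray | None = None,
                   pattern: int | str = "basin") -> DeltaCDFResult:
    """Do the same initial states still lead to the same bursts?

    Candidate set per epoch: bursts whose initial-state correlation to the
    reference cluster's initial states exceeds ``initial_threshold`` — by
    default against the cluster medoid's initial state (``criterion=
    'medoid'``), optionally against any member (``'any'``).  The dCDF is
    computed between the epochs' within-candidate-set pairwise corr2
    samples; a negative shift means bursts launched from the old basin no
    longer converge to a common pattern.
    """
    if len(reference) < 2:
        raise ValueError("reference cluster needs at least 2 members before stimulation")
    if criterion not in ("medoid", "any"):
        raise ValueError("criterion must be 'medoid' or 'any'")
    if criterion == "medoid":
        if vocab is not None and reference_cluster is not None \
                and reference_cluster in vocab.medoids:
            ref_states = [reference[0]]  # placeholder, replaced below
            medoid_id = vocab.medoids[reference_cluster]
            members = vocab.members(reference_cluster)
            # medoid burst must be among the reference bursts
            pos = {int(m): i for i, m in enumerate(members)}
            ref_states = [reference[pos[medoid_id]]] if medoid_id in pos else [reference[0]]
        else:
            # medoid of the reference set itself: member with the highest
            # mean initial-state correlation to the others
            isc = np.array([[initial_state_corr(a, b) for b in reference]
                            for a in reference])
            ref_states = [reference[int(np.nanargmax(np.nanmean(isc, axis=1)))]]
    else:
        ref_states = list(reference)

    def candidates(bursts: list[Burst]) -> list[Burst]:
        out = []
        for b in bursts:
            cs = [initial_state_corr(b, r) for r in ref_states]
            if np.nanmax(cs) > initial_threshold:
                out.append(b)
        return out

    cand_b = candidates(bursts_before)
    cand_a = candidates(bursts_after)
    alphas = DEFAULT_ALPHA_GRID if alphas is None else np.asarray(alphas, dtype=float)
    if len(cand_b) < 2 or len(cand_a) < 2:
        return DeltaCDFResult(pattern=pattern, alphas=alphas,
                              delta_cdf=np.full(len(alphas), np.nan),
                              insufficient=True)

    def pair_samples(cands: list[Burst]) -> np.ndarray:
        vals = [corr2(cands[i].matrix, cands[j].matrix)
                for i in range(len(cands)) for j in range(i + 1, len(cands))]
        vals = np.asarray(vals)
        return vals[np.isfinite(vals)]

    return delta_cdf(pair_samples(cand_b), pair_samples(cand_a), alphas,
                     pattern=pattern)
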