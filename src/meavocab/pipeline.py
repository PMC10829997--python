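"""High-level pipeline: events -> bursts -> vocabulary -> evoked/plasticity.

Convenience wrappers chaining the stage modules with their default
parameters, used by the CLI, the acceptance script, and end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst, BurstWindow, DetectionParams, detect_bursts, extract_bursts
from .geometry import ElectrodeGeometry, make_geometry
from .preprocess import ActivityMatrix, SummedTrace, mask_stimulation, smooth_and_bin, sum_activity
from .similarity import PairwiseSimilarity, pairwise_similarity
from .vocabulary import SimilarityGraph, ThresholdSet, Vocabulary, build_graph, fit_thresholds, spectral_cluster


@dataclass
class EpochAnalysis:
    """All per-epoch intermediates from events to extracted bursts."""

    matrix: ActivityMatrix
    trace: SummedTrace
    windows: list[BurstWindow]
    bursts: list[Burst]


def analyze_epoch(events: pd.DataFrame, geometry: ElectrodeGeometry | None = None,
                  epoch: str = "before", kind: str = "spontaneous",
                  duration_ms: float | None = None,
                  stim_log: pd.DataFrame | None = None,
                  params: DetectionParams | None = None,
                  keep_matrix: bool = False) -> EpochAnalysis:
    """Smooth, bin, (optionally) mask, detect and extract bursts."""
    geometry = geometry or make_geometry()
    params = params or DetectionParams()
    matrix = smooth_and_bin(events, geometry, duration_ms=duration_ms)
    if stim_log is not None and len(stim_log):
        matrix = mask_stimulation(matrix, stim_log)
    trace = sum_activity(matrix)
    windows = detect_bursts(trace, params)
    bursts = extract_bursts(matrix, windows, window_ms=params.window_ms,
                            kind=kind, epoch=epoch)
    if not keep_matrix:
        matrix = ActivityMatrix(values=np.empty((geometry.n_electrodes, 0)),
                                bin_ms=matrix.bin_ms, start_ms=matrix.start_ms,
                                geometry=geometry)
    return EpochAnalysis(matrix=matrix, trace=trace, windows=windows, bursts=bursts)


@dataclass
class VocabularyFit:
    pairwise: PairwiseSimilarity
    thresholds: ThresholdSet
    graph: SimilarityGraph
    vocabulary: Vocabulary


def build_vocabulary(bursts: list[Burst], geometry: ElectrodeGeometry | None = None,
                     k: int | str = "auto", seed: int = 0,
                     threshold_overrides: dict | None = None) -> VocabularyFit:
    """Pairwise metrics -> bimodal thresholds -> 0-3 graph -> vocabulary."""
    geometry = geometry or make_geometry()
    pw = pairwise_similarity(bursts, geometry)
    thr = fit_thresholds(pw, overrides=threshold_overrides)
    graph = build_graph(pw, thr)
    vocab = spectral_cluster(graph, k=k, seed=seed, thresholds=thr)
    return VocabularyFit(pairwise=pw, thresholds=thr, graph=graph, vocabulary=vocab)


def extract_evoked_responses(events: pd.DataFrame, stim_log: pd.DataFrame,
                             geometry: ElectrodeGeometry | None = None,
                             epoch: str = "probe",
                             window_ms: float = 100.0,
                             search_ms: float = 500.0,
                             params: DetectionParams | None = None,
                             apply_mask: bool = True
                             ) -> tuple[dict[int, list[Burst]], np.ndarray]:
    """Detect one evoked burst per stimulation pulse.

    The activity matrix is artifact-masked, bursts are detected on the
    summed trace, and each pulse is matched to the first detected burst
    starting within ``search_ms`` after it.  Returns the responses grouped
    by site id and the per-pulse response onset times (NaN where no burst
    followed the pulse).
    """
    geometry = geometry or make_geometry()
    params = params or DetectionParams()
    matrix = smooth_and_bin(events, geometry)
    if apply_mask:
        matrix = mask_stimulation(matrix, stim_log)
    trace = sum_activity(matrix)
    windows = detect_bursts(trace, params)
    bursts = extract_bursts(matrix, windows, window_ms=params.window_ms,
                            kind="evoked", epoch=epoch)
    starts = np.array([b.start_ms for b in bursts])
    by_site: dict[int, list[Burst]] = {}
    onset_times = np.full(len(stim_log), np.nan)
    used = np.zeros(len(bursts), dtype=bool)
    for i, (_, row) in enumerate(stim_log.iterrows()):
        p = float(row["pulse_time_ms"])
        sid = int(row["site"])
        cand = np.flatnonzero((starts >= p) & (starts < p + search_ms) & ~used)
        if len(cand) == 0:
            continue
        j = int(cand[0])
        used[j] = True
        b = bursts[j]
        b.site = sid
        by_site.setdefault(sid, []).append(b)
        onset_times[i] = b.start_ms
    return by_site, onset_times


def match_onsets(detected_ms: np.ndarray, truth_ms: np.ndarray,
                 tol_ms: float = 50.0) -> tuple[float, float, int]:
    """Greedy one-to-one matching of detected to ground-truth burst onsets.

    Returns ``(recall, precision, n_matched)`` with a match requiring
    |detected - truth| <= ``tol_ms``.
    """
    detected = np.sort(np.asarray(detected_ms, dtype=float))
    truth = np.sort(np.asarray(truth_ms, dtype=float))
    i = j = matched = 0
    while i < len(detected) and j < len(truth):
        d = detected[i] - truth[j]
        if abs(d) <= tol_ms:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    recall = matched / len(truth) if len(truth) else np.nan
    precision = matched / len(detected) if len(detected) else np.nan
    return recall, precision, matched


def match_clusters_to_templates(vocab: Vocabulary, template_labels: np.ndarray
                                ) -> dict[int, int]:
    """Majority-vote map from vocabulary cluster id to planted template id."""
    mapping: dict[int, int] = {}
    for c in vocab.cluster_ids:
        members = vocab.members(c)
        tl = template_labels[members]
        tl = tl[tl >= 0]
        if len(tl):
            mapping[c] = int(np.bincount(tl).argmax())
    return mapping
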