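"""Network-burst detection and extraction.

A network burst is detected on the summed activity trace: an upward
crossing of ``hi * sigma`` (default 4 sigma) triggers the event, and the
event is extended backward and forward to the nearest ``lo * sigma``
(default 0.5 sigma) crossings, which define its start and end.  Sigma is
the standard deviation of the whole epoch's summed trace, recomputed per
network and per epoch.  Analysis focuses on the first 100 ms of each burst
(20 bins of 5 ms), where the variability between repetitions of a pattern
is largest; the 120-dimensional activity in the first bin is the burst's
*initial state*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ActivityMatrix, SummedTrace


@dataclass
class DetectionParams:
    hi: float = 4.0          # trigger threshold, multiples of sigma
    lo: float = 0.5          # extent threshold, multiples of sigma
    window_ms: float = 100.0  # analysis window from burst start
    min_gap_bins: int = 0     # windows closer than this are merged

    def __post_init__(self):
        if not self.hi > self.lo > 0:
            raise ValueError(f"need hi > lo > 0, got hi={self.hi}, lo={self.lo}")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")


@dataclass
class BurstWindow:
    """One detected burst: bins on the epoch's summed trace."""

    start_bin: int    # first bin of the lo-exceedance run
    trigger_bin: int  # first hi-crossing bin
    end_bin: int      # last bin of the lo-exceedance run (inclusive)
    truncated: bool = False  # clipped by a recording edge

    def duration_ms(self, bin_ms: float) -> float:
        return (self.end_bin - self.start_bin + 1) * bin_ms


@dataclass
class Burst:
    """Fixed-length burst matrix with provenance.

    ``matrix`` is the N x T (120 x 20) slice of the activity matrix starting
    at the burst start; ``initial_state`` is its first column (the first
    5 ms of activity on all electrodes).
    """

    matrix: np.ndarray          # (N, T)
    initial_state: np.ndarray   # (N,)
    start_ms: float
    kind: str = "spontaneous"   # spontaneous | evoked
    epoch: str = "before"       # before | after | control | probe
    site: int = -1              # stimulation site id for evoked bursts
    window: BurstWindow | None = None
    padded: bool = False        # burst shorter than the analysis window
    mask: np.ndarray | None = field(default=None, repr=False)  # (N, T) validity
    burst_id: int = -1

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.matrix.shape, dtype=bool)


def detect_bursts(trace: SummedTrace, params: DetectionParams | None = None,
                  include_truncated: bool = False) -> list[BurstWindow]:
    """Detect network bursts by dual threshold crossing on the summed trace.

    Triggers on upward ``hi*sigma`` crossings and extends each event to the
    surrounding ``lo*sigma`` crossings.  Triggers falling inside the same
    lo-exceedance run are merged into a single window.  Windows clipped by
    the recording edges are flagged and excluded unless
    ``include_truncated``.
    """
    params = params or DetectionParams()
    x = trace.values
    if trace.sigma == 0:
        warnings.warn("summed trace is constant (sigma = 0); no bursts detected")
        return []
    above_lo = x >= params.lo * trace.sigma
    above_hi = x >= params.hi * trace.sigma
    trigger = above_hi & ~np.concatenate([[False], above_hi[:-1]])

    # label contiguous lo-exceedance runs
    run_start = above_lo & ~np.concatenate([[False], above_lo[:-1]])
    run_id = np.where(above_lo, np.cumsum(run_start), 0)

    windows: list[BurstWindow] = []
    seen: set[int] = set()
    for t in np.flatnonzero(trigger):
        rid = run_id[t]
        if rid == 0 or rid in seen:
            continue
        seen.add(rid)
        run = np.flatnonzero(run_id == rid)
        w = BurstWindow(start_bin=int(run[0]), trigger_bin=int(t), end_bin=int(run[-1]))
        w.truncated = run[0] == 0 or run[-1] == len(x) - 1
        windows.append(w)

    if params.min_gap_bins > 0 and len(windows) > 1:
        merged = [windows[0]]
        for w in windows[1:]:
            prev = merged[-1]
            if w.start_bin - prev.end_bin - 1 < params.min_gap_bins:
                prev.end_bin = w.end_bin
                prev.truncated = prev.truncated or w.truncated
            else:
                merged.append(w)
        windows = merged

    if not include_truncated:
        windows = [w for w in windows if not w.truncated]
    return windows


def extract_bursts(matrix: ActivityMatrix, windows: list[BurstWindow],
                   window_ms: float = 100.0,
                   anchor: str = "start",
                   kind: str = "spontaneous", epoch: str = "before",
                   site: int = -1) -> list[Burst]:
    """Slice fixed-length burst matrices out of the activity matrix.

    Each burst is the ``window_ms`` (100 ms = 20 bin) slice beginning at
    the window's start bin (``anchor='start'``) or at its hi-threshold
    trigger bin (``anchor='trigger'``).  Bursts whose lo-to-lo extent ends
    inside the slice are zero-padded beyond their end and flagged
    ``padded``; windows running past the recording end are dropped with a
    warning.
    """
    if anchor not in ("start", "trigger"):
        raise ValueError("anchor must be 'start' or 'trigger'")
    t_bins = int(round(window_ms / matrix.bin_ms))
    if t_bins < 1 or abs(t_bins * matrix.bin_ms - window_ms) > 1e-9:
        raise ValueError("window_ms must be a positive multiple of the bin width")
    out: list[Burst] = []
    dropped = 0
    for w in windows:
        b0 = w.start_bin if anchor == "start" else w.trigger_bin
        b1 = b0 + t_bins
        if b1 > matrix.n_bins:
            dropped += 1
            continue
        sl = matrix.values[:, b0:b1].copy()
        msk = matrix.mask[:, b0:b1].copy()
        padded = w.end_bin < b1 - 1
        if padded:
            sl[:, w.end_bin - b0 + 1:] = 0.0
        burst = Burst(matrix=sl, initial_state=sl[:, 0].copy(),
                      start_ms=matrix.start_ms + b0 * matrix.bin_ms,
                      kind=kind, epoch=epoch, site=site,
                      window=w, padded=padded, mask=msk, burst_id=len(out))
        out.append(burst)
    if dropped:
        warnings.warn(f"dropped {dropped} burst window(s) extending past the recording end")
    return out


def burst_stats(bursts: list[Burst], epoch_duration_ms: float,
                trace: SummedTrace | None = None,
                min_duration_ms: float = 250.0,
                profile_ms: float = 250.0) -> dict:
    """Summary statistics of a burst population.

    Returns bursts/hour and bursts/min, the duration distribution, and
    (when the summed trace is supplied) the mean +- std summed-activity
    profile across bursts lasting at least ``min_duration_ms``.
    """
    hours = epoch_duration_ms / 3.6e6
    durations = np.array([b.window.duration_ms(5.0 if trace is None else trace.bin_ms)
                          for b in bursts if b.window is not None])
    stats = {
        "n_bursts": len(bursts),
        "bursts_per_hour": len(bursts) / hours if hours > 0 else np.nan,
        "bursts_per_min": len(bursts) / (hours * 60) if hours > 0 else np.nan,
        "durations_ms": durations,
        "mean_profile": None,
        "std_profile": None,
    }
    if trace is not None and len(bursts):
        n_bins = int(round(profile_ms / trace.bin_ms))
        profs = []
        for b in bursts:
            if b.window is None or b.window.duration_ms(trace.bin_ms) < min_duration_ms:
                continue
            s = b.window.start_bin
            if s + n_bins <= len(trace.values):
                profs.append(trace.values[s:s + n_bins])
        if profs:
            profs = np.asarray(profs)
            stats["mean_profile"] = profs.mean(axis=0)
            stats["std_profile"] = profs.std(axis=0)
            stats["n_long_bursts"] = len(profs)
    return stats
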