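"""Pairwise burst-similarity metrics.

Three complementary views of a burst pair (X1, X2 in R^{N x T}):

* ``corr2`` — Pearson correlation of the flattened matrices ("2D
  correlation"), the primary similarity measure.
* ``com_distance`` — the bursts' activity centres of mass trace 2-D paths
  over the array; the distance is the summed per-bin Euclidean distance
  between the two paths (mm * bins).
* ``spatial_corr`` — Pearson correlation of the time-summed spatial
  profiles (which electrodes were active, regardless of when).

plus ``initial_state_corr``, the Pearson correlation of the two
120-dimensional first-bin vectors.  Pairs where a metric is undefined
(zero variance, no jointly valid bins) get NaN and are treated as
dissimilar downstream, never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bursts import Burst
from .geometry import ElectrodeGeometry


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float((a @ b) / (na * nb))


def corr2(x1: np.ndarray, x2: np.ndarray,
          valid: np.ndarray | None = None) -> float:
    """2D correlation: Pearson correlation of the flattened burst matrices.

    ``valid`` restricts the computation to a common support (e.g. excluding
    stimulating electrodes when comparing evoked to spontaneous bursts).
    Returns NaN if either matrix has zero variance over the support.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if not valid.any():
            return np.nan
        x1 = x1[valid]
        x2 = x2[valid]
    return _pearson(x1, x2)


def com_trajectory(x: np.ndarray, geometry: ElectrodeGeometry,
                   normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Centre-of-mass path of a burst over the array.

    Per time bin, the activity-weighted average of electrode positions:
    ``com[t] = sum_n x_n * X[n, t] / sum_n X[n, t]``.  Bins with zero total
    activity are invalid (the centre of mass is undefined there).

    Returns ``(com, valid)`` with ``com`` of shape (2, T) in mm and
    ``valid`` a length-T boolean flag.  ``normalized=False`` skips the
    denominator (raw weighted sum), provided as an escape hatch.
    """
    x = np.asarray(x, dtype=float)
    total = x.sum(axis=0)
    valid = total > 0
    num = geometry.coords.T @ x      # (2, T)
    com = np.full_like(num, np.nan)
    if normalized:
        com[:, valid] = num[:, valid] / total[valid]
    else:
        com[:, valid] = num[:, valid]
    return com, valid


def com_distance(x1: np.ndarray, x2: np.ndarray, geometry: ElectrodeGeometry,
                 normalized: bool = True) -> float:
    """Euclidean distance between two centre-of-mass trajectories.

    Sum over time bins of the per-bin Euclidean distance, restricted to
    bins valid in both bursts and rescaled by T / n_valid so values stay
    comparable across pairs with different valid-bin counts.  NaN if no
    bin is valid in both.
    """
    c1, v1 = com_trajectory(x1, geometry, normalized)
    c2, v2 = com_trajectory(x2, geometry, normalized)
    both = v1 & v2
    n_valid = int(both.sum())
    if n_valid == 0:
        return np.nan
    d = np.linalg.norm(c1[:, both] - c2[:, both], axis=0).sum()
    return float(d * (x1.shape[1] / n_valid))


def spatial_profile(x: np.ndarray) -> np.ndarray:
    """Per-electrode total activity over the burst (length-N vector)."""
    return np.asarray(x, dtype=float).sum(axis=1)


def spatial_corr(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation of the two bursts' spatial profiles."""
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return _pearson(spatial_profile(x1), spatial_profile(x2))


def initial_state_corr(b1: Burst | np.ndarray, b2: Burst | np.ndarray) -> float:
    """Pearson correlation of the two bursts' 120-d initial-state vectors."""
    v1 = b1.initial_state if isinstance(b1, Burst) else np.asarray(b1, dtype=float)
    v2 = b2.initial_state if isinstance(b2, Burst) else np.asarray(b2, dtype=float)
    return _pearson(v1, v2)


@dataclass
class PairwiseSimilarity:
    """All pairwise metrics over a burst population (symmetric B x B arrays)."""

    corr2: np.ndarray
    com_distance: np.ndarray
    spatial_corr: np.ndarray
    initial_corr: np.ndarray

    @property
    def n_bursts(self) -> int:
        return self.corr2.shape[0]

    def upper_values(self, metric: str) -> np.ndarray:
        """Upper-triangle (i < j) values of one metric, NaNs included."""
        m = getattr(self, metric)
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]


def _standardize_rows(flat: np.ndarray) -> np.ndarray:
    """Rows to zero mean / unit norm; zero-variance rows become NaN rows."""
    c = flat - flat.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(nrm > 0, c / nrm, np.nan)
    return z


def pairwise_similarity(bursts: list[Burst],
                        geometry: ElectrodeGeometry) -> PairwiseSimilarity:
    """Compute all four metrics for every burst pair (vectorised).

    Self-pairs get corr2 = spatial_corr = initial_corr = 1 and
    com_distance = 0 by construction.
    """
    b = len(bursts)
    mats = np.stack([bb.matrix for bb in bursts])          # (B, N, T)
    flat = mats.reshape(b, -1)

    z = _standardize_rows(flat)
    c2 = z @ z.T
    np.clip(c2, -1.0, 1.0, out=c2)

    zsp = _standardize_rows(mats.sum(axis=2))
    sp = zsp @ zsp.T
    np.clip(sp, -1.0, 1.0, out=sp)

    zin = _standardize_rows(np.stack([bb.initial_state for bb in bursts]))
    ic = zin @ zin.T
    np.clip(ic, -1.0, 1.0, out=ic)

    # COM distance: loop over time bins, accumulate pairwise point distances
    t = mats.shape[2]
    coms = np.empty((b, 2, t))
    valids = np.empty((b, t), dtype=bool)
    for i, bb in enumerate(bursts):
        coms[i], valids[i] = com_trajectory(bb.matrix, geometry)
    dist = np.zeros((b, b))
    counts = np.zeros((b, b))
    for tt in range(t):
        v = valids[:, tt]
        pts = coms[:, :, tt]
        dx = pts[:, 0][:, None] - pts[:, 0][None, :]
        dy = pts[:, 1][:, None] - pts[:, 1][None, :]
        d = np.sqrt(dx * dx + dy * dy)
        both = v[:, None] & v[None, :]
        dist += np.where(both, d, 0.0)
        counts += both
    with np.errstate(invalid="ignore", divide="ignore"):
        cd = np.where(counts > 0, dist * (t / counts), np.nan)
    np.fill_diagonal(cd, 0.0)

    for m in (c2, sp, ic):
        np.fill_diagonal(m, 1.0)
    # zero-variance bursts: restore NaN on the diagonal? self-similarity is
    # vacuous for an all-flat burst, keep the conventional values.
    return PairwiseSimilarity(corr2=c2, com_distance=cd, spatial_corr=sp,
                              initial_corr=ic)


def convergence_profile(bursts: list[Burst], theta: float,
                        pair_corr2: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and std over similar pairs of per-bin spatial correlation.

    For every pair with full-burst corr2 > theta, the instantaneous
    (per-bin) Pearson correlation of the two 120-d activity vectors is
    computed; returns ``(mean, std, n_pairs)`` across qualifying pairs per
    bin.  Shrinking std over burst time is the signature of convergence
    from variable initial states to a common pattern.
    """
    b = len(bursts)
    mats = np.stack([bb.matrix for bb in bursts])   # (B, N, T)
    if pair_corr2 is None:
        z = _standardize_rows(mats.reshape(b, -1))
        pair_corr2 = z @ z.T
    iu, ju = np.triu_indices(b, k=1)
    keep = pair_corr2[iu, ju] > theta
    iu, ju = iu[keep], ju[keep]
    if len(iu) == 0:
        return np.empty(0), np.empty(0), 0
    # per-bin standardization across electrodes
    c = mats - mats.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        zz = np.where(nrm > 0, c / nrm, np.nan)
    corr_t = np.einsum("pnt,pnt->pt", zz[iu], zz[ju])
    mean = np.nanmean(corr_t, axis=0)
    std = np.nanstd(corr_t, axis=0)
    return mean, std, len(iu)
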