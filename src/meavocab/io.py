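"""Reading and writing the pipeline's on-disk formats.

Spike events travel as CSV (``electrode,time_ms``) with a JSON sidecar
carrying geometry, epoch and simulation metadata; activity matrices and
burst stacks as HDF5; vocabularies, site summaries and dCDF tables as
CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bursts import Burst, BurstWindow
from .geometry import ElectrodeGeometry, make_geometry
from .preprocess import ActivityMatrix
from .vocabulary import Vocabulary


def write_events(path: str | Path, events: pd.DataFrame,
                 geometry: ElectrodeGeometry, epoch: str = "before",
                 duration_ms: float | None = None,
                 seed: int | None = None, extra: dict | None = None) -> None:
    """Write events CSV plus a `.json` sidecar with recording metadata."""
    path = Path(path)
    events.to_csv(path, index=False)
    meta = {
        "geometry": {"rows": geometry.rows, "cols": geometry.cols,
                     "dy_mm": geometry.dy_mm, "dx_mm": geometry.dx_mm},
        "epoch": epoch,
        "duration_ms": duration_ms,
        "seed": seed,
        "n_events": int(len(events)),
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_events(path: str | Path) -> tuple[pd.DataFrame, dict, ElectrodeGeometry]:
    """Read an events CSV and its JSON sidecar (if present)."""
    path = Path(path)
    events = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    g = meta.get("geometry", {})
    geometry = make_geometry(g.get("rows", 12), g.get("cols", 10),
                             g.get("dy_mm", 1.0), g.get("dx_mm", 1.5))
    return events, meta, geometry


def write_activity_h5(path: str | Path, matrix: ActivityMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values, compression="gzip")
        f.create_dataset("mask", data=matrix.mask, compression="gzip")
        f.attrs["bin_ms"] = matrix.bin_ms
        f.attrs["start_ms"] = matrix.start_ms
        f.attrs["rows"] = matrix.geometry.rows
        f.attrs["cols"] = matrix.geometry.cols
        f.attrs["dy_mm"] = matrix.geometry.dy_mm
        f.attrs["dx_mm"] = matrix.geometry.dx_mm


def read_activity_h5(path: str | Path) -> ActivityMatrix:
    with h5py.File(path, "r") as f:
        geometry = make_geometry(int(f.attrs["rows"]), int(f.attrs["cols"]),
                                 float(f.attrs["dy_mm"]), float(f.attrs["dx_mm"]))
        return ActivityMatrix(values=f["values"][()], mask=f["mask"][()].astype(bool),
                              bin_ms=float(f.attrs["bin_ms"]),
                              start_ms=float(f.attrs["start_ms"]),
                              geometry=geometry)


def write_bursts_h5(path: str | Path, bursts: list[Burst]) -> None:
    """Burst stack (B x N x T) with provenance tables."""
    with h5py.File(path, "w") as f:
        if bursts:
            f.create_dataset("bursts", data=np.stack([b.matrix for b in bursts]),
                             compression="gzip")
            f.create_dataset("masks", data=np.stack([b.mask for b in bursts]),
                             compression="gzip")
        f.create_dataset("start_ms", data=np.array([b.start_ms for b in bursts]))
        f.create_dataset("padded", data=np.array([b.padded for b in bursts]))
        f.create_dataset("site", data=np.array([b.site for b in bursts]))
        dt = h5py.string_dtype()
        f.create_dataset("kind", data=np.array([b.kind for b in bursts], dtype=dt))
        f.create_dataset("epoch", data=np.array([b.epoch for b in bursts], dtype=dt))


def read_bursts_h5(path: str | Path) -> list[Burst]:
    out: list[Burst] = []
    with h5py.File(path, "r") as f:
        if "bursts" not in f:
            return out
        mats = f["bursts"][()]
        masks = f["masks"][()]
        starts = f["start_ms"][()]
        padded = f["padded"][()]
        sites = f["site"][()]
        kinds = [k.decode() if isinstance(k, bytes) else k for k in f["kind"][()]]
        epochs = [e.decode() if isinstance(e, bytes) else e for e in f["epoch"][()]]
    for i in range(len(mats)):
        out.append(Burst(matrix=mats[i], initial_state=mats[i][:, 0].copy(),
                         start_ms=float(starts[i]), kind=kinds[i], epoch=epochs[i],
                         site=int(sites[i]), padded=bool(padded[i]),
                         mask=masks[i].astype(bool), burst_id=i))
    return out


def write_window_csv(path: str | Path, windows: list[BurstWindow],
                     bin_ms: float) -> None:
    pd.DataFrame({
        "start_bin": [w.start_bin for w in windows],
        "trigger_bin": [w.trigger_bin for w in windows],
        "end_bin": [w.end_bin for w in windows],
        "duration_ms": [w.duration_ms(bin_ms) for w in windows],
    }).to_csv(path, index=False)


def write_vocabulary(path_csv: str | Path, vocab: Vocabulary,
                     path_json: str | Path | None = None) -> None:
    pd.DataFrame({"burst_id": np.arange(vocab.n_bursts),
                  "cluster": vocab.labels}).to_csv(path_csv, index=False)
    if path_json is not None:
        summary = {
            "k": vocab.k,
            "theta": None if np.isnan(vocab.theta) else vocab.theta,
            "percent_explained": 100.0 * (vocab.n_bursts - vocab.n_unclassified)
            / vocab.n_bursts if vocab.n_bursts else None,
            "cluster_sizes": {str(c): s for c, s in vocab.cluster_sizes.items()},
            "medoids": {str(c): m for c, m in vocab.medoids.items()},
        }
        if vocab.thresholds is not None:
            summary["metric_thresholds"] = vocab.thresholds.metric_thresholds
            summary["initial_thresholds"] = vocab.thresholds.initial_thresholds
        Path(path_json).write_text(json.dumps(summary, indent=2))


def read_vocabulary_labels(path_csv: str | Path) -> np.ndarray:
    return pd.read_csv(path_csv)["cluster"].to_numpy()


def write_delta_cdf_table(path: str | Path, results: list, network=None) -> None:
    """Tidy CSV: network,pattern,alpha,delta_cdf,z,group."""
    rows = []
    for r in results:
        for i, a in enumerate(r.alphas):
            rows.append({
                "network": r.network if r.network is not None else network,
                "pattern": r.pattern,
                "alpha": float(a),
                "delta_cdf": float(r.delta_cdf[i]),
                "z": float(r.z_scored[i]) if r.z_scored is not None else np.nan,
                "group": getattr(r, "group", ""),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
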