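"""Persistence of weight matrices, spike rasters and statistics tables.

Weights and rasters are stored in HDF5 containers with their metadata;
rasters can also round-trip through a two-column plain-text format
(``time_ms neuron_id``) for inspection and interoperability.  Statistics
are emitted as tidy CSV (via pandas) and JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis import Avalanche, StateSegment
from .learning import WeightMatrix
from .simulate import SpikeRaster


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def save_weights(w: WeightMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=w.values, compression="gzip")
        if w.n_pos is not None:
            f.create_dataset("n_pos", data=w.n_pos)
        if w.n_neg is not None:
            f.create_dataset("n_neg", data=w.n_neg)
        for k, v in w.meta.items():
            f.attrs[k] = v


def load_weights(path) -> WeightMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        n_pos = f["n_pos"][...] if "n_pos" in f else None
        n_neg = f["n_neg"][...] if "n_neg" in f else None
        meta = {k: _plain(v) for k, v in f.attrs.items()}
    return WeightMatrix(values, n_pos=n_pos, n_neg=n_neg, meta=meta)


def export_edge_list(w: WeightMatrix, path) -> None:
    """Text export of the non-zero connections, one ``i j J_ij`` per line."""
    rows, cols = np.nonzero(w.values)
    with open(path, "w") as f:
        f.write("# postsynaptic_i presynaptic_j J_ij\n")
        for i, j in zip(rows, cols):
            f.write(f"{i} {j} {w.values[i, j]:.12g}\n")


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def save_raster(raster: SpikeRaster, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=raster.times, compression="gzip")
        f.create_dataset("neuron_ids", data=raster.ids, compression="gzip")
        f.attrs["n_neurons"] = raster.n_neurons
        f.attrs["t_total"] = raster.t_total
        f.attrs["t_transient"] = raster.t_transient
        for k, v in raster.meta.items():
            f.attrs[f"meta_{k}"] = v


def load_raster(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        times = f["times_ms"][...]
        ids = f["neuron_ids"][...]
        meta = {
            k[len("meta_"):]: _plain(v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        raster = SpikeRaster(
            times,
            ids,
            int(f.attrs["n_neurons"]),
            float(f.attrs["t_total"]),
            float(f.attrs["t_transient"]),
            meta,
        )
    return raster


def save_raster_text(raster: SpikeRaster, path) -> None:
    with open(path, "w") as f:
        f.write(
            f"# n_neurons={raster.n_neurons} t_total={raster.t_total!r} "
            f"t_transient={raster.t_transient!r}\n"
        )
        f.write("# time_ms neuron_id\n")
        for t, i in zip(raster.times, raster.ids):
            f.write(f"{t:.6f} {i}\n")


def load_raster_text(path) -> SpikeRaster:
    header = {}
    with open(path) as f:
        first = f.readline()
        for tok in first.lstrip("# ").split():
            k, _, v = tok.partition("=")
            header[k] = float(v)
    with open(path) as f:
        body = [ln for ln in f if not ln.startswith("#") and ln.strip()]
    data = np.array([[float(v) for v in ln.split()] for ln in body])
    if data.size == 0:
        times, ids = np.empty(0), np.empty(0, dtype=np.int64)
    else:
        times, ids = data[:, 0], data[:, 1].astype(np.int64)
    return SpikeRaster(
        times,
        ids,
        int(header["n_neurons"]),
        header["t_total"],
        header.get("t_transient", 0.0),
    )


# ---------------------------------------------------------------------------
# statistics tables
# ---------------------------------------------------------------------------


def avalanches_frame(avalanches: list[Avalanche]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.start_ms, a.duration_ms, a.size) for a in avalanches],
        columns=["start_ms", "duration_ms", "size"],
    )


def segments_frame(segments: list[StateSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.kind, s.start_ms, s.duration_ms) for s in segments],
        columns=["kind", "start_ms", "duration_ms"],
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_plain) + "\n")


def _plain(v):
    """Coerce numpy scalars/arrays to plain Python for JSON/meta round-trips."""
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, bytes):
        return v.decode()
    return v
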