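"""HDF5/JSON/CSV persistence for movies, masks, traces, and records."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .roi_detection import RoiMask
from .synthetic_data import ScanFieldMovie, StimulusProtocol
from .trace_processing import RoiTraceSet

__all__ = [
    "save_movie", "load_movie", "save_mask", "save_traces",
    "save_protocol", "load_protocol", "save_records",
]


def save_movie(path, movie: ScanFieldMovie) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=movie.pixels, compression="gzip")
        if movie.truth_mask is not None:
            f.create_dataset("truth_mask", data=movie.truth_mask)
        f.attrs["rate_hz"] = movie.rate_hz
        f.attrs["um_per_px"] = movie.um_per_px
        f.attrs["layer"] = movie.layer
        f.attrs["position_mm"] = movie.position_mm
        if movie.chat_band_rows is not None:
            f.attrs["chat_band_rows"] = movie.chat_band_rows


def load_movie(path) -> ScanFieldMovie:
    with h5py.File(path, "r") as f:
        chat = f.attrs.get("chat_band_rows")
        return ScanFieldMovie(
            pixels=f["pixels"][()],
            truth_mask=f["truth_mask"][()] if "truth_mask" in f else None,
            rate_hz=float(f.attrs["rate_hz"]), um_per_px=float(f.attrs["um_per_px"]),
            layer=str(f.attrs["layer"]), position_mm=float(f.attrs["position_mm"]),
            chat_band_rows=tuple(chat) if chat is not None else None)


def save_mask(path, mask: RoiMask) -> None:
    with h5py.File(path, "a") as f:
        if "roi_mask" in f:
            del f["roi_mask"]
        f.create_dataset("roi_mask", data=mask.labels)
        f.attrs["roi_threshold"] = mask.threshold
    table_path = Path(path).with_suffix(".rois.csv")
    mask.table.to_csv(table_path, index=False)


def save_traces(path, traces: RoiTraceSet) -> None:
    with h5py.File(path, "a") as f:
        for key in ("traces", "time"):
            if key in f:
                del f[key]
        f.create_dataset("traces", data=traces.traces, compression="gzip")
        f.create_dataset("time", data=traces.time_s)
        f.attrs["trace_rate_hz"] = traces.rate_hz


def save_protocol(path, protocol: StimulusProtocol) -> None:
    Path(path).write_text(protocol.to_json())


def load_protocol(path) -> StimulusProtocol:
    return StimulusProtocol.from_json(Path(path).read_text())


def save_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)
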