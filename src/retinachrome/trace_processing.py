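"""ΔF/F extraction, stimulus alignment, detrending, trial medians.

Per-ROI fluorescence is the mean over member pixels, converted to ΔF/F
against a robust baseline (8th percentile of the raw trace). Traces are
resampled to 500 Hz on a grid anchored at the first stimulus trigger, each
ROI's time base shifted by its scan-line offset (line-sequential scanning
means lower rows are acquired later within a frame), then detrended with a
zero-phase 2nd-order Butterworth high-pass at 0.1 Hz. Trial-structured
stimuli are summarised by the pointwise median across repetitions; the
T×R repetition matrix feeds the signal-to-noise quality index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "RoiTraceSet",
    "extract_dff",
    "line_offsets_s",
    "resample_align",
    "highpass_detrend",
    "preprocess",
    "trial_median",
    "TARGET_RATE_HZ",
]

TARGET_RATE_HZ = 500.0
F0_PERCENTILE = 8.0
HIGHPASS_HZ = 0.1


@dataclass
class RoiTraceSet:
    """ROI × time ΔF/F traces with the trial structure attached."""

    traces: np.ndarray          # (n_rois, n_samples)
    time_s: np.ndarray
    rate_hz: float
    roi_ids: np.ndarray
    offsets_s: np.ndarray | None = None
    trial_table: pd.DataFrame | None = None  # condition, time_s, repetition

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != self.time_s.size:
            raise ValueError("traces and time axis disagree")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]


def extract_dff(movie, mask) -> RoiTraceSet:
    """Mean-over-pixels ROI traces as ΔF/F.

    ``mask`` is a label image (0 = background). F0 is the 8th percentile of
    the raw ROI trace, a baseline robust to response transients; ΔF/F is
    invariant to multiplicative gain of the movie.
    """
    labels = np.asarray(mask.labels if hasattr(mask, "labels") else mask)
    pixels = movie.pixels
    roi_ids = np.unique(labels)
    roi_ids = roi_ids[roi_ids > 0]
    if roi_ids.size == 0:
        raise ValueError("mask contains no ROIs")
    traces = np.empty((roi_ids.size, pixels.shape[2]))
    for i, rid in enumerate(roi_ids):
        sel = labels == rid
        if not sel.any():
            raise ValueError(f"ROI {rid} is empty")
        f = pixels[sel].mean(axis=0)
        f0 = np.percentile(f, F0_PERCENTILE)
        if abs(f0) < 1e-12:
            f0 = 1e-12
        traces[i] = (f - f0) / f0
    t = np.arange(pixels.shape[2]) / movie.rate_hz
    return RoiTraceSet(traces=traces, time_s=t, rate_hz=movie.rate_hz,
                       roi_ids=roi_ids.astype(int))


def line_offsets_s(centroid_rows, n_rows: int, frame_rate_hz: float) -> np.ndarray:
    """Sub-frame acquisition offset of each ROI: (row / n_rows) / frame rate."""
    rows = np.asarray(centroid_rows, dtype=float)
    return rows / n_rows / frame_rate_hz


def resample_align(traces, rate_in_hz: float, trigger_times_s,
                   offsets_s=None, rate_out_hz: float = TARGET_RATE_HZ,
                   duration_s: float | None = None):
    """Linear-interpolation resampling onto a grid anchored at the first trigger.

    The output grid has step 1/rate_out and is phase-shifted so one sample
    falls exactly on the first trigger (alignment error bounded by the 2 ms
    grid step). Each ROI's input time base is shifted by its scan-line
    offset before interpolation. Idempotent on already-aligned input.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    trigger_times_s = np.asarray(trigger_times_s, dtype=float)
    n_in = traces.shape[1]
    t_in = np.arange(n_in) / rate_in_hz
    if duration_s is None:
        duration_s = n_in / rate_in_hz
    if trigger_times_s.size and (trigger_times_s.min() < 0 or
                                 trigger_times_s.max() > duration_s):
        bad = trigger_times_s[(trigger_times_s < 0) | (trigger_times_s > duration_s)]
        raise ValueError(f"trigger(s) outside the recording: {bad}")
    dt = 1.0 / rate_out_hz
    t0 = trigger_times_s[0] % dt if trigger_times_s.size else 0.0
    # grid stays within the sampled support, so re-running is a no-op
    t_last = (n_in - 1) / rate_in_hz
    n_out = int(np.floor((t_last - t0) / dt + 1e-9)) + 1
    t_out = t0 + np.arange(n_out) * dt
    if offsets_s is None:
        offsets_s = np.zeros(traces.shape[0])
    out = np.empty((traces.shape[0], n_out))
    for i in range(traces.shape[0]):
        out[i] = np.interp(t_out, t_in + offsets_s[i], traces[i])
    return out, t_out


def highpass_detrend(traces, rate_hz: float, cutoff_hz: float = HIGHPASS_HZ):
    """Zero-phase 2nd-order Butterworth high-pass (detrending above ~0.1 Hz)."""
    sos = _signal.butter(2, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, np.atleast_2d(np.asarray(traces, float)), axis=1)


def preprocess(trace_set: RoiTraceSet, trigger_times_s, offsets_s=None,
               trial_table: pd.DataFrame | None = None,
               rate_out_hz: float = TARGET_RATE_HZ,
               cutoff_hz: float = HIGHPASS_HZ) -> RoiTraceSet:
    """Resample to 500 Hz, correct scan-line offsets, detrend, attach trials."""
    aligned, t_out = resample_align(trace_set.traces, trace_set.rate_hz,
                                    trigger_times_s, offsets_s, rate_out_hz)
    detrended = highpass_detrend(aligned, rate_out_hz, cutoff_hz)
    return RoiTraceSet(traces=detrended, time_s=t_out, rate_hz=rate_out_hz,
                       roi_ids=trace_set.roi_ids,
                       offsets_s=None if offsets_s is None else np.asarray(offsets_s),
                       trial_table=trial_table)


def trial_median(trace, rate_hz: float, trial_table: pd.DataFrame, condition: str,
                 epoch_s: float, time_s=None):
    """Pointwise median across repetitions of one condition.

    Returns ``(median_trace, C)`` with C the T×R repetition matrix. All
    repetitions must yield equal-length segments (guaranteed when the epoch
    fits the recording for every trigger).
    """
    x = np.asarray(trace, dtype=float)
    rows = trial_table[trial_table["condition"] == condition]
    if len(rows) == 0:
        raise ValueError(f"no repetitions of condition {condition!r}")
    n_seg = int(round(epoch_s * rate_hz))
    t0 = float(time_s[0]) if time_s is not None else 0.0
    segs = []
    for t in rows["time_s"]:
        i = int(round((t - t0) * rate_hz))
        if i < 0 or i + n_seg > x.size:
            raise ValueError(f"repetition at {t} s does not fit the recording")
        segs.append(x[i:i + n_seg])
    C = np.stack(segs, axis=1)  # T × R
    return np.median(C, axis=1), C
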