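"""Response quality indices and layer-specific inclusion filters.

Two families of quality index are used:

* a baseline-vs-signal area ratio for kernels and event snippets,
  ``Qi = 1 − |F_Area(Baseline)| / |F_Area(Signal)|`` — near 1 for a clean
  kernel, near 0 (or negative) when the "signal" region looks like baseline;
* a repeated-trial signal-to-noise ratio for trial-structured stimuli,
  ``Qi = Var_t[ mean_r C ] / mean_r[ Var_t C ]`` on the T×R repetition
  matrix — 1 for identical repetitions, ≈ 1/R for pure noise.

Inclusion thresholds (config defaults): OPL flash responses need a
hyperpolarizing center or full-field response and Qi > 0.25; surround
analysis additionally needs an antagonistic surround with area >
|center area|/10; IPL/GCL need Qi_Kernel > 0.6 for the UV or green center
kernel; GCL group assignment additionally needs Qi_Chirp > 0.4 or
Qi_Bars > 0.6; scan fields in which fewer than 50% of cells pass are dropped
entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_QC_CONFIG",
    "qi_ratio",
    "qi_kernel",
    "qi_event",
    "qi_snr",
    "apply_layer_filters",
]

DEFAULT_QC_CONFIG = {
    "qi_flash_min": 0.25,          # OPL: Qi of full-field / center-surround flash responses
    "qi_kernel_min": 0.6,          # IPL & GCL: center stimulus-kernel quality
    "qi_event_min": 0.25,          # event-kernel quality gate for opponency
    "qi_chirp_min": 0.4,           # GCL grouping
    "qi_bars_min": 0.6,            # GCL grouping
    "surround_center_ratio": 0.1,  # antagonistic surround area > |center|/10
    "field_pass_fraction": 0.5,    # drop fields with < 50% passing cells
    "kernel_baseline_fraction": 0.25,  # earliest part of the lag window
}


def qi_ratio(signal_area: float, baseline_area: float) -> float:
    """Shared Qi form: 1 − |baseline| / |signal|.

    ≤ 1, may be negative; a zero signal area returns −inf so the record
    always fails any finite threshold.
    """
    s = abs(float(signal_area))
    if s == 0:
        return -np.inf
    return 1.0 - abs(float(baseline_area)) / s


def _window_area(seg: np.ndarray) -> float:
    # per-unit-time RMS area: windows of unequal length compare fairly, and
    # the null ratio concentrates tightly (thin lower tail even for short
    # baseline windows)
    return float(np.sqrt(np.mean(seg ** 2)))


def qi_kernel(kernel, baseline_fraction: float = 0.25) -> float:
    """Kernel quality from the baseline-vs-signal area ratio.

    Baseline = earliest ``baseline_fraction`` of the lag window (farthest
    from the event, where a causal kernel is flat); signal = the remainder.
    Both areas are per-unit-time RMS areas of the raw kernel — no window
    mean is subtracted, which would bias the short baseline window's RMS
    downward and distort the null calibration of the index.
    """
    k = np.asarray(kernel, dtype=float)
    if k.size < 4:
        raise ValueError("kernel too short for quality estimation")
    if np.any(~np.isfinite(k)):
        return -np.inf
    n_b = max(int(round(baseline_fraction * k.size)), 2)
    return qi_ratio(_window_area(k[n_b:]), _window_area(k[:n_b]))


def qi_event(event_kernel, lags_s, pre_s: float = 0.1) -> float:
    """Event-snippet quality: pre-step baseline vs post-step response area."""
    k = np.asarray(event_kernel, dtype=float)
    lags = np.asarray(lags_s, dtype=float)
    pre = lags < 0
    post = ~pre
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("event kernel needs both pre- and post-step samples")
    k = k - k[pre].mean()
    return qi_ratio(_window_area(k[post]), _window_area(k[pre]))


def qi_snr(C) -> float:
    """Repeated-trial signal-to-noise quality from the T×R repetition matrix."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError("C must be a T×R matrix with T ≥ 2 and R ≥ 2")
    num = np.var(C.mean(axis=1))        # variance over time of the trial mean
    den = np.mean(np.var(C, axis=0))    # trial mean of the per-trial variance
    if den == 0:
        raise ValueError("degenerate repetition matrix: all trials constant")
    return float(num / den)


def _col(records: pd.DataFrame, name: str) -> pd.Series:
    if name not in records.columns:
        raise KeyError(f"layer filter requires column {name!r}")
    return records[name]


def apply_layer_filters(records: pd.DataFrame, layer: str,
                        config: dict | None = None):
    """Apply the layer's inclusion rules; returns (passed, audit_log).

    The audit log has one row per (roi, rule) with the tested value, the
    threshold and the outcome, plus field-level drop events, so that
    ``n_pass + n_fail_rule + n_field_dropped == n_input``.
    """
    cfg = dict(DEFAULT_QC_CONFIG)
    cfg.update(config or {})
    records = records.copy()
    audit = []

    if layer == "OPL":
        hyper = (_col(records, "f_area_center") < 0) | (_col(records, "f_area_fullfield") < 0)
        qi = np.maximum(_col(records, "qi_fullfield").fillna(-np.inf),
                        _col(records, "qi_center_surround").fillna(-np.inf))
        passed = hyper & (qi > cfg["qi_flash_min"])
        for rid, h, q, p in zip(records["roi_id"], hyper, qi, passed):
            audit.append((rid, "opl_hyperpolarizing", float(h), 1.0, bool(h)))
            audit.append((rid, "opl_qi_flash", float(q), cfg["qi_flash_min"],
                          bool(q > cfg["qi_flash_min"])))
        # surround analysis gate, recorded but not part of the main pass set
        if "f_area_surround" in records.columns:
            thr = records["f_area_center"].abs() * cfg["surround_center_ratio"]
            records["pass_surround"] = passed & (records["f_area_surround"] > thr)
            for rid, v, t, p in zip(records["roi_id"], records["f_area_surround"],
                                    thr, records["pass_surround"]):
                audit.append((rid, "opl_antagonistic_surround", float(v), float(t), bool(p)))
    elif layer in ("IPL", "GCL"):
        qi = np.maximum(_col(records, "qi_kernel_uv_center").fillna(-np.inf),
                        _col(records, "qi_kernel_green_center").fillna(-np.inf))
        passed = qi > cfg["qi_kernel_min"]
        for rid, q, p in zip(records["roi_id"], qi, passed):
            audit.append((rid, "center_kernel_quality", float(q), cfg["qi_kernel_min"], bool(p)))
        if layer == "GCL" and "qi_chirp" in records.columns:
            group_ok = ((records["qi_chirp"].fillna(-np.inf) > cfg["qi_chirp_min"]) |
                        (records["qi_bars"].fillna(-np.inf) > cfg["qi_bars_min"]))
            records["pass_grouping"] = passed & group_ok
            for rid, g in zip(records["roi_id"], records["pass_grouping"]):
                audit.append((rid, "gcl_grouping_quality", float(g), 1.0, bool(g)))
    else:
        raise ValueError(f"unknown layer {layer!r}")

    records["pass_qc"] = np.asarray(passed, dtype=bool)

    # field-level rule: drop fields where fewer than 50% of cells pass
    if "field_id" in records.columns:
        frac = records.groupby("field_id")["pass_qc"].mean()
        bad_fields = frac[frac < cfg["field_pass_fraction"]].index
        dropped = records["field_id"].isin(bad_fields)
        for rid, fid in zip(records.loc[dropped, "roi_id"], records.loc[dropped, "field_id"]):
            audit.append((rid, "field_pass_fraction", float(frac[fid]),
                          cfg["field_pass_fraction"], False))
        records.loc[dropped, "pass_qc"] = False
        records["field_dropped"] = np.asarray(dropped, dtype=bool)

    audit_log = pd.DataFrame(audit, columns=["roi_id", "rule", "value", "threshold", "passed"])
    return records[records["pass_qc"]].copy(), audit_log
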