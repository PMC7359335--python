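"""Field- and population-level statistics.

* Density recovery profiles (DRPs): radial point density around each unit,
  in points/µm² per 2 µm annulus, averaged over units — flat under complete
  spatial randomness, depleted at short range for an exclusion-zone mosaic.
* Field entropy: Shannon entropy (bits) of spectral-contrast values binned
  at width 0.2 within one scan field — 0 when all units share a bin.
* Direction selectivity: SVD of the time × direction response matrix yields
  the tuning curve; the normalised vector sum is the DS index, its
  significance assessed by a trial-label permutation test.
* Match index: quality-weighted average of chirp and moving-bar template
  correlations, used to assign ganglion-cell-layer cells to functional
  groups (assignment requires Mi > 0.5).
* Group opponency test: a stratified permutation test asking whether a
  functional group contains more (or fewer) color-opponent cells than
  expected from its center-SC / SC_Diff composition alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FieldSummary",
    "ClusterMatch",
    "GroupTestResult",
    "density_recovery_profile",
    "field_entropy",
    "direction_selectivity",
    "assign_cluster",
    "group_opponency_test",
]


@dataclass
class FieldSummary:
    """Per-scan-field summary: DRP, SC entropy, counts."""

    drp: np.ndarray | None = None
    drp_bin_um: float = 2.0
    s_field: float = np.nan
    n_rois: int = 0
    sc_bin_counts: dict = field(default_factory=dict)


@dataclass
class ClusterMatch:
    """Match-index scores of one cell against candidate functional groups."""

    mi: dict                 # group_id -> Mi
    r_chirp: dict
    r_bar: dict
    qi_chirp: float
    qi_bar: float
    assigned_group: int | None
    reason: str = ""


@dataclass
class GroupTestResult:
    """Group-level opponency permutation-test outcome."""

    group_id: int
    n_cells: int
    observed_percent: float
    null_mean: float
    null_sd: float
    percentile: float
    p_two_sided: float
    direction: str           # "enriched" | "depleted"
    n_iterations: int
    n_unmatched: int = 0
    skipped: bool = False
    skip_reason: str = ""


# ---------------------------------------------------------------------------
# Density recovery profile
# ---------------------------------------------------------------------------

def density_recovery_profile(points_um, bin_um: float = 2.0,
                             max_radius_um: float = 20.0,
                             guard_um: float | None = None):
    """Mean radial density profile of a point set (points/µm² per bin).

    For every reference point the distances to all other points are
    histogrammed (bin width ``bin_um``), each bin normalised by its annulus
    area, and the per-point histograms averaged. ``guard_um`` restricts the
    *reference* points to those at least that far from the bounding box of
    the point set (all points remain distance targets), which removes the
    downward bias of annuli truncated by the field border; pass 0 to use
    every point. Default guard: ``max_radius_um``. Returns
    ``(profile, bin_edges_um)``.
    """
    pts = np.asarray(points_um, dtype=float)
    edges = np.arange(0.0, max_radius_um + bin_um, bin_um)
    n_bins = edges.size - 1
    if pts.ndim != 2 or len(pts) < 2:
        warnings.warn("fewer than 2 points: returning a zero profile")
        return np.zeros(n_bins), edges
    if guard_um is None:
        guard_um = max_radius_um
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    interior = np.all((pts >= lo + guard_um) & (pts <= hi - guard_um), axis=1)
    refs = np.flatnonzero(interior)
    if refs.size == 0:
        refs = np.arange(len(pts))  # field smaller than the guard: use everything
    d = np.sqrt(((pts[refs, None, :] - pts[None, :, :]) ** 2).sum(-1))
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    profiles = np.empty((refs.size, n_bins))
    for k, i in enumerate(refs):
        counts, _ = np.histogram(np.delete(d[k], i), bins=edges)
        profiles[k] = counts / areas
    return profiles.mean(axis=0), edges


# ---------------------------------------------------------------------------
# Field entropy
# ---------------------------------------------------------------------------

def field_entropy(sc_values, bin_size: float = 0.2) -> float:
    """Shannon entropy (bits) of binned spectral-contrast values.

    Bin edges are anchored at 0; ``p_i`` are bin proportions and
    0·log 0 ≡ 0, so a field whose units all share one bin has entropy 0 and
    a uniform spread over k bins has log2 k bits.
    """
    sc = np.asarray(sc_values, dtype=float)
    sc = sc[np.isfinite(sc)]
    if sc.size == 0:
        raise ValueError("field entropy needs at least one finite SC value")
    idx = np.floor(sc / bin_size).astype(int)
    counts = np.bincount(idx - idx.min())
    p = counts[counts > 0] / sc.size
    return float(max(0.0, -(p * np.log2(p)).sum()))


# ---------------------------------------------------------------------------
# Direction selectivity
# ---------------------------------------------------------------------------

def _tuning_from_matrix(M: np.ndarray) -> np.ndarray:
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    tuning = vt[0]
    # orient so the tuning agrees with the mean response across time
    if np.dot(tuning, M.mean(axis=0)) < 0:
        tuning = -tuning
    return tuning


def _vector_sum(tuning: np.ndarray, dirs_rad: np.ndarray):
    vec = np.sum(tuning * np.exp(1j * dirs_rad))
    denom = np.sum(np.abs(tuning))
    if denom == 0:
        return np.nan, np.nan
    return float(np.abs(vec)), float(np.abs(vec) / denom)


def direction_selectivity(responses, n_perm: int = 1000, seed: int = 0,
                          dirs_deg=None):
    """DS index and permutation p-value from trial-resolved responses.

    ``responses`` has shape (n_trials, n_time, n_directions). The mean
    response matrix is decomposed by SVD; the first right-singular vector
    (sign-fixed against the mean response) is the tuning curve, and

        DSI = |Σ_k w_k e^{iθ_k}| / Σ_k |w_k|

    its normalised vector sum (the raw vector length is also returned).
    The null distribution shuffles direction labels independently within
    each trial; p is the fraction of null DSIs ≥ the observed one.
    Returns ``(dsi, p, info)`` with tuning curve and vector length in info.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim == 2:
        R = R[None]
    n_trials, n_t, n_dirs = R.shape
    if dirs_deg is None:
        dirs_deg = np.arange(n_dirs) * 360.0 / n_dirs
    dirs_rad = np.deg2rad(np.asarray(dirs_deg, dtype=float))

    M = R.mean(axis=0)
    if not M.any():
        return np.nan, np.nan, {"tuning": np.full(n_dirs, np.nan),
                                "vector_length": np.nan}
    tuning = _tuning_from_matrix(M)
    vec_len, dsi = _vector_sum(tuning, dirs_rad)

    rng = np.random.default_rng(seed)
    if n_trials < 2:
        raise ValueError("permutation test needs at least 2 trials")
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = np.stack([R[t][:, rng.permutation(n_dirs)] for t in range(n_trials)])
        _, null[b] = _vector_sum(_tuning_from_matrix(shuffled.mean(axis=0)), dirs_rad)
    p = (1.0 + np.sum(null >= dsi)) / (1.0 + n_perm)
    return dsi, float(p), {"tuning": tuning, "vector_length": vec_len, "null": null}


# ---------------------------------------------------------------------------
# Cluster assignment by match index
# ---------------------------------------------------------------------------

def _corr(a, b) -> float:
    n = min(len(a), len(b))
    a, b = np.asarray(a[:n], float), np.asarray(b[:n], float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def assign_cluster(chirp_trace, bar_trace, qi_chirp: float, qi_bar: float,
                   templates: dict, is_ds: bool = False, is_alpha: bool = False,
                   rate_hz: float = 31.25, shift_s: float = 0.04,
                   boxcar_points: int = 5, mi_threshold: float = 0.5) -> ClusterMatch:
    """Assign a GCL cell to the best-matching functional group.

    The chirp trace is shifted by 40 ms and boxcar-smoothed (5 points)
    before correlation, compensating a stimulation frame-rate mismatch
    against the template set. Candidate groups are restricted by class
    (DS cells against DS groups, alpha cells — soma area > 170 µm² — against
    alpha groups, all others against the rest); the match index

        Mi = Qi_Chirp/(Qi_Chirp+Qi_Bar) · r_Chirp + Qi_Bar/(Qi_Chirp+Qi_Bar) · r_Bar

    combines template correlations, and assignment requires Mi > 0.5.
    """
    shift = int(round(shift_s * rate_hz))
    chirp = np.roll(np.asarray(chirp_trace, float), shift)
    if boxcar_points > 1:
        chirp = ndimage.uniform_filter1d(chirp, size=boxcar_points, mode="nearest")
    bar = np.asarray(bar_trace, float)

    if is_ds:
        candidates = {g: t for g, t in templates.items() if t.get("is_ds")}
    elif is_alpha:
        candidates = {g: t for g, t in templates.items() if t.get("is_alpha")}
    else:
        candidates = {g: t for g, t in templates.items()
                      if not t.get("is_ds") and not t.get("is_alpha")}
    if not candidates:
        return ClusterMatch(mi={}, r_chirp={}, r_bar={}, qi_chirp=qi_chirp,
                            qi_bar=qi_bar, assigned_group=None,
                            reason="no candidate templates after class restriction")

    qsum = qi_chirp + qi_bar
    if qsum <= 0:
        raise ValueError("quality indices must be positive")
    w_chirp, w_bar = qi_chirp / qsum, qi_bar / qsum
    mi, rc, rb = {}, {}, {}
    for g, t in candidates.items():
        rc[g] = _corr(chirp, t["chirp"])
        rb[g] = _corr(bar, t["bar"])
        mi[g] = w_chirp * rc[g] + w_bar * rb[g]
    best = max(mi, key=lambda g: (mi[g] if np.isfinite(mi[g]) else -np.inf))
    assigned = best if np.isfinite(mi[best]) and mi[best] > mi_threshold else None
    return ClusterMatch(mi=mi, r_chirp=rc, r_bar=rb, qi_chirp=qi_chirp,
                        qi_bar=qi_bar, assigned_group=assigned,
                        reason="" if assigned is not None else "max Mi below threshold")


# ---------------------------------------------------------------------------
# Group-level opponency permutation test
# ---------------------------------------------------------------------------

def group_opponency_test(records: pd.DataFrame, n_iter: int = 10000, seed: int = 0,
                         sc_diff_bin: float = 0.25, sc_center_tol: float = 0.1,
                         min_group_size: int = 15,
                         group_ids=None) -> list:
    """Stratified permutation test for per-group opponency enrichment.

    ``records`` needs columns ``group_id``, ``sc_center``, ``sc_diff``,
    ``is_opponent``. SC_Diff values are binned at width 0.25 (edges anchored
    at 0) across all groups; in each iteration every cell of a group is
    replaced by a randomly drawn *different* cell from the same SC_Diff bin
    with center SC within ±0.1, and the surrogate percentage of opponent
    cells recorded. The observed percentage's percentile within the null is
    reported, together with a two-sided p (2·min(pct, 1−pct)), since both
    enrichment and depletion are of interest. Groups with ≤ ``min_group_size``
    cells are skipped; a cell without any eligible partner keeps its own
    label in surrogates and is counted in ``n_unmatched``.
    """
    req = {"group_id", "sc_center", "sc_diff", "is_opponent"}
    missing = req - set(records.columns)
    if missing:
        raise KeyError(f"records missing columns: {sorted(missing)}")
    df = records.dropna(subset=["sc_center", "sc_diff"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    bins = np.floor(df["sc_diff"].to_numpy() / sc_diff_bin).astype(int)
    sc_c = df["sc_center"].to_numpy()
    opp = df["is_opponent"].to_numpy().astype(bool)

    # eligible partner lists per cell: same SC_Diff bin, similar center SC, not self
    by_bin = {}
    for i, b in enumerate(bins):
        by_bin.setdefault(b, []).append(i)
    partners = []
    for i in range(len(df)):
        pool = np.array(by_bin[bins[i]])
        pool = pool[(pool != i) & (np.abs(sc_c[pool] - sc_c[i]) <= sc_center_tol)]
        partners.append(pool)

    results = []
    gids = sorted(df["group_id"].unique()) if group_ids is None else group_ids
    for gid in gids:
        members = np.flatnonzero(df["group_id"].to_numpy() == gid)
        n = members.size
        if n <= min_group_size:
            results.append(GroupTestResult(
                group_id=int(gid), n_cells=int(n), observed_percent=np.nan,
                null_mean=np.nan, null_sd=np.nan, percentile=np.nan,
                p_two_sided=np.nan, direction="", n_iterations=0,
                skipped=True, skip_reason=f"group size {n} <= {min_group_size}"))
            continue
        observed = 100.0 * opp[members].mean()
        null_counts = np.zeros(n_iter)
        n_unmatched = 0
        for idx in members:
            pool = partners[idx]
            if pool.size == 0:
                n_unmatched += 1
                null_counts += opp[idx]  # no partner: the cell stands in for itself
                continue
            draws = pool[rng.integers(0, pool.size, size=n_iter)]
            null_counts += opp[draws]
        null_pct = 100.0 * null_counts / n
        pct = (np.sum(null_pct < observed) + 0.5 * np.sum(null_pct == observed)) / n_iter
        p2 = min(1.0, 2.0 * min(pct, 1.0 - pct))
        results.append(GroupTestResult(
            group_id=int(gid), n_cells=int(n), observed_percent=float(observed),
            null_mean=float(null_pct.mean()), null_sd=float(null_pct.std()),
            percentile=float(pct), p_two_sided=float(p2),
            direction="enriched" if pct >= 0.5 else "depleted",
            n_iterations=n_iter, n_unmatched=n_unmatched))
    return results


def group_test_table(results) -> pd.DataFrame:
    """Tidy table of :func:`group_opponency_test` results."""
    return pd.DataFrame([vars(r) for r in results])
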