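"""Correlation-based ROI segmentation and IPL depth assignment.

Functional units (cone terminals, bipolar-cell axon terminals, ganglion-cell
somata) share one underlying signal across their pixels, so neighbouring
pixels of a unit are correlated while background pixels are not. The local
correlation image — each pixel's mean Pearson correlation with its
8-neighbourhood — therefore highlights units; connected super-threshold
regions grown from local maxima become ROIs, restricted to the layer's
terminal/soma diameter range (3–7 µm for cone terminals, 1–4 µm for BC
terminals).

IPL depth is normalised against the two ChAT bands: 0 at the On band, 1 at
the Off band, linear beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "RoiMask",
    "correlation_image",
    "segment_rois",
    "ipl_depth",
]

_NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                     if (dr, dc) != (0, 0)]


@dataclass
class RoiMask:
    """Label image plus a per-ROI geometry table (µm units)."""

    labels: np.ndarray
    table: pd.DataFrame  # roi_id, centroid_row, centroid_col, centroid_row_um,
    #                      centroid_col_um, area_um2, eq_diam_um
    threshold: float
    um_per_px: float

    @property
    def n_rois(self) -> int:
        return len(self.table)


def correlation_image(movie) -> np.ndarray:
    """Mean Pearson correlation of each pixel's trace with its 8 neighbours.

    Border pixels use the neighbours that exist; zero-variance pixels
    contribute a correlation of 0.
    """
    px = np.asarray(movie.pixels, dtype=float)
    if px.shape[2] < 2:
        raise ValueError("correlation image needs at least 2 frames")
    if not np.all(np.isfinite(px)):
        raise ValueError("movie contains non-finite pixel values")
    z = px - px.mean(axis=2, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=2))
    flat = norm == 0
    norm[flat] = 1.0
    z /= norm[..., None]

    rows, cols = px.shape[:2]
    acc = np.zeros((rows, cols))
    cnt = np.zeros((rows, cols))
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0, r1 = max(dr, 0), rows + min(dr, 0)
        c0, c1 = max(dc, 0), cols + min(dc, 0)
        a = z[r0:r1, c0:c1]
        b = z[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        corr = (a * b).sum(axis=2)
        # a zero-variance member of the pair contributes zero correlation
        pair_flat = flat[r0:r1, c0:c1] | flat[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        corr[pair_flat] = 0.0
        acc[r0:r1, c0:c1] += corr
        cnt[r0:r1, c0:c1] += 1
    return acc / cnt


def _auto_threshold(corr_img: np.ndarray) -> float:
    """Otsu split of the correlation-image histogram, clamped to [0.1, 0.9]."""
    thr = threshold_otsu(corr_img.ravel())
    return float(np.clip(thr, 0.1, 0.9))


def segment_rois(corr_image_arr, movie, threshold="auto",
                 diameter_range_um=(3.0, 7.0)) -> RoiMask:
    """Grow ROIs from local maxima of the correlation image.

    Super-threshold pixels are assigned to correlation peaks by watershed
    (which also splits merged units); components outside the configured
    equivalent-diameter range are discarded. ``threshold="auto"`` picks an
    Otsu split of the correlation histogram clamped to [0.1, 0.9].
    """
    corr = np.asarray(corr_image_arr, dtype=float)
    um_per_px = movie.um_per_px
    if threshold == "auto":
        thr = _auto_threshold(corr)
    else:
        thr = float(threshold)
        if not -1.0 < thr < 1.0:
            raise ValueError("threshold must lie in (−1, 1) or be 'auto'")
    d_min, d_max = diameter_range_um
    mask = corr > thr

    empty_table = pd.DataFrame(columns=["roi_id", "centroid_row", "centroid_col",
                                        "centroid_row_um", "centroid_col_um",
                                        "area_um2", "eq_diam_um"])
    if not mask.any():
        warnings.warn("no pixels above the correlation threshold; empty ROI mask")
        return RoiMask(labels=np.zeros_like(corr, dtype=int), table=empty_table,
                       threshold=thr, um_per_px=um_per_px)

    min_dist = max(int(round(d_min / 2 / um_per_px)), 1)
    peaks = peak_local_max(corr, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    markers = np.zeros_like(corr, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-corr, markers=markers, mask=mask)

    keep = []
    for prop in regionprops(labels):
        eq_diam_um = prop.equivalent_diameter_area * um_per_px
        if d_min <= eq_diam_um <= d_max:
            keep.append(prop)
    out = np.zeros_like(labels)
    rows = []
    for new_id, prop in enumerate(keep, start=1):
        out[labels == prop.label] = new_id
        r, c = prop.centroid
        rows.append(dict(roi_id=new_id, centroid_row=r, centroid_col=c,
                         centroid_row_um=r * um_per_px, centroid_col_um=c * um_per_px,
                         area_um2=prop.area * um_per_px**2,
                         eq_diam_um=prop.equivalent_diameter_area * um_per_px))
    if not rows:
        warnings.warn("no component within the diameter range; empty ROI mask")
        return RoiMask(labels=out, table=empty_table, threshold=thr, um_per_px=um_per_px)
    return RoiMask(labels=out, table=pd.DataFrame(rows), threshold=thr,
                   um_per_px=um_per_px)


def ipl_depth(roi_centroid_row: float, chat_band_rows) -> float:
    """IPL depth normalised to the ChAT bands: 0 = On band, 1 = Off band.

    Linear in the centroid row, extrapolated beyond the bands (margins of
    the IPL legitimately map outside [0, 1]).
    """
    row_on, row_off = chat_band_rows
    if row_on == row_off:
        raise ValueError("ChAT band rows must be distinct")
    return (float(roi_centroid_row) - row_on) / (row_off - row_on)
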