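"""Spectral contrast, color opponency, and sine phase/F1 statistics.

Chromatic preference is summarised per cell by a spectral contrast (SC)
computed from the response areas to UV and green stimulation. When UV and
green responses share a polarity, SC is the Michelson contrast

    SC = (|F_g| − |F_uv|) / (|F_g| + |F_uv|)            ∈ [−1, 1],

with SC = −1 / +1 for a purely UV- / green-driven cell. When one color
responds with the polarity expected for the condition and the other is
antagonistic, SC extends beyond that range:

    green expected, UV antagonistic:  SC = 1 + |F_uv| / |F_g|   (> 1)
    UV expected, green antagonistic:  SC = 1 − |F_g| / |F_uv|   (< 1)

Full-field opponency is the minimum of the UV-vs-green correlations of the
onset and offset event kernels; a cell is classed color-opponent when either
correlation falls below −0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "AreaSummary",
    "CellChromaticRecord",
    "signed_f_area",
    "spectral_contrast",
    "sc_diff",
    "fullfield_opponency",
    "sine_phase_f1",
    "OPPONENCY_RHO_THRESHOLD",
]

#: Correlation threshold below which a UV/green event-kernel pair counts as
#: antagonistic (color-opponent).
OPPONENCY_RHO_THRESHOLD = -0.3


@dataclass
class AreaSummary:
    """Signed response area for one condition plus its polarity call."""

    area: float
    expected: bool | None  # True: expected polarity; False: antagonistic; None: undefined

    @property
    def abs_area(self) -> float:
        return abs(self.area)


@dataclass
class CellChromaticRecord:
    """Per-cell chromatic summary row (one ROI)."""

    roi_id: int
    layer: str
    position_mm: float = np.nan
    ipl_depth: float = np.nan
    sc_center: float = np.nan
    sc_center_case: int = 0
    sc_surround: float = np.nan
    sc_surround_case: int = 0
    sc_fullfield: float = np.nan
    sc_fullfield_case: int = 0
    sc_diff: float = np.nan
    rho_onset: float = np.nan
    rho_offset: float = np.nan
    opponency: float = np.nan
    is_opponent: bool = False
    group_id: int = -1


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def signed_f_area(kernel, reference_center_kernel=None, window=None,
                  baseline_samples: int = 0, dt: float = 1.0,
                  expected_sign: float = 1.0) -> AreaSummary:
    """Signed area under a kernel or trace, with a polarity call.

    The absolute response area is the integral of the baseline-subtracted
    signal over ``window`` (a slice or index array; default: everything after
    the baseline). The polarity call depends on the reference:

    * with ``reference_center_kernel`` (stimulus kernels): the response is
      *antagonistic* when its Pearson correlation with the reference is
      negative — its area is then made negative;
    * without a reference (flash traces): polarity is the sign of the area
      itself, and ``expected_sign`` states which sign is the expected
      response for the condition (e.g. −1 for a glutamate-decrease center).

    ``expected`` in the result is relative to the condition expectation, the
    flag the spectral-contrast case selection consumes.
    """
    k = np.asarray(kernel, dtype=float)
    if baseline_samples > 0:
        k = k - k[:baseline_samples].mean()
    if window is None:
        window = slice(baseline_samples, None)
    seg = k[window]
    if seg.size == 0:
        raise ValueError("empty integration window")
    raw_area = float(np.sum(seg) * dt)

    if reference_center_kernel is not None:
        rho = _pearson(np.asarray(kernel, float)[window],
                       np.asarray(reference_center_kernel, float)[window])
        if math.isnan(rho) or np.all(seg == 0):
            return AreaSummary(area=0.0, expected=None)
        correlated = rho >= 0
        area = abs(raw_area) if correlated else -abs(raw_area)
        # for kernels, "expected" means matching the center reference when
        # the condition expectation is the center polarity itself
        expected = correlated if expected_sign >= 0 else not correlated
        return AreaSummary(area=area, expected=expected)

    if raw_area == 0.0:
        return AreaSummary(area=0.0, expected=None)
    expected = (raw_area * expected_sign) > 0
    return AreaSummary(area=raw_area, expected=expected)


def projected_f_area(kernel, reference_center_kernel, window, dt: float = 1.0,
                     baseline_samples: int = 0, expected_sign: float = 1.0) -> AreaSummary:
    """Signed F_Area of a stimulus kernel by template projection.

    All of a cell's condition kernels share the temporal shape of its
    response filter, so the response area of one condition is estimated by
    projecting its kernel onto the unit-norm reference-center-kernel shape
    and rescaling to the reference's rectified area. This matched-template
    estimate ignores lag bins where the kernel carries no mass, which an
    unweighted integral would accumulate as stimulus-sampling noise. The
    sign of the projection is the anticorrelated-vs-reference polarity call.
    """
    k = np.asarray(kernel, dtype=float)
    r = np.asarray(reference_center_kernel, dtype=float)
    if baseline_samples > 0:
        k = k - k[:baseline_samples].mean()
        r = r - r[:baseline_samples].mean()
    seg, ref = k[window], r[window]
    norm = np.linalg.norm(ref)
    if norm == 0 or np.all(seg == 0):
        return AreaSummary(area=0.0, expected=None)
    unit = ref / norm
    proj = float(np.dot(seg, unit))
    area = proj * float(np.sum(np.abs(unit))) * dt
    expected = (proj >= 0) if expected_sign >= 0 else (proj < 0)
    return AreaSummary(area=area, expected=expected)


def spectral_contrast(f_area_green: float, f_area_uv: float,
                      green_expected: bool, uv_expected: bool):
    """Spectral contrast from absolute UV/green areas and polarity flags.

    Returns ``(sc, case)`` with case 1 the Michelson (same-polarity) branch,
    case 2 green-expected/UV-antagonistic (> 1), case 3 UV-expected/
    green-antagonistic (< 1). Raises on a zero denominator in the
    antagonistic branches; callers flag such records undefined.
    """
    g = abs(float(f_area_green))
    u = abs(float(f_area_uv))
    if g == 0 and u == 0:
        raise ValueError("spectral contrast undefined: both areas zero")
    if green_expected == uv_expected:
        return (g - u) / (g + u), 1
    if green_expected and not uv_expected:
        if g == 0:
            raise ValueError("spectral contrast undefined: green area zero in antagonistic case")
        return 1.0 + u / g, 2
    if u == 0:
        raise ValueError("spectral contrast undefined: UV area zero in antagonistic case")
    return 1.0 - g / u, 3


def sc_diff(sc_surround: float, sc_center: float) -> float:
    """Surround minus center spectral contrast; NaN propagates as undefined."""
    return float(sc_surround) - float(sc_center)


def fullfield_opponency(event_kernels: dict, qi_event: dict | None = None,
                        qi_event_threshold: float = 0.25):
    """UV-vs-green correlation of onset/offset event kernels and the opponency call.

    ``event_kernels`` maps ``(color, phase)`` → kernel array for colors
    {"uv", "green"} and phases {"onset", "offset"}; ``qi_event`` maps the
    same keys to event quality. A phase contributes only when both colors'
    kernels are present and pass quality. Returns
    ``(rho_onset, rho_offset, opponency, is_opponent)`` with NaN for an
    undefined phase; both undefined → opponency NaN, not opponent.
    """
    rhos = {}
    for phase in ("onset", "offset"):
        uv = event_kernels.get(("uv", phase))
        green = event_kernels.get(("green", phase))
        ok = uv is not None and green is not None
        if ok and qi_event is not None:
            ok = (qi_event.get(("uv", phase), -np.inf) > qi_event_threshold and
                  qi_event.get(("green", phase), -np.inf) > qi_event_threshold)
        rhos[phase] = _pearson(uv, green) if ok else np.nan
    rho_on, rho_off = rhos["onset"], rhos["offset"]
    candidates = [r for r in (rho_on, rho_off) if not math.isnan(r)]
    opponency = min(candidates) if candidates else np.nan
    is_opp = bool(candidates) and opponency < OPPONENCY_RHO_THRESHOLD
    return rho_on, rho_off, opponency, is_opp


def sine_phase_f1(mean_trace, sine_stimulus, rate_hz: float, freq_hz: float = 2.0):
    """Response phase and fundamental (F1) amplitude for sine stimulation.

    Phase is the lag of maximal cross-correlation between trace and stimulus,
    converted to degrees of the stimulus cycle and wrapped to [0, 360);
    F1 is the discrete-Fourier amplitude of the mean trace at ``freq_hz``.
    """
    x = np.asarray(mean_trace, float)
    s = np.asarray(sine_stimulus, float)
    period = rate_hz / freq_hz
    if x.size < period:
        raise ValueError("trace shorter than one stimulus period")
    x0 = x - x.mean()
    s0 = s - s.mean()
    cc = _signal.correlate(x0, s0, mode="full")
    lags = _signal.correlation_lags(x0.size, s0.size, mode="full")
    # restrict to one stimulus cycle of causal-ish lags around zero
    keep = np.abs(lags) <= period / 2
    best = lags[keep][np.argmax(cc[keep])]
    phase = (best / period) * 360.0 % 360.0

    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec = np.fft.rfft(x0)
    k = int(np.argmin(np.abs(freqs - freq_hz)))
    f1 = 2.0 * np.abs(spec[k]) / n
    return float(phase), float(f1)


def bin_phases(phases_deg, bin_deg: float = 15.0):
    """Polar histogram counts of response phases (bin width 15°)."""
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(np.mod(phases_deg, 360.0), bins=edges)
    return counts, edges
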