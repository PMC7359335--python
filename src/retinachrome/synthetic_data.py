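"""Synthetic stimuli, ground-truth cell populations, and scan-field movies.

This module generates the inputs the analysis pipeline expects from a
two-photon chromatic-processing experiment in the mouse retina, with known
ground truth attached:

* stimulus protocols — balanced binary center/surround flicker, interleaved
  UV/green flash epochs, chirps, 2 Hz sines and moving bars;
* cell populations with signed UV/green center and surround weights laid out
  along the dorso-ventral opsin gradient (UV-dominant ventrally,
  green-dominant dorsally), optionally with green antagonistic surrounds in
  the ventral retina;
* single-cell responses through a linear–nonlinear (LN) cascade
  (exponential-decay temporal filter, softplus output nonlinearity) plus
  additive Gaussian noise;
* scan-field movies in which each cell is rendered as a Gaussian terminal on
  an exclusion-zone mosaic, so ROI detection can be benchmarked against a
  ground-truth mask.

Sign convention: response weights are signed. For outer-retina (OPL)
glutamate recordings the driven center response is a *decrease* in the trace
(cones hyperpolarize to light), so center weights are negative and
antagonistic-surround weights positive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .chromatic_analysis import spectral_contrast

__all__ = [
    "StimulusProtocol",
    "GroundTruthCell",
    "ScanFieldMovie",
    "FieldGeometry",
    "LAYER_DEFAULTS",
    "make_flicker_protocol",
    "make_flash_protocol",
    "make_chirp_protocol",
    "make_sine_protocol",
    "make_population",
    "make_population_from_sc",
    "weights_from_sc",
    "truth_spectral_contrast",
    "simulate_cell_response",
    "simulate_scan_field",
    "noise_sd_for_snr",
    "make_group_templates",
]

#: Scan geometry used in the experiments this generator emulates.
LAYER_DEFAULTS = {
    "OPL": dict(shape=(128, 128), rate_hz=3.9, um_per_px=0.85,
                terminal_diam_um=(3.0, 7.0), kinetics_tau_s=0.15),
    "IPL": dict(shape=(64, 56), rate_hz=11.16, um_per_px=0.7,
                terminal_diam_um=(1.0, 4.0), kinetics_tau_s=0.15),
    "GCL": dict(shape=(64, 64), rate_hz=7.8125, um_per_px=1.5,
                terminal_diam_um=(8.0, 16.0), kinetics_tau_s=0.3),
}

FLICKER_CONDITIONS = ("uv_center", "green_center", "uv_surround", "green_surround")
FLASH_CONDITIONS = ("uv_center", "green_center", "uv_surround", "green_surround",
                    "uv_fullfield", "green_fullfield")


@dataclass
class StimulusProtocol:
    """Channel-resolved stimulus time course with trigger times.

    ``channels`` holds one intensity row per condition (UV/green ×
    center/surround/full-field as applicable), sampled at ``rate_hz``.
    Intensities are in arbitrary photoisomerization-rate units; flicker uses
    ±1 states, flashes 0/1.
    """

    kind: str
    channels: np.ndarray  # (n_conditions, n_steps)
    condition_names: tuple
    rate_hz: float
    trigger_times_s: np.ndarray
    duration_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        self.trigger_times_s = np.asarray(self.trigger_times_s, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(self.condition_names):
            raise ValueError("channels must be (n_conditions, n_steps)")
        t = self.trigger_times_s
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("trigger times must be strictly increasing within [0, duration]")

    @property
    def n_steps(self) -> int:
        return self.channels.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_steps) / self.rate_hz

    def condition_index(self, name: str) -> int:
        return self.condition_names.index(name) if isinstance(self.condition_names, list) \
            else list(self.condition_names).index(name)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["channels"] = self.channels.tolist()
        d["trigger_times_s"] = self.trigger_times_s.tolist()
        d["condition_names"] = list(self.condition_names)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusProtocol":
        d = json.loads(s)
        d["condition_names"] = tuple(d["condition_names"])
        return cls(**d)


@dataclass
class GroundTruthCell:
    """A simulated cell with known chromatic weights.

    Weights are signed response gains per stimulus condition; the
    ground-truth spectral contrast implied by them is available through
    :func:`truth_spectral_contrast`.
    """

    position_mm: float  # signed dorso-ventral distance from the optic nerve (<0 ventral)
    layer: str
    w_center_uv: float
    w_center_green: float
    w_surround_uv: float = 0.0
    w_surround_green: float = 0.0
    ipl_depth: float | None = None
    polarity: str = "Off"
    kinetics_tau_s: float = 0.06
    group_id: int | None = None

    def __post_init__(self):
        w = (self.w_center_uv, self.w_center_green, self.w_surround_uv, self.w_surround_green)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.kinetics_tau_s <= 0:
            raise ValueError("kinetics_tau_s must be positive")

    @property
    def center_expected_sign(self) -> float:
        """Sign of an expected-polarity center response (−1 for Off/OPL cells)."""
        return -1.0 if self.polarity == "Off" else 1.0

    @property
    def is_opponent_truth(self) -> bool:
        """Antagonistic chromatic organisation implied by the weights:
        UV and green full-field gains have opposite signs."""
        uv = self.w_center_uv + self.w_surround_uv
        green = self.w_center_green + self.w_surround_green
        return uv * green < 0


@dataclass
class ScanFieldMovie:
    """Pixel-grid fluorescence movie plus scan metadata and optional truth."""

    pixels: np.ndarray  # (rows, cols, frames)
    rate_hz: float
    um_per_px: float
    layer: str
    position_mm: float = 0.0
    chat_band_rows: tuple | None = None  # (row_on, row_off), IPL x–z scans only
    truth_mask: np.ndarray | None = None
    truth_cells: list | None = None
    truth_centers_px: np.ndarray | None = None

    def __post_init__(self):
        if self.chat_band_rows is not None and not self.chat_band_rows[0] < self.chat_band_rows[1]:
            raise ValueError("chat_band_rows must satisfy row_On < row_Off")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

def make_flicker_protocol(condition_count: int = 4, rate_hz: float = 10.0,
                          duration_s: float = 180.0, seed: int = 0) -> StimulusProtocol:
    """Balanced binary center-surround flicker.

    Each condition gets an exactly balanced ±1 sequence (a shuffled
    half-high template, not iid draws), independent across conditions.
    The default is the 180 s, 10 Hz protocol used for inner-retina
    glutamate recordings; 300 s at 5 Hz is the ganglion-cell-layer variant.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate_hz and duration_s must be positive")
    n_float = duration_s * rate_hz
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n % 2:
        raise ValueError(f"duration × rate must be an even integer of steps, got {n_float}")
    rng = np.random.default_rng(seed)
    template = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    channels = np.stack([rng.permutation(template) for _ in range(condition_count)])
    names = FLICKER_CONDITIONS[:condition_count] if condition_count <= 4 else tuple(
        f"cond{i}" for i in range(condition_count))
    return StimulusProtocol(
        kind="flicker_cs", channels=channels, condition_names=names, rate_hz=rate_hz,
        trigger_times_s=np.array([0.0]), duration_s=float(duration_s),
        metadata={"seed": seed},
    )


def make_flash_protocol(center_diam_um: float = 150.0, fullfield_diam_um: float = 700.0,
                        n_repeats: int = 25, flash_s: float = 1.0, gap_s: float = 1.0,
                        rate_hz: float = 500.0,
                        conditions: tuple = FLASH_CONDITIONS) -> StimulusProtocol:
    """Interleaved UV/green center, surround (annulus) and full-field flashes.

    Per repetition the six conditions are presented in a fixed interleaved
    order, each as a ``flash_s`` step followed by ``gap_s`` of darkness.
    Stimulus geometry (default 150 µm center, 700 µm full field; surround =
    annulus sparing the center) is metadata — the spatial integration is
    carried by the cells' condition weights, not rendered.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    epoch_s = flash_s + gap_s
    n_cond = len(conditions)
    duration_s = gap_s + n_repeats * n_cond * epoch_s  # lead-in gap before the first flash
    n_steps = int(round(duration_s * rate_hz))
    channels = np.zeros((n_cond, n_steps))
    triggers = []
    trial_table = []  # (condition, onset_s, repetition)
    t = gap_s
    for rep in range(n_repeats):
        for ci, cond in enumerate(conditions):
            i0 = int(round(t * rate_hz))
            i1 = int(round((t + flash_s) * rate_hz))
            channels[ci, i0:i1] = 1.0
            triggers.append(t)
            trial_table.append((cond, t, rep))
            t += epoch_s
    return StimulusProtocol(
        kind="flash_center_surround", channels=channels, condition_names=tuple(conditions),
        rate_hz=rate_hz, trigger_times_s=np.array(triggers), duration_s=duration_s,
        metadata={"center_diam_um": center_diam_um, "fullfield_diam_um": fullfield_diam_um,
                  "flash_s": flash_s, "gap_s": gap_s, "n_repeats": n_repeats,
                  "trial_table": trial_table},
    )


def _chirp_waveform(rate_hz: float) -> np.ndarray:
    """One ~32 s chirp: step, accelerating frequency sweep, contrast sweep."""
    def seg(dur, fn):
        t = np.arange(int(round(dur * rate_hz))) / rate_hz
        return fn(t)

    parts = [
        seg(2.0, lambda t: np.zeros_like(t)),                       # dark
        seg(3.0, lambda t: np.ones_like(t)),                        # bright step
        seg(3.0, lambda t: np.zeros_like(t)),
        seg(8.0, lambda t: 0.5 + 0.5 * np.sin(2 * np.pi * (0.5 * t + (7.5 / (2 * 8.0)) * t**2))),
        seg(2.0, lambda t: np.full_like(t, 0.5)),
        seg(8.0, lambda t: 0.5 + 0.5 * (t / 8.0) * np.sin(2 * np.pi * 2.0 * t)),
        seg(3.0, lambda t: np.zeros_like(t)),
    ]
    return np.concatenate(parts)


def make_chirp_protocol(n_repeats: int = 5, rate_hz: float = 100.0,
                        local: bool = False) -> StimulusProtocol:
    """Chirp probe (full-field or 100 µm local), repeated ``n_repeats`` times."""
    wave = _chirp_waveform(rate_hz)
    rep_s = wave.size / rate_hz
    channels = np.tile(wave, n_repeats)[None, :]
    triggers = np.arange(n_repeats) * rep_s
    return StimulusProtocol(
        kind="chirp_local" if local else "chirp_fullfield", channels=channels,
        condition_names=("chirp",), rate_hz=rate_hz, trigger_times_s=triggers,
        duration_s=rep_s * n_repeats,
        metadata={"diam_um": 100.0 if local else 700.0, "repeat_s": rep_s},
    )


def make_sine_protocol(freq_hz: float = 2.0, n_repeats: int = 3, epoch_s: float = 10.0,
                       rate_hz: float = 500.0) -> StimulusProtocol:
    """2 Hz sine modulation presented per condition (UV/green × center/surround)."""
    n_cond = 4
    n_epoch = int(round(epoch_s * rate_hz))
    duration_s = n_cond * n_repeats * epoch_s
    n_steps = n_cond * n_repeats * n_epoch
    channels = np.zeros((n_cond, n_steps))
    tt = np.arange(n_epoch) / rate_hz
    sine = np.sin(2 * np.pi * freq_hz * tt)
    triggers, trial_table = [], []
    k = 0
    for rep in range(n_repeats):
        for ci, cond in enumerate(FLICKER_CONDITIONS):
            channels[ci, k * n_epoch:(k + 1) * n_epoch] = sine
            triggers.append(k * epoch_s)
            trial_table.append((cond, k * epoch_s, rep))
            k += 1
    return StimulusProtocol(
        kind="sine_cs", channels=channels, condition_names=FLICKER_CONDITIONS,
        rate_hz=rate_hz, trigger_times_s=np.array(triggers), duration_s=duration_s,
        metadata={"freq_hz": freq_hz, "trial_table": trial_table, "epoch_s": epoch_s},
    )


# ---------------------------------------------------------------------------
# Ground-truth populations
# ---------------------------------------------------------------------------

def truth_spectral_contrast(w_green: float, w_uv: float, expected_sign: float) -> float:
    """Spectral contrast implied by a pair of signed condition weights.

    ``expected_sign`` is the sign of an expected-polarity response for the
    condition (e.g. −1 for a glutamate-decrease cone center, +1 for its
    antagonistic surround). Same-polarity pairs yield a Michelson contrast in
    [−1, 1]; a UV (green) weight antagonistic to expectation maps to the
    extended >1 (<−1) branches.
    """
    sc, _case = spectral_contrast(abs(w_green), abs(w_uv),
                                  green_expected=w_green * expected_sign >= 0,
                                  uv_expected=w_uv * expected_sign >= 0)
    return sc


def weights_from_sc(sc: float, expected_sign: float, amplitude: float = 1.0):
    """Invert the spectral-contrast cases to a (w_green, w_uv) weight pair.

    ``sc`` in [−1, 1] maps to same-polarity weights (Michelson); sc > 1 to a
    green-expected / UV-antagonistic pair; sc < −1 to UV-expected /
    green-antagonistic. ``|w_green| + |w_uv| = amplitude`` in every branch.
    """
    if not np.isfinite(sc):
        raise ValueError("sc must be finite")
    s = float(expected_sign)
    if abs(s) != 1.0:
        raise ValueError("expected_sign must be ±1")
    if -1.0 <= sc <= 1.0:
        g = amplitude * (1.0 + sc) / 2.0
        u = amplitude * (1.0 - sc) / 2.0
        return s * g, s * u
    if sc > 1.0:
        ratio = sc - 1.0  # |u| / |g|
        g = amplitude / (1.0 + ratio)
        u = amplitude * ratio / (1.0 + ratio)
        return s * g, -s * u
    ratio = 1.0 - sc  # |g| / |u|
    u = amplitude / (1.0 + ratio)
    g = amplitude * ratio / (1.0 + ratio)
    return -s * g, s * u


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_population(n_cells: int, layer: str = "OPL",
                    dorsoventral_range_mm=(-2.0, 2.0),
                    gradient_params: dict | None = None,
                    group_templates: dict | None = None,
                    seed: int = 0) -> list:
    """Cells laid out along the dorso-ventral opsin gradient.

    The expected center spectral contrast follows a logistic function of
    position (UV-dominant ventrally, green-dominant dorsally, mirroring
    S-/M-opsin co-expression in M-cones), with per-cell Gaussian jitter.
    Ventral cells receive green-shifted antagonistic surrounds (the
    rod/horizontal-cell pathway), so most of them are ground-truth opponent.

    gradient_params keys (defaults per layer, reflecting the much stronger
    surround green-shift at the photoreceptor stage than downstream):
    ``midpoint_mm`` (0.3), ``slope_mm`` (0.5), ``sc_jitter`` (0.15),
    ``sc_ventral`` / ``sc_dorsal`` (OPL −0.7 / 0.38; IPL −0.44 / 0.1;
    GCL −0.35 / 0.06), ``surround_sc_ventral`` / ``surround_sc_dorsal``
    (OPL 1.2 / 0.39; IPL 0.21 / 0.03; GCL 0.21 / 0.17), ``surround_jitter``
    (0.4), ``surround_scale`` (0.6).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if layer not in LAYER_DEFAULTS:
        raise ValueError(f"unknown layer {layer!r}")
    if layer == "GCL" and not group_templates:
        raise ValueError("GCL populations require group templates")
    layer_sc = {
        "OPL": dict(sc_ventral=-0.7, sc_dorsal=0.38,
                    surround_sc_ventral=1.2, surround_sc_dorsal=0.39),
        "IPL": dict(sc_ventral=-0.44, sc_dorsal=0.1,
                    surround_sc_ventral=0.21, surround_sc_dorsal=0.03),
        "GCL": dict(sc_ventral=-0.35, sc_dorsal=0.06,
                    surround_sc_ventral=0.21, surround_sc_dorsal=0.17),
    }
    gp = dict(midpoint_mm=0.3, slope_mm=0.5, sc_jitter=0.15,
              surround_jitter=0.4, surround_scale=0.6, **layer_sc[layer])
    gp.update(gradient_params or {})
    rng = np.random.default_rng(seed)
    lo, hi = dorsoventral_range_mm
    positions = rng.uniform(lo, hi, n_cells)
    tau0 = LAYER_DEFAULTS[layer]["kinetics_tau_s"]
    expected_sign = -1.0 if layer == "OPL" else 1.0
    polarity = "Off" if layer == "OPL" else "On"
    group_ids = sorted(group_templates) if group_templates else None

    cells = []
    for i in range(n_cells):
        p = positions[i]
        frac = _logistic((p - gp["midpoint_mm"]) / gp["slope_mm"])  # 0 ventral → 1 dorsal
        sc_c = gp["sc_ventral"] + frac * (gp["sc_dorsal"] - gp["sc_ventral"])
        sc_c += rng.normal(0, gp["sc_jitter"])
        wg_c, wu_c = weights_from_sc(sc_c, expected_sign)
        sc_s = gp["surround_sc_ventral"] + frac * (gp["surround_sc_dorsal"] - gp["surround_sc_ventral"])
        sc_s += rng.normal(0, gp["surround_jitter"])
        wg_s, wu_s = weights_from_sc(sc_s, -expected_sign, amplitude=gp["surround_scale"])
        cells.append(GroundTruthCell(
            position_mm=p, layer=layer,
            w_center_uv=wu_c, w_center_green=wg_c,
            w_surround_uv=wu_s, w_surround_green=wg_s,
            ipl_depth=float(rng.uniform(-0.1, 1.1)) if layer == "IPL" else None,
            polarity=polarity,
            kinetics_tau_s=float(tau0 * rng.lognormal(0, 0.2)),
            group_id=int(rng.choice(group_ids)) if group_ids else None,
        ))
    return cells


def make_population_from_sc(n_cells: int, layer: str,
                            center_sc_mean: float, center_sc_sd: float,
                            surround_sc_mean: float | None = None,
                            surround_sc_sd: float = 0.0,
                            surround_scale: float = 0.6,
                            position_mm: float = -1.5,
                            seed: int = 0) -> list:
    """Population whose ground-truth spectral contrasts are pinned.

    Per-cell center (and optionally surround) SC values are drawn from the
    given normal distributions and inverted to weights, so the population's
    direct-weight SC has the requested mean/s.d. — the construction used for
    parameter-recovery benchmarks against reported population means.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    expected_sign = -1.0 if layer == "OPL" else 1.0
    tau0 = LAYER_DEFAULTS[layer]["kinetics_tau_s"]
    cells = []
    for i in range(n_cells):
        sc_c = rng.normal(center_sc_mean, center_sc_sd)
        wg_c, wu_c = weights_from_sc(sc_c, expected_sign)
        wg_s = wu_s = 0.0
        if surround_sc_mean is not None:
            sc_s = rng.normal(surround_sc_mean, surround_sc_sd)
            wg_s, wu_s = weights_from_sc(sc_s, -expected_sign, amplitude=surround_scale)
        cells.append(GroundTruthCell(
            position_mm=position_mm, layer=layer,
            w_center_uv=wu_c, w_center_green=wg_c,
            w_surround_uv=wu_s, w_surround_green=wg_s,
            polarity="Off" if layer == "OPL" else "On",
            kinetics_tau_s=float(tau0 * rng.lognormal(0, 0.2)),
        ))
    return cells


# ---------------------------------------------------------------------------
# LN response simulation
# ---------------------------------------------------------------------------

def _softplus(x):
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)

#: Tonic operating point of the softplus output stage. Large enough that the
#: cascade is close to linear for unit-scale drives (tonic glutamate release
#: rectifies only under strong hyperpolarization).
SOFTPLUS_OFFSET = 3.0


def _condition_weight(cell: GroundTruthCell, name: str) -> float:
    if name.endswith("fullfield"):
        base = name.split("_")[0]
        return (getattr(cell, f"w_center_{base}") + getattr(cell, f"w_surround_{base}"))
    if name == "chirp":
        return cell.w_center_uv + cell.w_center_green
    try:
        return getattr(cell, f"w_{name.split('_', 1)[1]}_{name.split('_', 1)[0]}")
    except AttributeError:
        raise ValueError(f"cell has no weight for condition {name!r}")


def simulate_cell_response(cell: GroundTruthCell, protocol: StimulusProtocol,
                           noise_sd: float = 0.0, seed: int = 0,
                           nonlinearity: str = "softplus",
                           out_rate_hz: float = 500.0) -> np.ndarray:
    """LN-cascade response of one cell to a protocol, on a uniform time grid.

    ``trace = N( Σ_c w_c · (h ⊛ S_c) ) + ε`` with an exponential-decay
    temporal filter h (unit area, time constant ``cell.kinetics_tau_s``),
    ``N`` either identity or an offset softplus, and iid Gaussian ε.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    names = list(protocol.condition_names)
    weights = np.array([_condition_weight(cell, n) for n in names])

    n_out = int(round(protocol.duration_s * out_rate_hz))
    t_out = np.arange(n_out) / out_rate_hz
    idx = np.minimum((t_out * protocol.rate_hz).astype(int), protocol.n_steps - 1)
    drive_stim = weights @ protocol.channels  # combine on the stimulus grid first
    drive = drive_stim[idx]

    dt = 1.0 / out_rate_hz
    tau = cell.kinetics_tau_s
    n_k = max(int(round(5 * tau / dt)), 1)
    h = np.exp(-np.arange(n_k) * dt / tau)
    h /= h.sum()
    filtered = np.convolve(drive, h)[:n_out]

    if nonlinearity == "identity":
        out = filtered
    elif nonlinearity == "softplus":
        out = _softplus(filtered + SOFTPLUS_OFFSET)
    else:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    if noise_sd > 0:
        out = out + np.random.default_rng(seed).normal(0, noise_sd, n_out)
    return out


def noise_sd_for_snr(cell: GroundTruthCell, protocol: StimulusProtocol, snr: float,
                     nonlinearity: str = "softplus", out_rate_hz: float = 500.0) -> float:
    """Noise s.d. giving the requested response-amplitude SNR.

    Amplitude is the peak absolute deviation of the noiseless response from
    its median for flash protocols (flash response amplitude), and the
    response s.d. for continuously modulated stimuli.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = simulate_cell_response(cell, protocol, noise_sd=0.0,
                                   nonlinearity=nonlinearity, out_rate_hz=out_rate_hz)
    if protocol.kind.startswith("flash"):
        amp = float(np.max(np.abs(clean - np.median(clean))))
    else:
        amp = float(np.std(clean))
    return amp / snr


# ---------------------------------------------------------------------------
# Scan-field movies
# ---------------------------------------------------------------------------

@dataclass
class FieldGeometry:
    """Spatial layout and noise of a simulated scan field."""

    shape: tuple = (64, 64)
    um_per_px: float = 0.85
    terminal_diam_um: float = 5.0      # also the mosaic exclusion radius
    pixel_noise_sd: float = 0.1
    baseline_f: float = 1.0            # tonic fluorescence offset
    signal_amp: float = 0.5
    margin_um: float = 2.0
    max_placement_tries: int = 20000


def _place_mosaic(n: int, geom: FieldGeometry, rng) -> np.ndarray:
    """Dart-throwing placement with an exclusion zone of one terminal diameter."""
    h_um = geom.shape[0] * geom.um_per_px
    w_um = geom.shape[1] * geom.um_per_px
    m = geom.margin_um
    pts = []
    tries = 0
    while len(pts) < n:
        if tries > geom.max_placement_tries:
            raise RuntimeError(
                f"could not place {n} terminals with exclusion {geom.terminal_diam_um} µm "
                f"in a {h_um:.0f}×{w_um:.0f} µm field")
        tries += 1
        cand = np.array([rng.uniform(m, h_um - m), rng.uniform(m, w_um - m)])
        if all(np.hypot(*(cand - p)) >= geom.terminal_diam_um for p in pts):
            pts.append(cand)
    return np.array(pts)


def simulate_scan_field(cells: list, geom: FieldGeometry, protocol: StimulusProtocol,
                        seed: int = 0, rate_hz: float = 7.8125, layer: str = "OPL",
                        position_mm: float = 0.0, noise_sd_trace: float = 0.0,
                        chat_band_rows: tuple | None = None) -> ScanFieldMovie:
    """Render cells as Gaussian terminals on an exclusion-zone mosaic.

    Every pixel of a terminal carries that cell's response trace scaled by a
    Gaussian spatial profile, plus independent pixel noise — the shared-signal
    correlation structure that correlation-based ROI detection exploits.
    """
    rng = np.random.default_rng(seed)
    centers_um = _place_mosaic(len(cells), geom, rng)
    centers_px = centers_um / geom.um_per_px

    n_frames = int(round(protocol.duration_s * rate_hz))
    rows, cols = geom.shape
    rr, cc = np.mgrid[0:rows, 0:cols]

    movie = np.full((rows, cols, n_frames), geom.baseline_f)
    truth_mask = np.zeros((rows, cols), dtype=int)
    sigma_px = geom.terminal_diam_um / 4.0 / geom.um_per_px
    radius_px = geom.terminal_diam_um / 2.0 / geom.um_per_px

    for i, (cell, c_px) in enumerate(zip(cells, centers_px)):
        trace = simulate_cell_response(cell, protocol, noise_sd=noise_sd_trace,
                                       seed=int(rng.integers(2**31)), out_rate_hz=rate_hz)
        trace = trace[:n_frames]
        d2 = (rr - c_px[0]) ** 2 + (cc - c_px[1]) ** 2
        profile = np.exp(-d2 / (2 * sigma_px**2))
        inside = d2 <= radius_px**2
        truth_mask[inside] = i + 1
        movie[inside] += geom.signal_amp * profile[inside, None] * trace[None, :]
    if geom.pixel_noise_sd > 0:
        movie += rng.normal(0, geom.pixel_noise_sd, movie.shape)
    return ScanFieldMovie(
        pixels=movie, rate_hz=rate_hz, um_per_px=geom.um_per_px, layer=layer,
        position_mm=position_mm, chat_band_rows=chat_band_rows,
        truth_mask=truth_mask, truth_cells=list(cells), truth_centers_px=centers_px,
    )


# ---------------------------------------------------------------------------
# Functional-group templates (synthetic stand-ins for a published cluster set)
# ---------------------------------------------------------------------------

def make_group_templates(n_groups: int = 8, seed: int = 0, rate_hz: float = 31.25,
                         chirp_s: float = 32.0, bar_s: float = 4.0) -> dict:
    """Synthetic chirp/moving-bar mean traces for ``n_groups`` functional groups.

    Each template is a smoothed random trace, so templates are mutually
    distinguishable but carry no particular physiological shape — only the
    relative correlation structure matters for match-index assignment.
    Returns ``{group_id: {"chirp": array, "bar": array, "is_ds": bool,
    "is_alpha": bool}}``.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    out = {}
    for g in range(1, n_groups + 1):
        chirp = gaussian_filter1d(rng.standard_normal(int(chirp_s * rate_hz)), 8)
        bar = gaussian_filter1d(rng.standard_normal(int(bar_s * rate_hz)), 8)
        out[g] = {
            "chirp": chirp / np.std(chirp),
            "bar": bar / np.std(bar),
            "is_ds": bool(g % 4 == 0),
            "is_alpha": bool(g % 5 == 0),
            "rate_hz": rate_hz,
        }
    return out
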