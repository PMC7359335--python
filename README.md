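# retinachrome

Analysis pipeline for chromatic processing in two-photon functional imaging
of the mouse retina — from scan-field fluorescence movies to per-cell
spectral-contrast and color-opponency statistics and group-level permutation
tests, together with a ground-truth synthetic data generator that makes every
stage testable at desk scale.

Mouse vision is dichromatic: UV-sensitive S-opsin and green-sensitive
M-opsin are co-expressed in cones along a steep dorso-ventral gradient, and
green (rod/horizontal-cell-driven) signals can oppose UV signals in a cell's
receptive-field surround. Quantifying this requires the same statistics at
three processing stages — cone terminals (OPL), bipolar-cell terminals
(IPL), and ganglion-cell-layer somata (GCL) — which is what this package
implements, for people analysing iGluSnFR/OGB-1 recordings or building
simulations of them.

## The statistics at the core

**Spectral contrast (SC).** For absolute response areas F_green, F_UV with
the same response polarity, SC is the Michelson contrast

    SC = (|F_g| − |F_uv|) / (|F_g| + |F_uv|)           ∈ [−1, 1],

−1 for a purely UV-driven cell, +1 for purely green. When one color responds
with the polarity expected for the condition and the other antagonistically,
SC extends beyond that range:

    green expected, UV antagonistic:  SC = 1 + |F_uv|/|F_g|   (> 1)
    UV expected, green antagonistic:  SC = 1 − |F_g|/|F_uv|   (< 1)

`SC_Diff = SC_surround − SC_center` measures how chromatically distinct a
cell's surround is from its center.

**Event-triggered kernels.** Responses to binary center-surround flicker are
summarised by transient-triggered average stimuli. Events are positive
transients of the trace derivative exceeding a robust threshold
σ = median(|r(t)|)/0.6745; each event is weighted by its derivative
amplitude c(t_i) and the kernel per stimulus condition is
F(x, τ) = (1/M) Σᵢ c(tᵢ) · S(x, tᵢ + τ).

**Quality indices.** Kernel and event quality compare signal-window to
baseline-window area, Qi = 1 − |F_Area(Baseline)|/|F_Area(Signal)|; trial-
structured stimuli use the repetition signal-to-noise ratio
Qi = Var_t[⟨C⟩_r] / ⟨Var_t[C]⟩_r, which is 1 for identical repetitions and
≈ 1/R for pure noise.

**Opponency and population statistics.** Full-field color opponency is
min(ρ_onset, ρ_offset), the worse of the UV-vs-green correlations of onset
and offset response kernels; a cell is opponent when either falls below
−0.3. Field entropy (Shannon entropy of SC binned at 0.2) measures chromatic
heterogeneity per scan field; density recovery profiles expose mosaic
exclusion zones; direction selectivity uses an SVD tuning curve with a
permutation test; and a stratified permutation test (matching on SC_Diff
bins and center SC) asks whether a functional cell group is more or less
color-opponent than its chromatic composition predicts.

## Worked example

Simulate a ventral cone (UV-dominant center that decreases glutamate
release, green antagonistic surround), present the interleaved UV/green
center/surround/full-field flash protocol, and run the flash analysis path:

```python
import numpy as np
from retinachrome import synthetic_data as sd
from retinachrome.pipeline import analyze_flash_response
from retinachrome.trace_processing import highpass_detrend

cone = sd.GroundTruthCell(position_mm=-1.5, layer="OPL",
                          w_center_uv=-0.85, w_center_green=-0.15,
                          w_surround_uv=-0.06, w_surround_green=0.54,
                          kinetics_tau_s=0.15)
protocol = sd.make_flash_protocol(center_diam_um=150, fullfield_diam_um=700,
                                  n_repeats=25)
noise_sd = sd.noise_sd_for_snr(cone, protocol, snr=5.0)
trace = sd.simulate_cell_response(cone, protocol, noise_sd=noise_sd, seed=1)
trace = highpass_detrend(trace, 500.0)[0]

res = analyze_flash_response(trace, 500.0, protocol)
print(f"SC_center    = {res['sc_center']:+.2f}  (case {res['sc_center_case']})")
print(f"SC_surround  = {res['sc_surround']:+.2f}  (case {res['sc_surround_case']})")
print(f"SC_Diff      = {res['sc_diff']:+.2f}")
print(f"rho_onset    = {res['rho_onset']:+.2f}, rho_offset = {res['rho_offset']:+.2f}")
print(f"color-opponent: {res['is_opponent']}")
```

prints

```
SC_center    = -0.71  (case 1)
SC_surround  = +1.12  (case 2)
SC_Diff      = +1.83
rho_onset    = -0.96, rho_offset = -0.95
color-opponent: True
```

The cell's center is UV-dominant (SC_center −0.71, Michelson case), its
surround is green with an antagonistic UV component (case 2, beyond +1), the
large SC_Diff marks chromatically opposed center and surround, and the
strongly negative onset/offset correlations classify it color-opponent —
recovering the ground truth the generator put in (weight-implied
SC_center = −0.70, SC_surround = +1.11).

There is also a thin CLI: `retinachrome synth|segment|run|grouptest --help`.

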