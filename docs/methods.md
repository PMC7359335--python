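# Methods

This note documents the models, estimators and numerical choices behind
`retinachrome`, in the order data flows through the pipeline, and states
what the synthetic benchmarks do and do not demonstrate.

## Synthetic data model

**Response model.** Each ground-truth cell is a linear–nonlinear (LN)
cascade. Four (or six, for flash protocols) stimulus conditions — UV/green ×
center/surround(/full-field) — are each scaled by a signed weight, summed,
convolved with an exponential-decay temporal filter of unit area, passed
through an output nonlinearity, and corrupted with iid Gaussian noise:

    r(t) = N( Σ_c w_c · (h_τ ⊛ S_c)(t) ) + ε(t),   h_τ(u) ∝ e^(−u/τ)

The default nonlinearity is an offset softplus, `softplus(x + 3)`: a tonic
operating point on the quasi-linear part of the curve, rectifying only
strong hyperpolarizations — the behaviour of tonic glutamate release. An
identity option exists for linearity tests. Full-field weights are the sum
of center and surround weights of the same color.

*Sign convention.* Weights are signed response gains in trace units. Outer
retina (cone/glutamate) populations carry negative center weights — a light
increment decreases release — and positive antagonistic-surround weights.

*Filter time constant.* Defaults: 0.15 s for OPL/IPL glutamate (indicator
plus release kinetics; spreads flicker kernels over several 100 ms stimulus
steps, as in recorded kernels), 0.3 s for GCL calcium. Per-cell lognormal
jitter (σ = 0.2) around the default.

**Weights from spectral contrast.** Populations can be pinned to a target
SC distribution: per-cell SC values are drawn from a normal distribution and
inverted to a weight pair with |w_g| + |w_uv| = 1. SC in [−1, 1] inverts the
Michelson case with both weights at the condition's expected sign; SC > 1
and SC < −1 invert the two antagonistic cases. The inversion is exact by
construction (round-trip property-tested), so a population's *direct-weight*
SC distribution has the requested mean and s.d. without calibration.

**Opsin gradient.** `make_population` places cells along the dorso-ventral
axis and sets the expected center SC as a logistic function of position
(midpoint +0.3 mm, slope 0.5 mm), interpolating between layer-specific
ventral and dorsal endpoint values, with Gaussian per-cell jitter
(σ = 0.15). Surround SC follows its own, strongly green-shifted ventral
endpoint at the photoreceptor stage — the rod/horizontal-cell pathway —
making most ventral cells ground-truth color-opponent.

**Stimuli.** Balanced flicker sequences are shuffles of an exactly
half-high ±1 template (balance holds exactly, not just in expectation),
independent across the four conditions; defaults 180 s at 10 Hz (inner
retina) and 300 s at 5 Hz (GCL). Flash protocols interleave six conditions
as 1 s flash + 1 s gap epochs with a 1 s lead-in; stimulus geometry (150 µm
center, 700 µm full field, annular surround) is metadata, since spatial
integration lives in the weights. Chirp, 2 Hz sine, and moving-bar templates
are piecewise-analytic; only their correlation structure matters here.

**Scan fields.** Terminals are placed by dart-throwing with an exclusion
radius of one terminal diameter (the mosaic the density recovery profile
should detect) and rendered as Gaussian discs (σ = diameter/4); every pixel
of a terminal carries the cell's trace scaled by the spatial profile on a
tonic fluorescence offset, plus independent pixel noise. Neighbouring
pixels of one cell therefore share a signal — the correlation structure the
ROI detector exploits.

**Noise scale.** `noise_sd_for_snr` defines SNR as peak absolute response
amplitude over noise s.d. for flash protocols, and response s.d. over noise
s.d. for continuously modulated stimuli. Noise is iid within and across
trials; real rod/cone recordings have correlated (photon, motion, shared
network) noise this generator does not emulate, so recovery benchmarks
bound estimator behaviour under white noise only.

## ROI detection

The local correlation image is each pixel's mean Pearson correlation with
its 8-neighbourhood (borders use existing neighbours; a zero-variance pixel
contributes 0). Segmentation thresholds this image (auto mode: Otsu split
clamped to [0.1, 0.9]), places markers at local maxima at least one
terminal radius apart, grows regions by watershed on the negated
correlation image (splitting merged units), and discards components whose
equivalent diameter leaves the layer's range (3–7 µm cone terminals, 1–4 µm
BC terminals; GCL soma bounds by analogy). IPL depth is linear in the
centroid row between the two ChAT bands (0 = On, 1 = Off, extrapolated
beyond).

## Trace processing

ΔF/F uses F0 = 8th percentile of the raw ROI trace — robust to response
transients, and making ΔF/F invariant to multiplicative gain. Traces are
linearly interpolated onto a 500 Hz grid phase-anchored at the first
stimulus trigger; each ROI's input time base is shifted by its scan-line
offset, (row / n_rows) / frame_rate, before interpolation. The grid stays
inside the sampled support, so resampling aligned input is a no-op.
Detrending is a zero-phase 2nd-order Butterworth high-pass at 0.1 Hz
(zero-phase so kernel latencies are unbiased). Trial summaries are
pointwise medians across repetitions; the T×R repetition matrix feeds the
SNR quality index.

Because the 0.1 Hz filter's timescale (~10 s) spans several 2 s flash
epochs, large responses smear into neighbouring epochs. Flash response
areas therefore subtract a *linear* per-trial baseline through the
pre-onset window (0.2 s) and a late tail window (0.2 s, after the response
has decayed): smear that is approximately linear over one epoch cancels.

## Event detection and kernels

The trace is boxcar-smoothed over 50 ms (matched to the filter kinetics;
without it, white noise at 500 Hz dominates the derivative), differentiated
(first difference × rate), and thresholded at σ = median(|d|)/0.6745
computed on the derivative. Events are plateau-tolerant local maxima above
σ, ties resolved to the earliest sample; peaks within a few samples are one
transient (within a full smoothing window on a noise-free trace, where any
positive transient counts because σ degenerates to 0). Event weights are
the derivative values.

Stimulus kernels are computed on the stimulus time base over a lag window
of 2.0 s for 10 Hz flicker (1.0 s at 5 Hz): wide enough for the sub-second
kernel plus a pre-kernel baseline region. The divisor is the event count M,
so kernel amplitude is only meaningful relative to other conditions of the
same cell. A vectorized implementation is verified against a per-event
reference loop at 1e-12. Full-field event kernels average the trace from
0.1 s before to 1.0 s after each light increment/decrement, baseline-
subtracted on the pre-step window.

Because events weight each sample by the derivative, the kernels of a white
binary stimulus are biphasic (the step *into* the driving state appears
with opposite sign one lag earlier); polarity decisions therefore use the
dominant lobe, never the kernel's integral.

## Signed response areas and spectral contrast

*Flash traces* (outer retina): the signed area is the integral of the
baseline-corrected trial median over the response window (flash + 0.5 s);
polarity is the sign of that area against a per-condition expectation table
(center and full-field expect a decrease, antagonistic surround an
increase).

*Flicker kernels*: all of a cell's condition kernels share its temporal
filter shape, so the response area is estimated by projecting each kernel
onto the unit-norm dominant-center-kernel shape over the last 0.5 s of lags
and rescaling to the reference's rectified area. An unweighted integral
over the full lag window would accumulate stimulus-sampling noise in the
~17 lag bins where the true kernel carries no mass and destroy the UV:green
ratio; the projection is exact for noiseless LN cells. The projection's
sign is the anticorrelated-vs-reference polarity call (an antagonistic
surround gets a negative area).

When the two center kernels have opposite signs, the kernels alone cannot
decide which color carries the *expected* polarity — relabeling swaps the
two antagonistic SC branches. `analyze_flicker_response` accepts the cell's
polarity (in practice known from chirp/flash responses or stratification
depth) as `expected_center_sign` and orients the reference kernel's
dominant lobe accordingly; without it the dominant center is assumed
expected.

SC itself follows the three-case definition given in the README; the case
identifier is stored with every value because the antagonistic branches
overlap the Michelson range. Undefined situations (both areas zero, a zero
denominator in an antagonistic branch) are flagged, not guessed.

## Quality indices and filters

Qi_Kernel compares the per-unit-time RMS area of the earliest 25% of the
lag window (baseline, far from the event) against the remainder. Per-time
RMS was chosen over a plain or rectified integral because the baseline
window has only ~5 lag bins: integral forms give a null (weight-zero cell)
a 20–40% chance of exceeding the 0.6 inclusion threshold, while the RMS
ratio's null concentrates tightly (≈3% exceedance, property-tested), with
no loss on responsive cells. No window mean is subtracted — subtracting the
short baseline window's own mean deflates its RMS and biases the index up.
Qi_Event uses the same form on the pre-/post-step windows of event
kernels; the repetition SNR index uses population variances (ddof = 0).

Inclusion defaults: OPL — hyperpolarizing center or full-field response and
Qi > 0.25, surround analysis additionally requiring an antagonistic
surround with area > |center|/10; IPL/GCL — Qi_Kernel > 0.6 for either
center color; GCL grouping — additionally Qi_Chirp > 0.4 or Qi_Bars > 0.6;
scan fields with under 50% passing cells are dropped whole. Every decision
is written to an audit log (roi, rule, value, threshold, outcome).

## Population statistics

*Density recovery profile*: per-reference-point radial histograms (2 µm
bins) normalised by annulus area and averaged. Reference points are by
default restricted to at least `max_radius` from the point set's bounding
box (all points remain targets), removing the border-truncation bias that
otherwise depresses large-radius bins; pass `guard_um=0` for tiny fields.

*Field entropy*: SC binned at width 0.2 with edges anchored at 0; p_i are
bin **proportions** (with raw counts the expression is not an entropy) and
0·log 0 ≡ 0.

*Direction selectivity*: SVD of the trial-mean time × direction matrix; the
first right-singular vector, sign-oriented so its inner product with the
mean response across time is positive, is the tuning curve. DSI is the
vector-sum length normalised by Σ|w| (the raw length is also returned, as
some traditions report it unnormalised). The permutation test shuffles
direction labels independently within each trial, 1000 surrogates by
default, p = (1 + #{null ≥ observed})/(1 + n_perm).

*Cluster match*: chirp traces are shifted 40 ms and boxcar-smoothed over 5
samples before correlation (compensating a stimulation frame-rate
mismatch); candidates are class-restricted (DS cells to DS groups, alpha
cells — soma area > 170 µm² — to alpha groups, others to the rest);
Mi = [Qi_C r_C + Qi_B r_B]/(Qi_C + Qi_B); assignment requires Mi > 0.5.
The packaged template set is synthetic (smoothed noise with the right
correlation structure), a stand-in carrying the same interface as a
published cluster library.

*Group opponency test*: SC_Diff binned at 0.25 (edges anchored at 0) across
all groups; each group cell is replaced, per iteration, by a uniformly drawn
*different* cell from the same bin with center SC within ±0.1 (same-group
partners allowed; a cell with an empty partner pool keeps its own label and
is counted in `n_unmatched`). 10,000 iterations by default. The observed
percentage's mid-percentile within the null is reported together with a
two-sided p = 2·min(pct, 1−pct), since both enrichment and depletion are of
interest; groups with ≤ 15 cells are skipped.

## Pipeline

`run_pipeline` chains synthesis → correlation segmentation → ΔF/F →
alignment/detrending → per-cell analysis → QC filtering → field summaries
from a serializable `RunConfig` whose single seed fans out to fixed
per-stage child seeds, making stages independently reproducible and whole
runs bit-identical.

## Benchmark design and known limitations

- **Recovery benchmarks** pin generator populations to target SC
  distributions and compare the pipeline's recovered population mean. In
  the flicker benchmark each cell receives its own balanced sequence
  realization (as each recorded field would): a single 1800-step sequence
  has cross-channel sample correlations of order 1/√1800 that leak the
  dominant channel into the weaker one as a *shared* bias; independent
  sequences average it out.
- **Event-selection bias.** Thresholding events on the summed drive
  conditions the selected samples jointly across channels; at zero noise
  the robust σ measures signal rather than noise and this conditioning
  biases cross-channel kernel ratios by ~10–15% (an unselected
  derivative-weighted control is exact). At realistic noise the threshold
  regains its intended meaning and the residual bias on population-mean SC
  is small; benchmarks therefore run at the study's SNR, and the noiseless
  exactness tests use single-pathway cells, where no cross-channel
  conditioning exists.
- **Group-test calibration** is slightly anti-conservative when groups are
  large relative to their matching pools (the null's center is then itself
  noisy); calibration tests use many small groups over shared strata,
  the regime of the real application. The reported percentile is a
  mid-p value; with few iterations it is discrete.
- The DRP χ² flatness check inherits variance inflation from pairs being
  counted from both endpoints; it is assessed on the average p across
  seeds.
- The generator's noise is white; quality indices and recovery rates on
  real, temporally correlated noise will differ, and nothing here validates
  the biological interpretation of opponency — only the statistics'
  behaviour under their stated assumptions.
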