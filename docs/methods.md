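# Methods

## Signal model

The simulator and the analysis share one signal model.  The detected power
per pixel and frame is `P_d = P_r · (1 + C_bg(x, t) + Σᵢ Cᵢ · G(x − xᵢ; σ))`
with reference power `P_r = r²·P_i` (default r = 0.1, P_i = 2×10⁶
photons/pixel/frame, so P_r = 2×10⁴ e⁻); the pure scattered-intensity term
is negligible for single proteins and omitted.  `G` is the instrument PSF,
approximated as an isotropic Gaussian of HWHM 2.5 px (σ = 2.5/√(2 ln 2) ≈
2.12 px).  An event's signed contrast is `C = sign · slope · mass`, with a
default slope of 3×10⁻⁵ contrast/kDa (a 66 kDa protein sits at ≈ 2×10⁻³)
and a single sign per stack (negative by default; the interferometric phase
permits either).  Landing is an instantaneous step in time: the V-shaped
trace seen in the analysis arises purely from DRA windowing, so no approach
dynamics are simulated.

### Background

- **Static speckle**: white Gaussian noise low-pass filtered by the PSF and
  rescaled to a configured RMS (default 1.5×10⁻² contrast).  This encodes
  the one structural fact that matters: the background's spatial
  correlation length equals the PSF's, which is what makes it hard to
  distinguish from real particles.
- **Slow drift**: the speckle is modulated by `(1 + d(t))` where `d(t)` is
  Gaussian-filtered white noise with correlation time τ (default 1,000
  frames) and stationary RMS 0.3.  A smooth (differentiable) process was
  chosen deliberately: real mechanical/thermal/fluidic drifts are smooth,
  so the DRA residue they leave is *predictable from neighboring frames* —
  exactly the structure the self-supervised denoiser exploits.  A
  white-innovation process (e.g. Ornstein–Uhlenbeck) looks similar
  per-frame but its block-mean differences are white in time, which makes
  the DRA residue information-theoretically unpredictable from frames ±2N
  away; under such a background no neighbor-prediction scheme can work,
  contradicting the premise of the method being modeled.
- **Shot noise and camera**: per-pixel Poisson draws at the rendered photon
  means, rounded and clipped to the bit depth (16-bit default).

With the default window N = 200 this puts the residual DRA background at
roughly 1–2×10⁻³ contrast RMS, with the smooth drift residue comparable to
or larger than the shot-noise floor `√(2/(N·P_r))` ≈ 7×10⁻⁴ — the
structured-background-limited regime in which ML-based anomaly detection
has something real to remove.  The realized drift residue varies noticeably
between stacks (one smooth path per stack), which is why all SNR-calibrated
protocols measure the background RMS on an event-free *twin* of each stack
(identical speckle and drift substreams, events disabled) rather than once
globally.

### What the simulator does not emulate

Sample impurities and oligomers (except as explicit mixture draws in
photometry tests), mobile/diffusing particles, vectorial PSF effects,
camera fixed-pattern noise, TIRF evanescent-decay physics (the TIRF channel
is an incoherent spot per labeled event with Bernoulli labeling), and
interlaced acquisition gaps.  Passing tests therefore demonstrate that the
pipeline implements its algorithms correctly and reaches the intended
operating points *under this background model* — not that any particular
real instrument reaches them.

## DRA

`out[t] = mean(raw[t : t+N]) / mean(raw[t−N : t]) − 1`, pixel-wise, in
float64, output anchored to the first frame of the trailing half (output
index i ↔ raw frame i + N).  Ratio rather than difference is the default
because contrast is a relative quantity and the ratio is exactly invariant
under global gain; difference mode is available behind `mode="diff"`.
Division by the local background means a recovered contrast is `C/(1+bg)`,
a ≤ ~2% systematic for the default speckle — inherent to ratiometric
detection, not corrected.  A circular field mask (R = 33 px) excludes
border artifacts from all statistics; masked pixels are NaN sentinels.

## Detection paths

Analysis frames are taken every N/2 frames (half the DRA window), so every
landing transient (full width 2N) is sampled within 25% of its peak.

**Feature path.**  Per analysis frame, each unmasked pixel gets temporal
mean/std/slope/min/max over a ±2-frame window and spatial PSF-template
correlation and 3×3 variance on the frame itself; columns are standardized;
an isolation forest (100 trees, subsample 256, seeded) flags the
contamination quantile (default 0.01).  The bank is a re-derived default
covering the categories such pipelines use, not a copy of any particular
instrument's configuration.

**Denoiser path.**  A deliberately tiny convolutional regressor (three 3×3
conv layers, 8 channels, ~800 parameters, ReLU, zero-initialized output
layer) is trained with Adam (lr 5×10⁻³, 15 epochs × 40 batches of 8 random
32×32 patches) to predict frame t from frames t−k and t+k, k = 2N by
default so that both inputs are outside any transient peaking at t.  It is
implemented directly on numpy (im2col convolutions, manual backprop): the
prediction task is nearly linear, low capacity doubles as a guard against
memorizing the rare events, and training takes seconds on one core.  Rare
events are not masked out of the training loss; their contribution is
negligible.  The residual `frame_t − prediction` is matched-filtered with
the PSF (Gaussian smoothing — the optimal filter for a PSF-shaped signal in
spatially white shot noise, worth ~3× in SNR) and rank-normalized over
unmasked pixels to a probability map in [0, 1].  Maps are classified by the
same isolation-forest engine; by default each map is classified alone —
neighboring analysis frames share raw frames, so their rank maps are
strongly correlated and joint classification adds instability, not
information.  Flagged pixels must also rank above the median (anomalously
*quiet* pixels are not candidate events).

Both paths end with a morphological filter: 8-connected components smaller
than `min_connected` (default 2) are removed, since a real event is a PSF
and always covers neighboring pixels.

## Consolidation and verification

Because the classifiers flag a fixed pixel quantile per frame, masks are
never empty and candidate generation alone cannot bound the false-positive
rate.  Consolidation therefore has two stages:

1. **Candidate extraction.**  Masks are grouped into detection windows
   (silent gaps > N frames split them; within a run, windows are chunked to
   2N frames — one transient width — so that re-landings at the same
   position in disjoint windows stay distinct).  Hot-pixel counts per
   window are convolved with the PSF (HWHM 2.5 px) and candidates are
   extracted greedily: global maximum, center of mass within the 5-px
   binary-mask radius, clear everything within twice the mask radius (the
   non-overlap counting rule), repeat down to a robust noise floor
   (median + 3×1.4826×MAD of the density's nonzero support; robust
   statistics so that busy stacks with many true events do not drag the
   floor up).  Ties break lexicographically; duplicates of one transient
   extracted from adjacent chunks are merged, keeping the stronger.
2. **Matched-filter verification.**  A real landing leaves a deterministic
   signature in the residual video: PSF in space, triangular tent of full
   width 2N in time.  The PSF-smoothed residual at the candidate center is
   sampled over ±1.5N and projected onto zero-mean unit-norm tent
   templates (vertex scanned over ±N/2).  The null is self-calibrating:
   the same max-over-vertices statistic at 60 control positions elsewhere
   in the field, over the same frames, gives a robust z (median/MAD).
   Candidates below `verify_min_score` (default 3.5) are discarded.  The
   operating point was chosen from the simulated score distributions:
   clutter candidates — the flagged quantile of event-free frames — rarely
   exceed ~4, while true landings score roughly 3×SNR, so 3.5 admits most
   events from SNR ≈ 1.4 upward at a consolidated false-positive rate of a
   few percent.  Verification uses the denoiser residual for both paths
   (the verification denoiser is trained once per stack), keeping all
   downstream processing shared.
3. **Prediction-ghost suppression.**  A neighbor-prediction denoiser
   interpolates a landing transient from its inputs, so every real event
   leaves a half-amplitude echo in the residual at the same position offset
   by ±k frames — strong enough to pass verification at SNR ≥ 3.  Among
   detections at one position (within twice the mask radius) whose
   midpoints lie within k + N frames of each other, only the strongest is
   kept; the others are its echoes or chunk-boundary splits.  The cost is
   that genuine re-landings at the same spot within k + N frames collapse
   into one event — an accepted trade, since such events are not countable
   under the non-overlap rule anyway.

## Photometry

DoG localization (σ₁ = PSF σ, σ₂ = 1.6σ₁) with separable quadratic
sub-pixel refinement; candidates whose |DoG| extremum stays within 5 robust
standard deviations of the in-region response are flagged unlocalizable.
The V-trace is the bilinear sample of the DRA stack at the fixed localized
center over ±N frames around the event.  The two-line fit searches all
interior breakpoints exhaustively (traces are short), takes the
least-total-SSE split, and reports `|vertex − baseline|` with the baseline
defined as the mean level the two fitted lines reach at the trace ends —
the pre/post-event background, which makes the estimate exactly
offset-invariant.  Traces that a single line fits within 5% SSE of the best
split (or exactly linear traces) are rejected as non-V.

Population analysis: Gaussian mixtures of 1..4 components (BIC selection;
covariance regularization scaled to the sample variance — contrasts live at
the 10⁻³ scale, far below sklearn's absolute default floor).  The main mode
is the component with the smallest |mean| among those with weight > 0.1 —
monomers are the lightest abundant subpopulation; heavier components are
oligomers, aggregates, or impurities.  The mode contrast is the Gaussian
MLE (sample mean) over events within ±2σ of the selected component, and its
CI comes from bootstrapping events with replacement (> 1,000 cycles
enforced), recentering the ±2σ selection window on each resample's median
so the window-location uncertainty enters the interval (without this the
CI undercovers by several percent).

## Calibration and coincidence

Ordinary least squares with a free intercept on the (mass, main-mode
contrast) ladder — residual background biases the baseline, so a small
nonzero intercept is expected and estimated, not suppressed.  Accuracy per
point is the residual divided by the slope (kDa); precision is the
bootstrap CI half-width converted to kDa as a percentage of the nominal
mass; the fit's RMS deviation is reported in contrast units.  Coincidence
matches events greedily nearest-first within a 3-px radius (and an optional
frame tolerance for interlaced acquisition) and reports per-channel yields
plus the pixel-wise product of the two channels' binary event-mask images.

## Reproducibility and problem sizes

Every stochastic stage consumes `derive_seed(global_seed, stage_name)` =
`crc32(name) XOR (0x9E3779B1·seed)` folded to 31 bits; no stage reads
ambient randomness, and re-running a config reproduces all outputs.

Validation protocols run at desk scale on one core: the false-positive
protocol uses ten 64×64 × 5,000-frame stacks (DRA window 200) with 20
events each at SNR 3 against each stack's event-free twin; the SNR ladder
uses {1, 1.4, 2, 3, 5} × 50 events on 64×64 × 3,000-frame stacks (13 events
per stack); unit tests use 1,600-frame stacks with window 100.  These sizes
keep the full suite within tens of minutes while leaving ≥ 3 analysis
frames per transient and ≥ 2 drift correlation times per stack.

## Known limitations

- The verification stage assumes immobile events and exactly one transient
  shape (the DRA tent); unbinding events are treated identically through
  the |·| in the matched filter but are not separated out.
- Rank-based probability maps discard amplitude by design; sensitivity at
  low SNR therefore rests on the matched filters (spatial in candidate
  generation, spatio-temporal in verification).
- Per-frame contamination is a fixed quantile, so mask statistics on
  event-free data reflect the threshold, not an error rate; false-positive
  control lives entirely in consolidation + verification.
- The ratiometric DRA leaves a ≤ ~2% multiplicative bias of recovered
  contrasts in bright speckle regions.
- GMM component selection by BIC can merge heavily overlapping
  subpopulations at small sample sizes; the main-mode MLE is robust to
  this, the component table less so.
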