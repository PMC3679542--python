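# Methods

This note documents the models, estimators and numerical choices behind
`iftmotion`, in the order data flows through the pipeline.

## Train kinetics simulation

Anterograde and retrograde IFT trains are injected as independent
Poisson processes at the flagellar base and tip. Each train draws a
speed from N(v, σ_v²) (defaults v_antero = 2.0 µm/s, v_retro =
2.96 µm/s, σ_v = 0.2 µm/s, reflecting train-to-train variability) and
transits ballistically; trains vanish on arrival (tip/base remodeling is
out of scope — the analyses concern transit, not turnaround). Injections
begin 1.5 transit times before the acquisition so traffic is at steady
state at t = 0.

**Pausing.** Surface-anchoring pauses are generated as a *cell-level*
Poisson process with rate

    λ([Ca²⁺]) = λ_residual + (λ_max − λ_residual) · H([Ca²⁺]),

each event assigned to a uniformly random currently-moving train, with
exponential durations (mean 2 s; the durations are not constrained by
published values, and a few-second scale matches what gliding-cell
kymographs show). Under this convention λ is the per-cell pausing
frequency — exactly the quantity measured from kymographs as
(total events)/(acquisition time) — and the expected count is λ·T
independent of train occupancy. The alternative per-train reading would
make the aggregate rate depend on injection rates; the config documents
the choice. Defaults: λ_max = 0.125 s⁻¹ at 0.34 mM free Ca²⁺,
λ_residual = 0.0125 s⁻¹ (the ~10-fold reduction observed under Ca²⁺
deprivation).

**Ca²⁺ dose response.** H is a first-order Hill curve with
half-saturation 1 µM, rescaled so H(0) = 0 and H(0.34 mM) = 1. Only the
endpoints are empirically constrained; the half-saturation is exposed in
the config (`ca_half`).

**Bead.** A single membrane bead alternates reflected 1D diffusion
(default D = 0.05 µm²/s) with train-coupled runs: attachment is Poisson
with rate `bead_attach_rate · H([Ca²⁺])` (so Ca²⁺-deprived beads only
diffuse), coupling is to the nearest active train, and a coupled bead
moves at `bead_speed_factor` × the train's velocity. The default factor
0.7 models the ~30% slowdown of trains carrying 1-µm beads; analyses of
the small-bead colocalization regime use factor 1.0, where beads move at
train speeds.

**Gliding.** While retrograde-origin pauses are anchored and the anchor
count between the two flagella is unbalanced, the body moves at
`glide_speed` (default 1.49 µm/s, the uniflagellate value) toward the
majority side; anterograde-origin pauses never initiate motion; equal
counts cancel exactly; and motion stops when the driving pauses end or
the body reaches the nearest driving anchor — the body never overshoots
a paused train. Anchored driving trains are surface-fixed, so their
arc-length coordinate is decremented by the body's motion. When counts
are unbalanced, minority-side anchors are left in place rather than
dragged or broken — a deliberate simplification; the balanced-force
stationary case is exact.

## Rendering

Emitters are symmetric 2D Gaussians (σ = 0.11 µm) at subpixel positions
along a polyline path; counts are Poisson(signal + background) plus
Gaussian read noise, quantized to uint16. `render_kymograph` renders the
same emitters directly on the (time × arc length) grid — the fast path
for direction-analysis studies where 2D geometry is not under test. The
defaults (peak signal 150, background 20, read noise 2) give SNR ≈ 10.

## Kymography

Paths are resampled at a fixed 1 px arc-length step *from the base*, so
vertex j sits j px from the base in every frame; that is what keeps the
anchor (fixed common point) at one arc-length coordinate when keyframed
paths of a reorienting cell are interpolated (vertex-wise linear
blending of the two bounding keyframes; the scheme between assigned
curves is this package's choice — the construction is not otherwise
specified). Keyframes must share the anchor within 2 px. Sampling is
bilinear with edge padding, averaged over `linewidth_px` (default 3;
the flagellum is ≈2 px wide at 106 nm/px) perpendicular offsets.
Kymograph row r covers time [rΔt, (r+1)Δt); arc length is measured in
µm from the base; positive velocity is anterograde.

## FSDA

A ridge ds/dt = v concentrates spectral energy on f_t = −v·f_s. Masks
are built in the angle domain ψ = arctan(−f_t/f_s) (the f_s = 0 axis
maps to ψ = π/2), which is even under f → −f, with raised-cosine edges
spanning `softness` (default 10%) of each wedge's angular width;
overlapping edges are renormalized so the masks sum to exactly 1 at
every non-DC frequency, and an explicit symmetrization handles the
sign-ambiguous Nyquist row/column, making every component exactly real.
DC goes to a separate background component; the f_t = 0 axis (static
structures) falls in the paused bin; the f_s = 0 axis is shared between
the two open-ended bins by the softness rule. The default pause
threshold v_min = 0.2 µm/s sits an order of magnitude below train
speeds. A Tukey window (α = 0.25) suppresses border leakage; components
therefore reconstruct the *windowed* input (max abs error < 1e-6 of the
dynamic range), and recovery statistics are evaluated on the window
interior (the central 75% of the time axis), where the taper does not
suppress ridges.

Track extraction links per-row intensity maxima across rows with a
velocity-predictive gate (loose, `v_gate`·Δt + 2 px, for new tracks;
0.6·|v̂|·Δt + 1.5 px once a slope estimate from the last 5 points
exists), assigning candidates globally greedily by prediction error;
linked ridges are fit with least-squares lines. On simulated traffic at
SNR ≥ 5 this recovers 100% of interior trains with a median speed error
of ~0.5%.

## Event statistics

**Pauses.** Instantaneous velocity is a central difference over a
3-sample window; a pause is |v| < 0.2 µm/s sustained ≥ 0.4 s (2 frames
at 5 fps) in a track that moves before or after; fully immotile tracks
are excluded. The raw frequency (count/acquisition time, the standard
definition) censors pauses too short to detect. Assuming exponential
durations, a pause spanning k frozen frames is measured as a span of
exactly (k−3)Δt under the 3-sample stencil, so detection requires
k ≥ ⌈min_dur/Δt⌉ + 3; averaging over the uniform start phase gives a
detected fraction exp(−c_eff/τ) with c_eff = (⌈min_dur/Δt⌉+3)Δt − Δt/2,
and memorylessness lets τ be estimated from the mean detected excess.
`frequency_corrected` divides out this fraction and is unbiased within
~1% on simulation (the raw estimator under-counts by ~35% at τ = 2 s).

**Colocalization.** Observed distances are bead-to-nearest
same-direction train per time point; the null pools `n_null`
randomizations in which each train's start time is resampled uniformly
(circularly within the acquisition window), preserving every track's
geometry and speed while destroying temporal registration — this
package's concrete instantiation of a randomized-kymograph null. The
two-sample KS test assumes independent draws, and 5 fps samples of the
distance process are serially correlated over roughly (train spacing)/
(train speed) ≈ 0.5 s, so evaluated samples are thinned with a stride
(3 frames in the test suites). Under the null the resulting p-values
are uniform; in the coupled-bead regime (≥50% coupled, ≥300 samples)
power at p < 0.01 exceeds 95%.

**Lag times.** For each gliding onset, the lag is measured to the start
of the most recent retrograde pause in the leading flagellum (the
flagellum whose anchors pull in the observed gliding direction); onsets
with no preceding retrograde pause are flagged and excluded. The
exponential fit is maximum likelihood on the lags themselves (bin-free);
for an exponential the ML mean *is* the sample mean, reported with its
SEM. Pause start (not surface-anchoring time, which is unobservable)
defines the lag origin.

**Independence test.** The null that pausing and gliding are unrelated
makes each lag exponential with the observed mean inter-pause interval;
the p-value is the plus-one-corrected fraction of 10⁶ simulated
n-sample means at or below the observed mean lag (one-sided). The mean
of n exponentials is Gamma(n, m/n), which the test suite uses as an
independent closed-form cross-check. This Monte-Carlo construction
replaces an unspecified t-test formulation while testing the same
hypothesis; for mean lag 0.48 s, n = 36, inter-pause 8.25 s it returns
the Monte-Carlo floor 1/(10⁶+1) ≈ 1e-6 (the exact tail probability is
~1e-31).

**Pause profile.** The paused-train component is thresholded at a
configurable background percentile (default 50), time-averaged, and
binned over normalized arc length [0, 1].

## Trap analysis

Units are fixed: x in nm, κ in pN/nm, γ in pN·s/µm; τ = γ/(1000κ) s.

**Simulation.** Euler–Maruyama at 2 kHz (stability enforced:
Δt·κ/γ < 1): x ← x + Δt(F_motor − κx)/γ + √(2k_BT Δt/γ)·N(0,1). Motor
runs arrive as a renewal process; the force ramps at 100 pN/s to a stall
force drawn from N(25.2, 5²) pN, holds through an exponential dwell
(mean 0.15 s, which makes P(dwell ≥ 100 ms) ≈ 0.51, reproducing the
observed ~even stall/release split), then detaches (exponential recoil,
τ = γ/κ = 20 ms at the defaults) — or, for a configurable escape
fraction, keeps ramping past the detector range before the bead is lost
and a re-centred bead is trapped. Labels record each event's type,
direction, true peak force and dwell; the labelled dwell follows the
operational (velocity ≈ 0) definition, starting one trap relaxation
time after the stall force is first reached, when the bead has settled.

**Calibration.** κ = k_BT/var(x) on a ≥1 s motor-free segment;
stationarity is vetted by the split-half variance ratio ([0.5, 2]) and
a split-half mean-shift check (≤1 thermal SD), which catches both
variance drift and slow ramps.

**Classification.** The baseline is the histogram mode within ±2
thermal SD of the median. Excursions exceed 5 thermal SD, extended to
baseline crossings and split at prominent interior valleys (merged
back-to-back runs). Dwell at the peak is measured as the time from a
ramp→plateau change point (two-segment least-squares fit, which averages
noise over whole segments rather than relying on single-window
velocities) to the last sample above 75% of the peak; ≥100 ms scores a
stall, shorter a release, and |x| beyond the linear range (equivalently
κ|x| > 80 pN) an escape. Peak force is κ·max|x − baseline|. Against
simulator labels the dwell estimator is unbiased (+5 ms, SD 41 ms) and
type+direction agreement is ≈95%; residual disagreements are genuine
boundary cases of the exponential dwell distribution near 100 ms.

**Drag.** Recoils are fit with x(t) = x₀e^(−t/τ) + b (reject R² < 0.8,
<10 samples, or non-decaying input); γ = κτ·1000. The square-wave
oscillation protocol (±500 nm steps, κ = 0.07 pN/nm) fits each step's
relaxation and pools γ as mean ± SD/SEM; both γ uncertainties are
reported because published figures quote both a SEM-like and an SD-like
spread. Recoil and oscillation estimates agree within 15% on traces
simulated with one γ. Note the Euler–Maruyama discretization biases the
fitted τ by −Δt·κ/(2γ) ≈ −1.3% at the defaults, well inside the
estimator noise.

## Problem sizes and reproducibility

All randomness flows from one seed per simulation through
`numpy.random.SeedSequence` spawns (separate sub-streams for injection,
pausing, speeds, bead, rendering), so identical config + seed give
byte-identical outputs, including TIFF/CSV/JSON artifacts (JSON is
written with sorted keys and no timestamps). The test suites use 400 s
single-cell acquisitions (100 seeds for pause-frequency recovery),
60–200 s bead/gliding runs, 60 s trap traces (20 seeds) and 100
simulated recoils — sizes chosen so each recovery statistic has a
standard error comfortably below its tolerance.

## What the synthetic data does and does not emulate

Emulated: Poisson train traffic at realistic injection rates (~1 s⁻¹
per direction), Ca²⁺-dependent pausing, diffusive/processive bead
switching, anchor-limited gliding with two-flagella cancellation,
shot-noise-limited TIRF imaging at 106 nm/px and 5 fps, and thermal
trap dynamics at 2 kHz. Not emulated: axoneme mechanics and train
turnaround, 2D membrane diffusion, photobleaching, multicolor
crosstalk, bead-size-dependent hydrodynamics, and trap/QPD hardware
nonlinearity. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise models, not robustness to every
artifact of real recordings; in particular, real kymographs add
background structure (cell-body autofluorescence) that the FSDA
background component only partially captures.
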