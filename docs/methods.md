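# Methods

`coopgate` implements the quantitative pipeline used to study cooperative
gating of clustered CaV1.3 L-type Ca²⁺ channels: a coupled Markov-chain
gating model with maximum-likelihood estimation of the coupling coefficient
κ, quantal analysis of single-channel currents and optical Ca²⁺ sparklets,
whole-cell activation/inactivation metrics, automated step-photobleaching
stoichiometry, and localization-microscopy cluster quantification. Every
stage is driven by a synthetic-data generator that returns ground truth, so
the whole pipeline is verifiable at desk scale.

## The coupled gating model

A sparklet site (or patch) holds N exchangeable two-state channels. Time is
discrete at the acquisition rate (default dt = 10 ms, i.e. 100 Hz imaging;
10 kHz for electrophysiological sweeps); the state is the occupancy
k ∈ {0,…,N}, the number of open channels. The transition kernel is a convex
mixture

    T = (1 − κ) T_ind + κ T_coh,

where `T_ind` lets every channel flip independently (an open channel closes
with probability `p_close` per frame, a closed one opens with `p_open`; the
occupancy transition is a convolution of two binomials) and `T_coh` treats
the site as one super-channel (from k = 0, all N channels open together
with probability `p_open`; from any k ≥ 1 the site shuts completely with
`p_close`, otherwise all N open). The coupling coefficient κ ∈ [0, 1]
interpolates from purely independent (κ = 0, exact reduction to the product
chain) to all-or-none gating (κ = 1).

This mixture kernel is this package's concrete realization of the coupled
Markov-chain approach — it is **not** a bit-for-bit reimplementation of any
previously distributed script. It was chosen because (a) κ = 0 reduces
exactly to independence, (b) κ = 1 yields all-or-none gating, and (c) κ is
identifiable by maximum likelihood from a single record.

### Likelihood and estimation

For a raw fluorescence record the occupancy is hidden and the likelihood is
computed by an HMM forward recursion over the N+1 occupancy states with
Gaussian emissions of mean `baseline + k·q` and standard deviation
`noise_sd`; the initial distribution is the model's stationary
distribution, and the recursion is numerically stabilized by per-frame
scaling. The forward pass is verified in the test suite against exhaustive
enumeration of all hidden paths (N = 2, T ≤ 6, agreement < 1e−8). For an
already idealized occupancy record the emission layer is replaced by exact
state observation and the likelihood reduces to transition counts.

`estimate_kappa` maximizes the likelihood over (p_open, p_close, κ) with a
deterministic coarse grid (κ in steps of 0.05; probabilities log-spaced)
followed by Nelder–Mead refinement from the best three grid points in
transformed coordinates (log p, logit κ). Ties break toward smaller κ and
the optimizer is deterministic, so κ̂ is reproducible. Probabilities are
bounded in [1e−4, 0.9999] to keep the likelihood finite. N is supplied by
the caller (from the number of quantal levels observed at the site), not
estimated. A constant record is returned as κ̂ = 0 with a `no_transitions`
flag. Sites with κ̂ > 0.1 (configurable) are classified as coupled.

The estimator was checked by parameter recovery on synthetic sites
(2 channels, q = 38 nM, noise 8 nM, 2000 frames at 100 Hz): mean κ̂ over 15
sites at κ = 0.21 and 12 sites at κ = 0.08 falls within the corresponding
printed SEMs, independent sites (κ = 0) average κ̂ < 0.01, and fully
coupled sites return κ̂ = 1.

## Quantal fits

All-points amplitude histograms (bins aligned so one center is exactly at
0) are fitted with the multi-Gaussian quantal function

    N(i) = Σ_{j=1..n} a_j · exp[ −(i − j·q)² / (2·j·b) ],

in which component j has mean j·q and variance j·b — the `2jb` in the
exponent is read as a level-proportional variance, the natural model when
each open level superposes independent noise. The closed (j = 0) peak is
excluded from the quantal sum, following the equation's j starting at 1; it
is fitted simultaneously as a separate baseline Gaussian so its overlap
with the j = 1 peak is accounted for, but its parameters are not part of
the quantal result. Amplitudes are constrained ≥ 0. Sign convention: inward
currents are negative, and q is reported signed.

The quantal sum is degenerate under q → q/m (the true peak moves to
component m and component 1 empties), so the fit is multi-started at
q_init·{0.5, 1, 2} and near-ties in residual (within 5%) are broken toward
the largest |q|. Default bin widths: 0.02 pA for ~0.5 pA quantal currents
(≈ q/25), 0.04 pA for ~1.1 pA Ba²⁺ currents, 4 nM for sparklet amplitudes.

## Sparklet analysis

Baseline is the histogram mode with 1-nM bins (robust at active sites where
the mean exceeds baseline). An event is a maximal run of frames at or above
baseline + q/2 lasting at least 2 frames (20 ms at 100 Hz) — long enough to
reject single-frame noise, short enough to keep brief quantal events; both
thresholds are configurable. Per-frame quantal levels are
round((x − baseline)/q), rounding half away from zero.

Site activity nPs is defined as the time-averaged quantal occupancy
Σ_t k_t / T (the optical analog of NPo); Ps is the fraction of frames with
k ≥ 1 and n the maximal level. The formulation in the original sparklet
literature is not reproduced in the source we re-implement, so this
concrete definition is the package's documented choice.

Event-amplitude histograms pool the **per-frame** amplitudes of event
frames rather than per-event means: the mean of an event that wanders
between 1q and 2q is not a multiple of q, and using event means was found
to destroy the quantal structure of the histogram (the fit locked onto
q/2). Frame-pooled histograms recover the planted 38 nM amplitude to
within ±2 nM under 8 nM noise.

## Whole-cell metrics

Conductance is G = I/(V − E_rev), normalized to its maximum; default
reversal potentials are +54 mV (2 mM Ca²⁺) and +65 mV (2 mM Ba²⁺) for the
short isoform. Activation curves are fitted with the Boltzmann
g = 1/(1 + exp((V½ − V)/k)), seeded at the half-activation sample and
k = 8 mV. The activation time constant is a single-exponential fit
I(t) = I_max(1 − e^(−t/τ)) from depolarization onset to the smoothed peak.
The r300 metric is |I(300 ms)|/|I_peak| per trace, using absolute currents
(the ratio's sign convention is not stated in the source); percent
inactivation is 100·(1 − r). f300 is fixed as r300(Ba) − r300(Ca) so
stronger Ca²⁺-dependent inactivation gives a positive f300. Peaks are taken
on a 5-sample moving mean to avoid noise spikes. F/F0–voltage curves
average the last 10 frames of each per-voltage stack, sum over the cell
mask, and normalize by the −80 mV holding-potential value.

The activation-calibration presets (`cav13s_act`: τ = 1.17 ms,
`cav13l_act`: τ = 1.60 ms) are non-inactivating (τ_inact = ∞) so the rising
phase is a pure saturating exponential and the fit inverts the generator
exactly; waveforms with CDI use the separate `cav13s_cdi_*` presets.

## Step photobleaching

The detection image is the mean of the first 5 frames, rolling-ball
background subtraction (radius 10 px by default; the original radius is
unstated), then a spatial band-pass implemented as a difference of Gaussian
smoothings whose FWHMs equal the stated cut-offs: G(σ = 2/2.355 px) −
G(σ = 5/2.355 px). Thresholding (auto = mean + 3 SD), 8-connected
components, and a 4×4 px ROI anchored with the component's peak pixel at
window position (1,1) — a fixed convention, since "centered" is ambiguous
for an even window; border-touching components are dropped. The z-profile
is the per-frame sum over the ROI.

Step counting is automated (the original counting was manual): greedy
binary segmentation adds, at each iteration, the breakpoint that most
reduces the squared error of a piecewise-constant fit; the number of
breakpoints is selected by the Schwarz-type criterion
T·ln(SSE/T) + 2·m·ln(T). Only downward level changes with magnitude ≥
`min_step` count as bleaching steps; `auto` sets min_step to half the
median downward step of the unfiltered fit, which makes the count invariant
to rescaling the trace. Validation on synthetic ground truth: exact counts
on noiseless staircases of 1–10 steps with any spacing ≥ 5 frames, ≤ 5%
nonzero counts on flat pure-noise traces, and ≥ 90% exact counts at
step-SNR 3 over 200 replicates. Fluorophore blinking and incomplete GFP
maturation are not modeled, so real-data counts are lower bounds, as in the
GFP-counting literature.

## Localization microscopy

Localization precision follows DLR/√N. The default DLR is 710 nm — the
center of the 660–760 nm detection band used for far-red dyes — which gives
710/√1900 = 16.3 ≈ 16 nm for a bright Alexa-647-class emitter; both numbers
are configurable. Spot centroids come from least-squares 2-D Gaussian fits
(amplitude, x, y, σ, offset) with photons = 2πAσ². Rendering is a 2-D count
histogram at 10 nm/px; segmentation binarizes at ≥ 1 localization per pixel
(the original binarization rule is unstated), labels 8-connected
components, drops those below `min_pixels`, and reports pixel-count areas
in nm² plus clusters per µm². Because each localization is displaced by its
error σ_loc = DLR/√N, rendered cluster areas are dilated relative to the
true emitter footprint; this bias grows monotonically with σ_loc and is
verified, not corrected.

## Synthetic generators

The generators emulate the statistical structure the analyses assume, at
the study's operating points (presets): unitary currents of −0.49/−0.48 pA
(20 mM Ca²⁺) and −1.10/−1.14 pA (Ba²⁺) at −30 mV; sparklet quantal
amplitude 38 nM at 100 Hz with ~8 nM noise; coupling presets κ = 0.21
(short isoform), 0.08 (long), 0 (independent control); activation constants
1.17/1.60 ms. Per-frame gating probabilities are not printed anywhere, so
they are package choices fixed once: sparklet sites use p_open = 0.05,
p_close = 0.30 per frame (sites quiet most of the time, openings of a few
tens of ms), and single-channel sweeps use p_open = 0.06, p_close = 0.14 at
10 kHz, giving a stationary open probability of 0.3 as under
dihydropyridine-agonist recording.

Bleach times are geometric per frame (the memoryless discrete analog of
exponential survival) with a forced-time override for deterministic tests;
photon counts per switching event are lognormal by default (heavy right
tail). All randomness flows from one top-level seed through named
substreams, so outputs are bit-reproducible and adding a generator call
does not perturb other calls.

What the generators deliberately do not emulate: CDI kinetics inside the
gating chain (inactivation exists only in the whole-cell waveform
generator), optical PSF structure beyond a Gaussian, EMCCD gain/photon
statistics, fluorophore blinking, and drift. Passing tests therefore show
that the estimators invert the assumed data model at realistic noise
levels — not that the model captures every property of real recordings.

## Problem sizes and determinism

Validation runs use 15 + 12 + 8 simulated sparklet sites of 2000 frames for
κ recovery, 20 sweeps × 20 000 samples for quantal fits, 200 replicates for
the step-counter operating point, and 10⁴–10⁵ samples for distributional
checks — sizes at which each check completes in seconds to a couple of
minutes on one core while keeping Monte-Carlo error well inside the stated
tolerances. Every simulation is seeded; fixed seeds give byte-identical
pipeline outputs (JSON results are written with sorted keys).

## Known limitations

* κ is identified within the mixture-kernel family; records generated by a
  different coupling mechanism will map onto the nearest mixture member.
* N (channels per site) must be supplied; underestimating N truncates the
  emission grid and biases κ̂.
* The quantal fit assumes level-proportional variance; flicker noise or
  filtering-induced correlations are not modeled.
* Step counting undercounts when two fluorophores bleach within a few
  frames of each other (merged breakpoints) and when blinking is present.
* Rendered cluster areas carry the localization-error dilation bias noted
  above.
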