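# Methods

## The model

The package implements a spiking neural-network account of veridical
color perception and contour-induced afterimages.  A timed stimulus
sequence (a chromatic adaptation stage followed by one or two achromatic
test-contour stages, one second each by default) is processed by a
fixed retinotopic pipeline:

1. **Opponent coding.**  Each RGB frame (values in [0, 1]) is mapped
   pixelwise to single-opponent planes by the fixed matrix with rows
   (1/2, −1/2, 0), (−1/6, −1/6, 1/3), (1/3, 1/3, 1/3): a red/green
   (L/M) channel, a blue/yellow (S/(L+M)) channel, and luminance —
   mirroring retinal-ganglion/LGN opponent organization.
2. **Double-opponent edge detection.**  Each channel is convolved with
   a scaled discrete Laplacian, `DO(ch) = SO(ch) * (k_ch L)`, with
   k_RG = k_BY = 5, k_Lum = 2 and edge padding — a model of V1
   double-opponent cells.  The scale factors are folded into the
   kernels.
3. **Adaptation.**  The chromatic DO ensembles' outgoing connections
   carry a high-pass synapse (time constant 1 s), defined as the
   complement of the low-pass with equal tau, so
   `lowpass(u) + highpass(u) = u` exactly.  A sustained edge decays as
   `exp(-t/tau)`; at stimulus offset the output rebounds with reversed
   sign and magnitude `1 - exp(-T/tau)` of the sustained level — the
   seed of negative afterimages.  The luminance channel is not adapted.
4. **Contour-gated amplification.**  A modulatory gate
   `C = max(|DO_Lum| − β·(|SO_RG|+|SO_BY|) * 1_3x3, 0)` (β = 100) is
   excited by luminance edges and silenced by any physically present
   chromatic stimulus (the single-opponent magnitude is dilated with a
   3×3 box so inhibition covers both sides of a boundary).  The adapted
   gradient is decomposed into one-polarity components and the gate,
   scaled by α = 10, is added to each with matching sign:
   `E = sign(DO_ada)·(|DO_ada| + αC)`.  Pixels with no adapted gradient
   stay zero — a contour on virgin territory neither creates nor blocks
   color.
5. **Filling-in.**  Each channel reconstructs a surface by edge-driven
   diffusion, `dI/dt = c_r ΔI + c_i E` (c_r = 2, c_i = 0.25), compiled
   onto a recurrent connection with synaptic time constant τ_r = 0.01 s:
   the recurrent connection computes `τ_r c_r L(I) + I` (each pixel
   coupled to its four neighbors), the input connection `τ_r c_i E`.
   Zero padding makes the frame border absorbing.
6. **Readout.**  Channel outputs are sampled with a 50 ms low-pass
   probe every 50 ms, rescaled per channel by an anchored affine map
   (below), recombined through the inverse opponent matrix, and
   quantified as CIELAB (D65) region means: hue = atan2(b*, a*),
   chroma = hypot(a*, b*).  Polarity is positive within 60° of the
   inducer hue, negative within 60° of the opposite direction, neutral
   below chroma 1.

## Neural substrate

The network is built on a minimal Neural Engineering Framework engine
(`nef_core`): populations encode values through gain/bias/encoder
tuning curves and are read out with ridge-regularized least-squares
decoders; dynamical systems are compiled onto recurrent connections
through the synaptic low-pass filter.  Pixel stages use spiking
rectified-linear neurons at 200 Hz maximum rate — a +1/−1 encoder pair
per pixel for signed signals, a single one-polarity neuron for
rectified signals (intercept 0.1 for the magnitude masks, whose
threshold doubles as denoising; intercept 0 for the ±decomposition of
the adapted gradient).  The diffusion stages use leaky
integrate-and-fire neurons (τ_RC = 20 ms, τ_ref = 2 ms) with randomized
tuning; 20 per pixel at the desk-scale default, 200 in the reference
configuration.  The time step is 1 ms; simulations are bit-reproducible
given a seed.

Numerical choices: synapses use the exact zero-order-hold
discretization; decoders are solved on ≥500 uniform evaluation points
with ridge regularization 0.1·max_rate, followed by a gain-debiasing
step (the ridge shrink of a 2-neuron pair, ~3–4%, would otherwise act
as a spurious leak inside recurrent dynamics); LIF spiking uses exact
exponential integration with sub-step refractory and spike-time
correction, without which rates of a few hundred hertz are quantized
by the time step and biased low.

Representational radii: rectified-linear stages keep a fixed radius of
1 (they do not saturate; the fixed radius also fixes the amplification
deadband's scale).  The saturating LIF diffusion stages and the
threshold-bearing magnitude masks are calibrated per experiment from a
rate-mode pass (1.5× the largest input seen, floor 0.05), with the two
chromatic channels' magnitude masks sharing one radius so that a
channel carrying only a trace of signal keeps its small place on the
common scale.

Amplification deadband: the sign-gated `αC` term is recruited only
where the decomposed adapted gradient exceeds 5% of the decomposition
radius.  The gate is sign-only — without a floor, a chromatic channel
carrying essentially no signal (the S-axis of the pink stimulus, |SO|
≈ 0.006) would be amplified to the same strength as the channel
carrying the stimulus and rotate the percept hue.  Gradients above the
floor are amplified at full strength, which is what lets the partially
recovered adaptation state re-amplify under a second, alternating
contour.

## Percept rescaling

Edge-driven diffusion reconstructs a band-passed, contrast-inverted
copy of the stimulus (the steady state of `dI/dt = c_r ΔI + c_i ΔI_in`
is `−(c_i/c_r) I_in` up to smoothing), so the raw output is rescaled
against the single-opponent input when one is present.  The fit
regresses raw on anchor and inverts the slope — spike noise lives in
the network output, and the forward regression would be attenuated by
it — pooling the regression over successive frames of an anchored
stage.  Chromatic channels are fitted without an intercept (opponent
values are signed deviations from neutral; an intercept would tint
every neutral pixel); luminance keeps the full affine map.  If the
anchor pattern is undetectable in a channel's output (pooled R² below
0.005), that channel displays neutral rather than amplified noise.
During afterimage stages no chromatic anchor exists and the most recent
anchored coefficients are carried forward — this carry is what turns
the sign-reversed rebound into a complementary-hue percept.  For
display, each chromatic plane is saturated at the stimulus's own
opponent range: the sign-only amplification drives weak and strong
channels to comparable raw magnitudes, and clipping per channel in
opponent coordinates restores the stimulus's opponent ratio, whereas
clipping later at the RGB gamut would land on corner colors and destroy
hue.  In spiking runs the chromatic planes are first re-referenced to a
never-stimulated surround region, which reads out the diffusion
populations' slow, spatially coherent noise drift.

Classification reads the opponent-domain mean of the last 0.15 s of a
stage (the percept can still be crossing zero late in a stage; a long
window would straddle the crossing and cancel) and judges chroma at the
scene's background luminance (CIELAB chroma collapses on near-black
pixels, which would otherwise mask the chromatic content carried by a
reconstructed dark ring).

## Stimulus battery

The generator is deterministic and uses the published palette (CIE xyY
with the printed 8-bit sRGB values) or, for spirals, the published RGB
literals.  Closed square contours are concentric Chebyshev rings: the
chromatic band spans two rings with outer ring index N/3, and the
achromatic test contours abut it — outside for the negative
configuration, inside for the positive one — so that the contour's
luminance-edge support (±1 px) coincides with the adapted chromatic
edges, the coincidence the amplification mechanism requires.  The
double-contour conditions place the inducer-colored contour inside the
test contour and a flanking contour outside it: the opponent complement
of the inducer (computed by negating the chromatic opponent components)
for the constructive condition, the same color for the destructive one.
Star stimuli are two four-pointed polygonal stars rotated 45° with a
gray central overlap; the test stage outlines one star (and, in one
variant, adds an inner contour that touches no chromatic edge).  The
spiral is an Archimedean arm wide enough (≥5 px) that its two edge
contours are separated beyond the gate's ±1 px reach; spiral presets
therefore run at 30×30 in the fast battery while all other presets run
at 24×24 (reference sizes 36×36 and 50×50).

## Execution modes and what the tests show

Two execution modes share one network description.  `spiking` runs the
spiking neuron models and is the reference substrate; `rate` is the
ideal rate-based mode (values passed through the tuning-implied
nonlinearities exactly, no spike noise) used for fast tests and radius
calibration.  The diffusion stage is validated in both: the rate-mode
recurrent network matches an independent forward-Euler integration of
the diffusion equation within 2% on an 8×8 grid, and the spiking stage
at the reference budget (200 LIF/pixel) matches rate mode within 15%.
That 15% band is a property of the population size: the recurrent loop
recirculates decode noise through its slowly leaking spatial modes, so
the spiking/rate discrepancy scales roughly as 1/√n and reaches ~70%
at 20 neurons/pixel — which is why the qualitative percept battery is
evaluated in rate mode at the desk scale, with the spiking substrate
covered by the oracle checks.  Paper-fidelity spiking runs (native
grids, 200 LIF/pixel) are available through
`preset_catalog(fast=False)`.

The battery covers 36 presets: four colors × five closed-contour
configurations, star pairs ± inner contour, star and contour
alternations, six spiral conditions, and an adaptation-duration sweep.
At the desk scale the model reproduces: negative and positive
single-contour afterimages; constructive enhancement and destructive
cancellation of the filling-in (the latter judged on the fringe-free
interior — local afterimages adjacent to adapted contours are a
separate, stronger phenomenon, and the interior average including the
adapted region consistently exceeds the one excluding it); the uniform
complementary fill of the outlined star including its never-colored
overlap, unblocked by an inner contour; the inside/outside separation
of the full spiral contour and its inversion; the build-up → plateau →
decay time course with the adapted ring refilling before the naive
center; and the monotone growth of afterimage strength with adaptation
duration.

## Known limitations

* The positive condition for the pink stimulus reaches the correct hue
  but stays below the neutrality threshold: the opposing unamplified
  edge scales with the stimulus opponency while the contour
  amplification does not, so the strongest-opponency color nearly
  cancels its own positive fill.
* The alternating-contour polarity reversal is only partial at the
  desk scale: within a one-second stage the second contour's
  amplification reverses the contour-adjacent rings but cannot
  overturn the accumulated interior of a 24×24 map.
* The spiral's outer-edge variant does not become positive-dominant in
  the enclosed interior; both edge variants leave it
  complementary-signed, with the inner variant roughly twice as
  strong.  In a spiral, the arm's outer flank at one winding borders
  the same enclosed gap as the next winding's inner flank, so the
  outer/inner distinction is graded rather than signed here.
* The synthetic stimuli are noise-free, perfectly fixated, and use a
  single spatial scale; passing tests say nothing about eye movements,
  display calibration, or multi-scale filling-in.
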