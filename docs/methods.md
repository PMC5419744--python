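# Methods

## The exchange model

The replisome is modeled as one **resident** Pol III* binding site plus
`n_sites − 1` **auxiliary** sites (transient footholds on, e.g., the sliding
clamp or helicase). The continuous-time Markov chain has three reactions:

- an empty auxiliary site binds a competitor from solution at `k_on · C`
  (per site, C the free Pol III* concentration in nM);
- an occupied auxiliary site releases its occupant at `k_off`;
- while ≥ 1 auxiliary occupant is present, a handoff completes at
  `k_handoff`: the resident departs and one (uniformly chosen) auxiliary
  occupant becomes the new resident, vacating its site.

This is a *model choice*, not an experimentally established scheme: it is
the simplest instantiation of multisite competitive exchange that yields
both dilution stability (at `C = 0` no competitor ever arrives, so the
resident persists indefinitely) and a saturating, concentration-dependent
exchange time. In the `n_sites = 2, k_off = 0` limit the resident residence
time is the hypoexponential `Exp(k_on·C) + Exp(k_handoff)` with mean
`τ(C) = 1/(k_on·C) + 1/k_handoff`.

The chain is simulated exactly (event-driven Gillespie), then sampled onto a
regular frame grid; frame sampling introduces no kinetic error, only the
usual aliasing of events shorter than one frame. An event-count guard
rejects parameter/duration combinations whose expected event count exceeds
2×10⁶.

### Kinetic defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_sites` | 3 | up to three or four complexes are seen at the fork at 6.7 nM; configurable |
| `k_on` | 0.83 /nM/s | with `k_handoff`, the exchange-limited closed form passes through both measured smFRAP anchors: τ(13 nM) ≈ 1.85 s and τ(0.03 nM) ≈ 42 s |
| `k_handoff` | 0.57 /s | see above; sets the high-concentration saturation of the exchange time |
| `k_off` | 15 /s | auxiliary binding is transient; the value is chosen so the equilibrium occupancy distribution at 6.7 nM has its mode at **one** complex (per-site occupancy p = k_on·C/(k_on·C + k_off) ≈ 0.27 < 1/3), matching the measured modal stoichiometry |
| `cores_per_complex` | 3 | three αεθ cores per Pol III* |
| `label_efficiency` | 0.85 | labeling yields were 80–90%; each core carries an active fluorophore with this probability (binomial) |
| `color_fractions` | 0.5/0.5 | the two-color mixing experiments use 1:1 red:green |

Note the closed form `1/(k_on·C) + 1/k_handoff` describes the *resident
residence time*. The fluorescence recovery measured by smFRAP coincides with
it only in the exchange-limited regime (fast handoff, auxiliary sites empty
at the pulse); with the full defaults the recovery is handoff-limited at
high concentration and saturates near 1/k_handoff — the same qualitative
saturating trend, with a model-dependent prefactor.

## Photophysics

Bleaching is irreversible with per-frame probability
`1 − exp(−Δt · P / (τ_bleach · P_ref))`; the rate scales linearly with
excitation power, so a FRAP pulse is simply a window of elevated power.
Blinking is not modeled (the imaging buffer suppresses it). Intensity is
measured at the start of each frame, before that frame's bleaching, so a
pulse with per-frame bleach probability p leaves a fraction `(1−p)^m` after
m pulse frames. Detected intensity is `unit_intensity` per active
fluorophore plus Gaussian background; negative values are clipped at zero in
*rendered images only*, never in trace tables. Default bleach lifetime is
14.1 s at reference power (the measured surface-immobilized value); default
frame intervals are 0.5 s in vitro and 0.1 s in vivo — the acquisitions'
frame rates are not reported, so both are config entries flagged as
assumptions.

## Kymographs and fork tracking

DNA length maps to image position through γ = 2.1 µm / 7.2 kb (a 7.2 kb
flow-stretched template spans 2.1 µm; configurable). Spots are rendered as
1-D Gaussian PSF profiles (σ = 1 px) whose *column sum equals the spot
amplitude*, independent of position; the surface anchor sits 4σ from the
image edge so the PSF is never truncated. Departing complexes deposit
stationary spots at the departure position (polymerases left on
Okazaki-fragment 3′-termini) that fade with the bleach lifetime; with Pol I
present no deposits are rendered.

The tracker takes, per column, the **furthest** local maximum above
threshold that does not backtrack more than 2 px (the fork is the leading
spot; deposits trail it and may transiently be brighter), then refines to
sub-pixel precision with an intensity-weighted centroid over ±2 px.
Threshold default: median + 6 robust σ (MAD). Columns without a spot become
gaps, interpolated and flagged; > 50% gaps aborts.

## Change-point fitting (steps and segments)

Both the photobleaching step fitter (piecewise-constant) and the trajectory
segmenter (piecewise-linear in time) minimize

    total cost = Σ segment RSS + penalty × (number of change points)

exactly, by O(n²) dynamic programming with prefix-sum segment costs. On
exact cost ties the lexicographically smallest change-point sequence
(earliest change points) wins. The default penalty is `c·σ̂²·ln n`
(c = 3 for steps, 4 for segments) with σ̂ estimated robustly from first
(steps) or second (segments) differences — the criterion used in the
original analysis is not reported, so the default was calibrated once on
synthetic data. Steps smaller than `min_step` (default 2σ̂) are merged.
Minimum segment sizes: 2 frames (steps), 2 s (segments); both configurable.

## Rate, processivity, stoichiometry

Segment rates are histogrammed (Freedman–Diaconis bins) and fit with a
Gaussian; the reported uncertainty is the standard error of the mean.
Processivity is fit by the exponential maximum-likelihood estimator (the
sample mean) rather than a binned histogram fit — bin-free and exactly the
single-exponential assumption; the binned display is for plots only.

Counts per replisome divide the background-subtracted spot intensity by the
intensity of one complex, `cores_per_complex × label_efficiency ×`
(single-core intensity). Whether the original normalization used one core or
one complex is ambiguous; both factors are configurable and recorded in the
output metadata. The count histogram is fit by a Gaussian mixture with
**fixed integer means** 1..K and sds `√n · (σ₁/μ₁)` (independent-emitter
variance addition); only the weights are free, estimated by EM. K defaults
to 4 at 6.7 nM and 3 at 0.3 nM.

Colocalization matches spots one-to-one, greedily by distance within the
radius, preventing double counting.

## smFRAP analysis

Pulse positions come from schedule metadata when available, otherwise from
frames falling below 20% of the running median. Each post-pulse window is
normalized to the trace's pre-pulse steady state — the mean of the 10 frames
before each pulse, pooled over the trace's pulses (pooling reduces the noise
of the divisor) — averaged within the trace, then across traces. Pulse
frames are excluded from both normalization and fitting. The recovery is fit
with `I(t) = offset + amplitude·(1 − exp(−t/τ))`; the experimentally used fit form is
not reported, and this saturating single exponential is the reaction-dominant
default (alternatives selectable). Fits with non-positive amplitude or τ
beyond 10× the window are flagged "no recovery" (the `C = 0` behavior).

## Cross-correlation and mechanism discrimination

The CCF at lag ℓ is the Pearson correlation of the two overlapping trace
windows. Computing means and variances *per overlap window* guarantees the
invariants CCF ∈ [−1, 1], CCF(0) = 1 for identical traces, and
CCF_ab(ℓ) = CCF_ba(−ℓ); a global-variance normalization would not be
bounded. Correlation runs on unsmoothed traces (the 2 s moving average is
display-only; pre-smoothing would inflate the CCF width — a config flag
enables it for sensitivity analysis). A per-trace single-exponential
bleaching trend is divided out first (switchable): shared bleaching would
otherwise produce a spurious positive peak. The trend fit profiles the
lifetime on a fixed log grid with linear least squares for amplitude and
offset — derivative-free and fast enough to run on thousands of traces.

The null band comes from randomized cross-cell pairings (channel 1 of one
cell against channel 2 of another), matching the experimental control, not
from analytic bounds. A curve is called `positive_peak` when its maximum
within ±3 frames of zero lag exceeds the 99th percentile of ≥ 100 randomized
null draws at those lags. The four simulated mechanisms follow the
two-state-per-frame scheme (`k_on`, `k_off` in frames⁻¹): coupled complex
exchange drives both channels with one occupancy process; "stable" binding
uses `k_off = 10⁻⁶` frames⁻¹ as the documented "≪ 1" constant. Finite traces
bias sample correlations low at long lags (the window mean absorbs slow
fluctuations), so decay-time recovery tests use traces ≥ 2000 frames.

## Copy-number counting

Coverslip background is fit per field with `A·exp(−t/τ)+c`; cellular
autofluorescence is constant (asserted on the simulated control). Each
corrected cell trace is fit with a single exponential whose t = 0 value is
the amplitude; copies = amplitude / single-molecule intensity, the
amplitude-based variant of "mean intensity × area / unit" (which is also
available). The single-molecule intensity is the Gaussian mean of the
change-point step sizes. Copies convert to concentration through
`C = copies/(N_A·V)`; the cell volume is **not** a measured quantity here —
the default 2.4 fL is the value consistent with both measured
copy/concentration pairs (104 ↔ 72 nM and 96 ↔ 66–67 nM) and is exposed as
config, flagged as such. The Pol III* concentration estimator averages
ε/3 and τ/3 (reproducing the measured 23 nM); a limiting-subunit
alternative (min/3 ≈ 22 nM) is provided.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: exponential
processivities, Gaussian segment rates, Poissonian exchange kinetics,
binomial labeling, irreversible bleaching, Gaussian detection noise,
per-field exponential background, constant autofluorescence. It does **not**
model diffraction beyond a Gaussian PSF, stage drift, fluorophore blinking,
spectral cross-talk, cell segmentation (masks/areas are inputs), or
diffusion-limited FRAP. Passing tests therefore demonstrate correctness of
the *analysis chain* under the assumed noise model, not robustness to every
artifact of real microscopy data.

## Problem sizes and reproducibility

Simulation sizes used by the test suite and `scripts/acceptance.py` (chosen
so each estimator's Monte-Carlo error is comfortably below the tolerance it
is tested against): 100 FRAP traces × 14 pulses per residence time;
60 traces × 8 pulses per concentration in the series (frame interval scaled
to the expected recovery time); 300 two-color focus pairs × 400 frames with
100 randomized null draws; 100–300 replisomes for stoichiometry and
tracking round-trips; 100 cells / 150 focus traces for counting; 200 random
short traces for the exact change-point comparison; 1000 runs for CTMC
closed-form checks (using the first completed residence per run — completed
tenures in a finite window under-represent long ones). All stochastic
operations take explicit seeds and are bit-for-bit reproducible; the CLI
derives per-stage streams from one root seed and writes seeds, parameter
hashes and file checksums into every output.

## Known limitations

- The exchange CTMC is one concrete instantiation of multisite competitive
  exchange; rate constants other than the calibrated defaults change the
  quantitative (not qualitative) concentration dependence.
- The fluorescence-recovery time equals the residence closed form only in
  the exchange-limited regime; elsewhere it is a model-dependent mixture of
  arrival and handoff stages.
- The O(n²) change-point DP is exact but not suited to traces much longer
  than ~10⁴ frames.
- Copy-number concentrations inherit the uncertainty of the assumed cell
  volume (not independently measured here) linearly.
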