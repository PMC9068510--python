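# Methods

This note documents the models behind `orbichase`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Instrument model

The axial oscillation frequency of a trapped ion depends only on m/z:
`f = c (m/z / 1000)^(-1/2)` with the calibration coefficient
`c = 0.26055 MHz` as the default for the ultra-high-mass-range platform
modelled here. Path lengths are `duration × f × d`, with
`d = 93.7425 mm` the average travelled distance per axial oscillation along
the central electrode. `d` is treated as a constant: in reality it averages
over the spread of accepted ion energies and orbital radii, and no
energy-dependent radius model is attempted.

Charge calibration: the magnitude-mode spectral peak height of a single
non-decaying ion, under the length-invariant normalization described below,
equals `z / charge_gain` with `charge_gain = 175` charges per unit height.
This single number ties the simulator, the spectral normalization and the
CDMS charge read-out together, and the round trip (simulate → spectrum →
`intensity_to_charge`) is tested to better than 1% bias.

Gas physics: gas number density comes from the cold-cathode gauge read-out
via the ideal gas law (`1 mbar = 100 Pa` exactly, CODATA Boltzmann
constant), multiplied by a trap-pressure factor (default 2: the pressure in
the trap is about twofold the gauge read-out) and a gauge-gas sensitivity
correction (nitrogen 1.0; xenon read-outs are divided by 2.4, the relative
cold-cathode sensitivity — configurable, since gauges differ). Collision
cross-sections are hard-sphere, `π(r_ion + r_gas)²`, with user-supplied
ion radii; collision counts are path length over mean free path and
therefore exactly linear in duration and pressure. The bundled
`xenon_minimized` preset (gauge 8×10⁻¹¹ mbar, r_ion = 17 nm) is a
representative minimized-trap-gas condition for megadalton particles; it
yields ≈33 expected collisions over a 4.096 s transient at m/z 21,343 —
illustrating that these ions really do survive tens of collisions. The
radius and pressure behind any such figure are parameters, not constants of
the package.

The mass-scaling profile (`stability_scaling_profile`) assumes a
native-ESI-like charging law `z ∝ m^e` (default `e = 0.5`, configurable):
travelled distance then scales as `m^{-(1-e)/2}`, available centre-of-mass
energy as `z·m_gas/(m_gas+m)`, and CCS as `m^{2/3}` (constant-density
particle). Their combination — collision energy per surface area — falls
steeply with mass, which is the package's quantitative form of the argument
for why megadalton ions sit on a plateau of stability while small denatured
proteins fragment.

## Synthetic transients

`simulate_transient` sums, per ion, `a(t)·cos(φ(t))` with instantaneous
frequency given by the frequency law at the ion's current m/z and phase
kept continuous across events (piecewise-exact integration for discrete
events; trapezoidal integration for continuous deterministic drift).
Amplitude is `z/charge_gain`, times an optional per-ion scale factor (the
instrument accepts a range of ion energies and radii that modulate the
induced current; this is exposed as a knob rather than modelled).

Neutral loss is a point process with intensity
`λ(t) = λ_lin·v + λ_exp·e^{-t/τ}`: a constant rate per travelled distance
(collisional activation during detection) plus an exponentially decaying
term (a suddenly activated ion — energized during injection through the
much higher-pressure C-trap region — cooling by evaporation). Each event
removes a truncated-normal mass (default 18 Da, water; a 77 Da
ammonium-acetate-scale preset exists). Event times are drawn by
inverse-CDF sampling of the integrated intensity; a deterministic mode
applies the mean drift continuously for exact tests. The per-segment
expectation is exactly `α + β·e^{-k/τ_seg}`, and
`LossProcess.from_segment_model(α, β, τ_seg)` constructs the time-domain
rates from that parameterization losslessly. Cumulative-loss presets of
157 Da and 692 Da reproduce the small- and large-loss populations used as
working examples.

Charge stripping multiplies the amplitude by `(z-1)/z` and recomputes
`m/z = mass/(z-1)`; by default the departing charge carries one proton mass
(configurable — whether it carries more is not established). Radial motion
is modelled as pure amplitude modulation
`(1 + depth·cos(2π f_r t + φ))`, which produces the mirrored sideband pair
at ±f_r around the axial peak; frequency modulation of the axial motion is
not modelled. Detector noise is white Gaussian in the time domain.

Defaults define the simulated study conditions: 250 kHz sampling (all
axial frequencies at m/z > 4,500 are below 125 kHz; a 4 MHz full-rate model
exists), 1 s transients, noise σ = 3 (single-ion segment S/N ≈ 50 for
z ≈ 150, full-transient noise band ≈ 1 charge-equivalent at 1 s — a
plausibly instrument-like regime), populations with two mass modes at 3 and
4 MDa (capsid-like T=3/T=4 mixtures), charging `z ≈ 0.0831·m^0.5`
(z ≈ 144 at 3 MDa, matching the worked example), 70% stable ions, and a
few-percent charge-stripping probability. The charge-precision ensembles
use noise σ = 6 so that the measured spread is firmly noise-dominated
rather than limited by the ~0.1% residual interpolation error of the
three-point parabola height.

What the generator does **not** emulate — and what passing tests therefore
do not certify about real data: space charge and ion–ion interaction,
image-charge geometry, non-circular orbits and energy-dependent amplitudes,
1/f or ringing electronics noise, frequency (as opposed to amplitude)
radial modulation, and vendor file formats. Real-data quantities that
depend on those (absolute sampling-gain folds, absolute S/N values) are
treated as data-dependent and only their mechanisms are tested.

## Spectral processing

Transients are zero-padded ×4 (customary in FT-MS), transformed with a
real FFT and returned as magnitudes normalized by `2/n` so a unit
sinusoid has height 1.0 at any duration (verified to <1% over
128–4,096 ms). No apodization is applied by default, matching the
processing the analysis emulates. An `absorption_surrogate` mode returns
the real part after rotating by a known initial phase: a documented
stand-in for proprietary phase-aware ("enhanced FT") processing, usable
only when the phase is known (i.e. for simulated data); exact width
equivalence with the proprietary algorithm is not claimed, and analysis of
unknown-phase data falls back to magnitude mode.

Centroids are vertices of a least-squares parabola through the three
magnitude samples around a local maximum, applied to linear (not log)
magnitudes. With ×4 padding the worst-case frequency bias is ≈0.005 padded
bins and the height error ≤0.15% — an order of magnitude inside the 0.05-bin
accuracy contract. Peak picking thresholds on a robust noise sigma (window
median scaled by the Rayleigh std/median ratio) and suppresses, around each
accepted peak, both its main-lobe neighbourhood (12 natural bins) and
anything under twice the rectangular-window sidelobe envelope
`height/(π·Δbins)` within 200 bins: un-apodized high-S/N peaks otherwise
leak sidelobes above any fixed S/N threshold. A consequence is that a
genuinely weaker ion hiding under a stronger neighbour's sidelobe envelope
is not detectable — it is also not spectroscopically distinguishable from
that sidelobe.

FWHM uses linear interpolation of the half-height crossings (plateau ties
break toward the lower-frequency crossing); because `f ∝ (m/z)^{-1/2}`, the
m/z-domain resolving power is exactly half the frequency-domain one.
Noise-band sigma is the standard deviation of window magnitudes times the
charge gain; the window is validated against containing peaks by comparing
its maximum with the expected extreme of `n` Rayleigh draws plus a margin
(a fixed multiple would either false-alarm on large windows or miss peaks
in small ones).

## Frequency chasing

Segmentation: 15 equal windows per second with 50% overlap by default
(window length `duration/((n-1)(1-ov)+1)`, i.e. 125 ms for 1 s), exactly
tiling the transient. Isolation: any centroid with a neighbour closer than
2× the segment-level FWHM is dropped, symmetrically — below that distance
two ions are one unresolvable spectral object, and tracing through crossing
pairs is explicitly out of scope. Tracing: greedy nearest-in-m/z chaining,
earliest-started trace first (ties by intensity), each centroid used at
most once, bridging at most one missing segment, keeping traces covering
≥60% of segments. Earliest-first priority matters: at a charge-loss jump a
freshly spawned competitor trace would otherwise split the doublet into two
sub-threshold fragments.

Retained traces are filtered at standard deviations of 4 Th (m/z) and 0.2
(normalized intensity) across segments, then classified. Stability margin:
one full-transient Fourier bin, defined as `1/(duration × pad)` and
converted to Th at the trace's m/z. A charge-loss call requires the largest
between-segment jump to (i) exceed the propagated centroid uncertainty ×3,
the stability margin, and 5× the trace's median step (so noise blips on a
drifting ion do not masquerade as jumps), and (ii) match
`m/z_after/(m/z_after - m/z_before) = z` for an integer `z ≥ 2` within 3
propagated sigmas (floor 0.05). Jumps that match no integer are flagged
ambiguous and rejected, not guessed. Everything else past the margin is
gradual loss; upward gradual drift is flagged but kept.

Doublet resolution averages the m/z on both sides of the jump, excluding
the two segments whose overlapping windows straddle the event; this brings
the z uncertainty for the reference case (z = 144 at m/z 21,343, segment
S/N ≈ 50) to ≈0.05. Mass is `round(z) × (m/z_before − m_p)` with the proton
subtraction controlled by a flag (default on; at megadalton scale it is a
145 Da correction on 3 MDa). Note the arithmetic identity this package
implements gives 3,073,261 Da for the (z = 144, m/z 21,343.1) reference
ion with proton subtraction and 3,073,406 Da without; published values for
this example fall between the two, and the exact convention used there is
not recoverable, which is why the flag is exposed rather than tuned.

Drift-to-loss conversion: `loss_k = -z·(mz_k - mz_{k-1})` per segment,
cumulative by exact summation. The decay model `α + β·e^{-k/τ}` is fitted
by bounded nonlinear least squares (α, β ≥ 0 — the linear term is a
physical rate per travelled distance), with non-convergence flagged and a
`tau_unidentifiable` flag when β degenerates. On 1,000-ion ensemble means
with (α, β, τ) = (25 Da, 120 Da, 3 segments) the fit recovers α and β
within 10% with r² ≥ 0.998.

Sideband detection scans symmetric bands around the axial peak (default
minimum offset 8 natural bins), requires both candidates above 5 noise
sigmas and above twice the axial peak's own sidelobe envelope, and scores
mirror symmetry as the correlation between the lower-sideband profile and
the frequency-reversed upper-sideband profile; stable simulated modulation
scores ≥0.95.

## CDMS observables

Drift correction averages per-segment intensities and m/z values of a
retained trace: within a 125 ms window the drift is far below the 8 Hz
segment bin, so segment peak heights are unaffected by drift that splits
the 0.25 Hz full-transient bins. On ions drifting ~8 natural bins the
corrected intensity recovers ≥90% of the stable-ion reference while the
full-transient peak drops below 50% and is rejected by split-peak
filtering (the measured Fresnel-type height loss is 77% remaining at 3
natural bins of drift, 52% at 5, 42% at 8 — drift must reach several
natural bins before the full-spectrum peak truly collapses).

Split-peak filtering rejects peaks with a satellite local maximum ≥20% of
the main height within ±10 natural bins (outside a 2.5-bin main-lobe
exclusion — the first sidelobe of a clean rectangular-window peak is 21.7%
at 1.43 bins and must not trigger it) or a FWHM beyond 1.5× the
transform-limited width (1.2067 natural bins). Mass histograms enter each
accepted trace once with its real-valued (unrounded) charge; modes are
Gaussian-fitted over ±3σ windows and reported as mass/FWHM. Survival
ratio is the second-half/first-half peak intensity from a two-window
segmented transform. Charge-precision scaling fits `σ_z(t) = A·t^B`; white
detector noise gives B = −1/2, and quadrupling the transient from 1,024 to
4,096 ms halves σ_z (measured ratio ≈1.9 on 500-ion ensembles; the small
deficit is the parabola-height interpolation floor).

## Validation protocol sizes

The reproducible protocols in `orbichase.benchmarks` (run by
`scripts/acceptance.py` and the test suite) use: 20 noiseless transients
over m/z 5,000–35,000 for the frequency-law slope; 100 noise-only
transients at each of 128/256/512/1,024/2,048 ms for the noise-band
exponent; 1,000 ions × 15 segments for the decay-model refit; and 500 ions
per duration for the 1,024↔4,096 ms precision ratio. Tracing correctness
is validated on 200 simulated multi-ion transients with truth records
(≥95% of retained traces map one-to-one onto true ions; none mixes two
resolvable ions). These sizes are the package's chosen study conditions;
all are desk-scale on a single CPU.

## Known limitations

* Magnitude-mode widths, not phase-aware ("enhanced FT") widths; the
  surrogate needs a known phase.
* No multi-hypothesis (assignment-problem) tracking: crossing ion pairs are
  excluded upstream rather than disambiguated.
* Hard-sphere collision physics with user-supplied radii; no trajectory
  integration of the trap field.
* Ions-per-transient and m/z spacing in the population generator are tuned
  for sparse single-ion regimes; dense spectra will push more ions into the
  isolation filter.
* Absolute sampling-gain folds and absolute S/N depend on instrument data
  and are out of scope; the package tests their mechanisms (recovery of
  drifting ions, square-root noise scaling) on synthetic conditions.
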