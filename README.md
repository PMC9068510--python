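# orbichase

Single-ion **frequency chasing** for Orbitrap-based charge-detection mass
spectrometry (CDMS).

In Orbitrap CDMS, individual megadalton ions (virus capsids, nanocages,
antibody assemblies) are trapped for seconds and detected through their
image current. Each ion oscillates at an axial frequency set only by its
mass-to-charge ratio,

```
f = c · (m/z / 1000)^(-1/2)        c = 0.26055 MHz (m/z in Th)
```

and induces a spectral peak whose normalized height is proportional to its
charge (`z = height × 175` under the calibration modelled here), so every
detected ion yields an independent mass `M = z · (m/z − m_p)`. Over a
multi-second transient an ion travels kilometres and undergoes dozens of
background-gas collisions; instead of fragmenting, heavy ions gradually shed
residual solvent (their frequency drifts up) and, rarely, a single charge
(their frequency jumps down). Both effects split the full-transient Fourier
peaks and ruin the charge read-out.

`orbichase` implements the full analysis around this problem, for mass-
spectrometrists and methods developers who want to study or correct
single-ion frequency drift:

* **simulate** — synthetic single-ion transients with the frequency law,
  charge-proportional amplitudes, linear + exponentially-decaying neutral-loss
  processes, single charge-stripping events, radial amplitude modulation and
  white detector noise (`orbichase.simulate`);
* **spectral** — 4× zero-padded magnitude FFT with length-invariant
  normalization, three-point parabola centroiding, FWHM resolution, S/N and
  noise-band statistics (`orbichase.spectral`);
* **chase** — overlapping-window segmented FFT, nearest-in-m/z ion tracing,
  scatter filtering (4 Th / 0.2 intensity), drift classification
  (stable / gradual loss / charge loss), drift→dalton conversion, the
  linear+exponential decay-model fit, and direct charge/mass assignment from
  charge-loss doublets (`orbichase.chase`);
* **cdms** — intensity→charge conversion, drift-corrected ions, split-peak
  filtering, mass histograms with per-mode resolution, survival ratios,
  charge-precision scaling and sampling-utilization bookkeeping
  (`orbichase.cdms`);
* **instrument physics** — path lengths, collision cross-sections, mean free
  paths, expected collision counts, centre-of-mass energy fractions and the
  mass-scaling argument for the stability of megadalton ions
  (`orbichase.instrument`).

## Worked example: direct mass of one ion from a charge-loss doublet

A single z = 144 ion at m/z 21,343.1 (a ~3.07 MDa particle) loses one charge
halfway through a 1 s transient. Chasing its frequency across 15 overlapping
segments finds the quantized jump, and the doublet alone pins down charge
and mass — no intensity calibration involved:

```python
import orbichase as oc
from orbichase.chase import (plan_segments, segmented_centroids, isolate_candidates,
                             trace_ions, filter_traces, classify_trace,
                             full_bin_width_th, extract_charge_loss_event)

ion = oc.IonSpec(mass_da=144 * 21343.1, charge=144, charge_loss_time_s=0.5)
transient = oc.simulate_transient([ion], noise_sigma=3.0, duration_s=1.0, seed=3)

segs = segmented_centroids(transient, plan_segments(1.0), mz_range=(20000, 23000))
segs = [isolate_candidates(s) for s in segs]
trace = filter_traces(trace_ions(segs), mz_std_max=300.0)[0]
label = classify_trace(trace, full_bin_width_th(21343.1, 1.0))
event = extract_charge_loss_event(trace)
print(f"classification: {label}")
print(f"m/z before / after: {event.mz_before:.1f} / {event.mz_after:.1f} Th")
print(f"charge before the event: {event.z_estimate:.2f} +- {event.z_uncertainty:.2f}")
print(f"single-ion mass: {event.mass_estimate:,.0f} +- {event.mass_uncertainty:.0f} Da")
```

prints

```
classification: charge_loss
m/z before / after: 21343.1 / 21492.3 Th
charge before the event: 144.05 +- 0.05
single-ion mass: 3,073,263 +- 6 Da
```

The charge lands on a near-integer value, as it must for a real
charge-stripping event, and the mass is `round(z) × (m/z − m_p)` with the
uncertainty propagated from the segment centroids.

## Command line

```sh
orbichase simulate --preset hbv --n 50 --seed 1 --out-dir scans/
orbichase spectrum scans/transient_0000.trans --out centroids.csv
orbichase chase scans/*.trans --out-prefix run1 --segments 15 --overlap 0.5
orbichase histogram ions.csv --out hist.csv --bin-width 10000
orbichase physics --mz 21343.1 --duration 4.096 --radius-nm 17 --gas-preset xenon_minimized
```

Transients are stored as raw little-endian float32 samples with a JSON
metadata sidecar; all outputs are plain CSV/JSON and reproducible given
`--seed`.

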