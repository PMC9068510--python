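"""Charge-detection mass spectrometry observables.

In Orbitrap CDMS the normalized spectral peak height of a single ion is
proportional to its charge (height x charge_gain = z), so each ion yields an
independent (m/z, z) pair and hence a mass.  Ions whose frequency drifts
during the transient produce split peaks in the full-transient spectrum and
are normally discarded; frequency chasing recovers them by averaging each
traced ion's per-segment intensities and m/z values, which restores both the
charge read-out and the m/z position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .chase import IonTrace
from .instrument import DEFAULT_INSTRUMENT, InstrumentModel
from .simulate import Transient
from .spectral import (
    RECT_FWHM_BINS,
    Centroid,
    ScalingFit,
    Spectrum,
    compute_spectrum,
    fit_power_law,
    strongest_centroid,
)

__all__ = [
    "CDMSIon",
    "MassHistogram",
    "ModeFit",
    "SamplingReport",
    "intensity_to_charge",
    "ion_from_centroid",
    "drift_correct",
    "filter_split_peaks",
    "build_mass_histogram",
    "survival_ratio",
    "charge_sigma_vs_time",
    "sampling_report",
]


@dataclass
class CDMSIon:
    """One accepted single-ion measurement."""

    mz: float
    intensity: float
    charge: float
    mass_da: float
    source: str  # "eft_direct" | "drift_corrected"
    flags: list[str] = field(default_factory=list)

    @property
    def charge_int(self) -> int:
        return round(self.charge)


def intensity_to_charge(intensity: float, model: InstrumentModel = DEFAULT_INSTRUMENT) -> float:
    """Convert a normalized spectral intensity into charges (x charge_gain)."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return intensity * model.charge_gain


def _make_ion(
    mz: float,
    intensity: float,
    source: str,
    model: InstrumentModel,
    subtract_proton: bool,
) -> CDMSIon:
    charge = intensity_to_charge(intensity, model)
    mass = charge * (mz - (model.proton_mass_da if subtract_proton else 0.0))
    return CDMSIon(mz=mz, intensity=intensity, charge=charge, mass_da=mass, source=source)


def ion_from_centroid(
    centroid: Centroid,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    subtract_proton: bool = True,
) -> CDMSIon:
    """CDMS ion straight from a full-transient centroid (no drift correction)."""
    return _make_ion(centroid.mz, centroid.intensity, "eft_direct", model, subtract_proton)


def drift_correct(
    trace: IonTrace,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    subtract_proton: bool = True,
) -> CDMSIon:
    """Drift-corrected CDMS ion from a retained trace.

    Intensities and m/z values are averaged over the individual segments;
    within each short segment the drift is far below the segment bin width,
    so the per-segment peak heights are unaffected by the drift that splits
    the full-transient peak.
    """
    if trace.classification == "rejected":
        raise ValueError("cannot drift-correct a rejected trace")
    ion = _make_ion(
        float(np.mean(trace.mz)),
        float(np.mean(trace.intensity)),
        "drift_corrected",
        model,
        subtract_proton,
    )
    if trace.classification:
        ion.flags.append(trace.classification)
    return ion


def filter_split_peaks(
    spectrum: Spectrum,
    centroids: list[Centroid],
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    satellite_fraction: float = 0.2,
    satellite_window_bins: float = 10.0,
    satellite_exclusion_bins: float = 2.5,
    fwhm_tolerance: float = 1.5,
) -> tuple[list[Centroid], list[Centroid]]:
    """Split accepted from rejected full-transient peaks.

    A peak is rejected when it shows satellite structure (a secondary local
    maximum above ``satellite_fraction`` of the main height within
    ``satellite_window_bins`` natural bins, outside the main-lobe exclusion)
    or an anomalous width (measured FWHM beyond ``fwhm_tolerance`` times the
    transform-limited width of a stable sinusoid).  Drifts below about one
    Fourier bin leave peaks within the stability margin and are accepted.
    """
    mag = spectrum.magnitude
    pad = spectrum.zero_pad_factor
    theoretical_fwhm_hz = RECT_FWHM_BINS * spectrum.natural_bin_hz
    accepted, rejected = [], []
    for c in centroids:
        bad = False
        if c.fwhm_hz is not None and c.fwhm_hz > fwhm_tolerance * theoretical_fwhm_hz:
            bad = True
        if not bad:
            i0 = spectrum.freq_index(c.frequency_hz)
            excl = int(round(satellite_exclusion_bins * pad))
            span = int(round(satellite_window_bins * pad))
            lo = max(i0 - span, 1)
            hi = min(i0 + span, len(mag) - 2)
            idx = np.arange(lo, hi + 1)
            window = mag[lo: hi + 1]
            local_max = np.zeros(len(window), dtype=bool)
            local_max[1:-1] = (window[1:-1] > window[:-2]) & (window[1:-1] >= window[2:])
            outside = np.abs(idx - i0) > excl
            if np.any(local_max & outside & (window >= satellite_fraction * c.intensity)):
                bad = True
        (rejected if bad else accepted).append(c)
    return accepted, rejected


@dataclass
class ModeFit:
    """Gaussian fit of one histogram mode."""

    mass_da: float
    sigma_da: float
    fwhm_da: float
    resolution: float
    amplitude: float


@dataclass
class MassHistogram:
    bin_edges_da: np.ndarray
    counts: np.ndarray
    modes: list[ModeFit]

    @property
    def n_ions(self) -> int:
        return int(self.counts.sum())


def build_mass_histogram(
    ions: list[CDMSIon],
    bin_width_da: float,
    mode_prominence: float = 0.2,
) -> MassHistogram:
    """Histogram accepted ion masses and fit a Gaussian to each mode.

    Modes are local maxima of the counts with prominence above
    ``mode_prominence`` x the tallest bin; each is fitted over a +-3 sigma
    window and reported as mass, FWHM and resolution (mass / FWHM).
    Each accepted ion enters the histogram once, with its real-valued charge.
    """
    if not ions:
        raise ValueError("need at least one accepted ion")
    if bin_width_da <= 0:
        raise ValueError("bin_width_da must be positive")
    masses = np.asarray([i.mass_da for i in ions])
    lo = math.floor(masses.min() / bin_width_da) * bin_width_da
    hi = math.ceil(masses.max() / bin_width_da) * bin_width_da + bin_width_da
    edges = np.arange(lo, hi + bin_width_da / 2, bin_width_da)
    counts, edges = np.histogram(masses, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = find_peaks(counts, prominence=mode_prominence * counts.max())
    if len(peaks) == 0:
        peaks = [int(np.argmax(counts))]
    modes = []
    for p in peaks:
        sigma0 = max(_halfwidth_sigma(counts, p) * bin_width_da, bin_width_da / 2)
        sel = np.abs(centers - centers[p]) <= 3 * sigma0
        if sel.sum() < 4:
            sel = np.abs(centers - centers[p]) <= 6 * sigma0
        try:
            popt, _ = curve_fit(
                lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
                centers[sel],
                counts[sel],
                p0=(counts[p], centers[p], sigma0),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        a, mu, s = popt
        s = abs(float(s))
        fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * s
        modes.append(
            ModeFit(
                mass_da=float(mu),
                sigma_da=s,
                fwhm_da=fwhm,
                resolution=float(mu / fwhm) if fwhm > 0 else math.inf,
                amplitude=float(a),
            )
        )
    return MassHistogram(bin_edges_da=edges, counts=counts, modes=modes)


def _halfwidth_sigma(counts: np.ndarray, peak: int) -> float:
    """Half-height half-width of a histogram peak in bins, as a sigma estimate."""
    half = counts[peak] / 2.0
    width = 1.0
    for step in (1, -1):
        i = peak
        while 0 < i < len(counts) - 1 and counts[i] > half:
            i += step
        width = max(width, abs(i - peak))
    return width / 1.1774


def survival_ratio(
    transient: Transient,
    mz: float,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    mz_halfwidth_th: float = 50.0,
) -> float:
    """Second-half / first-half peak intensity of the ion near ``mz``.

    Both halves are processed under the same length-invariant normalization,
    so a persistent ion scores ~1 and an ion lost at half time scores ~0;
    intermediate losses interpolate (an ion lost at 75% of the transient is
    present for half of the second window, giving ~0.5).
    """
    n = transient.n_samples
    halves = []
    for sl in (slice(0, n // 2), slice(n // 2, n)):
        x = transient.samples[sl]
        sub = Transient(
            samples=x,
            sample_rate_hz=transient.sample_rate_hz,
            duration_s=len(x) / transient.sample_rate_hz,
        )
        spec = compute_spectrum(sub, model)
        c = strongest_centroid(
            spec, mz_range=(mz - mz_halfwidth_th, mz + mz_halfwidth_th),
            model=model, measure_width=False,
        )
        halves.append(c.intensity)
    first, second = halves
    if first <= 0:
        raise ValueError("ion not detectable in the first half")
    return float(second / first)


def charge_sigma_vs_time(charges_by_duration: dict[float, np.ndarray]) -> ScalingFit:
    """Power-law fit of the charge standard deviation versus transient time.

    For a white-noise-limited detector the exponent is -0.5 (charge
    precision improves with the square root of the transient length).
    Zero-spread (noiseless) ensembles yield a degenerate, flagged fit.
    """
    if len(charges_by_duration) < 3:
        raise ValueError("need at least 3 durations")
    durations = np.asarray(sorted(charges_by_duration))
    sigmas = np.asarray(
        [np.std(np.asarray(charges_by_duration[d]), ddof=1) for d in durations]
    )
    if np.any(sigmas <= 0):
        return ScalingFit(math.nan, math.nan, math.nan, degenerate=True)
    return fit_power_law(durations, sigmas)


@dataclass
class SamplingReport:
    """Signal-utilization bookkeeping for split-peak filtering vs chasing."""

    detected: int
    rejected_split: int
    recovered: int
    baseline_utilization: float
    corrected_utilization: float
    fold_improvement: float


def sampling_report(eft_accepted: int, eft_rejected: int, chase_recovered: int) -> SamplingReport:
    """Utilization fractions before and after drift-correction recovery.

    ``eft_accepted`` ions survive split-peak filtering of the full-transient
    spectra; ``chase_recovered`` of the rejected ones are recovered by
    frequency chasing.  The fold improvement is the ratio of the corrected
    to the baseline utilization.
    """
    if min(eft_accepted, eft_rejected, chase_recovered) < 0:
        raise ValueError("counts must be >= 0")
    if chase_recovered > eft_rejected:
        raise ValueError("cannot recover more ions than were rejected")
    detected = eft_accepted + eft_rejected
    if detected == 0:
        raise ValueError("no ions detected")
    if eft_accepted == 0:
        raise ValueError("baseline utilization is zero; fold improvement undefined")
    baseline = eft_accepted / detected
    corrected = (eft_accepted + chase_recovered) / detected
    return SamplingReport(
        detected=detected,
        rejected_split=eft_rejected,
        recovered=chase_recovered,
        baseline_utilization=baseline,
        corrected_utilization=corrected,
        fold_improvement=corrected / baseline,
    )
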