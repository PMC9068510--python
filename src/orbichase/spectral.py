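"""Transient -> spectrum -> centroid processing.

Transients are zero-padded (factor 4 by default), transformed with a
magnitude-mode FFT and normalized so that a unit-amplitude non-decaying
sinusoid yields a peak height of 1.0 regardless of transient length.  That
length-invariant normalization is what makes spectral peak height a direct
charge read-out (height = z / charge_gain) and makes noise-band statistics
comparable across transient durations.

Peak positions are refined to sub-bin precision with a three-point
least-squares parabola through the magnitude values around each local
maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instrument import DEFAULT_INSTRUMENT, InstrumentModel, freq_to_mz, mz_to_freq
from .simulate import Transient

__all__ = [
    "Spectrum",
    "Centroid",
    "ScalingFit",
    "RECT_FWHM_BINS",
    "RAYLEIGH_STD_OVER_MEDIAN",
    "compute_spectrum",
    "estimate_noise_sigma",
    "pick_peaks",
    "strongest_centroid",
    "centroid_parabola",
    "measure_fwhm_hz",
    "fwhm_resolution",
    "noise_band_sigma",
    "fit_power_law",
]

#: FWHM of the magnitude spectrum of an un-apodized (rectangular-window)
#: sinusoid, in units of natural Fourier bins (1/T).
RECT_FWHM_BINS = 1.2067
#: std/median ratio of a Rayleigh distribution; converts the robust median
#: of noise magnitudes into the noise-band standard deviation.
RAYLEIGH_STD_OVER_MEDIAN = math.sqrt(2.0 - math.pi / 2.0) / math.sqrt(2.0 * math.log(2.0))


@dataclass
class Spectrum:
    """One-sided, length-normalized spectrum of a transient."""

    frequency_hz: np.ndarray
    magnitude: np.ndarray
    mode: str
    effective_duration_s: float
    zero_pad_factor: int
    sample_rate_hz: float
    n_samples: int

    @property
    def bin_spacing_hz(self) -> float:
        """Frequency-axis spacing: sample_rate / (n_samples * zero_pad_factor)."""
        return self.sample_rate_hz / (self.n_samples * self.zero_pad_factor)

    @property
    def natural_bin_hz(self) -> float:
        """Un-padded Fourier bin width, 1 / effective duration."""
        return 1.0 / self.effective_duration_s

    def freq_index(self, freq_hz: float) -> int:
        return int(round(freq_hz / self.bin_spacing_hz))


@dataclass
class Centroid:
    """Sub-bin peak position with interpolated height."""

    mz: float
    frequency_hz: float
    intensity: float
    fwhm_th: float | None = None
    fwhm_hz: float | None = None
    snr: float | None = None
    segment_index: int | None = None


@dataclass
class ScalingFit:
    """Power-law fit y = A * x**B."""

    amplitude: float
    exponent: float
    r2: float
    degenerate: bool = False


def compute_spectrum(
    transient: Transient,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    mode: str = "magnitude",
    phase0_rad: float = 0.0,
) -> Spectrum:
    """Zero-pad, transform and normalize a transient.

    ``mode="magnitude"`` (default) returns absolute FFT values.
    ``mode="absorption_surrogate"`` returns the real part after rotating the
    spectrum by the known initial phase ``phase0_rad`` -- a stand-in for
    phase-aware enhanced-FT processing that is only applicable when the
    signal phase is known (e.g. for simulated data).
    """
    x = np.asarray(transient.samples, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("transient must contain at least 2 samples")
    pad = int(model.zero_pad_factor)
    m = n * pad
    spec = np.fft.rfft(x, m) * (2.0 / n)
    if mode == "magnitude":
        mag = np.abs(spec)
    elif mode == "absorption_surrogate":
        mag = np.real(spec * np.exp(-1j * phase0_rad))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    freq = np.arange(len(mag)) * (transient.sample_rate_hz / m)
    return Spectrum(
        frequency_hz=freq,
        magnitude=mag,
        mode=mode,
        effective_duration_s=n / transient.sample_rate_hz,
        zero_pad_factor=pad,
        sample_rate_hz=transient.sample_rate_hz,
        n_samples=n,
    )


def _mz_range_mask(spectrum: Spectrum, mz_range, model: InstrumentModel) -> np.ndarray:
    mask = np.ones(len(spectrum.magnitude), dtype=bool)
    mask[0] = False  # DC
    if mz_range is not None:
        lo, hi = mz_range
        if hi <= lo:
            raise ValueError("mz_range must be (low, high) with high > low")
        f_lo = mz_to_freq(hi, model)
        f_hi = mz_to_freq(lo, model)
        mask &= (spectrum.frequency_hz >= f_lo) & (spectrum.frequency_hz <= f_hi)
    return mask


def estimate_noise_sigma(spectrum: Spectrum, mz_range=None,
                         model: InstrumentModel = DEFAULT_INSTRUMENT) -> float:
    """Robust noise-band standard deviation of the magnitude spectrum.

    Uses the median of the magnitudes (peaks are sparse, so the median sits
    on the noise floor) scaled by the Rayleigh std/median ratio.
    """
    mask = _mz_range_mask(spectrum, mz_range, model)
    if not mask.any():
        raise ValueError("empty frequency range")
    return float(np.median(spectrum.magnitude[mask]) * RAYLEIGH_STD_OVER_MEDIAN)


def centroid_parabola(
    spectrum: Spectrum,
    peak_bin: int,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    segment_index: int | None = None,
    measure_width: bool = True,
) -> Centroid:
    """Three-point least-squares parabola through the magnitudes at
    (peak_bin - 1, peak_bin, peak_bin + 1); returns the vertex as a Centroid.
    """
    mag = spectrum.magnitude
    if peak_bin < 1 or peak_bin > len(mag) - 2:
        raise ValueError("peak_bin must have both neighbours in range")
    ym, y0, yp = mag[peak_bin - 1], mag[peak_bin], mag[peak_bin + 1]
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = float(y0 - 0.25 * (ym - yp) * delta)
    freq = (peak_bin + delta) * spectrum.bin_spacing_hz
    mz = freq_to_mz(freq, model) if freq > 0 else math.nan
    fwhm_hz = fwhm_th = None
    if measure_width:
        fwhm_hz = measure_fwhm_hz(spectrum, peak_bin)
        if fwhm_hz is not None and freq > 0:
            # |d(mz)/df| = 2 mz / f for the square-law frequency axis
            fwhm_th = fwhm_hz * 2.0 * mz / freq
    return Centroid(
        mz=mz,
        frequency_hz=float(freq),
        intensity=height,
        fwhm_hz=fwhm_hz,
        fwhm_th=fwhm_th,
        segment_index=segment_index,
    )


def measure_fwhm_hz(spectrum: Spectrum, peak_bin: int, max_span_bins: int | None = None) -> float | None:
    """Full width at half maximum around ``peak_bin`` via linear interpolation
    of the half-height crossings.  Returns None when a crossing cannot be
    found (unresolved or edge-bounded peak).
    """
    mag = spectrum.magnitude
    half = mag[peak_bin] / 2.0
    if max_span_bins is None:
        max_span_bins = 40 * spectrum.zero_pad_factor
    lo = None
    for i in range(peak_bin - 1, max(peak_bin - max_span_bins, 0) - 1, -1):
        if mag[i] < half:
            # ties at plateaus break toward the lower-frequency crossing
            lo = i + (half - mag[i]) / (mag[i + 1] - mag[i])
            break
        if mag[i] > mag[peak_bin]:
            return None
    hi = None
    for i in range(peak_bin + 1, min(peak_bin + max_span_bins, len(mag) - 1) + 1):
        if mag[i] < half:
            hi = i - (half - mag[i]) / (mag[i - 1] - mag[i])
            break
        if mag[i] > mag[peak_bin]:
            return None
    if lo is None or hi is None:
        return None
    return float((hi - lo) * spectrum.bin_spacing_hz)


def pick_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 10.0,
    mz_range=None,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    exclusion_bins: float = 12.0,
    sidelobe_range_bins: float = 200.0,
    sidelobe_guard: float = 2.0,
    max_peaks: int | None = None,
    measure_width: bool = True,
) -> list[Centroid]:
    """Detect and centroid peaks above ``snr_threshold`` x noise sigma.

    Local maxima are taken in order of decreasing height; anything within
    ``exclusion_bins`` natural Fourier bins of an already-accepted stronger
    peak is treated as part of that peak's lobe structure and suppressed, as
    is anything within ``sidelobe_range_bins`` that sits below
    ``sidelobe_guard`` times the rectangular-window sidelobe envelope
    (~height/(pi x offset)) of a stronger accepted peak.  Returned centroids
    are sorted by m/z.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    mag = spectrum.magnitude
    mask = _mz_range_mask(spectrum, mz_range, model)
    if not mask.any():
        return []
    sigma = estimate_noise_sigma(spectrum, model=model)
    floor = max(snr_threshold * sigma, 1e-12 * (mag.max() or 1.0))
    local_max = np.zeros(len(mag), dtype=bool)
    local_max[1:-1] = (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
    cand = np.flatnonzero(local_max & mask & (mag > floor))
    if len(cand) == 0:
        return []
    cand = cand[np.argsort(mag[cand])[::-1]]
    pad = spectrum.zero_pad_factor
    excl = exclusion_bins * pad
    lobe_range = sidelobe_range_bins * pad
    accepted: list[int] = []
    for i in cand:
        suppressed = False
        for j in accepted:
            dist = abs(i - j)
            if dist < excl:
                suppressed = True
                break
            if dist < lobe_range:
                envelope = mag[j] / (math.pi * dist / pad)
                if mag[i] < sidelobe_guard * envelope:
                    suppressed = True
                    break
        if suppressed:
            continue
        accepted.append(int(i))
        if max_peaks is not None and len(accepted) >= max_peaks:
            break
    out = []
    for i in accepted:
        if i < 1 or i > len(mag) - 2:
            continue
        c = centroid_parabola(spectrum, i, model, measure_width=measure_width)
        c.snr = c.intensity / sigma if sigma > 0 else math.inf
        out.append(c)
    out.sort(key=lambda c: c.mz)
    return out


def strongest_centroid(
    spectrum: Spectrum,
    mz_range=None,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    measure_width: bool = True,
) -> Centroid:
    """Centroid of the single strongest local maximum in ``mz_range``.

    Convenience path for constructed/noiseless spectra where a known peak is
    measured directly rather than detected against a noise floor.
    """
    mag = spectrum.magnitude
    mask = _mz_range_mask(spectrum, mz_range, model)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("empty frequency range")
    peak = int(idx[np.argmax(mag[idx])])
    # walk to the true local maximum in case the range boundary clipped it
    while 1 < peak < len(mag) - 2 and (mag[peak + 1] > mag[peak] or mag[peak - 1] > mag[peak]):
        peak += 1 if mag[peak + 1] > mag[peak] else -1
    return centroid_parabola(spectrum, peak, model, measure_width=measure_width)


def fwhm_resolution(
    spectrum: Spectrum,
    centroid: Centroid,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
) -> float:
    """Resolving power R = mz / FWHM(mz) of a centroided peak.

    Because f ~ (m/z)**-0.5, the m/z-domain resolution is half the
    frequency-domain resolution f/FWHM(f).  Returns NaN when the half-height
    crossings cannot be resolved.
    """
    peak_bin = spectrum.freq_index(centroid.frequency_hz)
    # snap to the nearest local maximum
    mag = spectrum.magnitude
    peak_bin = int(np.clip(peak_bin, 1, len(mag) - 2))
    while 1 < peak_bin < len(mag) - 2 and (
        mag[peak_bin + 1] > mag[peak_bin] or mag[peak_bin - 1] > mag[peak_bin]
    ):
        peak_bin += 1 if mag[peak_bin + 1] > mag[peak_bin] else -1
    fwhm_hz = measure_fwhm_hz(spectrum, peak_bin)
    if fwhm_hz is None or fwhm_hz <= 0:
        return math.nan
    return centroid.frequency_hz / (2.0 * fwhm_hz)


def noise_band_sigma(
    spectrum: Spectrum,
    mz_window: tuple[float, float],
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    peak_guard: float = 3.0,
) -> float:
    """Charge-equivalent noise sigma: std of the magnitudes in an ion-free
    m/z window times the charge gain.

    Raises if the window contains a peak: the maximum magnitude is compared
    against the expected extreme of the window's Rayleigh noise
    (~scale * sqrt(2 ln n)) plus a ``peak_guard`` margin in scale units.
    """
    mask = _mz_range_mask(spectrum, mz_window, model)
    if not mask.any():
        raise ValueError("noise window contains no spectral bins")
    window = spectrum.magnitude[mask]
    # Rayleigh scale from the window median; noise alone essentially never
    # exceeds the expected extreme by peak_guard scale units
    scale = np.median(window) / math.sqrt(2.0 * math.log(2.0))
    expected_max = math.sqrt(2.0 * math.log(len(window))) + peak_guard
    if scale > 0 and window.max() > expected_max * scale:
        raise ValueError("noise window overlaps a spectral peak")
    return float(np.std(window) * model.charge_gain)


def fit_power_law(x, y) -> ScalingFit:
    """Least-squares fit of y = A * x**B on log-log axes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")
    res = stats.linregress(np.log(x), np.log(y))
    return ScalingFit(
        amplitude=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        r2=float(res.rvalue**2),
    )
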