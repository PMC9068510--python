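"""Reproducible end-to-end validation protocols.

Each function runs a complete simulate -> process -> measure pipeline at a
fixed, documented problem size and returns the headline quantity it
measures, so the package's core claims (frequency-law calibration,
noise-limited charge precision scaling, the dual decay-loss model, the
square-root precision gain from longer transients) can be re-checked from
scratch with one call.  All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chase import DecayFitResult, fit_decay_model
from .instrument import DEFAULT_INSTRUMENT, InstrumentModel
from .simulate import IonSpec, LossProcess, simulate_segment_losses, simulate_transient
from .spectral import (
    ScalingFit,
    compute_spectrum,
    fit_power_law,
    noise_band_sigma,
    strongest_centroid,
)

__all__ = [
    "FrequencyLawFit",
    "frequency_law_slope",
    "noise_band_scaling",
    "decay_model_recovery",
    "charge_sigma_ensemble",
    "charge_sigma_ratio",
]


@dataclass
class FrequencyLawFit:
    slope_mhz: float
    intercept_mhz: float
    r2: float
    n_points: int


def frequency_law_slope(
    seed: int = 1,
    n_points: int = 20,
    mz_range: tuple[float, float] = (5000.0, 35000.0),
    duration_s: float = 1.0,
    charge: int = 100,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
) -> FrequencyLawFit:
    """Recover the frequency-law coefficient from simulated transients.

    Simulates ``n_points`` noiseless single-ion transients at m/z values
    evenly spaced over ``mz_range``, centroids each magnitude spectrum, and
    regresses the measured frequency (MHz) on (m/z in kTh)**-0.5.  The slope
    is the instrument calibration coefficient (default 0.26055 MHz).
    """
    mzs = np.linspace(*mz_range, n_points)
    freqs = []
    for mz in mzs:
        tr = simulate_transient(
            [IonSpec(mass_da=mz * charge, charge=charge)],
            model=model,
            duration_s=duration_s,
            seed=seed,
        )
        c = strongest_centroid(
            compute_spectrum(tr, model),
            mz_range=(mz - 200.0, mz + 200.0),
            model=model,
            measure_width=False,
        )
        freqs.append(c.frequency_hz / 1e6)
    x = (mzs / 1000.0) ** -0.5
    res = stats.linregress(x, freqs)
    return FrequencyLawFit(
        slope_mhz=float(res.slope),
        intercept_mhz=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=n_points,
    )


def noise_band_scaling(
    seed: int = 1,
    n_repeats: int = 100,
    durations_s: tuple[float, ...] = (0.128, 0.256, 0.512, 1.024, 2.048),
    noise_sigma: float = 3.0,
    mz_window: tuple[float, float] = (20000.0, 26000.0),
    model: InstrumentModel = DEFAULT_INSTRUMENT,
) -> ScalingFit:
    """Power-law exponent of the noise-band charge sigma versus transient time.

    Generates ``n_repeats`` white-noise-only transients at each duration,
    converts the standard deviation of the spectral magnitudes in a fixed
    peak-free m/z window into charge units, and fits sigma_z(t) = A * t**B.
    White detector noise under length-invariant normalization gives B = -1/2.
    """
    sigmas = []
    for d in durations_s:
        vals = [
            noise_band_sigma(
                compute_spectrum(
                    simulate_transient(
                        [], model=model, noise_sigma=noise_sigma,
                        duration_s=d, seed=(seed * 100000 + i) % (2**31 - 1),
                    ),
                    model,
                ),
                mz_window,
                model,
            )
            for i in range(n_repeats)
        ]
        sigmas.append(float(np.mean(vals)))
    return fit_power_law(durations_s, sigmas)


def decay_model_recovery(
    seed: int = 7,
    n_ions: int = 1000,
    n_segments: int = 15,
    alpha_da: float = 25.0,
    beta_da: float = 120.0,
    tau_segments: float = 3.0,
) -> DecayFitResult:
    """Fit the linear+exponential loss model to ensemble-averaged losses.

    Simulates Poissonized per-segment neutral losses for ``n_ions`` ions with
    the given true parameters, averages losses per segment across the
    ensemble and refits the model.  Returns the fit (the r^2 of which is the
    headline quality figure).
    """
    loss = LossProcess.from_segment_model(
        alpha_da, beta_da, tau_segments, segment_duration_s=1.0 / n_segments
    )
    table = simulate_segment_losses(loss, n_segments, n_ions, seed=seed)
    return fit_decay_model(table.mean(axis=0))


def charge_sigma_ensemble(
    duration_s: float,
    seed: int,
    n_ions: int = 500,
    ions_per_transient: int = 25,
    charge: int = 150,
    noise_sigma: float = 6.0,
    mz_span: tuple[float, float] = (16000.0, 26000.0),
    model: InstrumentModel = DEFAULT_INSTRUMENT,
) -> np.ndarray:
    """Charge estimates for ``n_ions`` identical-charge ions at one duration.

    Ions are spread over well-separated m/z slots (with a small random
    offset so the ensemble samples all sub-bin positions) and batched
    ``ions_per_transient`` per transient; each charge is read from the
    parabola-interpolated peak height times the charge gain.
    """
    rng = np.random.default_rng(seed)
    slots = np.linspace(*mz_span, ions_per_transient)
    charges = []
    for _ in range(max(1, n_ions // ions_per_transient)):
        mzs = slots + rng.uniform(-20.0, 20.0, ions_per_transient)
        ions = [
            IonSpec(mass_da=mz * charge, charge=charge, phase0_rad=rng.uniform(0, 2 * np.pi))
            for mz in mzs
        ]
        tr = simulate_transient(
            ions, model=model, noise_sigma=noise_sigma, duration_s=duration_s,
            seed=int(rng.integers(2**31 - 1)),
        )
        spec = compute_spectrum(tr, model)
        for mz in mzs:
            c = strongest_centroid(
                spec, mz_range=(mz - 100.0, mz + 100.0), model=model, measure_width=False
            )
            charges.append(c.intensity * model.charge_gain)
    return np.asarray(charges)


def charge_sigma_ratio(
    seed: int = 1,
    n_ions: int = 500,
    durations_s: tuple[float, float] = (1.024, 4.096),
    **kwargs,
) -> tuple[float, dict[float, np.ndarray]]:
    """sigma_z(short) / sigma_z(long) for a 4x transient-length increase.

    Square-root noise scaling predicts a ratio of 2 for the default
    1,024 ms -> 4,096 ms comparison.  Returns the ratio and the per-duration
    charge samples (for downstream mass-precision checks).
    """
    ensembles = {
        d: charge_sigma_ensemble(d, seed=seed + i, n_ions=n_ions, **kwargs)
        for i, d in enumerate(durations_s)
    }
    short, long_ = (ensembles[d] for d in durations_s)
    return float(np.std(short, ddof=1) / np.std(long_, ddof=1)), ensembles
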