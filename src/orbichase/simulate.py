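"""Synthetic single-ion image-current transients.

A trapped ion of charge z induces an image current proportional to z,
oscillating at the axial frequency set by its m/z.  A transient is the sum of
such tones plus white detector noise.  The generator reproduces the processes
the analysis downstream has to cope with:

* gradual neutral loss (solvent/adduct evaporation) -- discrete mass-loss
  events whose rate combines a constant term per travelled distance with an
  exponentially decaying injection-activation term, raising the frequency
  over the transient;
* rare single charge-stripping events -- the amplitude drops by 1/z and the
  frequency falls because m/z jumps from mass/z to mass/(z-1);
* amplitude modulation by a radial frequency, producing mirrored sidebands
  around the axial peak;
* ion loss from the trap at a configurable time.

Amplitudes are calibrated so a non-decaying ion of charge z yields a
normalized spectral peak height of exactly z / charge_gain, matching the
intensity-to-charge conversion used by the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .instrument import DEFAULT_INSTRUMENT, InstrumentModel, mz_to_freq

__all__ = [
    "LossProcess",
    "IonSpec",
    "Transient",
    "WATER_LOSS_MASS_DA",
    "ADDUCT_LOSS_MASS_DA",
    "DEFAULT_SPEED_KM_S",
    "HBV_MASS_MODES",
    "segment_loss_preset",
    "expected_segment_losses",
    "simulate_transient",
    "simulate_population",
    "simulate_segment_losses",
]

#: Water, the dominant small neutral loss.
WATER_LOSS_MASS_DA = 18.010565
#: Ammonium-acetate-scale adduct loss.
ADDUCT_LOSS_MASS_DA = 77.0

#: Travelled speed (km/s) of a reference megadalton ion (m/z 21,343.1),
#: used to convert loss rates per km into rates per second when no ion
#: is specified.
DEFAULT_SPEED_KM_S = 5.287

#: Two-mode mass distribution emulating icosahedral capsids co-existing in
#: T=3 / T=4 forms at ~3 and ~4 MDa: (weight, mean Da, sd Da).
HBV_MASS_MODES = ((0.5, 3.0e6, 3.0e4), (0.5, 4.0e6, 4.0e4))


@dataclass(frozen=True)
class LossProcess:
    """Neutral-loss event process for one ion.

    Event intensity at time t (events per second):

        lambda(t) = linear_rate_per_km * v  +  exp_rate_per_s * exp(-t / exp_tau_s)

    where v is the ion speed in km/s.  The first term models a constant
    collision rate per travelled distance during detection; the second a
    suddenly activated ion shedding solvent after energetic injection.
    Each event removes ~Normal(loss_mass_mean_da, loss_mass_sd_da) daltons
    (truncated at zero).  With ``stochastic=False`` the mean mass-loss curve
    is applied deterministically (continuous drift, exact for tests).
    """

    linear_rate_per_km: float = 0.0
    exp_rate_per_s: float = 0.0
    exp_tau_s: float = 0.2
    loss_mass_mean_da: float = WATER_LOSS_MASS_DA
    loss_mass_sd_da: float = 2.0
    stochastic: bool = True

    def __post_init__(self) -> None:
        if self.linear_rate_per_km < 0 or self.exp_rate_per_s < 0:
            raise ValueError("loss rates must be >= 0")
        if self.exp_tau_s <= 0:
            raise ValueError("exp_tau_s must be positive")
        if self.loss_mass_mean_da <= 0:
            raise ValueError("loss_mass_mean_da must be positive")
        if self.loss_mass_sd_da < 0:
            raise ValueError("loss_mass_sd_da must be >= 0")

    @classmethod
    def from_segment_model(
        cls,
        alpha_da_per_segment: float,
        beta_da: float,
        tau_segments: float,
        segment_duration_s: float,
        speed_km_s: float = DEFAULT_SPEED_KM_S,
        loss_mass_mean_da: float = WATER_LOSS_MASS_DA,
        loss_mass_sd_da: float = 2.0,
        stochastic: bool = True,
    ) -> "LossProcess":
        """Loss process whose expected loss in segment k is alpha + beta*exp(-k/tau).

        ``alpha_da_per_segment`` is the constant (linear) loss per segment of
        length ``segment_duration_s``; ``beta_da`` the amplitude of the
        decaying (injection-activation) term at k=0 and ``tau_segments`` its
        decay constant in segments.  The mapping is exact: integrating the
        time-domain rates over segment k reproduces alpha + beta*exp(-k/tau).
        """
        if alpha_da_per_segment < 0 or beta_da < 0:
            raise ValueError("alpha and beta must be >= 0")
        if tau_segments <= 0 or segment_duration_s <= 0:
            raise ValueError("tau_segments and segment_duration_s must be positive")
        tau_s = tau_segments * segment_duration_s
        linear_rate_per_km = alpha_da_per_segment / (
            loss_mass_mean_da * segment_duration_s * speed_km_s
        )
        # integral of r0*exp(-t/tau) over segment k equals
        # r0 * tau * (1 - exp(-dt/tau)) * exp(-k dt/tau); solve for r0.
        depletion = tau_s * (1.0 - math.exp(-segment_duration_s / tau_s))
        exp_rate_per_s = beta_da / (loss_mass_mean_da * depletion)
        return cls(
            linear_rate_per_km=linear_rate_per_km,
            exp_rate_per_s=exp_rate_per_s,
            exp_tau_s=tau_s,
            loss_mass_mean_da=loss_mass_mean_da,
            loss_mass_sd_da=loss_mass_sd_da,
            stochastic=stochastic,
        )

    def expected_event_integral(self, t: float, speed_km_s: float) -> float:
        """Expected number of events in [0, t] at constant speed."""
        return self.linear_rate_per_km * speed_km_s * t + self.exp_rate_per_s * self.exp_tau_s * (
            1.0 - math.exp(-t / self.exp_tau_s)
        )


def segment_loss_preset(
    total_da: float,
    n_segments: int = 15,
    beta_fraction: float = 0.47,
    tau_segments: float = 3.0,
    segment_duration_s: float = 1.0 / 15.0,
    **kwargs,
) -> LossProcess:
    """Loss process tuned so the expected cumulative loss over ``n_segments``
    equals ``total_da``, split between the decaying and the constant term.

    ``segment_loss_preset(157)`` and ``segment_loss_preset(692)`` reproduce the
    small- and large-loss populations used as working examples throughout.
    """
    if total_da <= 0:
        raise ValueError("total_da must be positive")
    geom = (1.0 - math.exp(-n_segments / tau_segments)) / (1.0 - math.exp(-1.0 / tau_segments))
    beta = beta_fraction * total_da / geom
    alpha = (total_da - beta * geom) / n_segments
    return LossProcess.from_segment_model(
        alpha, beta, tau_segments, segment_duration_s, **kwargs
    )


@dataclass(frozen=True)
class IonSpec:
    """One simulated ion.

    ``mass_da`` is the total (charged) ion mass, so m/z = mass/charge; after a
    charge-stripping event m/z becomes mass/(z-1) (minus one proton mass when
    the departing charge carries it, the default).
    """

    mass_da: float
    charge: int
    phase0_rad: float = 0.0
    loss: LossProcess | None = None
    charge_loss_time_s: float | None = None
    end_time_s: float | None = None
    radial_freq_hz: float | None = None
    radial_depth: float = 0.0
    radial_phase_rad: float = 0.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_da <= 0:
            raise ValueError("mass_da must be positive")
        if int(self.charge) != self.charge or self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if not (0.0 <= self.radial_depth < 1.0):
            raise ValueError("radial_depth must be in [0, 1)")
        if self.radial_depth > 0 and not self.radial_freq_hz:
            raise ValueError("radial_depth > 0 requires radial_freq_hz")

    @property
    def mz(self) -> float:
        return self.mass_da / self.charge


@dataclass
class Transient:
    """A uniformly sampled image-current record plus its generating truth."""

    samples: np.ndarray
    sample_rate_hz: float
    duration_s: float
    seed: int | None = None
    truth: list[dict] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        n_expected = round(self.sample_rate_hz * self.duration_s)
        if len(self.samples) != n_expected:
            raise ValueError(
                f"sample count {len(self.samples)} does not match "
                f"sample_rate*duration = {n_expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("transient contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def _sample_event_times(
    loss: LossProcess, duration_s: float, speed_km_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times of the inhomogeneous Poisson loss process on [0, duration]."""
    total = loss.expected_event_integral(duration_s, speed_km_s)
    if total <= 0:
        return np.empty(0)
    n = rng.poisson(total)
    if n == 0:
        return np.empty(0)
    # inverse-CDF sampling of the normalized cumulative intensity
    grid = np.linspace(0.0, duration_s, 4097)
    cum = (
        loss.linear_rate_per_km * speed_km_s * grid
        + loss.exp_rate_per_s * loss.exp_tau_s * (1.0 - np.exp(-grid / loss.exp_tau_s))
    )
    u = rng.uniform(0.0, cum[-1], size=n)
    return np.sort(np.interp(u, cum, grid))


def _ion_waveform(
    ion: IonSpec,
    model: InstrumentModel,
    duration_s: float,
    t: np.ndarray,
    rng: np.random.Generator,
    charge_loss_sheds_proton: bool,
) -> tuple[np.ndarray, dict]:
    """Time-domain contribution of one ion and its truth record."""
    f0 = mz_to_freq(ion.mz, model)
    speed_km_s = f0 * model.dist_per_osc_mm * 1e-6
    truth: dict = {
        "mass_da": ion.mass_da,
        "charge": int(ion.charge),
        "mz": ion.mz,
        "frequency_hz": f0,
        "charge_loss_time_s": ion.charge_loss_time_s,
        "end_time_s": ion.end_time_s,
        "radial_freq_hz": ion.radial_freq_hz,
        "radial_depth": ion.radial_depth,
        "loss_events": [],
    }

    deterministic_loss = ion.loss is not None and not ion.loss.stochastic
    if deterministic_loss:
        x, extra = _deterministic_waveform(
            ion, model, t, speed_km_s, charge_loss_sheds_proton
        )
        truth.update(extra)
    else:
        # event timeline: (time, kind) with kind "loss" or "charge"
        events: list[tuple[float, str, float]] = []
        if ion.loss is not None:
            times = _sample_event_times(ion.loss, duration_s, speed_km_s, rng)
            if len(times):
                masses = np.maximum(
                    rng.normal(ion.loss.loss_mass_mean_da, ion.loss.loss_mass_sd_da, len(times)),
                    0.0,
                )
                events += [(tt, "loss", mm) for tt, mm in zip(times, masses)]
        if ion.charge_loss_time_s is not None:
            if not (0.0 < ion.charge_loss_time_s < duration_s):
                raise ValueError("charge_loss_time_s must lie within (0, duration)")
            events.append((ion.charge_loss_time_s, "charge", 0.0))
        events.sort(key=lambda e: e[0])

        # piecewise-constant mass/charge timeline
        bounds = [0.0]
        mass, charge = ion.mass_da, int(ion.charge)
        masses_seg, charges_seg = [mass], [charge]
        for tt, kind, dm in events:
            if kind == "loss":
                mass = max(mass - dm, 1.0)
                truth["loss_events"].append({"time_s": float(tt), "mass_da": float(dm)})
            else:
                if charge <= 1:
                    raise ValueError("cannot strip charge from a singly charged ion")
                charge -= 1
                if charge_loss_sheds_proton:
                    mass -= model.proton_mass_da
            bounds.append(float(tt))
            masses_seg.append(mass)
            charges_seg.append(charge)
        bounds_arr = np.asarray(bounds)
        freqs = mz_to_freq(np.asarray(masses_seg) / np.asarray(charges_seg), model)
        freqs = np.atleast_1d(freqs)
        if np.max(freqs) >= model.sample_rate_hz / 2:
            raise ValueError(
                f"axial frequency {np.max(freqs):.0f} Hz violates Nyquist at "
                f"sample rate {model.sample_rate_hz:.0f} Hz"
            )
        amps = (
            ion.amplitude_scale
            * np.asarray(charges_seg, dtype=float)
            / model.charge_gain
        )
        # exact piecewise-linear phase (continuous across events)
        phase_at_bounds = np.concatenate(
            ([0.0], np.cumsum(2 * np.pi * freqs[:-1] * np.diff(bounds_arr)))
        )
        idx = np.searchsorted(bounds_arr, t, side="right") - 1
        phase = phase_at_bounds[idx] + 2 * np.pi * freqs[idx] * (t - bounds_arr[idx])
        amp = amps[idx]
        x = amp * np.cos(ion.phase0_rad + phase)
        truth["final_mass_da"] = float(masses_seg[-1])
        truth["final_charge"] = int(charges_seg[-1])
        truth["final_mz"] = float(masses_seg[-1] / charges_seg[-1])
        truth["final_frequency_hz"] = float(freqs[-1])

    if ion.radial_depth > 0:
        x = x * (
            1.0
            + ion.radial_depth
            * np.cos(2 * np.pi * ion.radial_freq_hz * t + ion.radial_phase_rad)
        )
    if ion.end_time_s is not None:
        x = np.where(t < ion.end_time_s, x, 0.0)
    return x, truth


def _deterministic_waveform(
    ion: IonSpec,
    model: InstrumentModel,
    t: np.ndarray,
    speed_km_s: float,
    charge_loss_sheds_proton: bool,
) -> tuple[np.ndarray, dict]:
    """Continuous mean-drift waveform for a deterministic loss process."""
    loss = ion.loss
    assert loss is not None
    cum_events = loss.linear_rate_per_km * speed_km_s * t + loss.exp_rate_per_s * loss.exp_tau_s * (
        1.0 - np.exp(-t / loss.exp_tau_s)
    )
    mass_t = ion.mass_da - loss.loss_mass_mean_da * cum_events
    if np.any(mass_t <= 0):
        raise ValueError("deterministic loss process exhausts the ion mass")
    charge_t = np.full(len(t), float(ion.charge))
    if ion.charge_loss_time_s is not None:
        after = t >= ion.charge_loss_time_s
        charge_t[after] -= 1.0
        if charge_loss_sheds_proton:
            mass_t = np.where(after, mass_t - model.proton_mass_da, mass_t)
    freq_t = mz_to_freq(mass_t / charge_t, model)
    if np.max(freq_t) >= model.sample_rate_hz / 2:
        raise ValueError("axial frequency violates Nyquist")
    dt = 1.0 / model.sample_rate_hz
    phase = np.empty(len(t))
    phase[0] = 0.0
    np.cumsum(2 * np.pi * 0.5 * (freq_t[1:] + freq_t[:-1]) * dt, out=phase[1:])
    amp = ion.amplitude_scale * charge_t / model.charge_gain
    x = amp * np.cos(ion.phase0_rad + phase)
    extra = {
        "final_mass_da": float(mass_t[-1]),
        "final_charge": int(charge_t[-1]),
        "final_mz": float(mass_t[-1] / charge_t[-1]),
        "final_frequency_hz": float(freq_t[-1]),
        "deterministic_loss": True,
    }
    return x, extra


def simulate_transient(
    ions: Sequence[IonSpec],
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    noise_sigma: float = 0.0,
    duration_s: float = 1.0,
    seed: int | None = 0,
    charge_loss_sheds_proton: bool = True,
) -> Transient:
    """Simulate one transient containing ``ions`` plus white Gaussian noise.

    Identical inputs and seed produce identical samples.  Samples are stored
    as float32 (the detector dynamic range does not warrant more); all
    internal accumulation is float64.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = round(model.sample_rate_hz * duration_s)
    t = np.arange(n) / model.sample_rate_hz
    x = np.zeros(n)
    truths: list[dict] = []
    for ion in ions:
        xi, truth = _ion_waveform(ion, model, duration_s, t, rng, charge_loss_sheds_proton)
        x += xi
        truths.append(truth)
    if noise_sigma > 0:
        x += rng.normal(0.0, noise_sigma, n)
    return Transient(
        samples=x.astype(np.float32),
        sample_rate_hz=model.sample_rate_hz,
        duration_s=duration_s,
        seed=seed,
        truth=truths,
    )


def simulate_population(
    n_ions: int,
    mass_modes: Sequence[tuple[float, float, float]] = HBV_MASS_MODES,
    charge_coeff: float = 0.0831,
    charge_exponent: float = 0.5,
    charge_sd: float = 2.0,
    loss: LossProcess | None = None,
    stable_fraction: float = 0.7,
    charge_loss_prob: float = 0.0,
    mean_ions_per_transient: float = 3.0,
    duration_s: float = 1.0,
    noise_sigma: float = 3.0,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    seed: int | None = 0,
) -> list[Transient]:
    """Simulate an ensemble of transients totalling at least ``n_ions`` ions.

    Ions per transient are Poisson distributed around
    ``mean_ions_per_transient`` (matching acquisitions that catch a handful
    of individual ions per scan).  Masses are drawn from a weighted mixture
    of normal modes; charges follow z ~ round(charge_coeff * m**charge_exponent
    + Normal(0, charge_sd)), a native-ESI-like charging law.  A
    ``1 - stable_fraction`` share of ions carries the ``loss`` process, and
    each ion strips a single charge at a uniform random time with probability
    ``charge_loss_prob``.
    """
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    weights = np.asarray([m[0] for m in mass_modes], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mass mode weights must be non-negative and sum > 0")
    if any(m[1] <= 0 or m[2] < 0 for m in mass_modes):
        raise ValueError("mass mode means must be positive and sds >= 0")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    transients: list[Transient] = []
    made = 0
    while made < n_ions:
        k = rng.poisson(mean_ions_per_transient)
        specs: list[IonSpec] = []
        for _ in range(k):
            mode = rng.choice(len(mass_modes), p=weights)
            _, mu, sd = mass_modes[mode]
            mass = max(rng.normal(mu, sd), 1000.0)
            z = max(2, round(charge_coeff * mass**charge_exponent + rng.normal(0, charge_sd)))
            ion_loss = None
            if loss is not None and rng.random() > stable_fraction:
                ion_loss = loss
            charge_loss_time = None
            if charge_loss_prob > 0 and rng.random() < charge_loss_prob:
                charge_loss_time = rng.uniform(0.2, 0.8) * duration_s
            specs.append(
                IonSpec(
                    mass_da=mass,
                    charge=z,
                    phase0_rad=rng.uniform(0, 2 * np.pi),
                    loss=ion_loss,
                    charge_loss_time_s=charge_loss_time,
                )
            )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        transients.append(
            simulate_transient(
                specs, model, noise_sigma=noise_sigma, duration_s=duration_s, seed=sub_seed
            )
        )
        made += k
    return transients


def expected_segment_losses(
    loss: LossProcess,
    n_segments: int,
    segment_duration_s: float = 1.0 / 15.0,
    speed_km_s: float = DEFAULT_SPEED_KM_S,
) -> np.ndarray:
    """Expected loss (Da) in each of ``n_segments`` consecutive segments.

    Closed form: alpha + beta * exp(-k / tau_segments) with alpha, beta, tau
    as produced by :meth:`LossProcess.from_segment_model`.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    edges = np.arange(n_segments + 1) * segment_duration_s
    cum = np.array([loss.expected_event_integral(e, speed_km_s) for e in edges])
    return np.diff(cum) * loss.loss_mass_mean_da


def simulate_segment_losses(
    loss: LossProcess,
    n_segments: int,
    n_ions: int,
    seed: int | None = 0,
    segment_duration_s: float = 1.0 / 15.0,
    speed_km_s: float = DEFAULT_SPEED_KM_S,
) -> np.ndarray:
    """Per-ion, per-segment neutral losses (Da), shape (n_ions, n_segments).

    Stochastic mode draws Poisson event counts per segment around the
    expected per-segment loss and gives each event a truncated-normal mass;
    deterministic mode returns the expected losses for every ion.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    expected = expected_segment_losses(loss, n_segments, segment_duration_s, speed_km_s)
    if not loss.stochastic:
        return np.tile(expected, (n_ions, 1))
    rng = np.random.default_rng(seed)
    lam = expected / loss.loss_mass_mean_da
    counts = rng.poisson(lam, size=(n_ions, n_segments))
    total_events = int(counts.sum())
    out = np.zeros((n_ions, n_segments))
    if total_events:
        masses = np.maximum(
            rng.normal(loss.loss_mass_mean_da, loss.loss_mass_sd_da, total_events), 0.0
        )
        flat_idx = np.repeat(np.arange(counts.size), counts.ravel())
        np.add.at(out.ravel(), flat_idx, masses)
    return out
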