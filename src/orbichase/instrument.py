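"""Instrument frequency law, geometry, charge calibration and ion-gas collision physics.

The Orbitrap axial frequency of an ion depends only on its m/z:

    f = c * (m/z / 1000)**-0.5   [MHz, with m/z in Th]

with the calibration coefficient ``c`` (default 0.26055 MHz) measured for the
ultra-high-mass-range instrument this package models.  Combined with the
averaged travelled distance per axial oscillation along the central electrode,
the frequency law yields per-ion path lengths of kilometres for multi-second
transients, which in turn sets the expected number of background-gas
collisions an ion experiences while it is being detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentModel",
    "GasModel",
    "CollisionEstimate",
    "DEFAULT_INSTRUMENT",
    "FULL_RATE_INSTRUMENT",
    "GAS_PRESETS",
    "K_BOLTZMANN",
    "MBAR_TO_PA",
    "XENON_GAUGE_SENSITIVITY",
    "mz_to_freq",
    "freq_to_mz",
    "path_length",
    "ccs_from_radius",
    "number_density",
    "mean_free_path",
    "expected_collisions",
    "com_energy_fraction",
    "stability_scaling_profile",
]

#: Boltzmann constant, CODATA, J/K.
K_BOLTZMANN = 1.380649e-23
#: Exact millibar -> pascal conversion.
MBAR_TO_PA = 100.0
#: Relative sensitivity of a nitrogen-calibrated cold-cathode gauge to xenon.
#: Gauge read-outs taken with xenon are divided by this factor.
XENON_GAUGE_SENSITIVITY = 2.4


def _check_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def _check_nonnegative(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class InstrumentModel:
    """Frequency law, geometry and charge calibration of the mass analyser.

    Parameters
    ----------
    freq_coeff_mhz:
        Calibration coefficient of the axial frequency law, in MHz for m/z
        expressed in kTh.
    dist_per_osc_mm:
        Average distance travelled per axial oscillation along the central
        electrode, in mm.  Treated as a constant averaged over the accepted
        range of ion energies and radial distances.
    sample_rate_hz:
        Sampling rate of the image-current transient.  The default 250 kHz
        covers every axial frequency above m/z ~4,500; a 4 MHz full-rate
        model is available as :data:`FULL_RATE_INSTRUMENT`.
    zero_pad_factor:
        Zero-padding factor applied before the FFT (customary value 4).
    charge_gain:
        Charges per unit of normalized spectral peak intensity (a single ion
        of charge z produces a normalized peak height z / charge_gain).
    proton_mass_da:
        Proton mass in Da, used when converting m/z to neutral mass.
    """

    freq_coeff_mhz: float = 0.26055
    dist_per_osc_mm: float = 93.7425
    sample_rate_hz: float = 250_000.0
    zero_pad_factor: int = 4
    charge_gain: float = 175.0
    proton_mass_da: float = 1.00728

    def __post_init__(self) -> None:
        _check_positive("freq_coeff_mhz", self.freq_coeff_mhz)
        _check_positive("dist_per_osc_mm", self.dist_per_osc_mm)
        _check_positive("sample_rate_hz", self.sample_rate_hz)
        _check_positive("charge_gain", self.charge_gain)
        _check_positive("proton_mass_da", self.proton_mass_da)
        if int(self.zero_pad_factor) != self.zero_pad_factor or self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be an integer >= 1")

    def with_sample_rate(self, sample_rate_hz: float) -> "InstrumentModel":
        return replace(self, sample_rate_hz=sample_rate_hz)


DEFAULT_INSTRUMENT = InstrumentModel()
FULL_RATE_INSTRUMENT = InstrumentModel(sample_rate_hz=4_000_000.0)


@dataclass(frozen=True)
class GasModel:
    """Background gas in the trap and the gauge read-out that measures it.

    The cold-cathode gauge sits outside the trap; the pressure in the trap
    itself is taken as ``trap_pressure_multiplier`` (default twofold) times
    the gauge read-out.  Gauges are nitrogen calibrated, so read-outs taken
    with other gases carry a ``gauge_gas_correction`` (for xenon the read-out
    is divided by :data:`XENON_GAUGE_SENSITIVITY`).
    """

    species: str = "nitrogen"
    gas_mass_da: float = 28.0134
    gas_radius_m: float = 1.88e-10
    gauge_pressure_mbar: float = 2.6e-10
    trap_pressure_multiplier: float = 2.0
    gauge_gas_correction: float = 1.0
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        _check_positive("gas_mass_da", self.gas_mass_da)
        _check_positive("gas_radius_m", self.gas_radius_m)
        _check_positive("gauge_pressure_mbar", self.gauge_pressure_mbar)
        _check_positive("gauge_gas_correction", self.gauge_gas_correction)
        _check_positive("temperature_k", self.temperature_k)
        if self.trap_pressure_multiplier < 1:
            raise ValueError("trap_pressure_multiplier must be >= 1")

    @property
    def trap_pressure_pa(self) -> float:
        """Estimated true pressure inside the trap, in Pa."""
        return (
            self.gauge_pressure_mbar
            * MBAR_TO_PA
            * self.trap_pressure_multiplier
            * self.gauge_gas_correction
        )


def xenon_gas(gauge_pressure_mbar: float, **kwargs) -> GasModel:
    """Xenon background gas with the nitrogen-gauge sensitivity correction applied."""
    kwargs.setdefault("gauge_gas_correction", 1.0 / XENON_GAUGE_SENSITIVITY)
    return GasModel(
        species="xenon",
        gas_mass_da=131.293,
        gas_radius_m=2.16e-10,
        gauge_pressure_mbar=gauge_pressure_mbar,
        **kwargs,
    )


#: Named pressure conditions.  ``low_pressure`` / ``high_pressure`` are the two
#: ultra-high-vacuum gauge read-outs used for the pressure-series measurements;
#: the ``xenon_*`` variants apply the gauge sensitivity correction, and
#: ``xenon_minimized`` is a representative minimized-trap-gas condition used
#: for the long-transient collision-count illustration.
GAS_PRESETS: dict[str, GasModel] = {
    "low_pressure": GasModel(gauge_pressure_mbar=2.6e-10),
    "high_pressure": GasModel(gauge_pressure_mbar=8e-10),
    "xenon_low_pressure": xenon_gas(2.6e-10),
    "xenon_high_pressure": xenon_gas(8e-10),
    "xenon_minimized": xenon_gas(8e-11),
}


@dataclass(frozen=True)
class CollisionEstimate:
    """Path-length / mean-free-path bookkeeping for one ion."""

    path_length_m: float
    ccs_m2: float
    number_density_m3: float
    mean_free_path_m: float
    expected_collisions: float
    com_energy_fraction: float | None = None
    energy_per_area: float | None = None


def mz_to_freq(mz, model: InstrumentModel = DEFAULT_INSTRUMENT):
    """Axial frequency (Hz) of an ion at ``mz`` (Th).

    Strictly decreasing in m/z: heavier (per charge) ions oscillate slower.
    """
    _check_positive("mz", mz)
    mz = np.asarray(mz, dtype=float)
    out = model.freq_coeff_mhz * 1e6 / np.sqrt(mz / 1000.0)
    return float(out) if out.ndim == 0 else out


def freq_to_mz(freq_hz, model: InstrumentModel = DEFAULT_INSTRUMENT):
    """Inverse of :func:`mz_to_freq`: m/z (Th) for an axial frequency (Hz)."""
    _check_positive("freq_hz", freq_hz)
    freq_hz = np.asarray(freq_hz, dtype=float)
    out = 1000.0 * (model.freq_coeff_mhz * 1e6 / freq_hz) ** 2
    return float(out) if out.ndim == 0 else out


def path_length(mz: float, duration_s: float, model: InstrumentModel = DEFAULT_INSTRUMENT) -> float:
    """Distance (m) travelled during ``duration_s``: duration x frequency x distance per oscillation."""
    _check_positive("duration_s", duration_s)
    return duration_s * mz_to_freq(mz, model) * model.dist_per_osc_mm * 1e-3


def ccs_from_radius(ion_radius_m: float, gas_radius_m: float = 0.0) -> float:
    """Hard-sphere collision cross-section pi*(r_ion + r_gas)**2 in m^2."""
    _check_nonnegative("ion_radius_m", ion_radius_m)
    _check_nonnegative("gas_radius_m", gas_radius_m)
    return math.pi * (ion_radius_m + gas_radius_m) ** 2


def number_density(gas: GasModel) -> float:
    """Gas number density (m^-3) in the trap from the gauge read-out, by the ideal gas law."""
    return gas.trap_pressure_pa / (K_BOLTZMANN * gas.temperature_k)


def mean_free_path(gas: GasModel, ccs_m2: float) -> float:
    """Mean free path (m) = 1 / (number density x CCS); infinite in vacuum."""
    _check_nonnegative("ccs_m2", ccs_m2)
    n_sigma = number_density(gas) * ccs_m2
    return math.inf if n_sigma == 0 else 1.0 / n_sigma


def expected_collisions(
    mz: float,
    duration_s: float,
    ion_radius_m: float,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    gas: GasModel = GAS_PRESETS["low_pressure"],
    ion_mass_da: float | None = None,
) -> CollisionEstimate:
    """Expected number of ion-gas collisions over one transient.

    The count is the travelled path length divided by the mean free path,
    so it is exactly linear in both transient duration and trap pressure.
    When ``ion_mass_da`` is supplied, the centre-of-mass energy fraction and
    the relative collision energy per CCS area are reported as well.
    """
    _check_positive("ion_radius_m", ion_radius_m)
    length = path_length(mz, duration_s, model)
    ccs = ccs_from_radius(ion_radius_m, gas.gas_radius_m)
    n = number_density(gas)
    mfp = mean_free_path(gas, ccs)
    collisions = 0.0 if math.isinf(mfp) else length / mfp
    com = epa = None
    if ion_mass_da is not None:
        com = com_energy_fraction(ion_mass_da, gas.gas_mass_da)
        epa = com * length / ccs
    return CollisionEstimate(
        path_length_m=length,
        ccs_m2=ccs,
        number_density_m3=n,
        mean_free_path_m=mfp,
        expected_collisions=collisions,
        com_energy_fraction=com,
        energy_per_area=epa,
    )


def com_energy_fraction(ion_mass_da: float, gas_mass_da: float) -> float:
    """Fraction of the lab-frame kinetic energy available in the centre-of-mass frame.

    For a heavy ion hitting a light neutral this is gas_mass/(gas_mass+ion_mass),
    which vanishes as the ion mass grows -- one reason megadalton particles
    shrug off collisions that fragment small denatured proteins.
    """
    _check_positive("ion_mass_da", ion_mass_da)
    _check_positive("gas_mass_da", gas_mass_da)
    return gas_mass_da / (gas_mass_da + ion_mass_da)


def stability_scaling_profile(
    masses_da: Sequence[float],
    reference_mass_da: float = 1e5,
    charge_law_exponent: float = 0.5,
    gas_mass_da: float = 131.293,
) -> pd.DataFrame:
    """How travelled distance, COM energy, CCS and energy-per-area scale with ion mass.

    Assumes a native-ESI-like charging law z ~ m**charge_law_exponent
    (Rayleigh-like, exponent 0.5 by default).  Per mass m:

    * travelled distance ~ (m/z)**-0.5 (through the frequency law),
    * COM energy ~ z * gas_mass / (gas_mass + m) (lab energy ~ z),
    * CCS ~ m**(2/3) (constant-density particle),
    * energy per area = COM x distance / CCS.

    All columns are normalized to 1.0 at ``reference_mass_da``; the energy
    transferred per surface area drops steeply with mass, which is the
    scaling argument behind the observed plateau of stability for
    megadalton particles.
    """
    masses = np.asarray(masses_da, dtype=float)
    _check_positive("masses_da", masses)
    _check_positive("reference_mass_da", reference_mass_da)

    def profile(m):
        z = m**charge_law_exponent
        mz = m / z
        distance = mz**-0.5
        com = z * gas_mass_da / (gas_mass_da + m)
        ccs = m ** (2.0 / 3.0)
        return distance, com, ccs, com * distance / ccs

    d0, c0, a0, e0 = profile(reference_mass_da)
    d, c, a, e = profile(masses)
    return pd.DataFrame(
        {
            "mass_da": masses,
            "rel_distance": d / d0,
            "rel_com_energy": c / c0,
            "rel_ccs": a / a0,
            "rel_energy_per_area": e / e0,
        }
    )
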