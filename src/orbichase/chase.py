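"""Segmented-FFT frequency chasing.

The transient is cut into overlapping windows, each window is processed into
centroids, and centroids are chained across windows into per-ion traces.
Traces are filtered on their m/z and intensity scatter, then classified:

* ``stable``       -- total m/z excursion below one full-transient Fourier bin;
* ``gradual_loss`` -- drift beyond a bin without a quantized jump (solvent or
  adduct evaporation; frequency rises, m/z falls);
* ``charge_loss``  -- a between-segment jump to higher m/z whose magnitude
  matches the z/(z-1) ratio for an integer charge, i.e. the loss of a single
  elementary charge.  These rare events pin down the ion's charge (and hence
  mass) directly, without an intensity calibration.

Frequency drift of a traced ion is converted to neutral loss in daltons via
its charge, and the ensemble-averaged per-segment losses are fitted with a
linear-plus-exponential decay model (constant collision-driven loss during
detection plus a decaying injection-activation term).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .instrument import DEFAULT_INSTRUMENT, InstrumentModel
from .simulate import Transient
from .spectral import Centroid, Spectrum, compute_spectrum, estimate_noise_sigma, pick_peaks

__all__ = [
    "SegmentationPlan",
    "IonTrace",
    "NeutralLossProfile",
    "DecayFitResult",
    "ChargeLossEvent",
    "SidebandReport",
    "plan_segments",
    "segmented_centroids",
    "isolate_candidates",
    "trace_ions",
    "filter_traces",
    "classify_trace",
    "full_bin_width_th",
    "drift_to_loss",
    "fit_decay_model",
    "charge_from_pair",
    "mass_from_pair",
    "extract_charge_loss_event",
    "detect_radial_sidebands",
    "centroid_sigma_th",
]


@dataclass(frozen=True)
class SegmentationPlan:
    """Equal-length overlapping windows exactly tiling [0, duration]."""

    duration_s: float
    n_segments: int
    overlap_fraction: float
    window_length_s: float
    starts_s: np.ndarray

    def sample_slices(self, sample_rate_hz: float) -> list[slice]:
        length = round(self.window_length_s * sample_rate_hz)
        return [
            slice(s0 := round(start * sample_rate_hz), s0 + length)
            for start in self.starts_s
        ]


def plan_segments(
    duration_s: float,
    n_segments: int | None = None,
    overlap_fraction: float = 0.5,
    segments_per_second: float = 15.0,
) -> SegmentationPlan:
    """Plan ``n_segments`` equal windows with the given overlap.

    Default segment density is 15 windows per second of transient.  With
    overlap o the window length is duration / ((n-1)(1-o) + 1); for o=0.5 and
    15 segments over 1 s that is 0.125 s.  Window starts are equally spaced
    and the last window ends exactly at ``duration_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_segments is None:
        n_segments = max(2, round(segments_per_second * duration_s))
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    length = duration_s / ((n_segments - 1) * (1.0 - overlap_fraction) + 1.0)
    starts = np.arange(n_segments) * length * (1.0 - overlap_fraction)
    return SegmentationPlan(
        duration_s=duration_s,
        n_segments=n_segments,
        overlap_fraction=overlap_fraction,
        window_length_s=length,
        starts_s=starts,
    )


def segmented_centroids(
    transient: Transient,
    plan: SegmentationPlan | None = None,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    snr_threshold: float = 10.0,
    mz_range=None,
    **pick_kwargs,
) -> list[list[Centroid]]:
    """Centroid sets per segment window, each tagged with its segment index.

    A failing segment (e.g. too short) yields an empty list instead of
    aborting the others.
    """
    if plan is None:
        plan = plan_segments(transient.duration_s)
    out: list[list[Centroid]] = []
    for k, sl in enumerate(plan.sample_slices(transient.sample_rate_hz)):
        window = transient.samples[sl]
        try:
            sub = Transient(
                samples=window,
                sample_rate_hz=transient.sample_rate_hz,
                duration_s=len(window) / transient.sample_rate_hz,
                seed=transient.seed,
            )
            spectrum = compute_spectrum(sub, model)
            cents = pick_peaks(
                spectrum, snr_threshold, mz_range=mz_range, model=model, **pick_kwargs
            )
        except ValueError:
            cents = []
        for c in cents:
            c.segment_index = k
        out.append(cents)
    return out


def isolate_candidates(
    centroids: list[Centroid],
    min_separation_th: float | None = None,
    fwhm_factor: float = 2.0,
) -> list[Centroid]:
    """Drop every centroid that has a neighbour closer than the separation.

    The rule is symmetric: both members of a close pair are removed, which
    prevents tracing through crossing or unresolved ion pairs.  The default
    separation for a pair is ``fwhm_factor`` times the wider of the two
    segment-level peak widths (the achievable resolving power at that
    segment length and m/z); pass ``min_separation_th`` to use a fixed value.
    """
    drop = set()
    ordered = sorted(range(len(centroids)), key=lambda i: centroids[i].mz)
    for a, b in zip(ordered[:-1], ordered[1:]):
        ca, cb = centroids[a], centroids[b]
        if min_separation_th is not None:
            sep = min_separation_th
        else:
            widths = [w for w in (ca.fwhm_th, cb.fwhm_th) if w]
            if not widths:
                continue
            sep = fwhm_factor * max(widths)
        if abs(cb.mz - ca.mz) < sep:
            drop.update((a, b))
    return [c for i, c in enumerate(centroids) if i not in drop]


@dataclass
class IonTrace:
    """One ion's chained per-segment centroids."""

    centroids: list[Centroid]
    n_segments: int
    classification: str | None = None
    assigned_charge: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centroids) < 2:
            raise ValueError("a trace needs at least 2 segments")
        segs = [c.segment_index for c in self.centroids]
        if any(b <= a for a, b in zip(segs[:-1], segs[1:])):
            raise ValueError("trace segments must be strictly ordered")

    @property
    def segments(self) -> np.ndarray:
        return np.asarray([c.segment_index for c in self.centroids])

    @property
    def mz(self) -> np.ndarray:
        return np.asarray([c.mz for c in self.centroids])

    @property
    def intensity(self) -> np.ndarray:
        return np.asarray([c.intensity for c in self.centroids])

    @property
    def mz_std(self) -> float:
        return float(np.std(self.mz))

    @property
    def intensity_std(self) -> float:
        return float(np.std(self.intensity))

    def __len__(self) -> int:
        return len(self.centroids)


def trace_ions(
    per_segment_centroids: list[list[Centroid]],
    max_jump_th: float = 300.0,
    max_gap: int = 1,
    min_length_fraction: float = 0.6,
) -> list[IonTrace]:
    """Chain centroids across segments into traces.

    Greedy nearest-in-m/z matching from the earliest appearance: traces are
    visited in order of decreasing last intensity, each claiming the closest
    unused centroid of the next segment within ``max_jump_th``; ties in
    distance break toward the more intense candidate.  Traces may bridge up
    to ``max_gap`` missing segments and must cover at least
    ``min_length_fraction`` of the segments to be kept.
    """
    n_segments = len(per_segment_centroids)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    open_traces: list[dict] = []
    closed: list[list[Centroid]] = []
    for k, cents in enumerate(per_segment_centroids):
        unused = set(range(len(cents)))
        # earliest-started traces match first; intensity breaks ties among
        # traces of the same age
        for tr in sorted(
            open_traces, key=lambda d: (d["start"], -d["chain"][-1].intensity)
        ):
            last_mz = tr["chain"][-1].mz
            best, best_d = None, math.inf
            for i in unused:
                d = abs(cents[i].mz - last_mz)
                if d < best_d - 1e-12 or (
                    abs(d - best_d) <= 1e-12
                    and best is not None
                    and cents[i].intensity > cents[best].intensity
                ):
                    best, best_d = i, d
            if best is not None and best_d <= max_jump_th:
                tr["chain"].append(cents[best])
                tr["gap"] = 0
                unused.discard(best)
            else:
                tr["gap"] += 1
        still_open = []
        for tr in open_traces:
            if tr["gap"] > max_gap:
                closed.append(tr["chain"])
            else:
                still_open.append(tr)
        open_traces = still_open
        for i in unused:
            open_traces.append({"chain": [cents[i]], "gap": 0, "start": k})
    closed += [tr["chain"] for tr in open_traces]
    min_len = max(2, math.ceil(min_length_fraction * n_segments))
    return [
        IonTrace(chain, n_segments=n_segments)
        for chain in closed
        if len(chain) >= min_len
    ]


def filter_traces(
    traces: list[IonTrace],
    mz_std_max: float = 4.0,
    intensity_std_max: float = 0.2,
) -> list[IonTrace]:
    """Reject traces whose per-segment scatter exceeds the thresholds.

    Defaults (4 Th in m/z, 0.2 in normalized intensity) match the filtering
    applied before drift correction; rejected traces are marked
    ``classification="rejected"`` and the retained ones are returned.
    """
    retained = []
    for tr in traces:
        if tr.mz_std > mz_std_max:
            tr.classification = "rejected"
            tr.flags.append("mz_std")
        if tr.intensity_std > intensity_std_max:
            tr.classification = "rejected"
            tr.flags.append("intensity_std")
        if tr.classification != "rejected":
            retained.append(tr)
    return retained


def full_bin_width_th(mz: float, duration_s: float,
                      model: InstrumentModel = DEFAULT_INSTRUMENT) -> float:
    """One full-transient Fourier bin (1 / (duration x zero-pad factor)),
    expressed in Th at the given m/z -- the stability margin for a 'no loss'
    classification."""
    from .instrument import mz_to_freq

    df = 1.0 / (duration_s * model.zero_pad_factor)
    f = mz_to_freq(mz, model)
    return df * 2.0 * mz / f


def centroid_sigma_th(centroid: Centroid, default: float = 0.05) -> float:
    """Approximate 1-sigma m/z uncertainty of a centroid: FWHM / (2.355 x SNR)."""
    if centroid.fwhm_th and centroid.snr and centroid.snr > 0:
        return centroid.fwhm_th / (2.355 * centroid.snr)
    return default


def classify_trace(
    trace: IonTrace,
    bin_width_th: float,
    jump_sigma_factor: float = 3.0,
    integer_tolerance_floor: float = 0.05,
    z_max: int = 2000,
) -> str:
    """Classify a retained trace as stable / gradual_loss / charge_loss.

    Stable: total m/z excursion below one Fourier bin.  Charge loss: the
    largest between-segment upward jump matches mz_after/(mz_after-mz_before)
    = z for an integer z within the propagated centroid uncertainty (x3, with
    a floor).  Anything else drifting is gradual loss; significant upward
    jumps that match no integer charge are flagged ambiguous and rejected
    rather than guessed.
    """
    if trace.classification == "rejected":
        return "rejected"
    mz = trace.mz
    excursion = float(mz.max() - mz.min())
    if excursion < bin_width_th:
        trace.classification = "stable"
        return trace.classification
    jumps = np.diff(mz)
    j = int(np.argmax(jumps))
    sig = np.asarray([centroid_sigma_th(c) for c in trace.centroids])
    jump_sigma = math.hypot(sig[j], sig[j + 1])
    # a genuine charge-stripping jump towers over the trace's ordinary
    # step-to-step structure (noise or gradual drift)
    typical_step = float(np.median(np.abs(jumps)))
    if jumps[j] > max(jump_sigma_factor * jump_sigma, bin_width_th, 5.0 * typical_step):
        z, z_sigma = charge_from_pair(mz[j], mz[j + 1], sig[j], sig[j + 1])
        tol = max(jump_sigma_factor * z_sigma, integer_tolerance_floor)
        if 2 <= round(z) <= z_max and abs(z - round(z)) <= tol:
            trace.classification = "charge_loss"
            trace.flags.append(f"jump_segment:{trace.centroids[j + 1].segment_index}")
        else:
            trace.classification = "rejected"
            trace.flags.append("ambiguous_jump")
        return trace.classification
    trace.classification = "gradual_loss"
    if mz[-1] - mz[0] > bin_width_th:
        trace.flags.append("upward_drift")
    return trace.classification


@dataclass
class NeutralLossProfile:
    """Per-segment and cumulative neutral loss (Da) of one traced ion."""

    per_segment_da: np.ndarray
    cumulative_da: np.ndarray
    charge: int


def drift_to_loss(trace: IonTrace, charge: int | None = None) -> NeutralLossProfile:
    """Convert a trace's m/z drift into neutral losses in daltons.

    Per-segment loss_k = -z * (mz_k - mz_{k-1}) (a drop in m/z at fixed
    charge is mass shed); the cumulative profile is the exact running sum,
    i.e. the loss with respect to the first segment.
    """
    z = charge if charge is not None else trace.assigned_charge
    if z is None:
        raise ValueError("trace has no assigned charge; pass charge explicitly")
    mz = trace.mz
    per_segment = np.concatenate(([0.0], -z * np.diff(mz)))
    return NeutralLossProfile(
        per_segment_da=per_segment,
        cumulative_da=np.cumsum(per_segment),
        charge=int(z),
    )


@dataclass
class DecayFitResult:
    """Linear + exponential neutral-loss model loss_k = alpha + beta*exp(-k/tau)."""

    alpha: float
    beta: float
    tau: float
    r2: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def fit_decay_model(losses, k=None) -> DecayFitResult:
    """Nonlinear least squares of loss_k = alpha + beta * exp(-k / tau).

    ``alpha`` (constant loss per segment, collisions per travelled distance)
    and ``beta`` (injection-activation amplitude) are constrained >= 0.  When
    the decaying term is absent the fit degenerates and ``tau`` is flagged
    unidentifiable.  Non-convergence is flagged rather than raised.
    """
    y = np.asarray(losses, dtype=float)
    if k is None:
        k = np.arange(len(y), dtype=float)
    k = np.asarray(k, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 segments to fit the decay model")

    def model_fn(kk, a, b, tau):
        return a + b * np.exp(-kk / tau)

    tail = max(float(np.mean(y[len(y) // 2:])), 1e-9)
    b0 = max(float(y[0]) - tail, 1e-9)
    p0 = (tail, b0, max(len(y) / 5.0, 0.5))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model_fn,
                k,
                y,
                p0=p0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 1e6]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return DecayFitResult(math.nan, math.nan, math.nan, math.nan,
                              converged=False, flags=["no_convergence"])
    alpha, beta, tau = (float(v) for v in popt)
    resid = y - model_fn(k, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    flags = []
    scale = max(abs(y).max(), 1e-12)
    if beta < 1e-3 * scale or tau > 100 * len(y):
        flags.append("tau_unidentifiable")
    return DecayFitResult(alpha, beta, tau, r2, flags=flags)


def charge_from_pair(
    mz_before: float,
    mz_after: float,
    sigma_before: float = 0.0,
    sigma_after: float = 0.0,
) -> tuple[float, float]:
    """Charge before a single charge-loss event from the m/z doublet.

    z = mz_after / (mz_after - mz_before); the uncertainty is propagated
    from the two centroid uncertainties.
    """
    if mz_after <= mz_before:
        raise ValueError("mz_after must exceed mz_before")
    delta = mz_after - mz_before
    z = mz_after / delta
    dz_dbefore = mz_after / delta**2
    dz_dafter = -mz_before / delta**2
    z_sigma = math.hypot(dz_dbefore * sigma_before, dz_dafter * sigma_after)
    return float(z), float(z_sigma)


@dataclass
class ChargeLossEvent:
    """A resolved single-charge-stripping doublet."""

    mz_before: float
    mz_after: float
    z_estimate: float
    z_uncertainty: float
    mass_estimate: float
    mass_uncertainty: float
    event_segment: int
    mz_before_sigma: float = 0.0
    mz_after_sigma: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mz_after <= self.mz_before:
            raise ValueError("mz_after must exceed mz_before")
        if self.z_estimate <= 1:
            raise ValueError("z_estimate must exceed 1")


def mass_from_pair(
    event: ChargeLossEvent,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    subtract_proton: bool = True,
    integer_warn_tolerance: float = 0.25,
) -> tuple[float, float]:
    """Direct mass from a charge-loss doublet: round(z) x (mz_before - m_p).

    The proton subtraction (negligible at megadalton scale) can be disabled.
    A z estimate further than ``integer_warn_tolerance`` from an integer is
    recorded as a warning flag on the event.
    """
    z_int = round(event.z_estimate)
    if abs(event.z_estimate - z_int) > integer_warn_tolerance:
        event.flags.append("z_not_integer")
        warnings.warn(
            f"z estimate {event.z_estimate:.3f} is {abs(event.z_estimate - z_int):.3f} "
            "from the nearest integer",
            stacklevel=2,
        )
    mass = z_int * (event.mz_before - (model.proton_mass_da if subtract_proton else 0.0))
    sigma = z_int * event.mz_before_sigma
    return float(mass), float(sigma)


def extract_charge_loss_event(
    trace: IonTrace,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    subtract_proton: bool = True,
) -> ChargeLossEvent | None:
    """Locate the largest upward jump in a trace and build a charge-loss event.

    The before/after m/z values are averaged over the segments on either
    side, excluding the two segments adjacent to the jump (whose overlapping
    windows straddle the event), which sharpens the doublet positions well
    beyond single-segment precision.
    """
    mz = trace.mz
    if len(mz) < 4:
        return None
    jumps = np.diff(mz)
    j = int(np.argmax(jumps))
    if jumps[j] <= 0:
        return None
    before = mz[: max(j, 1)]
    after = mz[min(j + 2, len(mz) - 1):]
    if len(after) == 0:
        after = mz[j + 1:]
    mzb, mza = float(np.mean(before)), float(np.mean(after))
    if mza <= mzb:
        return None

    def sem(vals, fallback_idx):
        if len(vals) > 1:
            return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        return centroid_sigma_th(trace.centroids[fallback_idx])

    sb, sa = sem(before, j), sem(after, min(j + 1, len(trace.centroids) - 1))
    z, z_sigma = charge_from_pair(mzb, mza, sb, sa)
    event = ChargeLossEvent(
        mz_before=mzb,
        mz_after=mza,
        z_estimate=z,
        z_uncertainty=z_sigma,
        mass_estimate=math.nan,
        mass_uncertainty=math.nan,
        event_segment=int(trace.centroids[j + 1].segment_index),
        mz_before_sigma=sb,
        mz_after_sigma=sa,
    )
    mass, mass_sigma = mass_from_pair(event, model, subtract_proton=subtract_proton)
    event.mass_estimate = mass
    event.mass_uncertainty = mass_sigma
    return event


@dataclass
class SidebandReport:
    """Mirrored radial-modulation sidebands around an axial peak."""

    main_mz: float
    found: bool
    upper_offset_hz: float | None = None
    lower_offset_hz: float | None = None
    upper_snr: float | None = None
    lower_snr: float | None = None
    mirror_symmetry_score: float = math.nan
    symmetric: bool = False


def detect_radial_sidebands(
    spectrum: Spectrum,
    main_centroid: Centroid,
    search_width_hz: float,
    min_offset_hz: float | None = None,
    snr_threshold: float = 5.0,
    model: InstrumentModel = DEFAULT_INSTRUMENT,
    symmetry_tolerance_bins: float = 2.0,
) -> SidebandReport:
    """Locate the strongest symmetric peak pair around the main axial peak.

    Amplitude modulation by a radial frequency places sidebands at +- that
    frequency around the axial peak; because both arise from the same radial
    oscillation their spectral profiles are mirror images of each other.
    ``mirror_symmetry_score`` is the correlation between the lower-sideband
    profile and the frequency-reversed upper-sideband profile.  When no
    sideband rises above the noise an empty report (found=False) is returned.
    """
    f0 = main_centroid.frequency_hz
    if min_offset_hz is None:
        min_offset_hz = 8.0 * spectrum.natural_bin_hz
    if search_width_hz <= min_offset_hz:
        raise ValueError("search_width_hz must exceed the minimum offset")
    df = spectrum.bin_spacing_hz
    mag = spectrum.magnitude
    sigma = estimate_noise_sigma(spectrum, model=model)
    i0 = spectrum.freq_index(f0)

    def band(lo_hz, hi_hz):
        lo = max(int(math.ceil(lo_hz / df)), 1)
        hi = min(int(hi_hz / df), len(mag) - 2)
        if hi <= lo:
            return None
        rel = int(np.argmax(mag[lo: hi + 1]))
        return lo + rel

    up = band(f0 + min_offset_hz, f0 + search_width_hz)
    lo = band(f0 - search_width_hz, f0 - min_offset_hz)
    report = SidebandReport(main_mz=main_centroid.mz, found=False)
    if up is None or lo is None:
        return report
    up_snr = mag[up] / sigma if sigma > 0 else math.inf
    lo_snr = mag[lo] / sigma if sigma > 0 else math.inf
    if up_snr < snr_threshold or lo_snr < snr_threshold:
        return report
    # reject candidates explainable by the axial peak's own sidelobe
    # envelope (~height / (pi x offset in natural bins))
    pad = spectrum.zero_pad_factor
    for idx in (up, lo):
        offset_bins = abs(idx - i0) / pad
        if mag[idx] < 2.0 * main_centroid.intensity / (math.pi * max(offset_bins, 1.0)):
            return report
    report.found = True
    report.upper_offset_hz = float(up * df - f0)
    report.lower_offset_hz = float(f0 - lo * df)
    report.upper_snr = float(up_snr)
    report.lower_snr = float(lo_snr)
    report.symmetric = (
        abs(report.upper_offset_hz - report.lower_offset_hz)
        <= symmetry_tolerance_bins * spectrum.natural_bin_hz
    )
    # mirror profiles about the main peak at the mean offset
    mean_off_bins = int(round(0.5 * (up - i0) + 0.5 * (i0 - lo)))
    half = max(int(round(4 * spectrum.natural_bin_hz / df)), 4)
    ui, li = i0 + mean_off_bins, i0 - mean_off_bins
    if li - half < 0 or ui + half >= len(mag):
        return report
    upper = mag[ui - half: ui + half + 1]
    lower = mag[li - half: li + half + 1]
    if np.std(upper) == 0 or np.std(lower) == 0:
        return report
    score = float(np.corrcoef(lower, upper[::-1])[0, 1])
    report.mirror_symmetry_score = score
    return report
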