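"""Shared fixtures: simulated ensembles reused across test modules.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive ensembles to a single simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

import orbichase as oc
from orbichase.chase import (
    classify_trace,
    filter_traces,
    full_bin_width_th,
    isolate_candidates,
    plan_segments,
    segmented_centroids,
    trace_ions,
)

REFERENCE_MZ = 21343.1  # working-example m/z of a ~3 MDa ion
REFERENCE_Z = 144


@pytest.fixture(scope="session")
def model():
    return oc.DEFAULT_INSTRUMENT


def make_drift_loss(drift_hz: float, charge: int, mz: float, duration_s: float = 1.0,
                    stochastic: bool = False) -> oc.LossProcess:
    """Deterministic loss process producing a given total frequency drift."""
    f = oc.mz_to_freq(mz)
    dmz = drift_hz * 2.0 * mz / f
    total_da = charge * dmz
    speed_km_s = f * oc.DEFAULT_INSTRUMENT.dist_per_osc_mm * 1e-6
    return oc.LossProcess(
        linear_rate_per_km=total_da / 18.010565 / (speed_km_s * duration_s),
        loss_mass_mean_da=18.010565,
        loss_mass_sd_da=0.0,
        stochastic=stochastic,
    )


def chase_transient(transient, mz_range=None, snr_threshold=10.0, **filter_kwargs):
    """Standard chase pipeline: segment, isolate, trace, filter, classify."""
    plan = plan_segments(transient.duration_s)
    segs = segmented_centroids(transient, plan, snr_threshold=snr_threshold, mz_range=mz_range)
    segs = [isolate_candidates(s) for s in segs]
    traces = trace_ions(segs)
    retained = filter_traces(traces, **filter_kwargs)
    for tr in retained:
        mz0 = float(np.median(tr.mz))
        classify_trace(tr, full_bin_width_th(mz0, transient.duration_s))
    # classification can reject ambiguous jumps on top of the std filter
    retained = [tr for tr in retained if tr.classification != "rejected"]
    return traces, retained


@pytest.fixture(scope="session")
def charge_loss_ensemble():
    """40 single-ion transients, each with one charge-stripping event."""
    rng = np.random.default_rng(42)
    transients = []
    for _ in range(40):
        z = int(rng.integers(120, 180))
        mz = rng.uniform(18000.0, 24000.0)
        ion = oc.IonSpec(
            mass_da=mz * z,
            charge=z,
            phase0_rad=rng.uniform(0, 2 * np.pi),
            charge_loss_time_s=rng.uniform(0.25, 0.75),
        )
        tr = oc.simulate_transient(
            [ion], noise_sigma=3.0, duration_s=1.0, seed=int(rng.integers(2**31 - 1))
        )
        transients.append((tr, z, mz))
    return transients


@pytest.fixture(scope="session")
def traced_population():
    """200 multi-ion transients with truth records, chased end to end."""
    loss = oc.segment_loss_preset(692.0)
    transients = oc.simulate_population(
        600,
        loss=loss,
        stable_fraction=0.7,
        charge_loss_prob=0.03,
        mean_ions_per_transient=3.0,
        noise_sigma=3.0,
        seed=2024,
    )[:200]
    results = []
    for tr in transients:
        traces, retained = chase_transient(tr, mz_range=(15000.0, 32000.0))
        results.append((tr, retained))
    return results


@pytest.fixture(scope="session")
def drift_mixture():
    """40 isolated-ion transients: 36 drifting ~8 natural bins, 4 stable."""
    rng = np.random.default_rng(7)
    out = []
    for i in range(40):
        z = int(rng.integers(130, 170))
        mz = rng.uniform(19000.0, 24000.0)
        drifting = i % 10 != 0
        ion = oc.IonSpec(
            mass_da=mz * z,
            charge=z,
            phase0_rad=rng.uniform(0, 2 * np.pi),
            loss=make_drift_loss(8.0, z, mz) if drifting else None,
        )
        tr = oc.simulate_transient(
            [ion], noise_sigma=3.0, duration_s=1.0, seed=int(rng.integers(2**31 - 1))
        )
        out.append((tr, z, mz, drifting))
    return out
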