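"""Segmentation, tracing, classification, drift-to-loss and decay fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orbichase as oc
from orbichase.chase import (
    IonTrace,
    centroid_sigma_th,
    charge_from_pair,
    classify_trace,
    detect_radial_sidebands,
    drift_to_loss,
    extract_charge_loss_event,
    filter_traces,
    fit_decay_model,
    full_bin_width_th,
    isolate_candidates,
    mass_from_pair,
    plan_segments,
    segmented_centroids,
    trace_ions,
)
from orbichase.spectral import Centroid, compute_spectrum, strongest_centroid

from conftest import REFERENCE_MZ, REFERENCE_Z, chase_transient, make_drift_loss


def synthetic_trace(mz_values, intensities=None, n_segments=None, fwhm_th=5.0, snr=100.0):
    intensities = intensities if intensities is not None else [0.8] * len(mz_values)
    cents = [
        Centroid(mz=m, frequency_hz=oc.mz_to_freq(m), intensity=i,
                 fwhm_th=fwhm_th, snr=snr, segment_index=k)
        for k, (m, i) in enumerate(zip(mz_values, intensities))
    ]
    return IonTrace(cents, n_segments=n_segments or len(cents))


class TestPlanSegments:
    def test_fifteen_segments_half_overlap(self):
        plan = plan_segments(1.0, 15, 0.5)
        assert plan.window_length_s == pytest.approx(0.125)
        assert plan.starts_s[0] == 0.0
        assert plan.starts_s[-1] + plan.window_length_s == pytest.approx(1.0)

    def test_zero_overlap_is_contiguous(self):
        plan = plan_segments(1.0, 10, 0.0)
        assert plan.window_length_s == pytest.approx(0.1)
        assert np.allclose(np.diff(plan.starts_s), 0.1)

    def test_windows_cover_duration(self):
        for n, ov in [(2, 0.0), (15, 0.5), (7, 0.3), (30, 0.9)]:
            plan = plan_segments(2.5, n, ov)
            assert plan.starts_s[0] == 0.0
            assert plan.starts_s[-1] + plan.window_length_s == pytest.approx(2.5)
            assert np.all(np.diff(plan.starts_s) > 0)

    def test_invalid_combinations(self):
        with pytest.raises(ValueError):
            plan_segments(1.0, 1)
        with pytest.raises(ValueError):
            plan_segments(1.0, 10, 1.0)
        with pytest.raises(ValueError):
            plan_segments(0.0, 10)


class TestSegmentedCentroids:
    def test_stable_ion_gives_full_trace(self):
        ion = oc.IonSpec(mass_da=REFERENCE_MZ * REFERENCE_Z, charge=REFERENCE_Z)
        tr = oc.simulate_transient([ion], noise_sigma=1.0, duration_s=1.0, seed=21)
        segs = segmented_centroids(tr, mz_range=(21000.0, 21700.0))
        assert [len(s) for s in segs] == [1] * 15
        mzs = [s[0].mz for s in segs]
        # all centroids within a fraction of a segment-level bin of each other
        seg_bin_th = full_bin_width_th(REFERENCE_MZ, 0.125)
        assert max(mzs) - min(mzs) < seg_bin_th
        # per-segment intensity of a stable ion constant within 5%
        ints = [s[0].intensity for s in segs]
        assert max(ints) / min(ints) < 1.05
        assert np.mean(ints) == pytest.approx(REFERENCE_Z / 175, rel=0.02)

    def test_ion_absent_after_half(self):
        ion = oc.IonSpec(mass_da=REFERENCE_MZ * REFERENCE_Z, charge=REFERENCE_Z,
                         end_time_s=0.5)
        tr = oc.simulate_transient([ion], noise_sigma=1.0, duration_s=1.0, seed=22)
        plan = plan_segments(1.0)
        segs = segmented_centroids(tr, plan, mz_range=(21000.0, 21700.0))
        for k, (start, cents) in enumerate(zip(plan.starts_s, segs)):
            if start >= 0.5:
                assert cents == []
            elif start + plan.window_length_s <= 0.5:
                assert len(cents) == 1


class TestIsolation:
    def test_close_pair_both_removed(self):
        a = Centroid(mz=21000.0, frequency_hz=1.0, intensity=1.0, fwhm_th=10.0)
        b = Centroid(mz=21003.0, frequency_hz=1.0, intensity=1.0, fwhm_th=10.0)
        assert isolate_candidates([a, b]) == []

    def test_lone_and_distant_ions_retained(self):
        a = Centroid(mz=21000.0, frequency_hz=1.0, intensity=1.0, fwhm_th=10.0)
        b = Centroid(mz=21100.0, frequency_hz=1.0, intensity=1.0, fwhm_th=10.0)
        assert isolate_candidates([a]) == [a]
        assert isolate_candidates([a, b]) == [a, b]

    def test_explicit_separation(self):
        a = Centroid(mz=21000.0, frequency_hz=1.0, intensity=1.0)
        b = Centroid(mz=21030.0, frequency_hz=1.0, intensity=1.0)
        assert isolate_candidates([a, b], min_separation_th=50.0) == []
        assert isolate_candidates([a, b], min_separation_th=10.0) == [a, b]


class TestTracing:
    def test_single_stable_ion_full_length(self):
        segs = [[Centroid(mz=21343.0, frequency_hz=1.0, intensity=0.8, segment_index=k)]
                for k in range(15)]
        traces = trace_ions(segs)
        assert len(traces) == 1
        assert len(traces[0]) == 15

    def test_drifting_ion_chained(self):
        # -1.5 Th over 15 segments
        segs = [[Centroid(mz=21343.0 - 0.1 * k, frequency_hz=1.0, intensity=0.8,
                          segment_index=k)]
                for k in range(15)]
        traces = trace_ions(segs)
        assert len(traces) == 1
        assert traces[0].mz[-1] == pytest.approx(21343.0 - 1.4)

    def test_two_distant_ions_disjoint(self):
        segs = [
            [
                Centroid(mz=21000.0, frequency_hz=1.0, intensity=0.8, segment_index=k),
                Centroid(mz=21100.0, frequency_hz=1.0, intensity=0.9, segment_index=k),
            ]
            for k in range(15)
        ]
        traces = trace_ions(segs)
        assert len(traces) == 2
        for tr in traces:
            assert tr.mz_std < 1e-9

    def test_short_traces_discarded(self):
        segs = [[Centroid(mz=21343.0, frequency_hz=1.0, intensity=0.8, segment_index=k)]
                if k < 5 else []
                for k in range(15)]
        assert trace_ions(segs) == []

    def test_gap_bridging(self):
        segs = [[] if k == 7 else
                [Centroid(mz=21343.0, frequency_hz=1.0, intensity=0.8, segment_index=k)]
                for k in range(15)]
        traces = trace_ions(segs)
        assert len(traces) == 1
        assert len(traces[0]) == 14


class TestFilterTraces:
    def test_clean_trace_retained(self):
        tr = synthetic_trace([21343.0] * 15)
        assert filter_traces([tr]) == [tr]
        assert tr.classification is None

    def test_mz_scatter_rejected(self):
        rng = np.random.default_rng(0)
        mz = 21343.0 + rng.normal(0, 6.0, 15)
        tr = synthetic_trace(list(mz))
        assert tr.mz_std > 4.0
        assert filter_traces([tr]) == []
        assert tr.classification == "rejected"

    def test_intensity_scatter_rejected(self):
        rng = np.random.default_rng(1)
        tr = synthetic_trace([21343.0] * 15, list(0.8 + rng.normal(0, 0.4, 15)))
        assert tr.intensity_std > 0.2
        assert filter_traces([tr]) == []
        assert "intensity_std" in tr.flags


class TestClassification:
    def test_zero_drift_is_stable(self):
        tr = synthetic_trace([21343.0] * 15)
        bw = full_bin_width_th(21343.0, 1.0)
        assert classify_trace(tr, bw) == "stable"

    def test_gradual_downward_drift(self):
        bw = full_bin_width_th(21343.0, 1.0)
        mz = 21343.0 - np.linspace(0.0, 3.0 * bw, 15)
        tr = synthetic_trace(list(mz))
        assert classify_trace(tr, bw) == "gradual_loss"

    def test_charge_loss_jump(self):
        # constructed z=144 jump: x2 = x1 * 144/143
        x1 = REFERENCE_MZ
        x2 = x1 * 144.0 / 143.0
        mz = [x1] * 7 + [x2] * 8
        tr = synthetic_trace(mz)
        bw = full_bin_width_th(x1, 1.0)
        assert classify_trace(tr, bw) == "charge_loss"

    def test_non_integer_jump_flagged_not_guessed(self):
        x1 = REFERENCE_MZ
        mz = [x1] * 7 + [x1 + 60.0] * 8  # z would be ~357.7, far from integer
        tr = synthetic_trace(mz, fwhm_th=5.0, snr=1000.0)
        bw = full_bin_width_th(x1, 1.0)
        assert classify_trace(tr, bw) == "rejected"
        assert "ambiguous_jump" in tr.flags


class TestDriftToLoss:
    def test_zero_drift_zero_loss(self):
        tr = synthetic_trace([21343.0] * 15)
        profile = drift_to_loss(tr, 144)
        assert np.all(profile.per_segment_da == 0.0)
        assert np.all(profile.cumulative_da == 0.0)

    def test_known_drift_conversion(self):
        tr = synthetic_trace([100.0, 100.0 - 1.57])
        profile = drift_to_loss(tr, 100)
        assert profile.per_segment_da[1] == pytest.approx(157.0)
        assert profile.cumulative_da[-1] == pytest.approx(157.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-0.5, max_value=0.5), min_size=2, max_size=20))
    def test_cumulative_is_exact_running_sum(self, steps):
        mz = 21343.0 + np.cumsum([0.0] + steps)[: len(steps) + 1]
        tr = synthetic_trace(list(mz))
        profile = drift_to_loss(tr, 144)
        assert np.allclose(profile.cumulative_da, np.cumsum(profile.per_segment_da))
        # conservation: cumulative equals first-vs-last m/z difference x charge
        assert profile.cumulative_da[-1] == pytest.approx(
            -144 * (mz[-1] - mz[0]), abs=1e-9
        )

    def test_missing_charge_raises(self):
        tr = synthetic_trace([21343.0] * 15)
        with pytest.raises(ValueError):
            drift_to_loss(tr)


class TestDecayModel:
    def test_pure_linear_degenerate(self):
        fit = fit_decay_model(np.full(15, 25.0))
        assert fit.alpha == pytest.approx(25.0, rel=0.02)
        assert "tau_unidentifiable" in fit.flags

    def test_parameter_recovery_at_dataset_scale(self):
        # 2,000 ions with (alpha=25, beta=120, tau=3)
        loss = oc.LossProcess.from_segment_model(25.0, 120.0, 3.0, 1 / 15)
        table = oc.simulate_segment_losses(loss, 15, 2000, seed=17)
        fit = fit_decay_model(table.mean(axis=0))
        assert fit.alpha == pytest.approx(25.0, rel=0.1)
        assert fit.beta == pytest.approx(120.0, rel=0.1)
        assert fit.tau == pytest.approx(3.0, rel=0.25)
        assert fit.r2 >= 0.998

    def test_asymptote_is_alpha(self):
        k = np.arange(15, dtype=float)
        fit = fit_decay_model(25.0 + 120.0 * np.exp(-k / 3.0))
        assert fit.alpha + fit.beta * math.exp(-1e6 / fit.tau) == pytest.approx(
            fit.alpha
        )
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_too_few_segments(self):
        with pytest.raises(ValueError):
            fit_decay_model([1.0, 2.0, 3.0])


class TestChargeFromPair:
    def test_exact_construction(self):
        z, sigma = charge_from_pair(99.0, 100.0)
        assert z == pytest.approx(100.0)
        assert sigma == 0.0

    def test_reference_doublet(self):
        z, _ = charge_from_pair(21343.1, 21492.35)
        assert z == pytest.approx(144.0, abs=0.05)

    def test_uncertainty_scales_with_centroid_uncertainty(self):
        _, s1 = charge_from_pair(21343.1, 21492.35, 0.2, 0.2)
        _, s2 = charge_from_pair(21343.1, 21492.35, 0.4, 0.4)
        assert s2 == pytest.approx(2 * s1)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            charge_from_pair(100.0, 99.0)


class TestMassFromPair:
    def test_trivial_pair_without_proton_subtraction(self):
        ev = oc.ChargeLossEvent(
            mz_before=99.0, mz_after=100.0, z_estimate=100.0, z_uncertainty=0.0,
            mass_estimate=0.0, mass_uncertainty=0.0, event_segment=5,
        )
        mass, _ = mass_from_pair(ev, subtract_proton=False)
        assert mass == pytest.approx(9900.0)

    def test_reference_ion_with_proton_subtraction(self):
        ev = oc.ChargeLossEvent(
            mz_before=21343.1, mz_after=21492.35, z_estimate=144.0, z_uncertainty=0.0,
            mass_estimate=0.0, mass_uncertainty=0.0, event_segment=5,
            mz_before_sigma=0.2,
        )
        mass, sigma = mass_from_pair(ev, subtract_proton=True)
        assert mass == pytest.approx(144 * (21343.1 - 1.00728))
        assert mass == pytest.approx(3_073_261.0, abs=1.0)
        assert sigma == pytest.approx(144 * 0.2)

    def test_non_integer_charge_warns(self):
        ev = oc.ChargeLossEvent(
            mz_before=99.0, mz_after=100.0, z_estimate=100.4, z_uncertainty=0.0,
            mass_estimate=0.0, mass_uncertainty=0.0, event_segment=5,
        )
        with pytest.warns(UserWarning):
            mass_from_pair(ev)
        assert "z_not_integer" in ev.flags


class TestChargeLossRecovery:
    def test_traced_doublet_charge_and_mass(self):
        z = REFERENCE_Z
        ion = oc.IonSpec(mass_da=z * REFERENCE_MZ, charge=z, charge_loss_time_s=0.5)
        tr = oc.simulate_transient([ion], noise_sigma=3.0, duration_s=1.0, seed=3)
        _, retained = chase_transient(tr, mz_range=(20500.0, 22500.0), mz_std_max=200.0)
        assert len(retained) == 1
        assert retained[0].classification == "charge_loss"
        ev = extract_charge_loss_event(retained[0])
        assert ev.z_estimate == pytest.approx(z, abs=0.2)
        assert ev.mass_estimate == pytest.approx(z * (REFERENCE_MZ - 1.00728), rel=1e-4)

    def test_near_integer_charge_in_95_percent_of_events(self, charge_loss_ensemble):
        hits = total = 0
        for tr, z_true, _mz in charge_loss_ensemble:
            _, retained = chase_transient(tr, mz_range=(16000.0, 27000.0),
                                          mz_std_max=300.0)
            doublets = [t for t in retained if t.classification == "charge_loss"]
            if not doublets:
                continue
            ev = extract_charge_loss_event(doublets[0])
            total += 1
            if abs(ev.z_estimate - z_true) < 0.2:
                hits += 1
        assert total >= 0.9 * len(charge_loss_ensemble)
        assert hits / total >= 0.95


class TestSidebands:
    def _am_spectrum(self, depth, seed=30, radial_freq=400.0):
        ion = oc.IonSpec(
            mass_da=REFERENCE_MZ * REFERENCE_Z, charge=REFERENCE_Z,
            radial_freq_hz=radial_freq if depth > 0 else None, radial_depth=depth,
        )
        tr = oc.simulate_transient([ion], noise_sigma=0.5, duration_s=1.0, seed=seed)
        spec = compute_spectrum(tr)
        main = strongest_centroid(spec, mz_range=(21000.0, 21700.0))
        return spec, main

    def test_sidebands_located_at_radial_frequency(self):
        spec, main = self._am_spectrum(0.1)
        rep = detect_radial_sidebands(spec, main, search_width_hz=1000.0)
        assert rep.found
        assert rep.upper_offset_hz == pytest.approx(400.0, abs=spec.natural_bin_hz)
        assert rep.lower_offset_hz == pytest.approx(400.0, abs=spec.natural_bin_hz)
        assert rep.symmetric

    def test_stable_modulation_mirror_score(self):
        spec, main = self._am_spectrum(0.1)
        rep = detect_radial_sidebands(spec, main, search_width_hz=1000.0)
        assert rep.mirror_symmetry_score >= 0.9

    def test_no_modulation_no_sidebands(self):
        spec, main = self._am_spectrum(0.0)
        rep = detect_radial_sidebands(spec, main, search_width_hz=1000.0)
        assert not rep.found


class TestCrossingPair:
    def test_no_trace_mixes_two_true_ions(self):
        # ion B starts above ion A and drifts down through A's m/z
        z = 150
        mz_a = 21300.0
        mz_b = 21320.0
        loss = make_drift_loss(55.0, z, mz_b)  # ~40 Th downward drift
        ions = [
            oc.IonSpec(mass_da=mz_a * z, charge=z),
            oc.IonSpec(mass_da=mz_b * z, charge=z, loss=loss, phase0_rad=1.5),
        ]
        tr = oc.simulate_transient(ions, noise_sigma=3.0, duration_s=1.0, seed=33)
        _, retained = chase_transient(tr, mz_range=(21000.0, 21600.0), mz_std_max=50.0)
        # path oracle straight from the generating truth
        speed = oc.mz_to_freq(mz_b) * oc.DEFAULT_INSTRUMENT.dist_per_osc_mm * 1e-6
        rate_da_s = loss.linear_rate_per_km * speed * loss.loss_mass_mean_da

        def true_b(t):
            return (mz_b * z - rate_da_s * t) / z

        plan = plan_segments(1.0)
        centers = plan.starts_s + plan.window_length_s / 2
        for trace in retained:
            owners = set()
            for c in trace.centroids:
                t = centers[c.segment_index]
                d_a = abs(c.mz - mz_a)
                d_b = abs(c.mz - true_b(t))
                owners.add("a" if d_a < d_b else "b")
            assert len(owners) == 1


class TestTracingCorrectness:
    @staticmethod
    def _owner_positions(transient):
        """Candidate (owner, mz) pairs: each ion's initial and, after a
        charge-stripping event, final m/z position."""
        positions = []
        for i, ion in enumerate(transient.truth):
            positions.append((i, ion["mz"]))
            if ion["charge_loss_time_s"] is not None:
                positions.append((i, ion["final_mz"]))
        return positions

    @staticmethod
    def _merge_unresolvable(owners, transient, separation_th=25.0):
        """Ions closer than the segment resolving power form one spectral
        object; collapse such owner pairs before counting mixing."""
        mzs = [transient.truth[i]["mz"] for i in owners]
        merged = []
        for i, m in sorted(zip(owners, mzs), key=lambda p: p[1]):
            if merged and abs(m - merged[-1][1]) < separation_th:
                continue
            merged.append((i, m))
        return {i for i, _ in merged}

    def test_retained_traces_map_one_to_one_to_true_ions(self, traced_population):
        """>=95% of retained traces correspond to exactly one true ion and
        no retained trace mixes centroids from two resolvable true ions."""
        pure = mixed = 0
        for transient, retained in traced_population:
            positions = self._owner_positions(transient)
            pos_mz = np.array([p[1] for p in positions])
            for trace in retained:
                owners = set()
                ok = True
                for c in trace.centroids:
                    d = np.abs(pos_mz - c.mz)
                    i = int(np.argmin(d))
                    if d[i] > 20.0:
                        ok = False
                        break
                    owners.add(positions[i][0])
                owners = self._merge_unresolvable(owners, transient)
                if not ok or len(owners) != 1:
                    mixed += 1
                else:
                    pure += 1
        assert pure + mixed > 100  # the ensemble must actually produce traces
        assert mixed == 0
        assert pure / (pure + mixed) >= 0.95

    def test_no_two_retained_traces_share_one_ion(self, traced_population):
        for transient, retained in traced_population:
            true_mz = np.array([ion["mz"] for ion in transient.truth])
            owners = []
            for trace in retained:
                d = np.abs(true_mz - float(np.median(trace.mz)))
                if d.min() <= 20.0:
                    owners.append(int(np.argmin(d)))
            assert len(owners) == len(set(owners))

    def test_stable_ions_rarely_misclassified(self, traced_population):
        """Noise alone should not push a stable ion past the one-bin margin."""
        stable_ok = stable_total = 0
        for transient, retained in traced_population:
            truth_by_mz = {ion["mz"]: ion for ion in transient.truth}
            true_mz = np.array(list(truth_by_mz))
            for trace in retained:
                d = np.abs(true_mz - float(np.median(trace.mz)))
                if d.min() > 20.0:
                    continue
                ion = truth_by_mz[float(true_mz[np.argmin(d)])]
                drifting = ion["loss_events"] or ion["charge_loss_time_s"]
                if not drifting:
                    stable_total += 1
                    bw = full_bin_width_th(ion["mz"], transient.duration_s)
                    excursion = trace.mz.max() - trace.mz.min()
                    if trace.classification == "stable" or excursion >= bw:
                        stable_ok += 1
        assert stable_total > 50
        assert stable_ok / stable_total >= 0.95
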