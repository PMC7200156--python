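"""TIRF trace analysis: segmentation, kinetics, and pathway classification."""

import math

import numpy as np
import pytest

from smexchange.burst import fit_fret_histogram
from smexchange.synthetic import FretTrace, TraceSimConfig, simulate_binding_times, simulate_trace
from smexchange.traces import (
    TraceCategory,
    TraceClass,
    alive_span,
    classification_summary,
    classify_trace,
    compute_trace_fret,
    filter_traces,
    find_binding_time,
    fit_association_constant,
    fit_dwell_rate,
    segment_states,
)

THREE_LEVELS = [0.2, 0.6, 0.8]


def make_trace(donor, acceptor, dt=0.1, injection=None):
    n = len(donor)
    return FretTrace(
        time=np.arange(n) * dt,
        donor=np.asarray(donor, dtype=float),
        acceptor=np.asarray(acceptor, dtype=float),
        frame_interval=dt,
        injection_time=injection,
    )


def seg_from_e(e, dt=0.1, **kw):
    kw.setdefault("min_dwell_frames", 3)
    return segment_states(np.asarray(e, dtype=float), THREE_LEVELS, frame_interval=dt, **kw)


class TestComputeTraceFret:
    def test_equal_channels_give_half(self):
        tr = make_trace(np.full(50, 500.0), np.full(50, 500.0))
        assert np.allclose(compute_trace_fret(tr), 0.5)

    def test_four_to_one_gives_point_eight(self):
        tr = make_trace(np.full(50, 200.0), np.full(50, 800.0))
        assert np.allclose(compute_trace_fret(tr), 0.8)

    def test_below_floor_is_nan_not_spurious(self):
        donor = np.concatenate([np.full(50, 500.0), np.full(50, 5.0)])
        acceptor = np.concatenate([np.full(50, 500.0), np.full(50, 5.0)])
        e = compute_trace_fret(make_trace(donor, acceptor))
        assert np.all(np.isfinite(e[:50]))
        assert np.all(np.isnan(e[50:]))

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_trace_fret(make_trace(np.zeros(10), np.zeros(10)))

    def test_simulated_state_mean(self):
        cfg = TraceSimConfig(
            states=[("MID", 0.62, 0.05)],
            rate_matrix=np.zeros((1, 1)),
            duration=300.0,
            seed=4,
        )
        e = compute_trace_fret(simulate_trace(cfg))
        assert np.nanmean(e) == pytest.approx(0.62, abs=0.01)


class TestFilterTraces:
    def _trace_alive_until(self, t_end, duration=300.0, dt=0.1):
        n = int(duration / dt)
        alive = (np.arange(n) * dt) < t_end
        donor = np.where(alive, 500.0, 1.0)
        acceptor = np.where(alive, 500.0, 1.0)
        return make_trace(donor, acceptor, dt)

    def test_early_bleach_excluded_long_trace_kept(self):
        early = self._trace_alive_until(60.0)
        full = self._trace_alive_until(300.0)
        kept = filter_traces([early, full], min_duration=210.0)
        assert kept == [full]

    def test_alive_span_measures_unbleached_extent(self):
        tr = self._trace_alive_until(120.0)
        assert alive_span(tr) == pytest.approx(120.0, abs=0.2)

    def test_survival_fraction_under_bleaching(self):
        """Retained fraction ~ exp(-k_b * 210 s) for exponential bleaching."""
        k_b = 5e-3
        root = np.random.default_rng(8)
        traces = [
            simulate_trace(
                TraceSimConfig(
                    states=[("MID", 0.6, 0.03)],
                    rate_matrix=np.zeros((1, 1)),
                    duration=300.0,
                    donor_bleach_rate=k_b,
                    noise_sd=5.0,
                    seed=int(root.integers(2**31)),
                )
            )
            for _ in range(400)
        ]
        kept = filter_traces(traces, min_duration=210.0, background_floor=200.0)
        expected = math.exp(-k_b * 210.0)
        se = math.sqrt(expected * (1 - expected) / 400)
        assert len(kept) / 400 == pytest.approx(expected, abs=4 * se)


class TestSegmentStates:
    def test_noiseless_step_boundary(self):
        e = np.concatenate([np.full(100, 0.6), np.full(100, 0.8)])
        seg = seg_from_e(e)
        assert [d.state for d in seg.dwells] == [1, 2]
        assert seg.dwells[1].t_start == pytest.approx(10.0)

    def test_noisy_constant_is_single_dwell(self, rng):
        e = rng.normal(0.6, 0.05, 1000)
        seg = seg_from_e(e, half_width=0.12)
        assert [d.state for d in seg.dwells] == [1]
        assert seg.dwells[0].duration == pytest.approx(100.0)

    def test_three_state_path_matches_truth(self):
        cfg = TraceSimConfig(
            states=[("LOW", 0.2, 0.04), ("MID", 0.6, 0.04), ("HIGH", 0.8, 0.04)],
            rate_matrix=np.array([[0, 0, 0.02], [0.02, 0, 0], [0, 0, 0]]),
            duration=300.0,
            initial_state=1,
            noise_sd=10.0,
            seed=21,
        )
        tr = simulate_trace(cfg)
        seg = seg_from_e(compute_trace_fret(tr))
        # segmentation agrees with the hidden path on nearly all frames
        agreement = np.mean(seg.labels == tr.truth["frame_state"])
        assert agreement > 0.98

    def test_short_runs_merged(self):
        e = np.concatenate([np.full(50, 0.6), np.full(2, 0.8), np.full(50, 0.6)])
        seg = seg_from_e(e, min_dwell_frames=3)
        assert [d.state for d in seg.dwells] == [1]

    def test_intensity_rescaling_invariance(self, rng):
        donor = rng.normal(400, 20, 500).clip(1)
        acceptor = rng.normal(600, 20, 500).clip(1)
        e1 = compute_trace_fret(make_trace(donor, acceptor))
        e2 = compute_trace_fret(make_trace(donor * 3.7, acceptor * 3.7))
        s1, s2 = seg_from_e(e1), seg_from_e(e2)
        assert np.array_equal(s1.labels, s2.labels)

    def test_levels_too_close_rejected(self):
        with pytest.raises(ValueError):
            segment_states(np.zeros(10), [0.5, 0.55], half_width=0.12)


class TestBindingTime:
    def test_transition_at_injection_gives_zero(self):
        e = np.concatenate([np.full(100, 0.6), np.full(100, 0.8)])
        seg = seg_from_e(e)
        assert find_binding_time(seg, 10.0, target_state=2) == pytest.approx(0.0)

    def test_no_transition_is_no_binding(self):
        seg = seg_from_e(np.full(200, 0.6))
        assert math.isnan(find_binding_time(seg, 5.0, target_state=2))

    def test_injection_outside_trace_rejected(self):
        seg = seg_from_e(np.full(100, 0.6))
        with pytest.raises(ValueError):
            find_binding_time(seg, 100.0, target_state=2)

    def test_ensemble_mean_waiting_time(self):
        """Mean binding time over an ensemble ~ 1/k (exponential waiting)."""
        k = 0.05
        root = np.random.default_rng(31)
        times = []
        for _ in range(300):
            tr = simulate_trace(
                TraceSimConfig(
                    states=[("LOW", 0.2, 0.03), ("MID", 0.6, 0.03), ("HIGH", 0.8, 0.03)],
                    rate_matrix=np.array([[0, 0, 0], [0, 0, k], [0, 0, 0]]),
                    duration=600.0,
                    injection_time=30.0,
                    initial_state=1,
                    noise_sd=10.0,
                    seed=int(root.integers(2**31)),
                )
            )
            seg = seg_from_e(compute_trace_fret(tr))
            t = find_binding_time(seg, 30.0, target_state=2)
            if not math.isnan(t):
                times.append(t)
        assert np.mean(times) == pytest.approx(1 / k, rel=0.15)


class TestDwellRate:
    def test_reciprocal_mean_exact(self):
        fit = fit_dwell_rate([1.0, 2.0, 3.0])
        assert fit.rate == pytest.approx(0.5)
        assert "low_confidence" in fit.flags

    def test_single_dwell_fallback(self):
        fit = fit_dwell_rate([4.0])
        assert fit.rate == pytest.approx(0.25)
        assert "low_confidence" in fit.flags

    def test_simulated_dwells_within_ten_percent(self, rng):
        dwells = rng.exponential(10.0, 1000)
        fit = fit_dwell_rate(dwells)
        assert fit.rate == pytest.approx(0.1, rel=0.1)
        assert not fit.flags

    def test_censored_excluded(self):
        fit = fit_dwell_rate([1.0, 2.0, 3.0, 99.0], censored=[False, False, False, True])
        assert fit.rate == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_dwell_rate([])


class TestAssociationFit:
    def test_noiseless_slope_exact(self):
        k_a = 8.4e4
        conc = np.array([0.2e-6, 0.5e-6, 1.0e-6])
        pts = [(c, k_a * c) for c in conc]
        fit = fit_association_constant(pts)
        assert fit.rate == pytest.approx(k_a, rel=1e-12)

    def test_all_zero_rates(self):
        fit = fit_association_constant([(0.2e-6, 0.0), (1.0e-6, 0.0)])
        assert fit.rate == 0.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_association_constant([(1e-6, 0.1), (1e-6, 0.2)])

    def test_end_to_end_recovery_from_binding_times(self):
        """Reciprocal-mean rates at three concentrations recover the slope."""
        k_a = 8.4e4
        conc = [0.2e-6, 0.5e-6, 1.0e-6]
        df = simulate_binding_times(k_a, conc, 50, seed=12)
        pts = [
            (c, 1.0 / g["waiting_time"].mean()) for c, g in df.groupby("concentration")
        ]
        fit = fit_association_constant(pts)
        assert fit.rate == pytest.approx(k_a, rel=0.2)


class TestClassification:
    def _seg(self, segments):
        e = np.concatenate([np.full(n, v) for v, n in segments])
        return seg_from_e(e)

    def test_direct_displacement(self):
        seg = self._seg([(0.6, 100), (0.8, 100)])
        c = classify_trace(seg, 5.0)
        assert c.category is TraceCategory.DISPLACEMENT_DIRECT
        assert c.n_low_visits == 0

    def test_via_intermediate(self):
        seg = self._seg([(0.6, 100), (0.2, 20), (0.8, 100)])
        c = classify_trace(seg, 5.0)
        assert c.category is TraceCategory.DISPLACEMENT_VIA_INTERMEDIATE
        assert c.n_low_visits == 1

    def test_constant_mid_is_no_binding(self):
        c = classify_trace(self._seg([(0.6, 200)]), 5.0)
        assert c.category is TraceCategory.NO_BINDING

    def test_intermediate_return(self):
        seg = self._seg([(0.6, 100), (0.2, 20), (0.6, 100)])
        c = classify_trace(seg, 5.0)
        assert c.category is TraceCategory.INTERMEDIATE_RETURN

    def test_multi_transition(self):
        seg = self._seg([(0.6, 50), (0.2, 20), (0.6, 50), (0.2, 20), (0.8, 50)])
        c = classify_trace(seg, 1.0)
        assert c.category is TraceCategory.MULTI_TRANSITION
        assert c.n_low_visits == 2

    def test_summary_displacement_total(self):
        """46/32/22 ensemble: displacement total is 54% by direct counting."""
        classes = (
            [TraceClass(TraceCategory.NO_BINDING)] * 46
            + [TraceClass(TraceCategory.DISPLACEMENT_DIRECT)] * 32
            + [TraceClass(TraceCategory.DISPLACEMENT_VIA_INTERMEDIATE, n_low_visits=1)] * 22
        )
        s = classification_summary(classes)
        assert s["displacement_total"] == pytest.approx(0.54)
        assert s["via_intermediate_share"] == pytest.approx(22 / 54)

    def test_summary_all_no_binding(self):
        s = classification_summary([TraceClass(TraceCategory.NO_BINDING)] * 10)
        assert s["displacement_total"] == 0.0
        assert math.isnan(s["via_intermediate_share"])

    def test_fractions_sum_to_one(self):
        classes = [
            TraceClass(TraceCategory.NO_BINDING),
            TraceClass(TraceCategory.DISPLACEMENT_DIRECT),
            TraceClass(TraceCategory.INTERMEDIATE_RETURN, n_low_visits=1),
        ]
        s = classification_summary(classes)
        total = sum(s[c.value] for c in TraceCategory)
        assert total == pytest.approx(1.0)

    def test_classifier_fidelity_on_labeled_ensemble(self):
        """>= 98% category agreement with ground-truth paths at high SNR."""
        root = np.random.default_rng(77)
        # MID -> LOW -> HIGH with a direct MID -> HIGH channel
        Q = np.array([[0.0, 0.0, 0.05], [0.01, 0.0, 0.01], [0.0, 0.0, 0.0]])
        correct = 0
        n = 150
        for _ in range(n):
            tr = simulate_trace(
                TraceSimConfig(
                    states=[("LOW", 0.2, 0.04), ("MID", 0.6, 0.04), ("HIGH", 0.8, 0.04)],
                    rate_matrix=Q,
                    duration=300.0,
                    injection_time=30.0,
                    initial_state=1,
                    noise_sd=10.0,
                    seed=int(root.integers(2**31)),
                )
            )
            seg = seg_from_e(compute_trace_fret(tr))
            got = classify_trace(seg, 30.0)
            want = _truth_category(tr.truth["frame_state"], tr.time, 30.0)
            correct += got.category is want
        assert correct / n >= 0.98


def _truth_category(frame_state, time, injection):
    """Independent classifier on the hidden path (low=0, mid=1, high=2)."""
    post = frame_state[time >= injection]
    states = [post[0]] + [s for a, s in zip(post, post[1:]) if s != a]
    n_low = states.count(0)
    if states[-1] == 2:
        if n_low == 0:
            return TraceCategory.DISPLACEMENT_DIRECT
        return (
            TraceCategory.DISPLACEMENT_VIA_INTERMEDIATE
            if n_low == 1
            else TraceCategory.MULTI_TRANSITION
        )
    if n_low > 0:
        return TraceCategory.INTERMEDIATE_RETURN
    return TraceCategory.NO_BINDING


class TestCumulativeHistogram:
    def test_pooled_trace_histogram_peak(self):
        """100 bound-state traces pool to a Gaussian peak at the state E."""
        root = np.random.default_rng(55)
        pooled = []
        for _ in range(100):
            tr = simulate_trace(
                TraceSimConfig(
                    states=[("BOUND", 0.62, 0.08)],
                    rate_matrix=np.zeros((1, 1)),
                    duration=300.0,
                    seed=int(root.integers(2**31)),
                )
            )
            pooled.append(compute_trace_fret(tr))
        (comp,) = fit_fret_histogram(np.concatenate(pooled), 1)
        assert comp.mean == pytest.approx(0.62, abs=0.02)
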