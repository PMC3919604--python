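"""Single-molecule analysis: filtering against simulator ground truth,
mixture and HMM state recovery, cross-correlation rate extraction, and
injection event detection/classification."""

import numpy as np
import pytest

from flapsm.pipelines import injection_binding_rate
from flapsm.simulate import (
    InjectionScheme,
    PhotophysicsModel,
    TwoStateKinetics,
    render_trace,
    simulate_injection_profile,
    simulate_state_path,
)
from flapsm.sm_analysis import (
    binary_segmentation,
    build_histogram,
    classify_transition,
    cross_correlate,
    detect_events,
    extract_dwells,
    filter_trace,
    fit_correlation,
    fit_mixture,
    hmm_two_state,
    sm_titration,
)

STATIC = dict(k_forward=0.0, k_backward=0.0)


def static_trace(e, phys, duration=100.0, frame_time=0.1, seed=0, pife=1.0, **kw):
    kin = TwoStateKinetics(**STATIC, E_state1=e, E_state2=e,
                           pife_state1=pife, pife_state2=pife)
    path = simulate_state_path(kin, duration, seed=seed, start_state=1)
    return render_trace(path, kin, phys, frame_time, seed=seed + 1, **kw)


class TestFiltering:
    def test_truncates_at_forced_acceptor_bleach(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, seed=3, acceptor_bleach_time=30.0)
        clean, mask = filter_trace(tr, background_donor=20, background_acceptor=20)
        assert abs(len(clean) - 300) <= 2

    def test_blink_interval_masked_not_truncated(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, seed=4)
        rng = np.random.default_rng(0)
        tr.acceptor_counts[500:510] = rng.poisson(20, 10)
        tr.donor_counts[500:510] = rng.poisson(520, 10)
        clean, mask = filter_trace(tr, background_donor=20, background_acceptor=20)
        assert len(clean) == len(tr)
        # the dark interval is masked (segment boundaries may be off by a frame)
        assert (~mask[500:510]).sum() >= 8
        assert mask[:498].all() and mask[512:].all()

    def test_bleach_time_recovered_on_population(self, tirf_phys):
        # >= 95% of stochastic bleach times recovered within 5 frames
        phys = PhotophysicsModel(
            total_brightness=500, background_donor=20, background_acceptor=20,
            acceptor_bleach_rate=0.02,
        )
        rng = np.random.default_rng(11)
        hits = total = 0
        for _ in range(200):
            tr = static_trace(0.6, phys, duration=100.0, seed=int(rng.integers(2**31)))
            t_bleach = tr.metadata["acceptor_bleach_time"]
            if not 5.0 < t_bleach < 90.0:
                continue
            total += 1
            try:
                clean, _ = filter_trace(tr, background_donor=20, background_acceptor=20)
            except ValueError:
                continue
            if abs(len(clean) - t_bleach / 0.1) <= 5:
                hits += 1
        assert total > 100
        assert hits / total >= 0.95

    def test_idempotent(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, seed=5, acceptor_bleach_time=60.0)
        tr.acceptor_counts[200:208] = 20.0
        tr.donor_counts[200:208] = 520.0
        once, mask1 = filter_trace(tr, background_donor=20, background_acceptor=20)
        twice, mask2 = filter_trace(once, background_donor=20, background_acceptor=20)
        assert len(twice) == len(once)
        np.testing.assert_array_equal(mask1[: len(mask2)], mask2)

    def test_dark_trace_rejected(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, seed=6)
        tr.donor_counts[:] = 20.0
        tr.acceptor_counts[:] = 20.0
        with pytest.raises(ValueError):
            filter_trace(tr, background_donor=20, background_acceptor=20)

    def test_short_trace_rejected(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, duration=3.0, seed=7)
        with pytest.raises(ValueError):
            filter_trace(tr)


class TestHistogramMixture:
    def test_histogram_covers_clamped_range(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, seed=1)
        counts, edges = build_histogram(tr, bin_width=0.025)
        assert edges[0] == pytest.approx(-0.2)
        assert counts.sum() == len(tr)

    def test_single_gaussian_recovered(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(0.6, 0.05, 5000)
        res = fit_mixture(frames)
        assert res.n_components == 1
        assert res.means[0] == pytest.approx(0.6, abs=0.01)

    def test_two_component_weights_recovered(self):
        rng = np.random.default_rng(3)
        frames = np.concatenate(
            [rng.normal(0.62, 0.08, 7000), rng.normal(0.37, 0.08, 3000)]
        )
        res = fit_mixture(frames)
        assert res.n_components == 2
        assert res.weights[0] == pytest.approx(0.3, abs=0.05)
        assert res.means[1] == pytest.approx(0.62, abs=0.02)

    def test_fast_exchange_merges_to_weighted_mean(self, tirf_phys):
        # dynamics far above the frame rate average to one peak at the
        # occupancy-weighted efficiency
        kin = TwoStateKinetics(80.0, 20.0, 0.37, 0.6)  # occupancy 0.2 / 0.8
        rng = np.random.default_rng(4)
        frames = []
        for _ in range(10):
            path = simulate_state_path(kin, 30.0, seed=rng)
            tr = render_trace(path, kin, tirf_phys, 0.1, seed=rng)
            e = tr.efficiency()
            frames.append(e[np.isfinite(e)])
        res = fit_mixture(np.concatenate(frames))
        expected = 0.2 * 0.37 + 0.8 * 0.6
        # one merged peak: any fitted components sit on top of each other at
        # the occupancy-weighted mean, far from the static state positions
        assert res.weighted_mean == pytest.approx(expected, abs=0.02)
        assert res.means.max() - res.means.min() < 0.1

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.random.default_rng(0).normal(0.5, 0.1, 100))


class TestCrossCorrelation:
    def test_independent_noise_has_no_correlation(self):
        from flapsm.trace import IntensityTrace

        rng = np.random.default_rng(5)
        traces = [
            IntensityTrace(
                times=np.arange(2000) * 0.016,
                donor_counts=rng.poisson(300, 2000),
                acceptor_counts=rng.poisson(300, 2000),
                frame_time=0.016,
            )
            for _ in range(10)
        ]
        curve = cross_correlate(traces, max_lag=0.5)
        assert np.abs(curve.amplitude[1:]).max() < 5e-4

    def test_telegraph_rate_recovered_within_20pct(self, tirf_phys):
        kin = TwoStateKinetics(5.0, 5.0, 0.37, 0.6)  # summed rate 10
        rng = np.random.default_rng(6)
        traces = []
        for _ in range(15):
            path = simulate_state_path(kin, 60.0, seed=rng)
            traces.append(render_trace(path, kin, tirf_phys, 0.016, seed=rng))
        curve = cross_correlate(traces, max_lag=1.0)
        assert curve.amplitude[1] < 0  # anticorrelated channels
        res = fit_correlation(curve)
        assert res["rate"] == pytest.approx(10.0, rel=0.2)

    def test_matches_telegraph_acf_closed_form(self, tirf_phys):
        # the two-state ACF decays as exp(-(k_f+k_b) tau): the fitted decay
        # profile must match the closed form lag by lag
        kin = TwoStateKinetics(8.0, 4.0, 0.37, 0.6)
        rng = np.random.default_rng(7)
        traces = []
        for _ in range(20):
            path = simulate_state_path(kin, 120.0, seed=rng)
            traces.append(render_trace(path, kin, tirf_phys, 0.016, seed=rng))
        curve = cross_correlate(traces, max_lag=0.6)
        res = fit_correlation(curve)
        assert res["rate"] == pytest.approx(12.0, rel=0.2)
        lags = curve.lags[1:15]
        model = res.params["amplitude"] * np.exp(-12.0 * lags)
        np.testing.assert_allclose(curve.amplitude[1:15], model,
                                   atol=0.1 * abs(curve.amplitude[1]))

    def test_error_shrinks_with_trace_length(self, tirf_phys):
        kin = TwoStateKinetics(6.0, 6.0, 0.37, 0.6)
        errs = []
        for duration, seed in [(15.0, 1), (60.0, 2), (240.0, 3)]:
            rng = np.random.default_rng(seed)
            traces = []
            for _ in range(15):
                path = simulate_state_path(kin, duration, seed=rng)
                traces.append(render_trace(path, kin, tirf_phys, 0.016, seed=rng))
            res = fit_correlation(cross_correlate(traces, max_lag=0.8))
            errs.append(abs(res["rate"] - 12.0))
        assert errs[2] < errs[0]

    def test_positive_zero_lag_flagged(self):
        from flapsm.trace import IntensityTrace

        rng = np.random.default_rng(8)
        common = rng.normal(0, 30, 3000)  # correlated brightness drift
        traces = [
            IntensityTrace(
                times=np.arange(3000) * 0.016,
                donor_counts=300 + common + rng.normal(0, 5, 3000),
                acceptor_counts=300 + common + rng.normal(0, 5, 3000),
                frame_time=0.016,
            )
        ]
        res = fit_correlation(cross_correlate(traces, max_lag=0.5))
        assert res.detail["non_anticorrelated"]


class TestHmm:
    def test_noiseless_square_wave_exact(self):
        e = np.tile(np.repeat([0.3, 0.7], 50), 10) + np.random.default_rng(0).normal(
            0, 1e-3, 1000
        )
        res = hmm_two_state(e, frame_time=0.1, seed=0)
        assert res.n_states == 2
        path = res.state_paths[0]
        expected = np.tile(np.repeat([1, 2], 50), 10)
        assert (path == expected).mean() > 0.999

    def test_rates_recovered_within_25pct(self, tirf_phys):
        kin = TwoStateKinetics(0.5, 0.5, 0.37, 0.6)
        rng = np.random.default_rng(9)
        etr = []
        for _ in range(15):
            path = simulate_state_path(kin, 60.0, seed=rng)
            etr.append(render_trace(path, kin, tirf_phys, 0.033, seed=rng).efficiency())
        res = hmm_two_state(etr, frame_time=0.033, seed=0)
        assert res.n_states == 2
        assert res.rates[1] == pytest.approx(0.5, rel=0.25)
        assert res.rates[2] == pytest.approx(0.5, rel=0.25)

    def test_static_trace_reported_one_state(self, tirf_phys):
        tr = static_trace(0.6, tirf_phys, duration=60.0, frame_time=0.033, seed=10)
        res = hmm_two_state(tr.efficiency(), frame_time=0.033, seed=0)
        assert res.n_states == 1
        assert res.rates == {}

    def test_hmm_and_xcorr_rates_agree(self, tirf_phys):
        # two estimators, one truth: dwell-MLE exit-rate sum vs correlation decay
        kin = TwoStateKinetics(1.5, 1.5, 0.37, 0.6)
        rng = np.random.default_rng(12)
        traces = []
        for _ in range(15):
            path = simulate_state_path(kin, 120.0, seed=rng)
            traces.append(render_trace(path, kin, tirf_phys, 0.033, seed=rng))
        hmm = hmm_two_state([t.efficiency() for t in traces], 0.033, seed=0)
        k_hmm = hmm.rates[1] + hmm.rates[2]
        xc = fit_correlation(cross_correlate(traces, max_lag=3.0))
        assert k_hmm == pytest.approx(xc["rate"], rel=0.25)

    def test_extract_dwells_censors_edges(self):
        path = np.array([1, 1, 2, 2, 2, 1, 1, 1, 2, 2])
        dw = extract_dwells(path, frame_time=0.1)
        times1, cens1 = dw[1]
        np.testing.assert_allclose(times1, [0.2, 0.3])
        assert list(cens1) == [True, False]
        times2, cens2 = dw[2]
        np.testing.assert_allclose(times2, [0.3, 0.2])
        assert list(cens2) == [False, True]


class TestTransitionClassification:
    def test_opposite_steps_anticorrelated(self):
        rng = np.random.default_rng(1)
        d = np.r_[np.full(10, 1000.0), np.full(10, 1400.0)] + rng.normal(0, 15, 20)
        a = np.r_[np.full(10, 600.0), np.full(10, 200.0)] + rng.normal(0, 15, 20)
        assert classify_transition(d, a, 10) == "anticorrelated"

    def test_donor_only_step_non_anticorrelated(self):
        rng = np.random.default_rng(2)
        d = np.r_[np.full(10, 1400.0), np.full(10, 900.0)] + rng.normal(0, 15, 20)
        a = np.full(20, 200.0) + rng.normal(0, 15, 20)
        assert classify_transition(d, a, 10) == "non_anticorrelated"

    def test_no_change_returns_none(self):
        rng = np.random.default_rng(3)
        d = np.full(20, 1000.0) + rng.normal(0, 15, 20)
        a = np.full(20, 500.0) + rng.normal(0, 15, 20)
        assert classify_transition(d, a, 10) == "none"

    def test_pife_toggling_classified_non_anticorrelated(self, tirf_phys):
        # clamp binding toggles the donor ~2-fold while the concurrent flap
        # opening leaves the acceptor nearly unchanged: the apparent E swings
        # 0.44 <-> 0.30 but the channels do not anticorrelate.  E2 = 0.4615
        # makes the raw apparent efficiency in the PIFE state exactly 0.30.
        kin = TwoStateKinetics(
            0.3, 0.3, E_state1=0.44, E_state2=0.4615,
            pife_state1=1.0, pife_state2=2.0,
        )
        rng = np.random.default_rng(13)
        n_ok = n_tot = 0
        for _ in range(20):
            path = simulate_state_path(kin, 60.0, seed=rng)
            tr = render_trace(path, kin, tirf_phys, 0.1, seed=rng)
            for state, t in path.segments[1:]:
                idx = int(round(t / 0.1))
                if idx < 5 or idx > len(tr) - 5:
                    continue
                # only toggles with >= 0.8 s of clean flank on both sides
                seg_ok = all(
                    abs(idx - int(round(tt / 0.1))) >= 8
                    for s2, tt in path.segments
                    if tt != t
                )
                if not seg_ok:
                    continue
                n_tot += 1
                cls = classify_transition(tr.donor_counts, tr.acceptor_counts, idx)
                n_ok += cls == "non_anticorrelated"
        assert n_tot >= 20
        assert n_ok / n_tot >= 0.9


class TestEventDetection:
    def test_binding_then_cleavage_within_one_frame(self, tirf_phys):
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=0.01, k_cleave=0.03,
            E_unbound=0.6, E_bound=0.44,
        )
        rng = np.random.default_rng(14)
        checked = 0
        for _ in range(20):
            tr = simulate_injection_profile(scheme, tirf_phys, 600.0, 0.2, seed=rng)
            m = tr.metadata
            if m["cleavage_time"] > 590 or m["cleavage_time"] - m["binding_time"] < 2:
                continue
            ev = detect_events(tr)
            checked += 1
            assert ev.binding_time == pytest.approx(m["binding_time"], abs=0.25)
            assert ev.cleavage_time == pytest.approx(m["cleavage_time"], abs=0.25)
            assert ev.terminal_class == "cleaved"
            # without PIFE the donor recovers on cleavage: anticorrelated
            assert ev.transition_class["cleavage"] == "anticorrelated"
            assert ev.pife_loss_time is None
        assert checked >= 10

    def test_simultaneous_pife_loss_non_anticorrelated(self, tirf_phys):
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=0.05, k_cleave=0.04,
            E_unbound=0.6, E_bound=0.3, pife_bound=2.0, p_delayed_pife_loss=0.0,
        )
        rng = np.random.default_rng(15)
        n_cls = 0
        for _ in range(20):
            tr = simulate_injection_profile(scheme, tirf_phys, 400.0, 0.2, seed=rng)
            ev = detect_events(tr)
            if ev.cleavage_time is None:
                continue
            n_cls += 1
            assert ev.transition_class["cleavage"] == "non_anticorrelated"
            assert ev.pife_loss_time == ev.cleavage_time
        assert n_cls >= 15

    def test_delayed_pife_loss_three_ordered_events(self, tirf_phys):
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=0.05, k_cleave=0.05,
            E_unbound=0.6, E_bound=0.3, pife_bound=2.0,
            p_delayed_pife_loss=1.0, k_pife_loss=1 / 15,
        )
        rng = np.random.default_rng(16)
        n_three = n_checked = 0
        for _ in range(25):
            tr = simulate_injection_profile(scheme, tirf_phys, 300.0, 0.2, seed=rng)
            m = tr.metadata
            if m["pife_loss_time"] > 290 or m["pife_loss_time"] - m["cleavage_time"] < 2:
                continue
            n_checked += 1
            ev = detect_events(tr)
            if (
                ev.binding_time is not None
                and ev.cleavage_time is not None
                and ev.pife_loss_time is not None
                and ev.binding_time < ev.cleavage_time < ev.pife_loss_time
            ):
                n_three += 1
                assert ev.transition_class["pife_loss"] == "non_anticorrelated"
        assert n_checked >= 10
        assert n_three / n_checked >= 0.8

    def test_no_events_survived(self, tirf_phys):
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=0.0, k_cleave=0.0, E_unbound=0.6, E_bound=0.44
        )
        tr = simulate_injection_profile(scheme, tirf_phys, 300.0, 0.2, seed=1)
        ev = detect_events(tr)
        assert ev.binding_time is None and ev.cleavage_time is None
        assert ev.terminal_class == "survived"

    def test_bleach_only_cleavage_false_positive_rate(self, tirf_phys):
        # no injection kinetics, acceptor bleach 0.002/s: acceptor losses must
        # be attributed to photobleach, not cleavage, in >= 95% of traces
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=0.0, k_cleave=0.0, E_unbound=0.6, E_bound=0.44
        )
        phys = PhotophysicsModel(
            total_brightness=500, background_donor=20, background_acceptor=20,
            acceptor_bleach_rate=0.002,
        )
        rng = np.random.default_rng(99)
        fp = 0
        for _ in range(200):
            tr = simulate_injection_profile(scheme, phys, 600.0, 0.2, seed=rng)
            ev = detect_events(tr)
            fp += ev.cleavage_time is not None
        assert fp / 200 <= 0.05


class TestSmTitration:
    def test_constant_efficiency_mean(self, quiet_phys):
        traces = [static_trace(0.6, quiet_phys, duration=30.0, seed=s) for s in range(3)]
        table = sm_titration({10.0: traces}, prefilter=False)
        assert table["mean_E"].iloc[0] == pytest.approx(0.6, abs=1e-9)
        assert table["n_frames"].iloc[0] == 900


class TestBindingRatePipelineBias:
    @pytest.mark.parametrize("k_bind", [0.005, 0.015, 0.05])
    def test_relative_bias_below_15pct(self, tirf_phys, k_bind):
        scheme = InjectionScheme(
            t_injection=15.0, k_bind=k_bind, k_cleave=0.04,
            E_unbound=0.6, E_bound=0.44,
        )
        res = injection_binding_rate(scheme, tirf_phys, 300, 600.0, 0.2, seed=11)
        assert abs(res["k_bind"] - k_bind) / k_bind < 0.15
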