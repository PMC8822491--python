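"""Trace-analysis pipeline: breakpoints, rates, and the inference chain."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoxkin import (AntioxidantSpec, ExperimentSystem, InhibitionModel,
                      ReactionParameters, Trace, analyze_experiment,
                      classify, closed_form_uptake, compute_Ri, compute_n,
                      compute_nu, correct_kinh, estimate_kinh,
                      estimate_phase_rates, estimate_tau, simulate,
                      steady_state_rox, synergy_n)
from autoxkin.errors import (AutoxkinWarning, FitFailureError,
                             InsufficientDataError, MissingReferenceError,
                             NoBreakpointError)
from conftest import make_piecewise_trace


class TestEstimateTau:
    def test_exact_piecewise_breakpoint(self, piecewise_trace):
        tau, tau_sd = estimate_tau(piecewise_trace, n_boot=50, seed=0)
        assert tau == pytest.approx(600.0, abs=1.0)
        assert tau_sd < 5.0

    def test_closed_form_generator_truth(self, closed_form_trace):
        tau, _ = estimate_tau(closed_form_trace, n_boot=0)
        assert tau == pytest.approx(432.0, rel=0.05)

    def test_noisy_recovery_median(self, closed_form_trace):
        rng = np.random.default_rng(7)
        taus = []
        for _ in range(20):
            y = closed_form_trace.o2_consumed + \
                rng.normal(0.0, 0.2e-6, len(closed_form_trace))
            tr = Trace(times=closed_form_trace.times, o2_consumed=y)
            taus.append(estimate_tau(tr, n_boot=0)[0])
        assert np.median(taus) == pytest.approx(432.0, rel=0.10)

    def test_straight_line_has_no_breakpoint(self):
        t = np.arange(0.0, 1000.0, 5.0)
        tr = Trace(times=t, o2_consumed=5e-10 * t)
        with pytest.raises(NoBreakpointError):
            estimate_tau(tr, n_boot=0)

    def test_noisy_line_has_no_breakpoint(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 1500.0, 5.0)
        tr = Trace(times=t,
                   o2_consumed=3e-10 * t + rng.normal(0, 0.2e-6, t.size))
        with pytest.raises(NoBreakpointError):
            estimate_tau(tr, n_boot=0)

    def test_too_few_points(self):
        t = np.arange(0.0, 50.0, 5.0)
        tr = Trace(times=t, o2_consumed=1e-9 * t)
        with pytest.raises(InsufficientDataError):
            estimate_tau(tr)

    def test_time_shift_equivariance(self):
        base = make_piecewise_trace(injection=100.0)
        shifted = Trace(times=base.times + 250.0,
                        o2_consumed=base.o2_consumed,
                        injection_time=base.injection_time + 250.0)
        assert estimate_tau(shifted, n_boot=0)[0] == \
            pytest.approx(estimate_tau(base, n_boot=0)[0], abs=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_uptake_rescaling_equivariance(self, scale):
        base = make_piecewise_trace()
        scaled = Trace(times=base.times, o2_consumed=base.o2_consumed * scale,
                       injection_time=base.injection_time)
        assert estimate_tau(scaled, n_boot=0)[0] == \
            pytest.approx(estimate_tau(base, n_boot=0)[0], rel=1e-9)

    def test_bootstrap_is_seeded(self, closed_form_trace):
        rng = np.random.default_rng(5)
        y = closed_form_trace.o2_consumed + \
            rng.normal(0, 0.2e-6, len(closed_form_trace))
        tr = Trace(times=closed_form_trace.times, o2_consumed=y)
        a = estimate_tau(tr, n_boot=100, seed=11)
        b = estimate_tau(tr, n_boot=100, seed=11)
        assert a == b


class TestPhaseRates:
    def test_exact_piecewise_rates(self, piecewise_trace):
        r_inh, r_ox2 = estimate_phase_rates(piecewise_trace, 600.0)
        assert r_inh == pytest.approx(20e-9, rel=1e-9)
        assert r_ox2 == pytest.approx(200e-9, rel=1e-9)

    def test_convex_trace_slope_bounds(self, closed_form_trace):
        # mean-value: the window slope lies between the instantaneous
        # slopes at the window edges
        tau, k_inh, k_p, LH = 432.0, 5.0e4, 36.0, 2.74e-3
        r_inh, _ = estimate_phase_rates(closed_form_trace, tau)
        slope_at = lambda t: k_p * LH / k_inh / (tau - t)  # noqa: E731
        assert slope_at(0.15 * tau) < r_inh < slope_at(0.85 * tau)

    def test_retarded_trace_uses_whole_record(self):
        t = np.arange(0.0, 1000.0, 5.0)
        tr = Trace(times=t, o2_consumed=2e-10 * t)
        r_inh, r_ox2 = estimate_phase_rates(tr, None)
        assert r_inh == pytest.approx(2e-10, rel=1e-9)
        assert np.isnan(r_ox2)

    def test_simulated_inhibited_rate_matches_oracle(self):
        # k_p [LH] R_i / (2 k_inh [ArOH]) with [ArOH] at the window
        # midpoint, measured after the phenoxyl pool has equilibrated but
        # with < 20% of the antioxidant consumed
        k_inh, R_i, conc = 6.0e3, 4.63e-9, 1e-6
        ax = AntioxidantSpec(name="A", conc0=conc, k_inh=k_inh)
        system = ExperimentSystem(medium="micelle", R_i=R_i,
                                  antioxidants=[ax])
        params = ReactionParameters(k_p=36.0)
        trace = simulate(system, params, t_end=500.0, dt_out=1.0)
        tau_cap = 2.0 * conc / R_i
        lo, hi = 0.2 * tau_cap, 0.4 * tau_cap
        m = (trace.times >= lo) & (trace.times <= hi)
        slope = np.polyfit(trace.times[m], trace.o2_consumed[m], 1)[0]
        remaining = conc - R_i * 0.5 * (lo + hi) / 2.0
        oracle = params.k_p * system.LH0 * R_i / (2.0 * k_inh * remaining)
        assert slope == pytest.approx(oracle, rel=0.05)

    def test_window_too_small(self):
        t = np.arange(0.0, 300.0, 5.0)
        tr = Trace(times=t, o2_consumed=1e-9 * t)
        with pytest.raises(InsufficientDataError):
            estimate_phase_rates(tr, 10.0)


class TestInferenceChain:
    """The induction-period arithmetic applied to printed-style values."""

    @pytest.mark.parametrize("tau,n,conc,expected", [
        (432.0, 2.0, 1e-6, 4.63e-9),     # micellar reference run
        (876.0, 2.0, 1e-6, 2.283e-9),    # liposomal pH-6 reference run
        (600.0, 1.0, 6e-7, 1.0e-9),
    ])
    def test_initiation_flux(self, tau, n, conc, expected):
        assert compute_Ri(tau, n, conc) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("tau,ri,conc,expected", [
        (2448.0, 2.283e-9, 1e-6, 5.59),  # liposomal pH-6 stilbene row
        (888.0, 3.876e-9, 1e-6, 3.44),   # liposomal pH-7 stilbene row
        (0.0, 1e-9, 1e-6, 0.0),
    ])
    def test_stoichiometric_factor(self, tau, ri, conc, expected):
        assert compute_n(tau, ri, conc) == pytest.approx(expected, abs=0.01)

    def test_eq8_round_trip(self):
        ri = compute_Ri(432.0, 2.0, 1e-6)
        assert compute_n(432.0, ri, 1e-6) == pytest.approx(2.0, rel=1e-12)

    @given(tau=st.floats(10.0, 1e5), n=st.floats(0.5, 10.0),
           c=st.floats(1e-8, 1e-4))
    @settings(max_examples=50, deadline=None)
    def test_eq8_round_trip_property(self, tau, n, c):
        assert compute_n(tau, compute_Ri(tau, n, c), c) == \
            pytest.approx(n, rel=1e-9)

    def test_division_errors(self):
        with pytest.raises(ZeroDivisionError):
            compute_Ri(0.0, 2.0, 1e-6)
        with pytest.raises(ZeroDivisionError):
            compute_n(100.0, 1e-9, 0.0)
        with pytest.raises(ZeroDivisionError):
            compute_nu(1e-9, 0.0)

    @pytest.mark.parametrize("k,n,expected", [
        (3.3e3, 5.6, 9.24e3),            # liposomal pH-6 stilbene
        (1.2e3, 4.9, 2.94e3),            # micellar pH-6 stilbene
        (7.7e3, 2.0, 7.7e3),             # identity at n = 2
    ])
    def test_capacity_corrected_kinh(self, k, n, expected):
        assert correct_kinh(k, n) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("r_inh,ri,expected", [
        (35e-9, 4.63e-9, 7.56),          # micellar pH-4 reference row
        (103e-9, 4.63e-9, 22.2),         # micellar pH-6 stilbene row
        (0.0, 4.63e-9, 0.0),
    ])
    def test_kinetic_chain_length(self, r_inh, ri, expected):
        assert compute_nu(r_inh, ri) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize("tmix,tref,ri,c,expected", [
        (3864.0, 876.0, 2.283e-9, 1e-6, 6.82),   # liposome pH 6 mixture
        (2448.0, 516.0, 3.876e-9, 1e-6, 7.49),   # liposome pH 7 mixture
        (876.0, 876.0, 2.283e-9, 1e-6, 0.0),
    ])
    def test_co_antioxidant_stoichiometry(self, tmix, tref, ri, c, expected):
        assert synergy_n(tmix, tref, ri, c) == pytest.approx(expected,
                                                             abs=0.01)

    def test_negative_synergy_warns(self):
        with pytest.warns(AutoxkinWarning):
            n = synergy_n(500.0, 800.0, 2e-9, 1e-6)
        assert n < 0


class TestEstimateKinh:
    def test_exact_inversion_of_closed_form(self):
        tau, k_inh, k_p, LH = 800.0, 7.5e3, 36.0, 2.74e-3
        t = np.linspace(0.0, 0.95 * tau, 400)
        tr = Trace(times=t,
                   o2_consumed=closed_form_uptake(t, tau, k_inh, k_p, LH))
        assert estimate_kinh(tr, tau, k_p, LH) == \
            pytest.approx(k_inh, rel=1e-6)

    @given(tau=st.floats(100.0, 5000.0), k=st.floats(1e2, 1e6))
    @settings(max_examples=40, deadline=None)
    def test_inversion_property(self, tau, k):
        t = np.linspace(0.0, 0.9 * tau, 200)
        tr = Trace(times=t,
                   o2_consumed=closed_form_uptake(t, tau, k, 36.0, 2.74e-3))
        assert estimate_kinh(tr, tau, 36.0, 2.74e-3) == \
            pytest.approx(k, rel=1e-6)

    def test_mechanistic_trace_recovery(self):
        # moderate single antioxidant at the liposomal pH-6 stilbene rate
        ax = AntioxidantSpec(name="A", conc0=1e-6, k_inh=3.3e3)
        system = ExperimentSystem(medium="liposome", R_i=2.28e-9,
                                  antioxidants=[ax])
        params = ReactionParameters(k_p=41.0)
        trace = simulate(system, params, t_end=2200.0, dt_out=4.0)
        tau, _ = estimate_tau(trace, n_boot=0)
        k = estimate_kinh(trace, tau, 41.0, 2.74e-3)
        assert k == pytest.approx(3.3e3, rel=0.15)

    def test_noisy_recovery_median(self):
        tau, k_inh = 1000.0, 5e3
        t = np.arange(0.0, 0.95 * tau, 5.0)
        clean = closed_form_uptake(t, tau, k_inh, 36.0, 2.74e-3)
        rng = np.random.default_rng(13)
        ks = []
        for _ in range(20):
            tr = Trace(times=t,
                       o2_consumed=clean + rng.normal(0, 0.2e-6, t.size))
            ks.append(estimate_kinh(tr, tau, 36.0, 2.74e-3))
        assert np.median(ks) == pytest.approx(k_inh, rel=0.15)

    def test_nonpositive_slope_fails(self):
        t = np.linspace(0.0, 700.0, 100)
        tr = Trace(times=t, o2_consumed=np.zeros_like(t) - 1e-9 * t / 700)
        with pytest.raises((FitFailureError, ValueError)):
            estimate_kinh(tr, 800.0, 36.0, 2.74e-3)


class TestClassification:
    def test_inhibition(self):
        assert classify(15.8, True) == "inhibition"

    def test_retardation_without_breakpoint(self):
        assert classify(1.4, False) == "retardation"

    def test_weak_breakpoint_demoted_to_retardation(self):
        assert classify(1.8, True) == "retardation"

    def test_none(self):
        assert classify(1.0, False) == "none"

    def test_missing_reference_signal(self):
        with pytest.raises(MissingReferenceError):
            classify(float("nan"), True)

    def test_monotone_in_kinh(self):
        # raising k_inh never demotes inhibition to retardation
        rank = {"none": 0, "retardation": 1, "inhibition": 2}
        system0 = ExperimentSystem(medium="micelle", R_i=4.63e-9)
        params = ReactionParameters(k_p=36.0)
        r_ox = steady_state_rox(system0, params)
        previous = -1
        for k in (6e2, 2.5e3, 1.4e4):
            ax = AntioxidantSpec(name="A", conc0=1e-6, k_inh=k)
            system = ExperimentSystem(medium="micelle", R_i=4.63e-9,
                                      antioxidants=[ax])
            trace = simulate(system, params, t_end=1200.0, dt_out=3.0)
            try:
                tau, _ = estimate_tau(trace, n_boot=0)
                found = True
            except NoBreakpointError:
                tau, found = None, False
            r_inh, _ = estimate_phase_rates(trace, tau)
            label = classify(r_ox / r_inh, found)
            assert rank[label] >= previous
            previous = rank[label]


class TestInhibitionModel:
    def _traces(self):
        ax = AntioxidantSpec(name="PMHC", conc0=1e-6, k_inh=1.4e4,
                             k_cross=1e5)
        system = ExperimentSystem(medium="micelle", R_i=4.63e-9,
                                  antioxidants=[ax])
        blank_system = ExperimentSystem(medium="micelle", R_i=4.63e-9)
        params = ReactionParameters(k_p=36.0)
        inhibited = simulate(system, params, t_end=1100.0, dt_out=3.0)
        blank = simulate(blank_system, params, t_end=1100.0, dt_out=3.0)
        return inhibited, blank

    def test_fit_produces_consistent_metrics(self):
        inhibited, blank = self._traces()
        res = InhibitionModel(inhibited, uninhibited=blank,
                              R_i=4.63e-9).fit(n_boot=50, seed=0)
        assert res.classification == "inhibition"
        assert res.tau == pytest.approx(2e-6 / 4.63e-9, rel=0.10)
        assert res.n == pytest.approx(2.0, abs=0.15)
        assert res.k_inh == pytest.approx(1.4e4, rel=0.20)
        assert res.slowdown > 3.0
        assert res.nu_inh == pytest.approx(res.R_inh / 4.63e-9, rel=1e-9)

    def test_summary_renders(self):
        inhibited, blank = self._traces()
        res = InhibitionModel(inhibited, uninhibited=blank,
                              R_i=4.63e-9).fit(n_boot=0)
        text = res.summary()
        assert "tau (min)" in text and "classification" in text

    def test_without_reference_no_classification(self):
        inhibited, _ = self._traces()
        res = InhibitionModel(inhibited).fit(n_boot=0)
        assert res.classification is None
        assert np.isnan(res.slowdown)


class TestAnalyzeExperiment:
    def test_single_uninhibited_trace(self):
        system = ExperimentSystem(medium="micelle", R_i=4.63e-9)
        blank = simulate(system, ReactionParameters(), t_end=500.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AutoxkinWarning)
            out = analyze_experiment([blank])
        assert len(out.metrics) == 1
        assert out.metrics.iloc[0].classification == "uninhibited"
        # whole-record average slope; slightly below the t=0 rate because
        # the lipid is being consumed
        assert out.metrics.iloc[0].R_ox_nM_s == pytest.approx(548.0, rel=0.10)
        assert out.synergy.empty

    def test_mixture_without_co_reference_flagged_incomplete(self):
        pm = AntioxidantSpec(name="PMHC", conc0=1e-6, k_inh=1.4e4,
                             k_cross=1e5)
        co = AntioxidantSpec(name="RSV", conc0=1e-6, k_inh=3e3)
        params = ReactionParameters(k_p=36.0)
        mk = lambda roster, t_end: simulate(  # noqa: E731
            ExperimentSystem(medium="micelle", R_i=4.63e-9,
                             antioxidants=roster), params,
            t_end=t_end, dt_out=4.0)
        traces = [mk([], 1200.0), mk([pm], 1200.0), mk([pm, co], 2400.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AutoxkinWarning)
            out = analyze_experiment(traces, n_boot=0)
        assert len(out.synergy) == 1
        row = out.synergy.iloc[0]
        assert not row.complete
        assert np.isnan(row.tau_sum_min)
        assert row.n_co > 0
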