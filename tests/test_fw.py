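import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synkin as sk
from synkin.fw import (
    JERK_OFFSET,
    DegenerateRegimeWarning,
    InductionUnresolvedWarning,
    FWFitConfig,
    FWParams,
    FWPhaseTimes,
)

from conftest import (
    A0_MM,
    GRID_A0,
    GRID_K1,
    GRID_K2,
    PERCHLORATE_CONDITIONS,
    ode_monomer,
)

params_strategy = st.builds(
    FWParams,
    k1=st.floats(0.005, 0.05),
    k2=st.floats(0.05, 0.3),
    a0=st.floats(0.5, 5.0),
)


class TestParams:
    @pytest.mark.parametrize("bad", [(0, 0.1, 2), (0.1, -1, 2), (0.1, 0.1, 0)])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError):
            FWParams(*bad)

    @given(params_strategy)
    def test_derived_quantities(self, p):
        assert p.rate == p.k1 + p.k2 * p.a0 > 0
        assert p.amplitude > p.a0


class TestMonomer:
    def test_initial_condition_exact(self, ref_params):
        assert sk.fw_monomer(ref_params, 0.0) == pytest.approx(ref_params.a0, rel=1e-12)

    def test_inflection_value_is_half_amplitude(self, ref_params):
        # A(tmax) = K/2, checked against the independent ODE oracle
        tm = sk.fw_tmax(ref_params)
        analytic = sk.fw_monomer(ref_params, tm)
        assert analytic == pytest.approx(ref_params.amplitude / 2, rel=1e-12)
        assert abs(analytic - ode_monomer(ref_params, [tm])[0]) <= 1e-6

    def test_near_complete_conversion_at_48h(self):
        p = FWParams(0.01, 0.11, 2.0)
        val = sk.fw_monomer(p, 48.0)
        assert val < 1e-3
        assert abs(val - ode_monomer(p, [48.0])[0]) <= 1e-6

    def test_negative_time_rejected(self, ref_params):
        with pytest.raises(ValueError):
            sk.fw_monomer(ref_params, -0.1)

    @given(params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_and_conserved(self, p):
        t = np.linspace(0, 30, 200)
        a = sk.fw_monomer(p, t)
        b = sk.fw_aggregate(p, t)
        # strict monotonicity away from double-precision saturation
        live = a[:-1] > 1e-12
        assert np.all(np.diff(a)[live] < 0)
        assert np.all(np.diff(b)[live] > 0)
        assert np.all(np.diff(a) <= 0)
        np.testing.assert_allclose(a + b, p.a0, rtol=1e-12)

    def test_oracle_equivalence_grid(self):
        t = np.linspace(0, 48, 97)
        for k1, k2, a0 in itertools.product(GRID_K1, GRID_K2, GRID_A0):
            p = FWParams(k1, k2, a0)
            assert np.max(np.abs(sk.fw_monomer(p, t) - ode_monomer(p, t))) <= 1e-6


class TestTmax:
    def test_reference_value(self, ref_params):
        # ln(k2*A0/k1)/r = ln(0.26/0.03)/0.29
        assert sk.fw_tmax(ref_params) == pytest.approx(
            math.log(0.26 / 0.03) / 0.29, rel=1e-12
        )
        assert sk.fw_tmax(ref_params) == pytest.approx(7.446, abs=1e-3)

    def test_matches_numeric_argmax_of_growth_rate(self, ref_params):
        t = np.linspace(0, 24, 200001)
        b = sk.fw_aggregate(ref_params, t)
        rate = np.gradient(b, t)
        assert t[np.argmax(rate)] == pytest.approx(sk.fw_tmax(ref_params), abs=1e-3)

    def test_balanced_rates_give_zero(self):
        p = FWParams(0.22, 0.11, 2.0)  # k1 == k2*A0
        with pytest.warns(DegenerateRegimeWarning):
            assert sk.fw_tmax(p) == 0.0

    def test_second_reference_value(self):
        p = FWParams(0.01, 0.115, 2.0)
        tm = sk.fw_tmax(p)
        assert tm == pytest.approx(math.log(23.0) / 0.24, rel=1e-12)
        assert tm == pytest.approx(13.0646, abs=1e-3)
        t = np.linspace(0, 40, 400001)
        rate = np.gradient(sk.fw_aggregate(p, t), t)
        assert t[np.argmax(rate)] == pytest.approx(tm, abs=1e-3)

    def test_degenerate_regime_warns(self):
        with pytest.warns(DegenerateRegimeWarning):
            assert sk.fw_tmax(FWParams(0.5, 0.1, 2.0)) < 0


class TestJerkTimes:
    def test_reference_offsets(self, ref_params):
        ph = sk.fw_jerk_times(ref_params)
        off = JERK_OFFSET / ref_params.rate
        assert off == pytest.approx(4.541, abs=1e-3)
        assert ph.t1 == pytest.approx(2.905, abs=1e-3)
        assert ph.t2 == pytest.approx(11.988, abs=1e-3)

    @pytest.mark.parametrize("row", PERCHLORATE_CONDITIONS.values(), ids=PERCHLORATE_CONDITIONS)
    def test_reference_midpoints(self, row):
        assert abs(sk.tmax_from_jerk_times(row["t1"], row["t2"]) - row["tmax"]) <= 0.01

    @given(params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, p):
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = sk.fw_jerk_times(p)
        assert (ph.t1 + ph.t2) / 2 == pytest.approx(ph.tmax, rel=1e-12, abs=1e-12)
        assert ph.tmax - ph.t1 == pytest.approx(ph.t2 - ph.tmax, rel=1e-9)

    def test_numeric_oracle_agreement(self, ref_params):
        pa = sk.fw_jerk_times(ref_params)
        pn = sk.fw_jerk_times_numeric(ref_params)
        assert abs(pa.t1 - pn.t1) <= 1e-5
        assert abs(pa.t2 - pn.t2) <= 1e-5

    def test_numeric_oracle_agreement_grid(self):
        import warnings

        for k1, k2, a0 in itertools.product(GRID_K1, GRID_K2, GRID_A0):
            p = FWParams(k1, k2, a0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pa = sk.fw_jerk_times(p)
                pn = sk.fw_jerk_times_numeric(p)
            assert abs(pa.t1 - pn.t1) <= 1e-5, (k1, k2, a0)
            assert abs(pa.t2 - pn.t2) <= 1e-5, (k1, k2, a0)

    def test_numeric_convergence_under_step_halving(self, ref_params):
        r = ref_params.rate
        a = sk.fw_jerk_times_numeric(ref_params, h=0.02 / r)
        b = sk.fw_jerk_times_numeric(ref_params, h=0.01 / r)
        assert abs(a.t1 - b.t1) < 1e-5
        assert abs(a.t2 - b.t2) < 1e-5

    def test_unresolvable_induction_warns(self):
        p = FWParams(0.1, 0.11, 2.0)  # tmax ~ 2.5 h, offset ~ 4.1 h
        with pytest.warns(InductionUnresolvedWarning):
            ph = sk.fw_jerk_times(p)
        assert ph.t1 < 0
        assert not ph.induction_resolved

    def test_degenerate_numeric_matches_analytic_branch(self):
        import warnings

        p = FWParams(0.3, 0.1, 2.0)  # k1 >= k2*A0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pa = sk.fw_jerk_times(p)
            pn = sk.fw_jerk_times_numeric(p)
        assert pn.t1 < 0
        assert abs(pa.t1 - pn.t1) <= 1e-5

    def test_phase_time_ordering_enforced(self):
        with pytest.raises(ValueError):
            FWPhaseTimes(t1=3.0, tmax=2.0, t2=4.0)

    def test_midpoint_requires_ordering(self):
        with pytest.raises(ValueError):
            sk.tmax_from_jerk_times(5.0, 4.0)


class TestMaxRate:
    def test_reference_value(self, ref_params):
        assert sk.fw_max_rate(ref_params) == pytest.approx(0.29 * (2 + 0.03 / 0.13) / 4)
        assert sk.fw_max_rate(ref_params) == pytest.approx(0.1617, abs=1e-4)

    def test_matches_numeric_max_of_derivative(self, ref_params):
        t = np.linspace(0, 24, 200001)
        rate = np.gradient(sk.fw_aggregate(ref_params, t), t)
        assert np.max(rate) == pytest.approx(sk.fw_max_rate(ref_params), rel=1e-6)

    @given(params_strategy, st.floats(0.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_is_an_upper_bound(self, p, t):
        h = 1e-5
        rate = (sk.fw_aggregate(p, t + h) - sk.fw_aggregate(p, max(t - h, 0.0))) / (
            (t + h) - max(t - h, 0.0)
        )
        assert rate <= sk.fw_max_rate(p) * (1 + 1e-9)

    def test_small_k1_limit_quadratic_in_a0(self):
        k2 = 0.13
        lo = sk.fw_max_rate(FWParams(1e-9, k2, 1.0))
        hi = sk.fw_max_rate(FWParams(1e-9, k2, 2.0))
        assert lo == pytest.approx(k2 * 1.0**2 / 4, rel=1e-6)
        assert hi == pytest.approx(k2 * 2.0**2 / 4, rel=1e-6)
        assert hi / lo == pytest.approx(4.0, rel=1e-6)


class TestFit:
    def test_noise_free_recovery(self, ref_params):
        trace = sk.gen_fw_trace(ref_params, np.linspace(0, 24, 49))
        fit = sk.fit_fw(trace)
        assert fit.params.k1 == pytest.approx(ref_params.k1, rel=1e-4)
        assert fit.params.k2 == pytest.approx(ref_params.k2, rel=1e-4)
        assert fit.quality == "good"
        assert fit.r_squared > 0.9999
        # phase recomputed from fitted params obeys the ordering invariant
        assert fit.phase.t1 < fit.phase.tmax < fit.phase.t2

    def test_noise_free_recovery_complement_target(self, ref_params):
        trace = sk.gen_fw_trace(ref_params, np.linspace(0, 24, 49))
        fit = sk.fit_fw(trace, FWFitConfig(fit_complement=True))
        assert fit.params.k1 == pytest.approx(ref_params.k1, rel=1e-4)
        assert fit.params.k2 == pytest.approx(ref_params.k2, rel=1e-4)

    def test_aggregate_trace_accepted(self, ref_params):
        trace = sk.gen_fw_trace(ref_params, np.linspace(0, 24, 49)).complement()
        fit = sk.fit_fw(trace)
        assert fit.params.k2 == pytest.approx(ref_params.k2, rel=1e-4)

    def test_flat_trace_flagged_poor(self):
        trace = sk.AggregationTrace(
            times=np.linspace(0, 24, 25), values=np.full(25, 2.0), a0=2.0
        )
        fit = sk.fit_fw(trace)
        assert fit.quality == "poor"
        assert fit.warnings

    def test_too_few_points_rejected(self, ref_params):
        trace = sk.gen_fw_trace(ref_params, np.linspace(0, 24, 5))
        with pytest.raises(ValueError):
            sk.fit_fw(trace)

    def test_out_of_range_concentration_rejected(self):
        trace = sk.AggregationTrace(
            times=np.linspace(0, 24, 10), values=np.full(10, 2.5), a0=2.0
        )
        with pytest.raises(ValueError):
            sk.fit_fw(trace)

    def test_deterministic(self, ref_params):
        trace = sk.gen_fw_trace(
            ref_params, np.linspace(0, 24, 49), sk.NoiseSpec(sigma=0.04, seed=7)
        )
        a = sk.fit_fw(trace, FWFitConfig(seed=3))
        b = sk.fit_fw(trace, FWFitConfig(seed=3))
        assert a.params == b.params

    def test_noisy_replicates_small_k2_bias(self, ref_params):
        # smoke-scale version of the acceptance simulation study
        times = np.linspace(0, 24, 49)
        rel = []
        for seed in range(20):
            trace = sk.gen_fw_trace(ref_params, times, sk.NoiseSpec(0.04, seed))
            fit = sk.fit_fw(trace)
            rel.append((fit.params.k2 - ref_params.k2) / ref_params.k2)
        assert abs(float(np.median(rel))) < 0.05

    def test_fit_amplitude_handles_incomplete_conversion(self, ref_params):
        times = np.linspace(0, 24, 49)
        pool = 1.6  # only 1.6 of 2.0 mM converts
        inner = sk.fw_monomer(FWParams(ref_params.k1, ref_params.k2, pool), times)
        trace = sk.AggregationTrace(times=times, values=(2.0 - pool) + inner, a0=2.0)
        fit = sk.fit_fw(trace, FWFitConfig(fit_amplitude=True))
        assert fit.amplitude == pytest.approx(pool, rel=1e-3)
        assert fit.quality == "good"
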