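"""Three-element Windkessel model: exact values, ODE consistency, properties."""

import numpy as np
import pytest

from aortohemo import windkessel as wk
from aortohemo.synthetic_cohort import FlowWaveform


def rk4_pressure(params, Q_fun, dQ_fun, P0, t_end, dt):
    """Independent oracle: classic RK4 on dP/dt = ((R1+R2)Q − P)/(R2C) + R1 dQ/dt."""
    R1, R2, C = params.R1, params.R2, params.C

    def f(t, P):
        return ((R1 + R2) * Q_fun(t) - P) / (R2 * C) + R1 * dQ_fun(t)

    n = int(round(t_end / dt))
    P = P0
    t = 0.0
    out = np.empty(n + 1)
    out[0] = P0
    for i in range(n):
        k1 = f(t, P)
        k2 = f(t + dt / 2, P + dt / 2 * k1)
        k3 = f(t + dt / 2, P + dt / 2 * k2)
        k4 = f(t + dt, P + dt * k3)
        P = P + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        out[i + 1] = P
    return out


class TestDefaults:
    @pytest.mark.parametrize("label, triple", [
        ("BA", (0.100, 2.480, 0.466)),
        ("LCCA", (0.110, 2.510, 0.443)),
        ("LSA", (0.150, 2.624, 0.437)),
        ("DAo", (0.120, 2.118, 0.421)),
    ])
    def test_packaged_outlet_parameters(self, label, triple):
        p = wk.default_params(label)
        assert (p.R1, p.R2, p.C) == triple
        assert p.label == label

    def test_unknown_label_names_valid_outlets(self):
        with pytest.raises(KeyError, match="BA.*DAo|valid labels"):
            wk.default_params("femoral")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            wk.WindkesselParams(R1=-0.1, R2=2.0, C=0.4)
        with pytest.raises(ValueError):
            wk.WindkesselParams(R1=0.1, R2=2.0, C=0.0)


class TestSteadyPressure:
    @pytest.mark.parametrize("label, Q, expected", [
        ("BA", 10.0, 25.8),
        ("BA", 0.0, 0.0),
        ("DAo", 5.0, 11.19),
    ])
    def test_steady_limit(self, label, Q, expected):
        assert wk.steady_pressure(wk.default_params(label), Q) == pytest.approx(expected)

    def test_nonfinite_flow_rejected(self):
        with pytest.raises(ValueError):
            wk.steady_pressure(wk.default_params("BA"), np.nan)


class TestStep:
    def test_fixed_point_of_constant_flow(self):
        p = wk.default_params("BA")
        Q = 12.5
        st = wk.WindkesselState(P=wk.steady_pressure(p, Q), Q=Q)
        nxt = wk.step(p, st, Q, dt=0.01)
        assert nxt.P == pytest.approx(st.P, abs=1e-12)
        assert nxt.t == pytest.approx(0.01)

    def test_single_step_from_rest(self):
        # independent hand evaluation of the backward-Euler update
        p = wk.default_params("BA")
        dt = 0.01
        beta = p.R2 * p.C / dt
        expected = (p.R1 + p.R2 + p.R1 * beta) * 10.0 / (1.0 + beta)
        st = wk.step(p, wk.WindkesselState(P=0.0, Q=0.0), 10.0, dt)
        assert st.P == pytest.approx(expected, rel=1e-14)
        assert st.P == pytest.approx(1.21275, abs=1e-4)

    def test_nonpositive_dt_rejected(self):
        p = wk.default_params("BA")
        with pytest.raises(ValueError):
            wk.step(p, wk.WindkesselState(P=0, Q=0), 1.0, dt=0.0)

    def test_backward_euler_converges_to_ode_with_order_one(self):
        """Stepped trajectory approaches the RK4 oracle as dt shrinks."""
        p = wk.default_params("BA")
        T = 0.8
        w = FlowWaveform(period=T, systolic_time=0.3 * T, stroke_volume=20.0)

        def dQ(t):
            ts = w.systolic_time
            ph = t % T
            return (w.peak_flow * np.pi / ts * np.cos(np.pi * ph / ts)
                    if ph < ts else 0.0)

        errs = []
        for n in (200, 400, 800):
            dt = T / n
            t = np.arange(n + 1) * dt
            P = wk.replay(p, w(t), dt, P0=0.0)
            ref = rk4_pressure(p, w, dQ, 0.0, T, dt / 100)[::100]
            errs.append(np.abs(P - ref).max())
        order = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        assert min(order) >= 0.9

    def test_printed_update_without_flow_term_is_inconsistent(self):
        """Dropping the Q_{n+1} factor breaks consistency with the ODE.

        The variant P' = ((R1+R2+R1β) − R1βQ_n + βP_n)/(1+β) (a constant
        first term instead of one proportional to the new flow) does not
        converge to the continuous solution under refinement, while the
        implemented update does.
        """
        p = wk.default_params("BA")
        T = 0.8
        w = FlowWaveform(period=T, systolic_time=0.3 * T, stroke_volume=20.0)

        def dQ(t):
            ts = w.systolic_time
            ph = t % T
            return (w.peak_flow * np.pi / ts * np.cos(np.pi * ph / ts)
                    if ph < ts else 0.0)

        errs_ok, errs_bad = [], []
        for n in (200, 800):
            dt = T / n
            t = np.arange(n + 1) * dt
            Q = w(t)
            beta = p.R2 * p.C / dt
            P_ok = wk.replay(p, Q, dt, P0=0.0)
            P_bad = np.zeros_like(Q)
            for i in range(1, len(Q)):
                P_bad[i] = ((p.R1 + p.R2 + p.R1 * beta) - p.R1 * beta * Q[i - 1]
                            + beta * P_bad[i - 1]) / (1 + beta)
            ref = rk4_pressure(p, w, dQ, 0.0, T, dt / 100)[::100]
            errs_ok.append(np.abs(P_ok - ref).max())
            errs_bad.append(np.abs(P_bad - ref).max())
        assert errs_ok[1] < 0.5 * errs_ok[0]          # refines
        assert errs_bad[1] > 10 * errs_ok[1]          # does not


class TestSimulate:
    def test_zero_inflow_decays_with_time_constant_r2c(self):
        """P(t) = P0·exp(−t/R2C); checked at t = R2C to 0.1%."""
        p = wk.default_params("BA")
        tau = p.R2 * p.C
        dt = tau / 1000.0
        states = wk.simulate(p, FlowWaveform(period=tau, systolic_time=0.3 * tau,
                                             stroke_volume=0.0),
                             dt=dt, n_cycles=1, P0=100.0)
        P_tau = states[1000].P
        assert states[1000].t == pytest.approx(tau)
        assert P_tau == pytest.approx(100.0 * np.exp(-1.0), rel=1e-3)

    def test_constant_inflow_relaxes_monotonically_to_steady(self):
        p = wk.default_params("BA")
        T = 2.0
        w = _ConstantQ(10.0, T)
        states = wk.simulate(p, w, dt=T / 2000, n_cycles=6, P0=0.0)
        P = np.array([s.P for s in states])
        assert np.all(np.diff(P) >= -1e-12)
        assert P[-1] == pytest.approx(25.8, rel=1e-3)

    def test_cycle_mean_pressure_matches_dc_resistance(self):
        """Derivative terms average out: mean P over a settled cycle equals
        (R1+R2)·mean Q to 0.5%."""
        p = wk.default_params("BA")
        w = FlowWaveform(period=0.6, systolic_time=0.18, stroke_volume=25.0)
        n_per = 600
        states = wk.simulate(p, w, dt=w.period / n_per, n_cycles=14)
        P = np.array([s.P for s in states])[-n_per:]
        assert P.mean() == pytest.approx((p.R1 + p.R2) * w.mean_flow, rel=5e-3)

    def test_pressure_linear_in_flow_scale(self):
        p = wk.default_params("LCCA")
        w1 = FlowWaveform(period=0.6, systolic_time=0.2, stroke_volume=10.0)
        w3 = FlowWaveform(period=0.6, systolic_time=0.2, stroke_volume=30.0)
        s1 = wk.simulate(p, w1, dt=1e-3, n_cycles=2, P0=0.0)
        s3 = wk.simulate(p, w3, dt=1e-3, n_cycles=2, P0=0.0)
        P1 = np.array([s.P for s in s1])
        P3 = np.array([s.P for s in s3])
        np.testing.assert_allclose(P3, 3.0 * P1, rtol=1e-12, atol=1e-12)

    def test_cycle_to_cycle_change_decreases(self):
        p = wk.default_params("DAo")
        w = FlowWaveform(period=0.5, systolic_time=0.15, stroke_volume=20.0)
        n_per = 500
        states = wk.simulate(p, w, dt=w.period / n_per, n_cycles=8, P0=0.0)
        P = np.array([s.P for s in states[1:]]).reshape(8, n_per)
        deltas = [np.abs(P[i + 1] - P[i]).max() for i in range(7)]
        assert all(d2 < d1 + 1e-12 for d1, d2 in zip(deltas[1:], deltas[2:]))

    def test_dt_larger_than_period_rejected(self):
        p = wk.default_params("BA")
        w = FlowWaveform(period=0.5, systolic_time=0.15, stroke_volume=20.0)
        with pytest.raises(ValueError):
            wk.simulate(p, w, dt=0.5, n_cycles=1)


class _ConstantQ:
    def __init__(self, flow, period):
        self.flow = flow
        self.period = period
        self.mean_flow = flow

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.flow)


class TestIO:
    def test_params_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "outlets.yaml"
        wk.write_params(path, wk.DEFAULT_OUTLETS)
        loaded = wk.read_params(path)
        assert loaded == wk.DEFAULT_OUTLETS

    def test_trace_export_columns(self, tmp_path):
        p = wk.default_params("BA")
        w = FlowWaveform(period=0.5, systolic_time=0.15, stroke_volume=20.0)
        df = wk.states_to_frame(wk.simulate(p, w, dt=1e-2, n_cycles=1))
        assert list(df.columns) == ["t_s", "Q_ml_s", "P_mmHg"]
        csv = tmp_path / "trace.csv"
        df.to_csv(csv, index=False)
        assert csv.read_text().startswith("t_s,Q_ml_s,P_mmHg")
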