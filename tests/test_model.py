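import numpy as np
import pytest

import drnlha
from drnlha import (
    FixedPointError,
    SlowCurrentState,
    StimulusProtocol,
    assemble_drive,
    instantaneous_rates,
    integrate,
    rate_transfer,
    slow_current_derivatives,
    slow_jacobian,
    steady_state,
)
from drnlha.model import TimeSeries

from conftest import BASELINE_RATES, KNOCKOUT_5HT_RATE


class TestRateTransfer:
    @pytest.mark.parametrize(
        "g, I, I0, expected",
        [
            (0.033, 151.47, 0.13, 4.99422),   # 5-HT baseline drive
            (0.205, -10.0, 0.0, 0.0),          # sub-threshold clamps
            (0.061, 246.0, 0.0, 15.006),       # DRN-GABA baseline drive
            (1.0, 0.5, 0.5, 0.0),              # exactly at threshold
        ],
    )
    def test_threshold_linear(self, g, I, I0, expected):
        assert rate_transfer(g, I, I0) == pytest.approx(expected, abs=1e-9)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            rate_transfer(0.033, float("nan"), 0.0)
        with pytest.raises(ValueError):
            rate_transfer(0.033, float("inf"), 0.0)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            rate_transfer(0.0, 10.0, 0.0)


class TestAssembleDrive:
    def test_baseline_fixed_point_drive(self, defaults, baseline):
        """5-HT drive decomposes as background - auto - GABA + orexin."""
        drives = assemble_drive(
            defaults,
            baseline.currents,
            gaba_rates=(baseline.rate("GABA_DRN"), baseline.rate("GABA_LHA")),
        )
        # 231.47 - 16*f_5HT - 5*f_GABA_DRN + 15*f_Ox
        expected = (
            231.47
            - 16 * BASELINE_RATES[0]
            - 5 * BASELINE_RATES[1]
            + 15 * BASELINE_RATES[2]
        )
        assert drives[0] == pytest.approx(expected, abs=1e-5)
        assert 151.5 < drives[0] < 151.9

    def test_zero_currents_leave_background(self, defaults):
        drives = assemble_drive(defaults, SlowCurrentState.zeros(), (0.0, 0.0))
        np.testing.assert_allclose(drives, defaults.background_array())

    def test_stimulus_adds_exactly_its_amplitude(self, defaults, baseline):
        gaba = (baseline.rate("GABA_DRN"), baseline.rate("GABA_LHA"))
        quiet = assemble_drive(defaults, baseline.currents, gaba)
        pulsed = assemble_drive(defaults, baseline.currents, gaba, stim=(150.0, 0.0))
        np.testing.assert_allclose(pulsed - quiet, [150.0, 0.0, 0.0, 0.0])

    def test_negative_inputs_rejected(self, defaults):
        bad = SlowCurrentState(np.full(8, -1.0))
        with pytest.raises(ValueError):
            assemble_drive(defaults, bad, (0.0, 0.0))


def _brute_force_rates(params, slow, stim=(0.0, 0.0), iters=5000):
    """Independent oracle: fixed-point iteration of the algebraic subsystem."""
    g = params.g_array()
    I0 = params.I0_array()
    f = np.zeros(4)
    for _ in range(iters):
        drives = assemble_drive(params, slow, (f[1], f[3]), stim)
        f = np.maximum(g * (drives - I0), 0.0)
    return f


class TestInstantaneousRates:
    def test_baseline_rates(self, defaults, baseline):
        sol = instantaneous_rates(defaults, baseline.currents)
        np.testing.assert_allclose(sol.rates, BASELINE_RATES, atol=1e-6)

    def test_zero_everything_gives_silence(self, defaults):
        silent = defaults.with_updates(
            {f"I_bg.{p}": 0.0 for p in ("5HT", "GABA_DRN", "Ox", "GABA_LHA")}
        )
        sol = instantaneous_rates(silent, SlowCurrentState.zeros())
        np.testing.assert_array_equal(sol.rates, 0.0)

    def test_gaba_closed_form(self, defaults):
        """f = g*X/(1 + g*J_self) on the active branch (LHA example)."""
        p = defaults.with_updates({"I_bg.GABA_LHA": 0.0})
        slow = SlowCurrentState.from_dict({"5HT_to_GABA_LHA": 50.9})
        sol = instantaneous_rates(p, slow)
        assert sol.rate("GABA_LHA") == pytest.approx(
            0.195 * 50.9 / (1 + 0.195 * 5.0), abs=1e-9
        )
        assert sol.rate("GABA_LHA") == pytest.approx(5.026, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_iteration(self, defaults, seed):
        rng = np.random.default_rng(seed)
        slow = SlowCurrentState(rng.uniform(0.0, 100.0, size=8))
        stim = (float(rng.uniform(0, 150)), float(rng.uniform(0, 150)))
        sol = instantaneous_rates(defaults, slow, stim)
        oracle = _brute_force_rates(defaults, slow, stim)
        np.testing.assert_allclose(sol.rates, oracle, atol=1e-9)


class TestSlowCurrentDerivatives:
    def test_steady_currents_have_zero_derivative(self, defaults, baseline):
        sol = instantaneous_rates(defaults, baseline.currents)
        d = slow_current_derivatives(defaults, baseline.currents, sol)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_relaxation_rates(self, defaults):
        """dI/dt = (-I + J*f_pre)/tau, per connection."""
        slow = SlowCurrentState.from_dict({"Ox_to_5HT": 150.0})
        rates = np.array([5.0, 0.0, 5.0, 0.0])  # f_5HT = f_Ox = 5 Hz
        d = slow_current_derivatives(defaults, slow, rates)
        idx = drnlha.SLOW_CONNECTIONS.index
        # 5HT auto: I=0, J=16, tau=1 -> +80 pA/s
        assert d[idx("5HT_auto")] == pytest.approx(80.0)
        # Ox->5HT: I=150, J=15, tau=60 -> (-150 + 75)/60
        assert d[idx("Ox_to_5HT")] == pytest.approx(-1.25)


class TestSteadyState:
    def test_baseline(self, baseline):
        np.testing.assert_allclose(baseline.rates, BASELINE_RATES, atol=1e-6)
        assert baseline.stable
        assert baseline.active == ("5HT", "GABA_DRN", "Ox", "GABA_LHA")

    def test_baseline_is_near_in_vivo_rates(self, baseline):
        np.testing.assert_allclose(
            baseline.rates, [5.0, 15.0, 5.0, 5.0], atol=0.2
        )

    def test_current_conservation_at_fixed_point(self, defaults, baseline):
        """Every slow current equals J times its presynaptic rate."""
        J8 = defaults.slow_J_array()
        pre = np.array([0, 2, 0, 2, 2, 0, 2, 0])
        np.testing.assert_allclose(
            baseline.currents.values, J8 * baseline.rates[pre], atol=1e-9
        )

    def test_orexin_knockout_rate(self, defaults):
        ko = defaults.with_updates(
            {f"J.{c}": 0.0
             for c in ("Ox_auto", "Ox_to_5HT", "Ox_to_GABA_DRN", "Ox_to_GABA_LHA")}
        )
        fp = steady_state(ko)
        assert fp.rate("5HT") == pytest.approx(KNOCKOUT_5HT_RATE, abs=1e-6)

    def test_zero_background_silent_and_stable(self, defaults):
        silent = defaults.with_updates(
            {f"I_bg.{p}": 0.0 for p in ("5HT", "GABA_DRN", "Ox", "GABA_LHA")}
        )
        fp = steady_state(silent)
        np.testing.assert_array_equal(fp.rates, 0.0)
        assert fp.stable

    def test_weak_lha_coupling_is_unstable(self, defaults):
        fp = steady_state(defaults.with_updates({"J.5HT_to_GABA_LHA": 0.4}))
        assert not fp.stable
        assert fp.max_real_eigenvalue > 0

    def test_simulation_cross_check_accepts_baseline(self, defaults):
        steady_state(defaults, verify_by_simulation=True)


class TestJacobian:
    def test_numerical_jacobian_agreement(self, defaults, baseline):
        """Analytic branch derivatives match central differences.

        Evaluated at an interior point of the all-active branch (the
        Jacobian is constant on a branch) so that finite differences never
        cross zero-current or threshold boundaries."""
        x = baseline.currents.values + 1.0
        state0 = SlowCurrentState(x)
        A = slow_jacobian(defaults, state0)
        eps = 1e-6
        num = np.zeros((8, 8))
        for m in range(8):
            for sgn, col in ((1, x.copy()), (-1, x.copy())):
                col[m] += sgn * eps
                state = SlowCurrentState(col)
                sol = instantaneous_rates(defaults, state)
                d = slow_current_derivatives(defaults, state, sol)
                num[:, m] += sgn * d / (2 * eps)
        np.testing.assert_allclose(A, num, atol=1e-6)


class TestIntegrate:
    def test_fixed_point_is_invariant(self, defaults, baseline):
        ts = integrate(defaults, T=100.0, dt=0.01, initial=baseline.currents)
        assert np.abs(ts.rates - baseline.rates).max() < 1e-6

    def test_converges_to_analytic_fixed_point(self, defaults, baseline):
        ts = integrate(defaults, T=2000.0, dt=0.01, initial="zero")
        np.testing.assert_allclose(ts.rates[-1], baseline.rates, atol=1e-3)

    def test_halving_dt_barely_changes_result(self, defaults, baseline):
        x0 = SlowCurrentState(baseline.currents.values * 1.5)
        a = integrate(defaults, T=50.0, dt=0.01, initial=x0).rates[-1]
        b = integrate(defaults, T=50.0, dt=0.005, initial=x0).rates[-1]
        assert np.abs(a - b).max() < 1e-3

    def test_rk2_second_order_convergence(self, defaults, baseline):
        """Global error shrinks ~4x per halving of dt (explicit midpoint)."""
        x0 = SlowCurrentState(baseline.currents.values * 1.5)
        ref = integrate(defaults, T=100.0, dt=0.001, initial=x0).rates[-1]
        errs = [
            np.abs(integrate(defaults, T=100.0, dt=dt, initial=x0).rates[-1] - ref).max()
            for dt in (0.1, 0.05, 0.025)
        ]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 3.0 < r < 5.0

    def test_rates_never_negative(self, defaults):
        ts = integrate(
            defaults.with_updates({"J.5HT_to_GABA_LHA": 0.2}),
            T=500.0, dt=0.01, initial="zero",
        )
        assert ts.rates.min() >= 0.0

    def test_too_coarse_dt_rejected(self, defaults):
        with pytest.raises(ValueError, match="too coarse"):
            integrate(defaults, T=1.0, dt=0.2)

    def test_time_grid(self, defaults, baseline):
        ts = integrate(defaults, T=1.0, dt=0.01, initial=baseline.currents)
        assert ts.times.size == 101
        assert ts.dt == pytest.approx(0.01)
        np.testing.assert_allclose(np.diff(ts.times), 0.01)


class TestTimeSeries:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            TimeSeries(
                np.arange(3.0), np.zeros((2, 4)), np.zeros((2, 4)), np.zeros((2, 8))
            )

    def test_nonuniform_times_rejected(self):
        t = np.array([0.0, 1.0, 3.0])
        with pytest.raises(ValueError):
            TimeSeries(t, np.zeros((3, 4)), np.zeros((3, 4)), np.zeros((3, 8)))

    def test_window_and_accessors(self, defaults, baseline):
        ts = integrate(defaults, T=10.0, dt=0.01, initial=baseline.currents)
        w = ts.window(5.0)
        assert w.times[0] == pytest.approx(5.0)
        assert w.rate("5HT").shape == w.times.shape
        df = ts.to_frame(include_currents=True)
        assert "f_5HT_Hz" in df.columns and "I_Ox_to_5HT_pA" in df.columns
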