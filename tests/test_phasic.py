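import numpy as np
import pytest

from drnlha import (
    ParameterError,
    TimescaleVariant,
    TimeSeries,
    UnstableBaselineError,
    fast_orexin_variant,
    fast_serotonin_variant,
    knockout,
    phasic_metrics,
    run_pulse,
    slow_orexin_variant,
    slow_serotonin_variant,
    steady_state,
)

from conftest import KNOCKOUT_5HT_RATE


class TestPhasicMetrics:
    def test_constant_series(self):
        t = np.arange(0.0, 10.0, 0.01)
        ts = TimeSeries.from_rates(t, np.full((t.size, 4), 5.0))
        m = phasic_metrics(ts, onset=1.0, duration=0.5)
        for arr in (m.baseline, m.peak, m.trough, m.rebound):
            np.testing.assert_allclose(arr, 5.0)
        np.testing.assert_allclose(m.fold, 1.0)

    def test_triangle_pulse_extrema(self):
        """Metrics recover the constructed extrema of a synthetic trace."""
        t = np.arange(0.0, 10.0, 0.1)
        f = np.full(t.size, 2.0)
        f[(t >= 1.0) & (t <= 1.5)] = np.linspace(2.0, 8.0, ((t >= 1.0) & (t <= 1.5)).sum())
        f[(t > 1.5) & (t < 3.0)] = 0.5   # undershoot
        f[(t >= 3.0) & (t < 4.0)] = 3.0  # rebound
        ts = TimeSeries.from_rates(t, f)
        m = phasic_metrics(ts, onset=1.0, duration=0.5)
        assert m.baseline[0] == pytest.approx(2.0)
        assert m.peak[0] == pytest.approx(8.0)
        assert m.fold[0] == pytest.approx(4.0)
        assert m.trough[0] == pytest.approx(0.5)
        assert m.rebound[0] == pytest.approx(3.0)

    def test_window_violations_rejected(self):
        t = np.arange(0.0, 1.0, 0.1)
        ts = TimeSeries.from_rates(t, np.zeros((t.size, 4)))
        with pytest.raises(ValueError):
            phasic_metrics(ts, onset=2.0, duration=0.5)


class TestSerotoninPulse:
    def test_pulse_roughly_doubles_5ht_rate(self, defaults):
        """150 pA for 0.5 s gives close to a 2-fold 5-HT peak."""
        _, m = run_pulse(defaults, "5HT")
        s = m.for_population("5HT")
        assert s["fold"] == pytest.approx(1.98943, abs=1e-3)
        assert s["peak"] == pytest.approx(s["baseline"] + 0.033 * 150.0, abs=0.01)

    def test_zero_amplitude_pulse_changes_nothing(self, defaults):
        _, m = run_pulse(defaults, "5HT", amplitude=0.0)
        np.testing.assert_allclose(m.fold, 1.0, atol=1e-9)
        np.testing.assert_allclose(m.peak, m.baseline, atol=1e-9)

    def test_5ht_undershoots_after_pulse(self, defaults):
        """Autoreceptor + local GABA feedback pull 5-HT below baseline."""
        _, m = run_pulse(defaults, "5HT")
        s = m.for_population("5HT")
        assert s["trough"] < s["baseline"] - 0.1

    def test_ox_suppressed_by_5ht_pulse(self, defaults):
        _, m = run_pulse(defaults, "5HT")
        ox = m.for_population("Ox")
        assert ox["trough"] < ox["baseline"]

    def test_5ht_trace_insensitive_to_5ht_timescales(self, defaults):
        """Fast vs slow 5-HT receptor variants overlap through the rebound."""
        ts_fast, _ = run_pulse(defaults, "5HT", fast_serotonin_variant())
        ts_slow, _ = run_pulse(defaults, "5HT", slow_serotonin_variant())
        window = ts_slow.times <= 6.0
        fast_on_slow_grid = np.interp(
            ts_slow.times[window], ts_fast.times, ts_fast.rate("5HT")
        )
        diff = np.abs(fast_on_slow_grid - ts_slow.rate("5HT")[window])
        assert diff.max() < 0.1

    def test_ox_rebound_higher_under_fast_5ht_receptors(self, defaults):
        """Fast 5-HT3A-like kinetics disinhibit Ox faster after the pulse."""
        _, m_fast = run_pulse(defaults, "5HT", fast_serotonin_variant())
        _, m_slow = run_pulse(defaults, "5HT", slow_serotonin_variant())
        assert (
            m_fast.for_population("Ox")["rebound"]
            > m_slow.for_population("Ox")["rebound"]
        )


class TestOrexinPulse:
    def test_ox_self_amplifies_during_stimulus(self, defaults):
        """With the reference (slow) kinetics the Ox2 autoreceptor keeps
        amplifying the Ox rate for the whole pulse."""
        ts, m = run_pulse(defaults, "Ox")
        during = (ts.times >= 1.0) & (ts.times < 1.5)
        f_ox = ts.rate("Ox")[during]
        assert np.all(np.diff(f_ox) >= 0)
        assert f_ox[-1] > f_ox[0]
        assert m.for_population("Ox")["fold"] > 2.0

    def test_fast_ox_to_5ht_excites_more_than_slow(self, defaults):
        _, m_fast = run_pulse(defaults, "Ox", fast_orexin_variant())
        _, m_slow = run_pulse(defaults, "Ox", slow_orexin_variant())
        fold_fast = m_fast.for_population("5HT")["fold"]
        fold_slow = m_slow.for_population("5HT")["fold"]
        assert fold_fast > fold_slow
        assert fold_fast > 1.1     # clear transient excitation
        assert fold_slow < 1.05    # hardly activated

    def test_post_stimulus_undershoots(self, defaults):
        _, m = run_pulse(defaults, "Ox", fast_orexin_variant())
        for pop in ("Ox", "5HT"):
            d = m.for_population(pop)
            assert d["trough"] < d["baseline"]

    def test_ox_to_drn_gaba_timescale_barely_matters(self, defaults):
        _, m5 = run_pulse(defaults, "Ox", TimescaleVariant("fast", {"Ox_to_GABA_DRN": 5.0}))
        _, m60 = run_pulse(defaults, "Ox", TimescaleVariant("slow", {"Ox_to_GABA_DRN": 60.0}))
        p5 = m5.for_population("5HT")["peak"]
        p60 = m60.for_population("5HT")["peak"]
        assert abs(p5 - p60) / p5 < 0.05

    def test_slow_variant_uses_long_horizon(self, defaults):
        ts, _ = run_pulse(defaults, "Ox", slow_orexin_variant())
        assert ts.times[-1] == pytest.approx(600.0)


class TestVariants:
    def test_override_must_target_dynamic_connection(self):
        with pytest.raises(ParameterError):
            TimescaleVariant("bad", {"GABA_LHA_to_Ox": 0.05})
        with pytest.raises(ParameterError):
            TimescaleVariant("bad", {"5HT_to_Ox": 0.0})

    def test_apply_sets_time_constants(self, defaults):
        p = fast_serotonin_variant().apply(defaults)
        assert p.connections["5HT_to_Ox"].tau == 0.05
        assert p.connections["5HT_to_GABA_LHA"].tau == 0.05
        # strengths untouched
        assert p.connections["5HT_to_Ox"].J == defaults.connections["5HT_to_Ox"].J


class TestRunPulsePreconditions:
    def test_unstable_baseline_rejected(self, defaults):
        p = defaults.with_updates({"J.5HT_to_GABA_LHA": 0.4})
        with pytest.raises(UnstableBaselineError):
            run_pulse(p, "5HT")

    def test_bad_target_rejected(self, defaults):
        with pytest.raises(ValueError):
            run_pulse(defaults, "GABA_DRN")


class TestKnockout:
    def test_remove_ox_lets_5ht_keep_firing(self, defaults):
        """Without any orexin drive, 5-HT settles near 3.5 Hz, not zero."""
        fp = steady_state(knockout(defaults, "remove_Ox"))
        assert fp.rate("5HT") == pytest.approx(KNOCKOUT_5HT_RATE, abs=1e-6)
        assert fp.rate("5HT") == pytest.approx(3.5, abs=0.2)

    def test_empty_custom_list_is_identity(self, defaults):
        assert knockout(defaults, []).to_flat_dict() == defaults.to_flat_dict()

    def test_autoreceptor_knockout_stabilizes_weak_coupling(self, defaults):
        p = defaults.with_updates({"J.5HT_to_GABA_LHA": 0.4})
        assert not steady_state(p).stable
        assert steady_state(knockout(p, "remove_Ox_autoreceptor")).stable

    def test_unknown_scenario_rejected(self, defaults):
        with pytest.raises(ParameterError):
            knockout(defaults, "remove_everything")
        with pytest.raises(ParameterError):
            knockout(defaults, ["not_a_connection"])
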