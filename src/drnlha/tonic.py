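"""Tonic (steady-state) analysis: parameter sweeps and the oscillation regime.

The circuit's stable fixed point loses stability through a Hopf bifurcation
when the 5HT -> GABA_LHA coupling becomes weak: the interplay of strong
GABAergic inhibition of Ox neurons with the excitatory Ox autoreceptor then
sustains slow rate oscillations (periods of minutes).  The boundary is
located by bisection on the leading eigenvalue of the slow-current Jacobian;
direct simulation serves as an independent cross-check.

Because the leading eigenvalue's real part is tiny (~1e-4 /s) near the
boundary, transients decay or grow over thousands of seconds there.  The
simulation-based classifier therefore does not threshold a single amplitude:
it kicks the system off its fixed point and compares the oscillation
amplitude in an early and a late window, calling the circuit oscillatory
only when the amplitude persists or grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model import SteadyState, TimeSeries, integrate, steady_state
from .params import CONNECTIONS, POPULATIONS, CircuitParameters, SlowCurrentState

__all__ = [
    "OscillationSummary",
    "SweepResult",
    "BoundaryError",
    "detect_oscillation",
    "classify_oscillation",
    "sweep_parameter",
    "oscillation_boundary",
]

#: Default peak-to-trough threshold (Hz) separating oscillation from
#: integrator-level ripple; well above RK2 noise (<1e-3 Hz), well below the
#: observed oscillation amplitudes (tens of Hz).
AMPLITUDE_THRESHOLD = 0.05


class BoundaryError(RuntimeError):
    """Bisection preconditions violated or criteria in disagreement."""


@dataclass
class OscillationSummary:
    """Scalar description of a (possible) rate oscillation."""

    oscillatory: bool
    amplitude: float          # peak-to-trough of f_5HT, Hz
    period: float | None = None  # s; None when not estimable

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.oscillatory and self.period is not None and self.period <= 0:
            raise ValueError("period must be positive")


def _estimate_period(times: np.ndarray, f: np.ndarray, prominence: float):
    peaks, _ = find_peaks(f, prominence=prominence)
    if len(peaks) < 3:
        return None
    return float(np.mean(np.diff(times[peaks])))


def detect_oscillation(
    ts: TimeSeries,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    transient: float = 1000.0,
    min_window: float = 1000.0,
) -> OscillationSummary:
    """Threshold the 5-HT peak-to-trough amplitude after a discarded transient.

    The trajectory must extend at least ``min_window`` seconds beyond the
    transient.  The period is the mean interval between successive maxima
    (at least three maxima required, found with prominence half the
    amplitude threshold).
    """
    span = ts.times[-1] - transient
    if span < min_window - 1e-9:
        raise ValueError(
            f"analysis window of {span:.0f} s after the {transient:.0f} s "
            f"transient is shorter than the required {min_window:.0f} s"
        )
    w = ts.window(transient)
    f = w.rate("5HT")
    amplitude = float(f.max() - f.min())
    oscillatory = amplitude > amplitude_threshold
    period = (
        _estimate_period(w.times, f, amplitude_threshold / 2)
        if oscillatory
        else None
    )
    return OscillationSummary(oscillatory, amplitude, period)


def classify_oscillation(
    params: CircuitParameters,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    kick: float = 0.05,
    horizon: float = 4000.0,
    window: float = 1000.0,
    dt: float = 0.01,
    persistence_ratio: float = 0.8,
) -> OscillationSummary:
    """Simulation-based oscillation classification.

    Starts from the analytic fixed point with its slow currents scaled by
    ``1 + kick`` (plus 1 pA so zero currents are also perturbed), integrates
    for ``horizon`` seconds, and compares the 5-HT peak-to-trough amplitude
    in the first and last ``window`` seconds.  Oscillatory means the late
    amplitude exceeds ``amplitude_threshold`` *and* at least
    ``persistence_ratio`` times the early amplitude, i.e. the deviation is
    not a decaying transient.
    """
    fp = steady_state(params)
    x0 = SlowCurrentState(fp.currents.values * (1.0 + kick) + 1.0)
    ts = integrate(params, T=horizon, dt=dt, initial=x0)
    early = ts.window(0.0, window).rate("5HT")
    late = ts.window(horizon - window).rate("5HT")
    a_early = float(np.ptp(early))
    a_late = float(np.ptp(late))
    oscillatory = (
        a_late > amplitude_threshold and a_late > persistence_ratio * a_early
    )
    w = ts.window(horizon - window)
    period = (
        _estimate_period(w.times, w.rate("5HT"), amplitude_threshold / 2)
        if oscillatory
        else None
    )
    return OscillationSummary(oscillatory, a_late if oscillatory else a_late, period)


def _apply_value(params: CircuitParameters, name: str, value: float):
    """Set connection ``name`` to ``value``.

    For the experimentally undetermined ``5HT_to_GABA_LHA`` link a negative
    value is interpreted as an inhibitory connection of strength ``|value|``.
    """
    if name not in CONNECTIONS:
        raise ValueError(f"unknown connection {name!r}")
    if name == "5HT_to_GABA_LHA":
        return params.with_updates(
            {f"J.{name}": abs(value), f"sign.{name}": 1 if value >= 0 else -1}
        )
    if value < 0:
        raise ValueError(f"{name}: strengths are nonnegative (sign is separate)")
    return params.with_updates({f"J.{name}": value})


@dataclass
class SweepResult:
    """Steady-state responses along a one-parameter grid."""

    parameter: str
    values: np.ndarray
    rates: np.ndarray            # (n, 4): fixed-point or window-mean rates
    stable: np.ndarray           # (n,) bool
    env_min: np.ndarray          # (n,) 5-HT envelope minimum, Hz
    env_max: np.ndarray          # (n,) 5-HT envelope maximum, Hz
    period: np.ndarray           # (n,) s, NaN where non-oscillatory
    errors: list = field(default_factory=list)

    def rate(self, population: str) -> np.ndarray:
        return self.rates[:, POPULATIONS.index(population)]

    def to_frame(self):
        import pandas as pd

        data = {"param_value": self.values}
        for j, p in enumerate(POPULATIONS):
            data[f"f_{p}"] = self.rates[:, j]
        data["stable"] = self.stable.astype(int)
        data["env_min_5HT"] = self.env_min
        data["env_max_5HT"] = self.env_max
        data["period_s"] = self.period
        return pd.DataFrame(data)


def sweep_parameter(
    params: CircuitParameters,
    name: str,
    grid,
    transient: float = 1000.0,
    window: float = 1000.0,
    dt: float = 0.01,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> SweepResult:
    """Steady states (and oscillation envelopes) along a connection-strength grid.

    Stable points are solved analytically.  Where the fixed point is
    unstable the circuit is integrated from zero currents for
    ``transient + window`` seconds, the transient discarded, and the 5-HT
    envelope plus mean rates over the remaining window recorded.  Per-point
    failures are recorded in ``errors`` without aborting the sweep.
    """
    values = np.asarray(list(grid), dtype=float)
    if values.size and np.any(np.diff(values) <= 0):
        raise ValueError("grid values must be strictly increasing")
    n = values.size
    rates = np.full((n, 4), np.nan)
    stable = np.zeros(n, dtype=bool)
    env_min = np.full(n, np.nan)
    env_max = np.full(n, np.nan)
    period = np.full(n, np.nan)
    errors: list[tuple[float, str]] = []

    for i, v in enumerate(values):
        try:
            p = _apply_value(params, name, v)
            fp = steady_state(p)
            stable[i] = fp.stable
            if fp.stable:
                rates[i] = fp.rates
                env_min[i] = env_max[i] = fp.rate("5HT")
            else:
                ts = integrate(p, T=transient + window, dt=dt, initial="zero")
                w = ts.window(transient)
                rates[i] = w.rates.mean(axis=0)
                f = w.rate("5HT")
                env_min[i] = f.min()
                env_max[i] = f.max()
                summ = detect_oscillation(
                    ts, amplitude_threshold, transient, min_window=window
                )
                if summ.period is not None:
                    period[i] = summ.period
        except Exception as exc:  # keep sweeping past pathological points
            errors.append((float(v), f"{type(exc).__name__}: {exc}"))

    return SweepResult(name, values, rates, stable, env_min, env_max, period, errors)


def oscillation_boundary(
    params: CircuitParameters,
    lo: float = 0.0,
    hi: float = 6.0,
    tol: float = 1e-3,
    cross_check: bool = True,
) -> float:
    """Locate the Hopf crossing in the 5HT -> GABA_LHA strength by bisection.

    The primary criterion is linear stability of the analytic fixed point
    (sign of the leading Jacobian eigenvalue's real part).  With
    ``cross_check`` the simulation-based classifier must agree with the
    eigenvalue criterion at both brackets; disagreement raises
    :class:`BoundaryError` rather than being silently resolved.  ``lo`` may
    be negative (inhibitory connection of strength ``|lo|``).
    """

    def unstable(v: float) -> bool:
        return not steady_state(_apply_value(params, "5HT_to_GABA_LHA", v)).stable

    u_lo, u_hi = unstable(lo), unstable(hi)
    if u_lo == u_hi:
        state = "unstable (oscillatory)" if u_lo else "stable"
        raise BoundaryError(
            f"no stability change in [{lo}, {hi}]: {state} throughout"
        )
    if cross_check:
        for v, expect in ((lo, u_lo), (hi, u_hi)):
            sim = classify_oscillation(_apply_value(params, "5HT_to_GABA_LHA", v))
            if sim.oscillatory != expect:
                raise BoundaryError(
                    f"eigenvalue and simulation criteria disagree at "
                    f"J={v}: eigenvalue says {'oscillatory' if expect else 'stable'}, "
                    f"simulation says {'oscillatory' if sim.oscillatory else 'stable'}"
                )

    a, b = float(lo), float(hi)
    u_a = u_lo
    while abs(b - a) > tol:
        mid = 0.5 * (a + b)
        if unstable(mid) == u_a:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
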