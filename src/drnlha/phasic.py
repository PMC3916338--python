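"""Phasic (pulse-stimulation) experiments and knockout scenarios.

Short current pulses (0.5 s, 150 pA by default) injected into the 5-HT or
Ox drive probe the transient behaviour of the circuit.  Because several
receptor families coexist on the same targets (fast ligand-gated channels
like 5-HT3A alongside slow G-protein-coupled receptors), the experiments are
run under *timescale variants* that set the relevant connection time
constants to a fast or a slow value; the two regimes are simulated
separately, never mixed.

Knockouts emulate peptide/gene removal by zeroing outgoing connection
strengths, e.g. removing every orexin effect from the circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SteadyState, TimeSeries, integrate, steady_state
from .params import (
    CONNECTIONS,
    POPULATIONS,
    SLOW_CONNECTIONS,
    CircuitParameters,
    ParameterError,
    StimulusProtocol,
)

__all__ = [
    "TimescaleVariant",
    "PhasicMetrics",
    "UnstableBaselineError",
    "fast_serotonin_variant",
    "slow_serotonin_variant",
    "fast_orexin_variant",
    "slow_orexin_variant",
    "run_pulse",
    "phasic_metrics",
    "knockout",
]

#: Effective timescale (s) of a fast ligand-gated (5-HT3A-like) channel.
FAST_LIGAND_GATED_TAU = 0.05


class UnstableBaselineError(RuntimeError):
    """Pulse experiments require a stable baseline fixed point."""


@dataclass
class TimescaleVariant:
    """Named set of time-constant overrides for dynamic connections."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for conn, tau in self.overrides.items():
            if conn not in SLOW_CONNECTIONS:
                raise ParameterError(
                    f"{conn!r} is not a dynamic connection; cannot retime it"
                )
            if not tau > 0:
                raise ParameterError(f"{conn}: tau must be positive")

    def apply(self, params: CircuitParameters) -> CircuitParameters:
        return params.with_updates(
            {f"tau.{c}": v for c, v in self.overrides.items()}
        )


def fast_serotonin_variant(tau: float = FAST_LIGAND_GATED_TAU) -> TimescaleVariant:
    """5-HT acts on the LHA through fast 5-HT3A-like channels."""
    return TimescaleVariant("fast", {"5HT_to_Ox": tau, "5HT_to_GABA_LHA": tau})


def slow_serotonin_variant(tau: float = 2.0) -> TimescaleVariant:
    """5-HT acts on the LHA through slow G-protein-coupled receptors."""
    return TimescaleVariant("slow", {"5HT_to_Ox": tau, "5HT_to_GABA_LHA": tau})


def fast_orexin_variant(tau: float = 5.0) -> TimescaleVariant:
    """Direct Ox -> 5-HT action on the faster measured timescale."""
    return TimescaleVariant("fast", {"Ox_to_5HT": tau})


def slow_orexin_variant(tau: float = 60.0) -> TimescaleVariant:
    """Direct Ox -> 5-HT action on the slow (reference) timescale."""
    return TimescaleVariant("slow", {"Ox_to_5HT": tau})


@dataclass
class PhasicMetrics:
    """Scalar transient metrics per population (arrays ordered as POPULATIONS).

    ``baseline`` is the pre-onset rate, ``peak`` the maximum during the
    stimulus, ``trough``/``rebound`` the post-offset minimum/maximum, and
    ``fold`` the peak-to-baseline ratio.
    """

    baseline: np.ndarray
    peak: np.ndarray
    fold: np.ndarray
    trough: np.ndarray
    rebound: np.ndarray

    def for_population(self, population: str) -> dict[str, float]:
        j = POPULATIONS.index(population)
        return {
            "baseline": float(self.baseline[j]),
            "peak": float(self.peak[j]),
            "fold": float(self.fold[j]),
            "trough": float(self.trough[j]),
            "rebound": float(self.rebound[j]),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "population": POPULATIONS,
                "baseline_Hz": self.baseline,
                "peak_Hz": self.peak,
                "fold": self.fold,
                "trough_Hz": self.trough,
                "rebound_Hz": self.rebound,
            }
        )


def phasic_metrics(ts: TimeSeries, onset: float, duration: float) -> PhasicMetrics:
    """Scalarize a pulse-response trajectory.

    Baseline is the last sample strictly before onset; peak is taken over
    the closed stimulus window, trough and rebound over everything after the
    stimulus ends.
    """
    t = ts.times
    pre = t < onset - 1e-12
    during = (t >= onset - 1e-12) & (t <= onset + duration + 1e-12)
    post = t > onset + duration + 1e-12
    if not pre.any() or not during.any() or not post.any():
        raise ValueError(
            "trajectory must include samples before, during and after the pulse"
        )
    baseline = ts.rates[pre][-1]
    peak = ts.rates[during].max(axis=0)
    trough = ts.rates[post].min(axis=0)
    rebound = ts.rates[post].max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(baseline > 0, peak / baseline, np.nan)
    return PhasicMetrics(baseline, peak, fold, trough, rebound)


def run_pulse(
    params: CircuitParameters,
    target: str,
    variant: TimescaleVariant | None = None,
    amplitude: float = 150.0,
    duration: float = 0.5,
    onset: float = 1.0,
    horizon: float | None = None,
    dt: float | None = None,
) -> tuple[TimeSeries, PhasicMetrics]:
    """Apply a rectangular pulse to ``target`` ("5HT" or "Ox") from rest.

    The circuit starts at its stable fixed point (an unstable baseline
    raises :class:`UnstableBaselineError`).  The horizon defaults to 60 s,
    stretched to 600 s when the direct Ox -> 5-HT connection acts on its
    slow (>= 30 s) timescale and Ox is stimulated, so the slow relaxation is
    fully captured.  ``dt`` defaults to 10 ms, refined as needed for fast
    timescale variants.
    """
    if target not in ("5HT", "Ox"):
        raise ValueError("pulse target must be '5HT' or 'Ox'")
    p = variant.apply(params) if variant is not None else params
    fp = steady_state(p)
    if not fp.stable:
        raise UnstableBaselineError(
            "baseline fixed point is unstable; phasic experiments require "
            "the default stable regime"
        )
    tau_min = p.slow_tau_array().min()
    if dt is None:
        dt = min(0.01, tau_min / 10.0)
    if horizon is None:
        tau_ox_5ht = p.connections["Ox_to_5HT"].tau
        horizon = 600.0 if (target == "Ox" and tau_ox_5ht >= 30.0) else 60.0
    protocol = StimulusProtocol(
        targets=(target,), amplitude=amplitude, onset=onset, duration=duration
    )
    ts = integrate(p, protocol, T=horizon, dt=dt, initial=fp.currents)
    return ts, phasic_metrics(ts, onset, duration)


#: Named knockout scenarios -> connections zeroed.
KNOCKOUT_SCENARIOS: dict[str, tuple[str, ...]] = {
    "remove_Ox": ("Ox_auto", "Ox_to_5HT", "Ox_to_GABA_DRN", "Ox_to_GABA_LHA"),
    "remove_Ox_autoreceptor": ("Ox_auto",),
}


def knockout(params: CircuitParameters, scenario) -> CircuitParameters:
    """Return parameters with the scenario's connection strengths zeroed.

    ``scenario`` is either a named scenario (``"remove_Ox"`` zeroes every
    orexin-sourced connection, ``"remove_Ox_autoreceptor"`` only the Ox2
    autoreceptor) or an explicit iterable of connection names.
    """
    if isinstance(scenario, str):
        if scenario not in KNOCKOUT_SCENARIOS:
            raise ParameterError(
                f"unknown knockout scenario {scenario!r}; "
                f"choose from {sorted(KNOCKOUT_SCENARIOS)} or pass connection names"
            )
        names = KNOCKOUT_SCENARIOS[scenario]
    else:
        names = tuple(scenario)
        for n in names:
            if n not in CONNECTIONS:
                raise ParameterError(f"unknown connection {n!r} in knockout list")
    return params.with_updates({f"J.{n}": 0.0 for n in names})
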