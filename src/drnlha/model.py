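"""Dynamics of the DRN-LHA circuit.

The model is a Wilson-Cowan-type mean-field rate model with a twist in the
timescale structure: population rates are threshold-linear, *instantaneous*
functions of their total drive (membrane dynamics, ~10 ms, are slaved to the
much slower receptor kinetics), while the eight non-GABA receptor currents
are first-order filtered with time constants of 1-60 s,

    tau_ji * dI_ji/dt = -I_ji + J_ji * f_i .

The four GABA_A synapses (~4 ms) are treated as instantaneous, which turns
each GABA population's rate into a closed-form algebraic function of the
slow currents.  The dynamical state is therefore the 8-vector of slow
currents; rates are re-resolved algebraically whenever needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _core
from .params import (
    CONNECTIONS,
    INSTANT_CONNECTIONS,
    POPULATIONS,
    SLOW_CONNECTIONS,
    CircuitParameters,
    ParameterError,
    SlowCurrentState,
    StimulusProtocol,
)

__all__ = [
    "RateSolution",
    "SteadyState",
    "TimeSeries",
    "FixedPointError",
    "IntegrationError",
    "rate_transfer",
    "assemble_drive",
    "instantaneous_rates",
    "slow_current_derivatives",
    "integrate",
    "steady_state",
    "slow_jacobian",
]

_POP_INDEX = {p: k for k, p in enumerate(POPULATIONS)}


class FixedPointError(RuntimeError):
    """No self-consistent active set, or analytic/simulated disagreement."""


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


def rate_transfer(g: float, I_total: float, I_0: float) -> float:
    """Threshold-linear f-I curve: ``f = g * [I_total - I_0]_+``.

    Parameters are the slope ``g`` (Hz/pA, positive), the total drive
    ``I_total`` (pA) and the current threshold ``I_0`` (pA).
    """
    if not (math.isfinite(g) and math.isfinite(I_total) and math.isfinite(I_0)):
        raise ValueError("rate_transfer requires finite inputs")
    if not g > 0:
        raise ValueError("f-I slope g must be positive")
    z = I_total - I_0
    return g * z if z > 0 else 0.0


@dataclass
class RateSolution:
    """Population rates (Hz) and total drives (pA) at one instant."""

    rates: np.ndarray
    drives: np.ndarray

    def rate(self, population: str) -> float:
        return float(self.rates[_POP_INDEX[population]])

    def drive(self, population: str) -> float:
        return float(self.drives[_POP_INDEX[population]])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(POPULATIONS, map(float, self.rates)))


def _unpack(params: CircuitParameters):
    return (
        params.g_array(),
        params.I0_array(),
        params.background_array(),
        params.slow_sign_array(),
        params.instant_J_array(),
        params.slow_J_array(),
        params.slow_tau_array(),
    )


def _stim_pair(stim) -> tuple[float, float]:
    if stim is None:
        return 0.0, 0.0
    if isinstance(stim, StimulusProtocol):
        raise TypeError(
            "pass the instantaneous stimulus as (I_stim_5HT, I_stim_Ox); "
            "use StimulusProtocol.amplitude_at(t, pop) to evaluate it"
        )
    s5, sox = stim
    return float(s5), float(sox)


def assemble_drive(
    params: CircuitParameters,
    slow: SlowCurrentState,
    gaba_rates: Sequence[float],
    stim=None,
) -> np.ndarray:
    """Total local drive per population, in pA.

    ``I_local = I_background + sum(sign * I_connection) + I_stim`` where the
    slow connections contribute their filtered currents and the GABA_A
    connections contribute ``J * f_GABA`` instantaneously.  ``gaba_rates``
    are ``(f_GABA_DRN, f_GABA_LHA)`` in Hz; ``stim`` is the instantaneous
    ``(I_stim_5HT, I_stim_Ox)`` pair in pA.
    """
    x = np.asarray(slow.values, dtype=float)
    if np.any(x < 0):
        raise ValueError("slow currents must be nonnegative")
    fd, fl = (float(v) for v in gaba_rates)
    if fd < 0 or fl < 0:
        raise ValueError("GABA rates must be nonnegative")
    ss, so = _stim_pair(stim)

    g, I0, bg, s8, jinst, _, _ = _unpack(params)
    drives = np.empty(4)
    drives[0] = bg[0] + s8[0] * x[0] + s8[1] * x[1] - jinst[0] * fd + ss
    drives[1] = bg[1] + s8[2] * x[2] + s8[3] * x[3] - jinst[1] * fd
    drives[2] = bg[2] + s8[4] * x[4] + s8[5] * x[5] - jinst[2] * fl + so
    drives[3] = bg[3] + s8[6] * x[6] + s8[7] * x[7] - jinst[3] * fl
    return drives


def instantaneous_rates(
    params: CircuitParameters, slow: SlowCurrentState, stim=None
) -> RateSolution:
    """Resolve all four rates given the slow currents.

    The GABA populations' instantaneous self-inhibition makes their rates
    implicit; on the active branch ``f = g*(X - J_self*f - I0)`` solves to
    ``f = g*(X - I0)/(1 + g*J_self)`` (the sub-threshold branch clamps to
    zero).  Uniqueness holds because ``1 + g*J_self > 0``.  The principal
    populations then follow explicitly.
    """
    x = np.asarray(slow.values, dtype=float)
    if np.any(x < 0):
        raise ValueError("slow currents must be nonnegative")
    ss, so = _stim_pair(stim)
    g, I0, bg, s8, jinst, _, _ = _unpack(params)
    f, iloc = _core.resolve_rates(x, g, I0, bg, s8, jinst, ss, so)
    return RateSolution(rates=np.asarray(f), drives=np.asarray(iloc))


def slow_current_derivatives(
    params: CircuitParameters, slow: SlowCurrentState, rates
) -> np.ndarray:
    """Time derivative (pA/s) of each of the eight slow currents."""
    x = np.asarray(slow.values, dtype=float)
    f = rates.rates if isinstance(rates, RateSolution) else np.asarray(rates, float)
    J8 = params.slow_J_array()
    tau8 = params.slow_tau_array()
    if np.any(tau8 <= 0):
        raise ParameterError("dynamic time constants must be positive")
    return np.asarray(_core.slow_derivatives(x, f, J8, tau8))


@dataclass
class TimeSeries:
    """Uniformly sampled trajectory of the circuit.

    ``rates`` and ``drives`` have shape (n, 4) in the order of
    :data:`~drnlha.params.POPULATIONS`; ``currents`` has shape (n, 8) in the
    order of :data:`~drnlha.params.SLOW_CONNECTIONS`.
    """

    times: np.ndarray
    rates: np.ndarray
    drives: np.ndarray
    currents: np.ndarray
    params: CircuitParameters | None = None
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.rates = np.asarray(self.rates, float)
        n = self.times.size
        if self.rates.shape != (n, 4):
            raise ValueError("rates must have shape (len(times), 4)")
        if self.drives.shape != (n, 4) or self.currents.shape != (n, 8):
            raise ValueError("inconsistent trajectory array shapes")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("times must increase with a constant step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def rate(self, population: str) -> np.ndarray:
        return self.rates[:, _POP_INDEX[population]]

    def window(self, t_start: float, t_stop: float | None = None) -> "TimeSeries":
        """Sub-trajectory with ``t_start <= t <= t_stop`` (inclusive)."""
        t_stop = self.times[-1] if t_stop is None else t_stop
        m = (self.times >= t_start - 1e-12) & (self.times <= t_stop + 1e-12)
        return TimeSeries(
            self.times[m], self.rates[m], self.drives[m], self.currents[m],
            self.params, self.protocol,
        )

    def final_state(self) -> SlowCurrentState:
        return SlowCurrentState(self.currents[-1].copy())

    def to_frame(self, include_currents: bool = False):
        import pandas as pd

        data = {"time_s": self.times}
        for j, p in enumerate(POPULATIONS):
            data[f"f_{p}_Hz"] = self.rates[:, j]
        if include_currents:
            for k, c in enumerate(SLOW_CONNECTIONS):
                data[f"I_{c}_pA"] = self.currents[:, k]
        return pd.DataFrame(data)

    @classmethod
    def from_rates(
        cls, times: np.ndarray, rates: np.ndarray, params=None, protocol=None
    ) -> "TimeSeries":
        """Build a rate-only trajectory (drives/currents zero-filled).

        Useful for constructing synthetic inputs to the analysis routines.
        """
        times = np.asarray(times, float)
        rates = np.asarray(rates, float)
        if rates.ndim == 1:  # a single population given: broadcast to 5HT slot
            full = np.zeros((times.size, 4))
            full[:, 0] = rates
            rates = full
        return cls(
            times, rates,
            np.zeros((times.size, 4)), np.zeros((times.size, 8)),
            params, protocol,
        )

    def plot(self, ax=None, populations: Sequence[str] = POPULATIONS):
        """Rate traces on a matplotlib axis (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for p in populations:
            ax.plot(self.times, self.rate(p), label=p)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("firing rate (Hz)")
        ax.legend(frameon=False)
        return ax


def integrate(
    params: CircuitParameters,
    protocol: StimulusProtocol | None = None,
    T: float = 100.0,
    dt: float = 0.01,
    initial: SlowCurrentState | str = "fixed_point",
) -> TimeSeries:
    """Integrate the slow-current system with the explicit midpoint rule.

    ``dt`` defaults to 10 ms and must not exceed one tenth of the smallest
    dynamic time constant.  ``initial`` is a :class:`SlowCurrentState`, the
    string ``"fixed_point"`` (currents of the analytic steady state, the
    default) or ``"zero"``.
    """
    params.validate()
    protocol = protocol or StimulusProtocol.none()
    if not T > 0 or not dt > 0:
        raise ValueError("T and dt must be positive")
    tau8 = params.slow_tau_array()
    if dt > tau8.min() / 10 + 1e-12:
        raise ValueError(
            f"dt={dt} too coarse for the fastest time constant "
            f"{tau8.min()} s (need dt <= tau_min/10)"
        )
    if isinstance(initial, str):
        if initial == "fixed_point":
            x0 = steady_state(params).currents.values.copy()
        elif initial == "zero":
            x0 = np.zeros(8)
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    else:
        x0 = np.asarray(initial.values, float).copy()

    n = int(round(T / dt))
    rates = np.empty((n + 1, 4))
    drives = np.empty((n + 1, 4))
    currents = np.empty((n + 1, 8))
    g, I0, bg, s8, jinst, J8, _ = _unpack(params)
    status = _core.rk2_integrate(
        x0, n, dt, g, I0, bg, s8, jinst, J8, tau8,
        "5HT" in protocol.targets, "Ox" in protocol.targets,
        float(protocol.amplitude), float(protocol.onset), float(protocol.duration),
        rates, drives, currents,
    )
    if status != 0:
        raise IntegrationError(
            "state became non-finite during integration (parameter pathology)"
        )
    times = dt * np.arange(n + 1)
    return TimeSeries(times, rates, drives, currents, params, protocol)


def integrate_to_convergence(
    params: CircuitParameters,
    dt: float = 0.01,
    initial: SlowCurrentState | str = "zero",
    tol: float = 1e-4,
    chunk: float = 2000.0,
    max_T: float = 20000.0,
) -> RateSolution:
    """Integrate in chunks until the rates stop changing.

    Convergence means the maximum rate change between consecutive chunk ends
    falls below ``tol`` Hz.  Raises :class:`IntegrationError` if ``max_T``
    seconds pass without settling (e.g. in an oscillatory regime).
    """
    state = initial
    prev = None
    elapsed = 0.0
    while elapsed < max_T:
        ts = integrate(params, T=chunk, dt=dt, initial=state)
        elapsed += chunk
        end = ts.rates[-1]
        if prev is not None and np.abs(end - prev).max() < tol:
            return RateSolution(rates=end.copy(), drives=ts.drives[-1].copy())
        prev = end
        state = ts.final_state()
    raise IntegrationError(
        f"rates did not settle to {tol} Hz within {max_T} s "
        "(oscillatory or marginally stable circuit?)"
    )


# ---------------------------------------------------------------------------
# Fixed points and linear stability
# ---------------------------------------------------------------------------


@dataclass
class SteadyState:
    """Analytic fixed point of the circuit with its linear stability."""

    rates: np.ndarray
    drives: np.ndarray
    currents: SlowCurrentState
    stable: bool
    eigenvalues: np.ndarray
    active: tuple[str, ...]

    def rate(self, population: str) -> float:
        return float(self.rates[_POP_INDEX[population]])

    @property
    def max_real_eigenvalue(self) -> float:
        return float(self.eigenvalues.real.max())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(POPULATIONS, map(float, self.rates)))


def _rest_reachable_active_set(g, b, M, iters=2000, alpha=0.2, tol=1e-10):
    """Active set of the fixed point reached from rest by the damped rate map.

    Iterates ``f <- f + alpha * (g*[b + M f]_+ - f)`` from silence.  The
    piecewise-linear system can be multistable (e.g. the supercritical Ox
    self-excitation, g*J_auto > 1, supports a self-sustained branch even
    with zero background drive); this picks the branch a simulation started
    at rest would land on.  Returns None if the iteration does not settle.
    """
    f = np.zeros(4)
    for _ in range(iters):
        nxt = f + alpha * (np.maximum(g * (b + M @ f), 0.0) - f)
        if np.abs(nxt - f).max() < tol:
            return tuple(j for j in range(4) if b[j] + (M @ nxt)[j] > 0)
        f = nxt
    return None


def _candidate_active_sets(first=None):
    # rest-reachable guess first (if any), then all-active, then by
    # decreasing size
    if first is not None:
        yield tuple(first)
    idx = range(4)
    yield tuple(idx)
    for size in (3, 2, 1, 0):
        for sub in itertools.combinations(idx, size):
            yield sub


def steady_state(
    params: CircuitParameters,
    verify_by_simulation: bool = False,
    tol: float = 1e-9,
    sim_tol: float = 1e-3,
) -> SteadyState:
    """Solve the piecewise-linear fixed-point system analytically.

    At a fixed point every slow current satisfies ``I = J * f_pre`` (the
    instantaneous GABA currents always do), so the rates obey
    ``f = g * [b + M f]_+`` with ``b = I_background - I_0`` and ``M`` the
    signed strength matrix.  The solver enumerates candidate active sets —
    first the set suggested by a damped iteration of the rate map from rest
    (which disambiguates multistable configurations), then all-active, then
    by decreasing size — solves the restricted linear system, and keeps the
    first branch that is self-consistent (active populations above
    threshold, clamped ones at or below it).

    Stability comes from the eigenvalues of the 8x8 Jacobian of the
    slow-current system with rates eliminated algebraically.  With
    ``verify_by_simulation`` a long RK2 integration from a perturbed start is
    required to land within ``sim_tol`` Hz of the analytic rates (only
    meaningful for stable fixed points).
    """
    params.validate()
    g = params.g_array()
    b = params.background_array() - params.I0_array()
    M = params.signed_connection_matrix()

    outcomes = []
    solution = None
    seen = set()
    guess = _rest_reachable_active_set(g, b, M)
    for active in _candidate_active_sets(guess):
        if active in seen:
            continue
        seen.add(active)
        a = list(active)
        f = np.zeros(4)
        if a:
            A = np.eye(len(a)) - (g[a, None] * M[np.ix_(a, a)])
            try:
                f[a] = np.linalg.solve(A, g[a] * b[a])
            except np.linalg.LinAlgError:
                outcomes.append((active, "singular restricted system"))
                continue
        drive_excess = b + M @ f  # I_local - I_0
        ok = all(f[j] > -tol for j in a) and all(
            drive_excess[j] <= tol for j in range(4) if j not in a
        )
        if ok:
            f = np.clip(f, 0.0, None)
            solution = (active, f, drive_excess)
            break
        outcomes.append((active, f"inconsistent (f={np.round(f, 4)})"))

    if solution is None:
        report = "; ".join(f"{act}: {msg}" for act, msg in outcomes)
        raise FixedPointError(f"no self-consistent active set found ({report})")

    active, f, _ = solution
    currents = SlowCurrentState(
        params.slow_J_array() * f[np.asarray(_core.PRE_INDEX)]
    )
    sol = instantaneous_rates(params, currents)
    eig = np.linalg.eigvals(slow_jacobian(params, currents))
    stable = bool(eig.real.max() < 0)

    if verify_by_simulation and stable:
        ts = integrate(
            params, T=2000.0, dt=min(0.01, params.slow_tau_array().min() / 10),
            initial=SlowCurrentState(currents.values * 1.05 + 1.0),
        )
        if np.abs(ts.rates[-1] - sol.rates).max() > sim_tol:
            raise FixedPointError(
                "analytic and simulated fixed points disagree: "
                f"{sol.rates} vs {ts.rates[-1]}"
            )

    return SteadyState(
        rates=sol.rates,
        drives=sol.drives,
        currents=currents,
        stable=stable,
        eigenvalues=eig,
        active=tuple(POPULATIONS[j] for j in active),
    )


def slow_jacobian(
    params: CircuitParameters, slow: SlowCurrentState
) -> np.ndarray:
    """Jacobian of the 8-dimensional slow-current flow at a given state.

    Uses the analytic derivative of the algebraically resolved rates on the
    local piecewise-linear branch (populations exactly at threshold are
    treated as inactive).
    """
    g, I0, bg, s8, jinst, J8, tau8 = _unpack(params)
    x = np.asarray(slow.values, float)
    sol = instantaneous_rates(params, SlowCurrentState(x))
    active = sol.drives - I0 > 0

    dfdx = np.zeros((4, 8))
    cD = g[1] / (1.0 + g[1] * jinst[1]) if active[1] else 0.0
    cL = g[3] / (1.0 + g[3] * jinst[3]) if active[3] else 0.0
    dfdx[1, 2] = s8[2] * cD
    dfdx[1, 3] = s8[3] * cD
    dfdx[3, 6] = s8[6] * cL
    dfdx[3, 7] = s8[7] * cL
    if active[0]:
        dfdx[0, 0] = g[0] * s8[0]
        dfdx[0, 1] = g[0] * s8[1]
        dfdx[0, :] -= g[0] * jinst[0] * dfdx[1, :]
    if active[2]:
        dfdx[2, 4] = g[2] * s8[4]
        dfdx[2, 5] = g[2] * s8[5]
        dfdx[2, :] -= g[2] * jinst[2] * dfdx[3, :]

    pre = np.asarray(_core.PRE_INDEX)
    A = (J8[:, None] * dfdx[pre, :] - np.eye(8)) / tau8[:, None]
    return A
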