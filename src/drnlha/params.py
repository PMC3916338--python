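"""Parameterization of the four-population DRN-LHA circuit.

The circuit couples the dorsal raphe nucleus (DRN: a serotonergic population
``5HT`` and a local GABAergic population ``GABA_DRN``) with the lateral
hypothalamus (LHA: an orexinergic population ``Ox`` and a local GABAergic
population ``GABA_LHA``).  Each population receives exactly three afferents:
a self-feedback connection plus projections from two other populations,
giving twelve connections in total.

Connections are split by receptor class.  The four GABA-mediated synapses are
ionotropic (GABA_A, ~4 ms) and treated as instantaneous; the remaining eight
connections act through slow (metabotropic or effective) receptor currents
governed by first-order kinetics with time constants of seconds to a minute.

Units follow the electrophysiology convention used throughout the package:
currents in pA, rates in Hz, connection strengths in pA/Hz, time in s, and
f-I slopes in Hz/pA.
"""

from __future__ import annotations

import copy as _copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Canonical population order used by every array-valued quantity.
POPULATIONS: tuple[str, ...] = ("5HT", "GABA_DRN", "Ox", "GABA_LHA")

#: The eight slow (dynamically filtered) connections, in canonical state order.
SLOW_CONNECTIONS: tuple[str, ...] = (
    "5HT_auto",          # 5-HT1A autoreceptor, inhibitory
    "Ox_to_5HT",         # orexin excitation of 5-HT neurons
    "5HT_to_GABA_DRN",   # 5-HT excitation of DRN GABAergic neurons
    "Ox_to_GABA_DRN",    # orexin excitation of DRN GABAergic neurons
    "Ox_auto",           # Ox2 autoreceptor, excitatory
    "5HT_to_Ox",         # 5-HT inhibition of orexin neurons
    "Ox_to_GABA_LHA",    # very weak; ~0 by default
    "5HT_to_GABA_LHA",   # sign experimentally undetermined; +1 by default
)

#: The four instantaneous (ionotropic GABA_A) connections.
INSTANT_CONNECTIONS: tuple[str, ...] = (
    "GABA_DRN_to_5HT",
    "GABA_DRN_to_GABA_DRN",
    "GABA_LHA_to_Ox",
    "GABA_LHA_to_GABA_LHA",
)

CONNECTIONS: tuple[str, ...] = SLOW_CONNECTIONS + INSTANT_CONNECTIONS

#: (source, target) for every connection.
CONNECTION_ENDPOINTS: dict[str, tuple[str, str]] = {
    "5HT_auto": ("5HT", "5HT"),
    "Ox_to_5HT": ("Ox", "5HT"),
    "5HT_to_GABA_DRN": ("5HT", "GABA_DRN"),
    "Ox_to_GABA_DRN": ("Ox", "GABA_DRN"),
    "Ox_auto": ("Ox", "Ox"),
    "5HT_to_Ox": ("5HT", "Ox"),
    "Ox_to_GABA_LHA": ("Ox", "GABA_LHA"),
    "5HT_to_GABA_LHA": ("5HT", "GABA_LHA"),
    "GABA_DRN_to_5HT": ("GABA_DRN", "5HT"),
    "GABA_DRN_to_GABA_DRN": ("GABA_DRN", "GABA_DRN"),
    "GABA_LHA_to_Ox": ("GABA_LHA", "Ox"),
    "GABA_LHA_to_GABA_LHA": ("GABA_LHA", "GABA_LHA"),
}

# Net effect of each connection on its target drive.  GABAergic synapses and
# the 5-HT1A-mediated connections (autoreceptor, 5-HT -> Ox) are inhibitory;
# orexin projections and the Ox2 autoreceptor are excitatory; 5-HT excites
# DRN GABAergic neurons.  The 5HT -> GABA_LHA sign is the one connection whose
# polarity is experimentally open; excitatory is the default working
# hypothesis (the inhibitory alternative produces large-amplitude slow
# oscillations never seen in vivo).
DEFAULT_SIGNS: dict[str, int] = {
    "5HT_auto": -1,
    "Ox_to_5HT": +1,
    "5HT_to_GABA_DRN": +1,
    "Ox_to_GABA_DRN": +1,
    "Ox_auto": +1,
    "5HT_to_Ox": -1,
    "Ox_to_GABA_LHA": +1,
    "5HT_to_GABA_LHA": +1,
    "GABA_DRN_to_5HT": -1,
    "GABA_DRN_to_GABA_DRN": -1,
    "GABA_LHA_to_Ox": -1,
    "GABA_LHA_to_GABA_LHA": -1,
}

# Reference defaults: connection strengths J (pA/Hz) derived from measured
# current amplitudes at the in-vivo baseline rates, slow time constants tau
# (s) from GIRK-current / firing-rate relaxation measurements.
_DEFAULT_J: dict[str, float] = {
    "5HT_auto": 16.0,
    "Ox_to_5HT": 15.0,
    "5HT_to_GABA_DRN": 10.0,
    "Ox_to_GABA_DRN": 5.0,
    "Ox_auto": 6.0,
    "5HT_to_Ox": 6.0,
    "Ox_to_GABA_LHA": 0.0,      # no Ox receptors found on LHA GABA neurons
    "5HT_to_GABA_LHA": 6.0,
    "GABA_DRN_to_5HT": 5.0,
    "GABA_DRN_to_GABA_DRN": 5.0,
    "GABA_LHA_to_Ox": 118.0,
    "GABA_LHA_to_GABA_LHA": 5.0,
}

_DEFAULT_TAU: dict[str, float] = {
    "5HT_auto": 1.0,
    "Ox_to_5HT": 60.0,
    "5HT_to_GABA_DRN": 60.0,
    "Ox_to_GABA_DRN": 5.0,
    "Ox_auto": 10.0,
    "5HT_to_Ox": 2.0,
    "Ox_to_GABA_LHA": 10.0,
    "5HT_to_GABA_LHA": 2.0,
}

# Threshold-linear f-I parameters and background drives per population.
_DEFAULT_G = {"5HT": 0.033, "GABA_DRN": 0.061, "Ox": 0.205, "GABA_LHA": 0.195}
_DEFAULT_I0 = {"5HT": 0.13, "GABA_DRN": 0.0, "Ox": 0.0, "GABA_LHA": 0.0}
_DEFAULT_BACKGROUND = {
    "5HT": 231.47,
    "GABA_DRN": 246.0,
    "Ox": 617.6,
    "GABA_LHA": 20.9,
}

#: Default phasic stimulation: amplitude chosen so a pulse roughly doubles
#: the 5-HT rate; duration on the behavioural timescale.
DEFAULT_STIMULUS_AMPLITUDE = 150.0  # pA
DEFAULT_STIMULUS_DURATION = 0.5     # s


class ParameterError(ValueError):
    """Raised for structurally invalid circuit parameters."""


@dataclass
class PopulationParams:
    """Threshold-linear f-I description of one population.

    Attributes
    ----------
    name : str
        One of :data:`POPULATIONS`.
    g : float
        f-I slope in Hz/pA; must be positive.
    I_0 : float
        Current threshold in pA.
    I_background : float
        Background current from the rest of the brain, in pA.
    """

    name: str
    g: float
    I_0: float
    I_background: float

    def validate(self) -> None:
        if self.name not in POPULATIONS:
            raise ParameterError(f"unknown population {self.name!r}")
        if not (self.g > 0):
            raise ParameterError(f"{self.name}: f-I slope g must be > 0")
        if self.I_0 < 0:
            raise ParameterError(f"{self.name}: threshold I_0 must be >= 0")
        if not math.isfinite(self.I_background):
            raise ParameterError(f"{self.name}: background current not finite")


@dataclass
class ConnectionParams:
    """One directed connection.

    ``J`` is the (nonnegative) connection strength in pA/Hz; the polarity of
    the postsynaptic effect is carried separately in ``sign``.  ``kinetics``
    is ``"dynamic"`` for slow receptor currents (first-order filtered with
    time constant ``tau``) and ``"instantaneous"`` for the four ionotropic
    GABA synapses (``tau`` is then ``None``).
    """

    source: str
    target: str
    J: float
    sign: int
    kinetics: str
    tau: float | None = None

    @property
    def name(self) -> str:
        if self.source == self.target:
            if self.source in ("5HT", "Ox"):
                return f"{self.source}_auto"
            return f"{self.source}_to_{self.target}"
        return f"{self.source}_to_{self.target}"

    def validate(self) -> None:
        name = self.name
        if name not in CONNECTION_ENDPOINTS:
            raise ParameterError(f"unknown connection {name!r}")
        if self.J < 0:
            raise ParameterError(f"{name}: J must be >= 0 (sign is separate)")
        if self.sign not in (-1, 1):
            raise ParameterError(f"{name}: sign must be +1 or -1")
        if self.kinetics == "dynamic":
            if name not in SLOW_CONNECTIONS:
                raise ParameterError(f"{name}: GABA_A synapses are instantaneous")
            if self.tau is None or not (self.tau > 0):
                raise ParameterError(f"{name}: dynamic connection needs tau > 0")
        elif self.kinetics == "instantaneous":
            if name not in INSTANT_CONNECTIONS:
                raise ParameterError(
                    f"{name}: only GABA_A-mediated connections are instantaneous"
                )
        else:
            raise ParameterError(f"{name}: bad kinetics {self.kinetics!r}")


@dataclass
class StimulusProtocol:
    """Rectangular current pulse injected into 5-HT and/or Ox drives.

    An empty ``targets`` tuple describes the unstimulated condition.
    """

    targets: tuple[str, ...] = ()
    amplitude: float = DEFAULT_STIMULUS_AMPLITUDE
    onset: float = 0.0
    duration: float = DEFAULT_STIMULUS_DURATION

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        for t in self.targets:
            if t not in ("5HT", "Ox"):
                raise ParameterError(
                    f"stimulus target must be '5HT' or 'Ox', got {t!r}"
                )
        if not math.isfinite(self.amplitude):
            raise ParameterError("stimulus amplitude must be finite")
        if self.targets and not (self.duration > 0):
            raise ParameterError("stimulus duration must be > 0")
        if self.onset < 0:
            raise ParameterError("stimulus onset must be >= 0")

    def active(self, t: float) -> bool:
        """Whether the pulse is on at time ``t`` (half-open window)."""
        return bool(self.targets) and self.onset <= t < self.onset + self.duration

    def amplitude_at(self, t: float, population: str) -> float:
        if population in self.targets and self.active(t):
            return self.amplitude
        return 0.0

    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls(targets=())


@dataclass
class CircuitParameters:
    """Complete parameter set of the four-population circuit."""

    populations: dict[str, PopulationParams]
    connections: dict[str, ConnectionParams]

    # -- construction ---------------------------------------------------

    @classmethod
    def defaults(cls) -> "CircuitParameters":
        """The reference parameter set (see :func:`default_parameters`)."""
        pops = {
            name: PopulationParams(
                name, _DEFAULT_G[name], _DEFAULT_I0[name], _DEFAULT_BACKGROUND[name]
            )
            for name in POPULATIONS
        }
        conns = {}
        for name in CONNECTIONS:
            src, tgt = CONNECTION_ENDPOINTS[name]
            dyn = name in SLOW_CONNECTIONS
            conns[name] = ConnectionParams(
                source=src,
                target=tgt,
                J=_DEFAULT_J[name],
                sign=DEFAULT_SIGNS[name],
                kinetics="dynamic" if dyn else "instantaneous",
                tau=_DEFAULT_TAU[name] if dyn else None,
            )
        return cls(populations=pops, connections=conns)

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if set(self.populations) != set(POPULATIONS):
            raise ParameterError(
                f"expected populations {POPULATIONS}, got {tuple(self.populations)}"
            )
        if set(self.connections) != set(CONNECTIONS):
            missing = set(CONNECTIONS) - set(self.connections)
            extra = set(self.connections) - set(CONNECTIONS)
            raise ParameterError(
                f"bad connection set (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for p in self.populations.values():
            p.validate()
        for c in self.connections.values():
            c.validate()
        # every population has exactly three afferents: self + two others
        for pop in POPULATIONS:
            aff = [c for c in self.connections.values() if c.target == pop]
            if len(aff) != 3 or not any(c.source == pop for c in aff):
                raise ParameterError(f"{pop}: expected self + 2 other afferents")

    # -- convenience accessors -------------------------------------------

    @property
    def sign_5HT_to_GABA_LHA(self) -> int:
        """Polarity of the experimentally undetermined 5HT -> GABA_LHA link."""
        return self.connections["5HT_to_GABA_LHA"].sign

    @sign_5HT_to_GABA_LHA.setter
    def sign_5HT_to_GABA_LHA(self, value: int) -> None:
        if value not in (-1, 1):
            raise ParameterError("sign must be +1 or -1")
        self.connections["5HT_to_GABA_LHA"].sign = value

    def copy(self) -> "CircuitParameters":
        return _copy.deepcopy(self)

    def with_updates(self, updates: Mapping[str, float]) -> "CircuitParameters":
        """Return a copy with dotted-key overrides applied.

        Keys use the flat config-file grammar, e.g. ``"J.5HT_to_GABA_LHA"``,
        ``"tau.Ox_to_5HT"``, ``"g.5HT"``, ``"I0.GABA_DRN"``, ``"I_bg.Ox"``,
        ``"sign.5HT_to_GABA_LHA"``.
        """
        new = self.copy()
        for key, value in updates.items():
            new._set_dotted(key, value)
        new.validate()
        return new

    def _set_dotted(self, key: str, value: float) -> None:
        try:
            prefix, rest = key.split(".", 1)
        except ValueError:
            raise ParameterError(f"malformed parameter key {key!r}") from None
        if prefix == "J":
            conn = self._connection(rest, key)
            conn.J = float(value)
        elif prefix == "tau":
            conn = self._connection(rest, key)
            if conn.kinetics != "dynamic":
                raise ParameterError(f"{key}: instantaneous connections have no tau")
            conn.tau = float(value)
        elif prefix == "sign":
            conn = self._connection(rest, key)
            conn.sign = int(value)
        elif prefix in ("g", "I0", "I_bg"):
            if rest not in self.populations:
                raise ParameterError(f"unknown population in key {key!r}")
            pop = self.populations[rest]
            if prefix == "g":
                pop.g = float(value)
            elif prefix == "I0":
                pop.I_0 = float(value)
            else:
                pop.I_background = float(value)
        else:
            raise ParameterError(f"unknown parameter key {key!r}")

    def _connection(self, name: str, key: str) -> ConnectionParams:
        if name not in self.connections:
            raise ParameterError(f"unknown connection in key {key!r}")
        return self.connections[name]

    def to_flat_dict(self) -> dict[str, float]:
        """All parameters under their dotted config keys, canonical order."""
        out: dict[str, float] = {}
        for name in POPULATIONS:
            out[f"g.{name}"] = self.populations[name].g
        for name in POPULATIONS:
            out[f"I0.{name}"] = self.populations[name].I_0
        for name in POPULATIONS:
            out[f"I_bg.{name}"] = self.populations[name].I_background
        for name in CONNECTIONS:
            out[f"J.{name}"] = self.connections[name].J
        for name in SLOW_CONNECTIONS:
            out[f"tau.{name}"] = self.connections[name].tau
        out["sign.5HT_to_GABA_LHA"] = float(self.sign_5HT_to_GABA_LHA)
        return out

    # -- array views used by the numerical core ---------------------------

    def g_array(self) -> np.ndarray:
        return np.array([self.populations[p].g for p in POPULATIONS])

    def I0_array(self) -> np.ndarray:
        return np.array([self.populations[p].I_0 for p in POPULATIONS])

    def background_array(self) -> np.ndarray:
        return np.array([self.populations[p].I_background for p in POPULATIONS])

    def slow_J_array(self) -> np.ndarray:
        return np.array([self.connections[c].J for c in SLOW_CONNECTIONS])

    def slow_tau_array(self) -> np.ndarray:
        return np.array([self.connections[c].tau for c in SLOW_CONNECTIONS])

    def slow_sign_array(self) -> np.ndarray:
        return np.array(
            [self.connections[c].sign for c in SLOW_CONNECTIONS], dtype=float
        )

    def instant_J_array(self) -> np.ndarray:
        return np.array([self.connections[c].J for c in INSTANT_CONNECTIONS])

    def signed_connection_matrix(self) -> np.ndarray:
        """4x4 matrix M with M[j, i] = sign * J of the i -> j connection.

        At a fixed point every slow current equals J times its presynaptic
        rate and the instantaneous currents always do, so the local drive is
        ``I_background + M @ f`` (plus any stimulus).
        """
        M = np.zeros((4, 4))
        idx = {p: k for k, p in enumerate(POPULATIONS)}
        for c in self.connections.values():
            M[idx[c.target], idx[c.source]] += c.sign * c.J
        return M


def default_parameters() -> CircuitParameters:
    """Return the reference (Table-derived) circuit parameter set.

    Connection strengths come from measured postsynaptic current amplitudes
    divided by the in-vivo baseline presynaptic rates, time constants from
    receptor-current relaxation measurements, and background currents are the
    free parameters tuned so the baseline rates are ~5 Hz (5-HT, Ox,
    LHA-GABA) and ~15 Hz (DRN-GABA).
    """
    p = CircuitParameters.defaults()
    p.validate()
    return p


@dataclass
class SlowCurrentState:
    """Vector of the eight dynamically filtered receptor currents (pA).

    Ordered as :data:`SLOW_CONNECTIONS`.  Each current relaxes toward
    ``J * f_presynaptic`` with its own time constant, so a state initialized
    nonnegative stays nonnegative under nonnegative presynaptic rates.
    """

    values: np.ndarray = field(
        default_factory=lambda: np.zeros(len(SLOW_CONNECTIONS))
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SLOW_CONNECTIONS),):
            raise ParameterError(
                f"slow-current state must have shape ({len(SLOW_CONNECTIONS)},)"
            )

    def __getitem__(self, connection: str) -> float:
        return float(self.values[SLOW_CONNECTIONS.index(connection)])

    @classmethod
    def zeros(cls) -> "SlowCurrentState":
        return cls()

    @classmethod
    def from_dict(cls, currents: Mapping[str, float]) -> "SlowCurrentState":
        vals = np.zeros(len(SLOW_CONNECTIONS))
        for name, v in currents.items():
            if name not in SLOW_CONNECTIONS:
                raise ParameterError(f"unknown dynamic connection {name!r}")
            vals[SLOW_CONNECTIONS.index(name)] = v
        return cls(vals)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SLOW_CONNECTIONS, map(float, self.values)))

    def copy(self) -> "SlowCurrentState":
        return SlowCurrentState(self.values.copy())
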