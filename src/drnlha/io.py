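"""Plain-text serialization: parameter config files and result tables.

Parameter files are flat ``key = value`` text with one dotted key per model
symbol (``J.5HT_to_GABA_LHA = 6.0``, ``tau.Ox_to_5HT = 60.0``, ``g.5HT =
0.033``, ``I0.5HT = 0.13``, ``I_bg.Ox = 617.6``,
``sign.5HT_to_GABA_LHA = 1``).  ``#`` starts a comment.  The writer emits
keys in canonical order with shortest-round-trip float formatting, so
``load -> save`` is byte-identical for canonical files.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np

from .model import TimeSeries
from .params import CircuitParameters, ParameterError, default_parameters
from .tonic import SweepResult

__all__ = [
    "load_parameters",
    "save_parameters",
    "default_parameter_file_text",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_sweep_tsv",
]

log = logging.getLogger("drnlha")

_HEADER = "# drnlha circuit parameters (pA, Hz, s; J in pA/Hz, g in Hz/pA)"


def _format_value(key: str, value: float) -> str:
    if key.startswith("sign."):
        return str(int(value))
    return repr(float(value))


def save_parameters(
    params: CircuitParameters, path, extra_header: str | None = None
) -> None:
    """Write a canonical parameter file (see module docstring)."""
    lines = [_HEADER]
    if extra_header:
        lines.append(f"# {extra_header}")
    for key, value in params.to_flat_dict().items():
        lines.append(f"{key} = {_format_value(key, value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_parameters(text: str, source: str = "<string>") -> CircuitParameters:
    """Parse parameter text; unknown keys are rejected with their line number."""
    updates: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{source}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        try:
            num = float(value.strip())
        except ValueError:
            raise ParameterError(
                f"{source}:{lineno}: non-numeric value for {key!r}"
            ) from None
        if key in updates:
            raise ParameterError(f"{source}:{lineno}: duplicate key {key!r}")
        updates[key] = num

    base = default_parameters()
    known = set(base.to_flat_dict())
    unknown = [k for k in updates if k not in known]
    if unknown:
        raise ParameterError(
            f"{source}: unknown parameter key(s) {sorted(unknown)}"
        )
    missing = known - set(updates)
    if missing:
        log.info(
            "%s: %d key(s) missing, filled from defaults", source, len(missing)
        )
    return base.with_updates(updates)


def load_parameters(path) -> CircuitParameters:
    """Load a parameter file; missing keys fall back to the defaults."""
    p = Path(path)
    return parse_parameters(p.read_text(), source=str(p))


def default_parameter_file_text() -> str:
    """Text of the shipped reference parameter file."""
    return (
        resources.files("drnlha").joinpath("data/defaults.cfg").read_text()
    )


# ---------------------------------------------------------------------------
# Time series and sweep tables
# ---------------------------------------------------------------------------

from .params import POPULATIONS, SLOW_CONNECTIONS  # noqa: E402


def write_timeseries_csv(ts: TimeSeries, path, include_currents: bool = False):
    """CSV with ``time_s`` plus per-population rate columns (6 decimals);
    per-connection slow-current columns (3 decimals) are optional."""
    cols = ["time_s"] + [f"f_{p}_Hz" for p in POPULATIONS]
    if include_currents:
        cols += [f"I_{c}_pA" for c in SLOW_CONNECTIONS]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for i, t in enumerate(ts.times):
            row = [f"{t:.6f}"] + [f"{v:.6f}" for v in ts.rates[i]]
            if include_currents:
                row += [f"{v:.3f}" for v in ts.currents[i]]
            fh.write(",".join(row) + "\n")


def read_timeseries_csv(path) -> TimeSeries:
    """Inverse of :func:`write_timeseries_csv` (drives are not serialized)."""
    import pandas as pd

    df = pd.read_csv(path)
    n = len(df)
    rates = df[[f"f_{p}_Hz" for p in POPULATIONS]].to_numpy()
    current_cols = [f"I_{c}_pA" for c in SLOW_CONNECTIONS]
    if all(c in df.columns for c in current_cols):
        currents = df[current_cols].to_numpy()
    else:
        currents = np.zeros((n, 8))
    return TimeSeries(
        df["time_s"].to_numpy(), rates, np.zeros((n, 4)), currents
    )


def write_sweep_tsv(result: SweepResult, path) -> None:
    """TSV table of a one-parameter sweep (rates at 6 decimals)."""
    cols = (
        ["param_value"]
        + [f"f_{p}" for p in POPULATIONS]
        + ["stable", "env_min_5HT", "env_max_5HT", "period_s"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, v in enumerate(result.values):
            row = [f"{v:.6g}"]
            row += [f"{x:.6f}" for x in result.rates[i]]
            row.append(str(int(result.stable[i])))
            row += [
                f"{result.env_min[i]:.6f}",
                f"{result.env_max[i]:.6f}",
                f"{result.period[i]:.6f}",
            ]
            fh.write("\t".join(row) + "\n")
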