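"""Regenerate the package's headline figures (steady-state sweeps, the
oscillation regime, and pulse responses) as PNGs.

Not part of the tested API; run as  python examples/make_figures.py [outdir]
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import drnlha as d

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/figures")
outdir.mkdir(parents=True, exist_ok=True)
params = d.default_parameters()

# steady-state rates vs the 5HT -> GABA_LHA strength
sweep = d.sweep_parameter(params, "5HT_to_GABA_LHA", np.arange(1.0, 21.0))
fig, ax = plt.subplots()
for pop in d.POPULATIONS:
    ax.plot(sweep.values, sweep.rate(pop), label=pop)
ax.set_xlabel("J 5HT->GABA_LHA (pA/Hz)")
ax.set_ylabel("steady-state rate (Hz)")
ax.legend(frameon=False)
fig.savefig(outdir / "sweep_5HT_to_GABA_LHA.png", dpi=150)

# oscillation envelope across the Hopf boundary
grid = np.round(np.arange(0.1, 1.6, 0.1), 10)
env = d.sweep_parameter(params, "5HT_to_GABA_LHA", grid)
fig, ax = plt.subplots()
ax.fill_between(env.values, env.env_min, env.env_max, alpha=0.3, label="5HT envelope")
ax.plot(env.values, env.rate("5HT"), "k", label="5HT mean/fixed point")
j_star = d.oscillation_boundary(params, 0.0, 6.0, cross_check=False)
ax.axvline(j_star, ls="--", c="gray", label=f"Hopf at {j_star:.3f}")
ax.set_xlabel("J 5HT->GABA_LHA (pA/Hz)")
ax.set_ylabel("f_5HT (Hz)")
ax.legend(frameon=False)
fig.savefig(outdir / "oscillation_boundary.png", dpi=150)

# pulse responses
fig, axes = plt.subplots(1, 2, figsize=(10, 4))
for ax, target in zip(axes, ("5HT", "Ox")):
    ts, _ = d.run_pulse(params, target, horizon=20.0)
    for pop in ("5HT", "Ox"):
        ax.plot(ts.times, ts.rate(pop), label=pop)
    ax.set_title(f"150 pA, 0.5 s pulse on {target}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (Hz)")
    ax.legend(frameon=False)
fig.tight_layout()
fig.savefig(outdir / "pulse_responses.png", dpi=150)
print(f"wrote figures to {outdir}")
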