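# drnlha

A mean-field firing-rate model of the coupled **dorsal raphe nucleus (DRN)**
and **lateral hypothalamus (LHA)** — the circuit through which serotonin
(5-HT) and orexin/hypocretin (Ox) regulate each other. The package is aimed
at computational neuroscientists studying neuromodulator circuit dynamics:
it simulates the circuit, solves its tonic steady states analytically,
locates the slow-oscillation (Hopf) boundary, and runs phasic
pulse-stimulation and knockout experiments.

## The model

Four neural populations are reduced to mean-field units: serotonergic
(`5HT`) and GABAergic (`GABA_DRN`) neurons in the DRN, orexinergic (`Ox`)
and GABAergic (`GABA_LHA`) neurons in the LHA. Each population has a
threshold-linear f-I curve

    f_j = g_j [ I_local,j − I_0,j ]₊ ,

with the local drive assembled from a background current, a signed sum of
synaptic currents (self-feedback plus two afferents per population), and an
optional stimulus pulse. Membrane dynamics (~10 ms) are slaved to the far
slower receptor kinetics, so rates are instantaneous functions of the
currents. The four GABA_A synapses (~4 ms) equilibrate instantly
(I = J·f), while the eight remaining connections act through slow
(metabotropic or effective) receptor currents,

    τ_ji · dI_ji/dt = −I_ji + J_ji · f_i ,

with time constants from 1 s (5-HT1A autoreceptor) to 60 s (Ox effect on
5-HT neurons). Connection strengths J (pA/Hz) derive from measured
postsynaptic current amplitudes at in-vivo baseline rates; background
currents are calibrated so the baseline is ~5 Hz for 5-HT, Ox and LHA-GABA
and ~15 Hz for DRN-GABA. Integration uses the explicit midpoint (RK2) rule
at a 10 ms step; steady states and their linear stability come from the
exact piecewise-linear fixed-point solve and the 8×8 Jacobian of the
slow-current system.

## Worked example

```python
>>> import drnlha as d
>>> params = d.default_parameters()          # reference parameter set
>>> fp = d.steady_state(params)
>>> fp.as_dict()
{'5HT': 5.002899085763518, 'GABA_DRN': 15.011683654621882,
 'Ox': 5.024520416281381, 'GABA_LHA': 5.027287053338386}
>>> fp.stable
True
```

The tonic baseline sits at the in-vivo rates (~5/15/5/5 Hz). Weakening the
5HT → GABA_LHA coupling destabilizes it through a Hopf bifurcation into
slow oscillations (periods of minutes):

```python
>>> d.oscillation_boundary(params, 0.0, 6.0, tol=1e-3, cross_check=False)
0.8045654296875    # pA/Hz; oscillatory below, quiescent above
```

A 0.5 s, 150 pA pulse into the 5-HT drive roughly doubles the 5-HT rate
(fold ≈ 1.99) and transiently silences Ox neurons, which rebound after the
stimulus:

```python
>>> ts, metrics = d.run_pulse(params, "5HT")
>>> print(metrics.to_frame().to_string(index=False))
population  baseline_Hz   peak_Hz     fold  trough_Hz  rebound_Hz
       5HT     5.002899  9.952899 1.989426   4.098824    5.089174
  GABA_DRN    15.011684 15.012093 1.000027  14.460450   15.440927
        Ox     5.024520  5.024520 1.000000   0.000000    7.099690
  GABA_LHA     5.027287  5.605771 1.115069   4.964085    5.600195
```

Removing every orexin effect from the circuit (an in-model Ox knockout)
leaves 5-HT neurons firing at a reduced but nonzero rate:

```python
>>> d.steady_state(d.knockout(params, "remove_Ox")).rate("5HT")
3.574116981510391
```

The same experiments are available from the shell:

```bash
drnlha steady-state
drnlha boundary --lo 0 --hi 6 --tol 1e-3
drnlha knockout --scenario remove_Ox
drnlha phasic --target 5HT --out-prefix pulse
drnlha sweep --connection 5HT_to_GABA_LHA --start 1 --stop 20 --num 20 --out sweep.tsv
drnlha generate-params --scale 0.1 --seed 1 --out perturbed.cfg
```

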