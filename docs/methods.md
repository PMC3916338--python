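# Methods

## Model

The circuit couples four mean-field neural populations: serotonergic (5HT)
and local GABAergic (GABA_DRN) units in the dorsal raphe nucleus, and
orexinergic (Ox) and local GABAergic (GABA_LHA) units in the lateral
hypothalamus. Glutamatergic populations are omitted: local glutamate is
weak relative to GABA in the DRN, and the excitatory feedback of LHA
glutamatergic neurons onto Ox cells is absorbed into the excitatory Ox2
autoreceptor term.

Each population converts its total drive into a rate through a
threshold-linear f-I curve, `f_j = g_j [I_local,j − I_0,j]₊`, with slope
`g_j` (Hz/pA) and threshold `I_0,j` (pA) taken from slice
electrophysiology. The drive is

    I_local,j = I_background,j + Σ_i s_ji · I_ji + I_stim,j ,

a background current (the free parameter representing the rest of the
brain), the signed synaptic currents of exactly three afferents
(self-feedback plus two projections), and an optional rectangular stimulus
pulse applied to the 5HT and/or Ox drive. Signs encode the net effect of
each connection: the 5-HT1A autoreceptor, all GABAergic synapses and the
5-HT effect on Ox neurons are inhibitory; orexin projections, the Ox2
autoreceptor and the 5-HT effect on DRN GABAergic neurons are excitatory.
The polarity of the 5HT → GABA_LHA projection is experimentally
undetermined and is an explicit model switch (excitatory by default; the
inhibitory alternative produces large-amplitude slow oscillations never
observed in vivo, which is the argument for the default).

Two timescale classes structure the dynamics. Membrane time constants
(~10 ms) and GABA_A synapses (~4 ms) are much faster than every other
process, so rates and GABA currents are treated as instantaneous: each GABA
population's rate solves `f = g·[X − J_self·f − I_0]₊` in closed form
(`f = g·(X − I_0)/(1 + g·J_self)` on the active branch; unique because
`1 + g·J_self > 0`). The eight non-GABA connections act through slow
first-order receptor currents, `τ_ji · dI_ji/dt = −I_ji + J_ji · f_i`, with
`J_ji` the ratio of the measured postsynaptic current to the presynaptic
baseline rate. The dynamical state is therefore the 8-vector of slow
currents; everything else is resolved algebraically at each instant.

## Parameters

Defaults live in `drnlha.params` and in the shipped `data/defaults.cfg`
(flat `key = value` text). Strengths J are in pA/Hz (e.g. 5-HT1A
autoreceptor 16, Ox → 5HT 15, GABA_LHA → Ox 118, Ox → GABA_LHA 0 since no
Ox receptors were found on LHA GABAergic neurons), time constants from 1 s
(5-HT autoreceptor) to 60 s (Ox → 5HT, 5HT → GABA_DRN), slopes
g = 0.033/0.061/0.205/0.195 Hz/pA and thresholds 0.13/0/0/0 pA for
5HT/GABA_DRN/Ox/GABA_LHA, and background currents 231.47/246/617.6/20.9 pA.
The `g_Ox` and `g_GABA_LHA` rows of the source table carry descriptions
that appear swapped relative to their symbols; values are assigned by
symbol (either assignment yields ~5 Hz baselines, and both slopes are
configurable).

Five tying constraints reduce the free parameters: τ(5HT→GABA_LHA) =
τ(5HT→Ox); τ(Ox→GABA_LHA) = τ(Ox-auto); J(5HT→GABA_LHA) = J(5HT→Ox);
J(Ox→GABA_LHA) = J(Ox-auto), waived while Ox→GABA_LHA is pinned at zero;
and equal GABAergic self-inhibition in DRN and LHA. `check_constraints`
reports them; `perturb` re-imposes them after perturbing.

`calibrate_background` inverts the fixed-point equations at target baseline
rates (defaults 5, 15, 5, 5 Hz): `I_bg = f/g + I_0 − (M f)` with `M` the
signed strength matrix. The inversion reproduces the shipped backgrounds to
within 0.6% (231.65/245.90/614.39/20.64 pA); the residual exists because
the shipped backgrounds put the baseline only approximately at 5/15/5/5 Hz
and their exact rounding provenance is not recoverable. Round-trips are
verified to 1e-6 Hz.

## Numerics

* **Integration.** Explicit midpoint (RK2) with a fixed 10 ms step; rates
  are re-resolved algebraically at both stages and the stimulus is
  evaluated at stage times. The step must satisfy dt ≤ τ_min/10 (fast
  timescale variants refine dt automatically). Halving dt changes terminal
  rates by <1e-3 Hz, and the global error scales as O(dt²) against a
  dt = 1 ms reference (verified in the suite on a smooth 100 s relaxation
  started 50% above the fixed-point currents, which avoids threshold
  crossings that would degrade the formal order).
* **Fixed points.** The piecewise-linear system `f = g[b + Mf]₊` is solved
  exactly by active-set enumeration (at most 2⁴ branches). Because the Ox
  self-excitation is supercritical (g_Ox·J_auto ≈ 1.23 > 1) the system can
  be multistable — e.g. with all backgrounds zeroed a tiny self-sustained
  Ox state coexists with silence. Candidate branches are therefore tried in
  the order: the active set reached by a damped iteration of the rate map
  from rest (the branch a simulation from silence lands on), then
  all-active, then decreasing size; the first self-consistent branch wins.
  Active populations must sit above threshold and clamped ones at or below
  it (tolerance 1e-9).
* **Stability.** Eigenvalues of the 8×8 Jacobian of the slow-current flow
  with rates eliminated analytically on the local branch (populations
  exactly at threshold count as silent; the Jacobian is constant within a
  branch). Stable means every real part is negative.
* **Oscillation boundary.** Bisection on the leading eigenvalue's sign in
  J(5HT→GABA_LHA), default tolerance 1e-3 pA/Hz so the crossing (≈0.805
  pA/Hz) is resolved at the third decimal. Linear stability is the primary
  criterion; simulation is a cross-check that must agree at the brackets
  (disagreement raises, it is never silently resolved). Negative sweep
  values denote the inhibitory-sign variant of that connection.
* **Oscillation detection.** `detect_oscillation` thresholds the 5-HT
  peak-to-trough amplitude at 0.05 Hz over a ≥1000 s window after a 1000 s
  discarded transient — far above integrator ripple (<1e-3 Hz), far below
  the observed oscillation amplitudes (tens of Hz). Periods are mean
  intervals between maxima (≥3 maxima required). Near the boundary the
  leading eigenvalue's real part is ~1e-4 /s, so transients grow or decay
  over thousands of seconds and a single amplitude threshold misclassifies;
  `classify_oscillation` instead kicks the fixed-point currents by 5%,
  integrates 4000 s, and calls the circuit oscillatory only if the late
  (last 1000 s) amplitude both exceeds the threshold and persists at ≥80%
  of the early amplitude. This classification agrees exactly with the
  eigenvalue criterion on a 30-point grid across the boundary.
* **Sweeps.** Stable grid points use the analytic solve; unstable points
  are integrated 2000 s from zero currents, the first 1000 s discarded, and
  the 5-HT envelope plus window-mean rates recorded. Per-point failures are
  collected without aborting the sweep.

## Phasic experiments

Pulses default to 150 pA for 0.5 s (amplitude chosen so a 5-HT pulse
roughly doubles the 5-HT rate; duration on the behavioural timescale),
onset 1 s after a fixed-point start, horizon 60 s — stretched to 600 s when
Ox is stimulated and the Ox → 5HT connection keeps its slow (60 s)
timescale, so the slow relaxation completes. Metrics are the pre-onset
baseline, the in-pulse peak and fold, and the post-offset trough and
rebound, per population.

Receptor-timescale variants mimic the coexistence of fast ligand-gated and
slow G-protein-coupled receptors and are always simulated separately, never
mixed. The fast 5-HT3A-like time constant is not pinned by measurements;
the default is 0.05 s (ligand-gated channel scale, configurable) applied to
5HT → Ox and 5HT → GABA_LHA, with the slow variant at the reference 2 s.
The direct Ox → 5HT connection is compared at 5 s (fast) versus 60 s
(slow). One consequence of the 0.05 s choice: the 5-HT trace is insensitive
to its own efferent timescales through the stimulus-and-rebound epoch
(<0.05 Hz difference out to ~6 s — the "overlapping curves" regime), but
the slow Ox → 5HT feedback integrates the different Ox histories and
accumulates a ~0.14 Hz (≈3% of baseline) difference tens of seconds later.

Knockouts zero outgoing strengths: `remove_Ox` removes all four Ox-sourced
connections (5-HT then settles at 3.574 Hz, reduced but not silent — the
basis of the orexin-knockout prediction) and `remove_Ox_autoreceptor`
removes only the Ox2 self-excitation, which abolishes the oscillatory
regime entirely.

## Synthetic parameter generation

`perturb` multiplies every J, τ and g by independent factors drawn
uniformly from [1−s, 1+s] (seeded NumPy generator, s ≤ 0.5), re-imposes the
five tying constraints by copying each master value onto its tied partner,
and re-calibrates backgrounds to the default targets so perturbed circuits
sit at identical baselines — isolating connectivity effects from
operating-point shifts. This emulates parameter uncertainty around the
reference set, not biological variability: it preserves the sign structure
and topology exactly, and the re-calibration step means background currents
are never themselves perturbed. At s = 0.1, a 50-seed run leaves 84% of
circuits with a stable fixed point and all rates in (0, 50) Hz; the
remainder are pushed across the Hopf boundary, which is a genuine property
of the circuit, not a generator artifact.

## What the tests do and do not show

The suite verifies the model against its own analytic structure (closed
forms, conservation at fixed points, integrator order, eigenvalue/
simulation agreement) and against the reported circuit-level behaviours
(baselines, knockout rate, boundary location, pulse fold, regime
properties). All inputs are the reference parameter table and seeded
perturbations of it; nothing here validates the model against recordings,
and conclusions inherit the mean-field assumptions: no spiking, no
heterogeneity within populations, no noise, no spatial structure, and
receptor diversity reduced to a sign and a time constant per connection.

## Problem sizes

Default analyses use: 2000 s trajectories (10 ms steps) for envelopes and
convergence cross-checks, 4000 s for near-boundary classification, 30-point
grids for boundary scans, 50-seed batches for robustness, and 60/600 s
horizons for pulse experiments — enough that every reported quantity is
converged at the stated tolerances on a single CPU in minutes.
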