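"""Hot numerical kernels: algebraic rate resolution and the RK2 stepper.

Kept free of the dataclass layer so they can be JIT-compiled with numba when
it is installed; without numba the same functions run as plain Python.

State layout (length 8, order of ``params.SLOW_CONNECTIONS``)::

    0: 5HT_auto        1: Ox_to_5HT       2: 5HT_to_GABA_DRN  3: Ox_to_GABA_DRN
    4: Ox_auto         5: 5HT_to_Ox       6: Ox_to_GABA_LHA   7: 5HT_to_GABA_LHA

Population order: 0 = 5HT, 1 = GABA_DRN, 2 = Ox, 3 = GABA_LHA.  The four
instantaneous GABA_A strengths are packed as
``jinst = [GABA_DRN->5HT, GABA_DRN self, GABA_LHA->Ox, GABA_LHA self]``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


#: Presynaptic population index for each slow current.
PRE_INDEX = np.array([0, 2, 0, 2, 2, 0, 2, 0], dtype=np.int64)


@njit(cache=True)
def resolve_rates(x, g, I0, bg, s8, jinst, stim_s, stim_o):
    """Resolve the algebraic (instantaneous) part of the model.

    GABAergic synapses equilibrate instantly, so each GABA population's rate
    solves the scalar self-consistency ``f = g*[X - J_self*f - I0]_+`` in
    closed form; the two principal populations then follow directly from the
    threshold-linear transfer function.

    Returns ``(f, I_local)`` where ``I_local`` is the total drive per
    population (background + signed synaptic currents + stimulus).
    """
    f = np.empty(4)
    iloc = np.empty(4)

    # DRN GABA: slow afferents are 5HT_to_GABA_DRN (x[2]) and Ox_to_GABA_DRN
    # (x[3]); instantaneous self-inhibition with strength jinst[1].
    xd = bg[1] + s8[2] * x[2] + s8[3] * x[3]
    fd = g[1] * (xd - I0[1]) / (1.0 + g[1] * jinst[1])
    if fd < 0.0:
        fd = 0.0
    f[1] = fd
    iloc[1] = xd - jinst[1] * fd

    # LHA GABA: slow afferents Ox_to_GABA_LHA (x[6]) and 5HT_to_GABA_LHA
    # (x[7]); instantaneous self-inhibition jinst[3].
    xl = bg[3] + s8[6] * x[6] + s8[7] * x[7]
    fl = g[3] * (xl - I0[3]) / (1.0 + g[3] * jinst[3])
    if fl < 0.0:
        fl = 0.0
    f[3] = fl
    iloc[3] = xl - jinst[3] * fl

    # 5-HT: autoreceptor (x[0]), orexin input (x[1]), instantaneous GABA.
    i_s = bg[0] + s8[0] * x[0] + s8[1] * x[1] - jinst[0] * fd + stim_s
    iloc[0] = i_s
    fs = g[0] * (i_s - I0[0])
    f[0] = fs if fs > 0.0 else 0.0

    # Ox: autoreceptor (x[4]), 5-HT input (x[5]), instantaneous GABA.
    i_o = bg[2] + s8[4] * x[4] + s8[5] * x[5] - jinst[2] * fl + stim_o
    iloc[2] = i_o
    fo = g[2] * (i_o - I0[2])
    f[2] = fo if fo > 0.0 else 0.0

    return f, iloc


@njit(cache=True)
def slow_derivatives(x, f, J8, tau8):
    """d/dt of the eight slow currents: (-I + J * f_presynaptic) / tau."""
    d = np.empty(8)
    for k in range(8):
        d[k] = (-x[k] + J8[k] * f[PRE_INDEX[k]]) / tau8[k]
    return d


@njit(cache=True)
def rk2_integrate(
    x0,
    n_steps,
    dt,
    g,
    I0,
    bg,
    s8,
    jinst,
    J8,
    tau8,
    stim_s_on,
    stim_o_on,
    amplitude,
    onset,
    duration,
    rates_out,
    drives_out,
    currents_out,
):
    """Explicit-midpoint (RK2) integration of the slow-current system.

    Rates are re-resolved algebraically at both stages of every step; the
    stimulus is evaluated at the stage times.  Outputs are written in place
    (``n_steps + 1`` rows including the initial instant).  Returns 0 on
    success, 1 if the state became non-finite (parameter pathology).
    """
    x = x0.copy()
    offset = onset + duration

    for k in range(8):
        currents_out[0, k] = x[k]

    for step in range(n_steps + 1):
        t = step * dt
        on = onset <= t < offset
        ss = amplitude if (on and stim_s_on) else 0.0
        so = amplitude if (on and stim_o_on) else 0.0
        f, iloc = resolve_rates(x, g, I0, bg, s8, jinst, ss, so)
        for j in range(4):
            rates_out[step, j] = f[j]
            drives_out[step, j] = iloc[j]
        if step == n_steps:
            break

        k1 = slow_derivatives(x, f, J8, tau8)

        tm = t + 0.5 * dt
        on_m = onset <= tm < offset
        ss_m = amplitude if (on_m and stim_s_on) else 0.0
        so_m = amplitude if (on_m and stim_o_on) else 0.0
        xm = np.empty(8)
        for k in range(8):
            xm[k] = x[k] + 0.5 * dt * k1[k]
        fm, _ = resolve_rates(xm, g, I0, bg, s8, jinst, ss_m, so_m)
        k2 = slow_derivatives(xm, fm, J8, tau8)

        ok = True
        for k in range(8):
            x[k] = x[k] + dt * k2[k]
            if not np.isfinite(x[k]):
                ok = False
        if not ok:
            return 1
        for k in range(8):
            currents_out[step + 1, k] = x[k]

    return 0
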