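"""Independent reference implementations used to cross-check the package.

Deliberately simple and separate from the library code paths: a fixed-step
classical RK4 integrator written directly against the model equations, and
the closed-form solution of the readout gene under constant drive.
"""

import numpy as np


def rk4_kinase(params, pf, nf, t_end=120.0, dt=0.001, k4=None, k5=None):
    """Fixed-step RK4 of the kinase model; returns (times, active) at each step.

    ``pf``/``nf`` are callables (may be None when the corresponding rate is 0);
    ``k4``/``k5`` override the parameter values (regime knockouts).  The
    time-dependent drives are evaluated once on the half-step grid, then the
    state is stepped with the classical Runge–Kutta scheme.
    """
    sp = params.signal_params
    k1, k2, km1, km2, total = params.k1, params.k2, params.km1, params.km2, params.total
    k4 = params.k4 if k4 is None else k4
    k5 = params.k5 if k5 is None else k5

    n = int(round(t_end / dt))
    times = np.linspace(0.0, t_end, n + 1)
    half = np.linspace(0.0, t_end, 2 * n + 1)
    signal = sp.amplitude * (np.exp(-sp.decay_rate * half) - np.exp(-sp.rise_rate * half))
    act_drive = k1 * signal
    if k4:
        act_drive = act_drive + k4 * np.asarray(pf(half), dtype=float)
    deact_rate = np.full(half.shape, k2)
    if k5:
        deact_rate = deact_rate + k5 * np.asarray(nf(half), dtype=float)

    def rhs(j, a):
        # j indexes the half-step grid
        inact = total - a
        return act_drive[j] * inact / (km1 + inact) - deact_rate[j] * a / (km2 + a)

    active = np.empty(n + 1)
    a = 0.0
    active[0] = a
    for i in range(n):
        j = 2 * i
        f1 = rhs(j, a)
        f2 = rhs(j + 1, a + dt / 2 * f1)
        f3 = rhs(j + 1, a + dt / 2 * f2)
        f4 = rhs(j + 2, a + dt * f3)
        a += dt / 6 * (f1 + 2 * f2 + 2 * f3 + f4)
        active[i + 1] = a
    return times, active


def gene_constant_drive(times, c, p):
    """X(t) for constant kinase level c: (k_syn/k_deg)·H·(1 − e^(−k_deg·t))."""
    h = c**p.n / (p.k_half**p.n + c**p.n)
    return (p.k_syn / p.k_deg) * h * (1.0 - np.exp(-p.k_deg * np.asarray(times, dtype=float)))
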