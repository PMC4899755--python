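"""Fast fixed-step RK4 forward simulation of the kinase model for fitting.

Least-squares objectives evaluate the forward model thousands of times; the
adaptive stiff solver in :mod:`bsignal.model_a_kinase` is accurate but its
per-call overhead dominates a fit.  The model is smooth and non-stiff on the
0–120 min window at realistic rates, so a fixed-step classical RK4 at
dt = 0.02 min (global error far below measurement noise and below the
adaptive solver's own tolerance) is used inside the objective, jit-compiled
with numba.  The feedback drives PF/NF are precomputed on the half-step grid
once per fit; the signal pulse is evaluated analytically inside the loop
because its rates are themselves fitted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["DriveCache", "active_on_grid"]

_DT = 0.02  # min


@njit(cache=False)
def _rk4_loop(k1, k2, k4, k5, km1, km2, total, sa, sb, pf_half, nf_half, t0, dt, n_steps):
    out = np.empty(n_steps + 1)
    a = 0.0
    out[0] = a
    for i in range(n_steps):
        t = t0 + i * dt
        th = t + 0.5 * dt
        t1 = t + dt
        s0 = np.exp(-sa * t) - np.exp(-sb * t)
        sh = np.exp(-sa * th) - np.exp(-sb * th)
        s1 = np.exp(-sa * t1) - np.exp(-sb * t1)
        p0, ph, p1 = pf_half[2 * i], pf_half[2 * i + 1], pf_half[2 * i + 2]
        q0, qh, q1 = nf_half[2 * i], nf_half[2 * i + 1], nf_half[2 * i + 2]

        x = a
        f1 = (k1 * s0 + k4 * p0) * (total - x) / (km1 + total - x) - (k2 + k5 * q0) * x / (km2 + x)
        x = a + 0.5 * dt * f1
        f2 = (k1 * sh + k4 * ph) * (total - x) / (km1 + total - x) - (k2 + k5 * qh) * x / (km2 + x)
        x = a + 0.5 * dt * f2
        f3 = (k1 * sh + k4 * ph) * (total - x) / (km1 + total - x) - (k2 + k5 * qh) * x / (km2 + x)
        x = a + dt * f3
        f4 = (k1 * s1 + k4 * p1) * (total - x) / (km1 + total - x) - (k2 + k5 * q1) * x / (km2 + x)
        a = a + (dt / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        out[i + 1] = a
    return out


class DriveCache:
    """Precomputed feedback drives and output indexing for one regime's data."""

    def __init__(self, t_data: np.ndarray, pf, nf, use_pf: bool, use_nf: bool, dt: float = _DT):
        t_data = np.asarray(t_data, dtype=float)
        t_end = float(t_data[-1])
        self.n_steps = max(1, int(round(t_end / dt)))
        self.dt = t_end / self.n_steps
        half = np.linspace(0.0, t_end, 2 * self.n_steps + 1)
        self.grid = half[::2]
        zeros = np.zeros_like(half)
        self.pf_half = np.asarray(pf(half), dtype=float) if (use_pf and pf is not None) else zeros
        self.nf_half = np.asarray(nf(half), dtype=float) if (use_nf and nf is not None) else zeros
        self.t_data = t_data

    def active(self, k1, k2, k4, k5, km1, km2, total, sig_decay, sig_rise) -> np.ndarray:
        dense = _rk4_loop(
            k1, k2, k4, k5, km1, km2, total, sig_decay, sig_rise,
            self.pf_half, self.nf_half, 0.0, self.dt, self.n_steps,
        )
        return np.interp(self.t_data, self.grid, dense)


def active_on_grid(values: dict, cache: DriveCache, total: float = 1.0) -> np.ndarray:
    """Model-predicted active kinase at the cache's data times."""
    return cache.active(
        values["k1"], values["k2"], values.get("k4", 0.0), values.get("k5", 0.0),
        values["km1"], values["km2"], total,
        values["sig_decay"], values["sig_decay"] + values["sig_gap"],
    )
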