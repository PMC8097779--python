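"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form code paths: the
concentration oracle integrates the compartmental ODEs with an adaptive
solver, so agreement with the analytic superposition is a genuine
cross-check rather than a tautology.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration_1cpt(cl, v, doses, t_eval, rtol=1e-10, atol=1e-12):
    """One-compartment infusion model solved numerically.

    ``doses`` is a list of (start time, amount, duration) tuples.
    Returns concentrations at ``t_eval`` (must be sorted, >= 0).
    """
    doses = [(float(t0), float(a), float(d)) for t0, a, d in doses]

    def infusion_rate(t):
        return sum(a / d for t0, a, d in doses if t0 <= t < t0 + d)

    def rhs(t, y):
        return [infusion_rate(t) - (cl / v) * y[0]]

    # integrate piecewise between rate discontinuities for solver accuracy
    breaks = sorted({0.0, *[t0 for t0, _, _ in doses], *[t0 + d for t0, _, d in doses],
                     *map(float, t_eval)})
    breaks = [b for b in breaks if b <= max(t_eval)]
    out = {}
    y0 = [0.0]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        wanted = [t for t in t_eval if lo < t <= hi]
        sol = solve_ivp(rhs, (lo, hi), y0, t_eval=wanted or None,
                        rtol=rtol, atol=atol, max_step=(hi - lo))
        for tt, amt in zip(sol.t, sol.y[0]):
            out[float(tt)] = amt / v
        y0 = [float(sol.y[0, -1])]
    return np.array([out.get(float(t), 0.0) if t > 0 else 0.0 for t in t_eval])


def ode_concentration_2cpt(cl, v1, q, v2, doses, t_eval, rtol=1e-10, atol=1e-12):
    """Two-compartment infusion model solved numerically (central conc)."""
    doses = [(float(t0), float(a), float(d)) for t0, a, d in doses]
    k10, k12, k21 = cl / v1, q / v1, q / v2

    def infusion_rate(t):
        return sum(a / d for t0, a, d in doses if t0 <= t < t0 + d)

    def rhs(t, y):
        a1, a2 = y
        return [infusion_rate(t) - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    breaks = sorted({0.0, *[t0 for t0, _, _ in doses], *[t0 + d for t0, _, d in doses],
                     *map(float, t_eval)})
    breaks = [b for b in breaks if b <= max(t_eval)]
    out = {}
    y0 = [0.0, 0.0]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        wanted = [t for t in t_eval if lo < t <= hi]
        sol = solve_ivp(rhs, (lo, hi), y0, t_eval=wanted or None,
                        rtol=rtol, atol=atol, max_step=(hi - lo))
        for tt, amt in zip(sol.t, sol.y[0]):
            out[float(tt)] = amt / v1
        y0 = [float(sol.y[0, -1]), float(sol.y[1, -1])]
    return np.array([out.get(float(t), 0.0) for t in t_eval])
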