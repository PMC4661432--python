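"""Independent numerical oracles shared by the test modules."""

import numpy as np
from scipy.integrate import solve_ivp


def linear_system_ode(matrix, rate, duration, times, rtol=1e-12):
    """Runge-Kutta reference for dx/dt = M x + rate*e0 on [0, duration), then M x.

    Integrates the two phases separately so the infusion cut-off is a phase
    boundary rather than a discontinuity inside one integration, which keeps
    the step count independent of the infusion length (bolus limit included).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    times = np.asarray(times, dtype=float)
    tmax = float(times.max())
    forcing = np.zeros(n)
    forcing[0] = rate
    out = np.empty((n, times.size))
    t_break = min(duration, tmax)
    phase1 = times <= t_break
    eval1 = np.unique(np.concatenate([times[phase1], [t_break]]))
    sol1 = solve_ivp(
        lambda t, y: matrix @ y + forcing, (0.0, t_break), np.zeros(n),
        t_eval=eval1, rtol=rtol, atol=1e-16, method="DOP853",
    )
    assert sol1.success
    lookup = {t: sol1.y[:, j] for j, t in enumerate(eval1)}
    for j, t in enumerate(times):
        if phase1[j]:
            out[:, j] = lookup[t]
    if np.any(~phase1):
        sol2 = solve_ivp(
            lambda t, y: matrix @ y, (t_break, tmax), sol1.y[:, -1],
            t_eval=times[~phase1], rtol=rtol, atol=1e-16, method="DOP853",
        )
        assert sol2.success
        out[:, ~phase1] = sol2.y
    return out


def two_compartment_matrix(k_pc, k_cp, k_el):
    return np.array([[-(k_el + k_cp), k_pc], [k_cp, -k_pc]])
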