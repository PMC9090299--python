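"""Brute-force numerical oracles, independent of the package's solvers."""

import numpy as np


def rk4_cascade(params, y0, t_end, step=1e-3):
    """Classic fixed-step RK4 integration of the three-species cascade.

    Deliberately re-derives the right-hand side from the model definition
    instead of calling anything in rrnapipe.
    """
    s, k1, k2, a, k3 = params.sigma, params.k45, params.k35, params.alpha, params.kpa3

    def f(y):
        return np.array(
            [
                s - k1 * y[0],
                k1 * y[0] - k2 * y[1],
                a * k2 * y[1] - k3 * y[2],
            ]
        )

    n = max(1, int(np.ceil(t_end / step)))
    h = t_end / n
    y = np.asarray(y0, dtype=float).copy()
    for _ in range(n):
        k_1 = f(y)
        k_2 = f(y + h / 2 * k_1)
        k_3 = f(y + h / 2 * k_2)
        k_4 = f(y + h * k_3)
        y = y + h / 6 * (k_1 + 2 * k_2 + 2 * k_3 + k_4)
    return y


def rk4_schedule(schedule, params_by_regime, y0, t, step=1e-3):
    """Piecewise RK4 across schedule segments up to time t."""
    y = np.asarray(y0, dtype=float).copy()
    for seg in schedule.segments:
        if t <= seg.start_h:
            break
        dur = min(t, seg.end_h) - seg.start_h
        y = rk4_cascade(params_by_regime[seg.regime], y, dur, step=step)
        if t <= seg.end_h:
            break
    return y
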