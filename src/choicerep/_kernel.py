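"""Compiled inner loop of the two-population attractor model.

The Euler–Maruyama integration runs once per decision at a 1 ms step, so it
lives in a numba-compiled scalar function; everything above it (trial
bookkeeping, inter-trial decay, logging) stays in plain Python.
"""

import numpy as np
from numba import njit

# return codes for the choice field
SN = 0
LF = 1


@njit(cache=True)
def integrate_race(
    x_sn,
    x_lf,
    input_sn,
    input_lf,
    polarization,
    leak,
    w_self,
    w_inh,
    noise_sd,
    threshold,
    dt,
    max_steps,
    seed,
):
    """Integrate the two-unit rate model until one rectified activity crosses
    threshold.

    dx_i = [-leak*x_i + w_self*g(x_i) - w_inh*g(x_j) + I_i + pol] dt
           + noise_sd*sqrt(dt)*eta,  g(x) = max(x, 0)

    Returns (choice, steps, x_sn, x_lf, timed_out).  Ties within a step are
    broken by the larger activity, then by a coin flip.
    """
    np.random.seed(seed)
    sq = noise_sd * np.sqrt(dt)
    for step in range(1, max_steps + 1):
        g_sn = x_sn if x_sn > 0.0 else 0.0
        g_lf = x_lf if x_lf > 0.0 else 0.0
        new_sn = (
            x_sn
            + (-leak * x_sn + w_self * g_sn - w_inh * g_lf + input_sn + polarization) * dt
            + sq * np.random.normal()
        )
        new_lf = (
            x_lf
            + (-leak * x_lf + w_self * g_lf - w_inh * g_sn + input_lf + polarization) * dt
            + sq * np.random.normal()
        )
        x_sn = new_sn
        x_lf = new_lf
        sn_hit = x_sn >= threshold
        lf_hit = x_lf >= threshold
        if sn_hit or lf_hit:
            if sn_hit and lf_hit:
                if x_sn > x_lf:
                    choice = SN
                elif x_lf > x_sn:
                    choice = LF
                else:
                    choice = SN if np.random.random() < 0.5 else LF
            else:
                choice = SN if sn_hit else LF
            return choice, step, x_sn, x_lf, False
    # timeout: resolve by the currently larger activity
    choice = SN if x_sn >= x_lf else LF
    return choice, max_steps, x_sn, x_lf, True
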