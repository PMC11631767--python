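"""Independent brute-force oracles used to validate the implementation.

Deliberately written without reusing the library's solver internals: plain
interval-halving bisection on the raw mass-balance equations, with weights
re-derived from first principles.
"""

from __future__ import annotations

import math

import numpy as np

R_KCAL = 1.987204259e-3


def oracle_weights(dG_close, Kd_key, Kd_target, temperature_K, K_free, T_free):
    """Boltzmann weights of the five cage states, written independently."""
    RT = R_KCAL * temperature_K
    return np.array(
        [
            math.exp(-dG_close / RT),
            1.0,
            T_free / Kd_target,
            K_free / Kd_key,
            (K_free / Kd_key) * (T_free / Kd_target),
        ]
    )


def oracle_equilibrium(
    dG_close,
    Kd_key,
    Kd_target,
    C_tot,
    K_tot,
    T_tot,
    temperature_K=298.15,
    n_bisect=200,
):
    """Nested interval-halving bisection on the two mass balances.

    Outer bisection on T_free in [0, T_tot]; for each trial T_free an inner
    bisection finds K_free in [0, K_tot] from the Key balance.  Both
    residuals are monotone in their own free variable, so plain bisection
    converges to machine precision in ~200 halvings.
    """

    def populations(K_free, T_free):
        w = oracle_weights(dG_close, Kd_key, Kd_target, temperature_K, K_free, T_free)
        return w / w.sum()

    def key_residual(K_free, T_free):
        p = populations(K_free, T_free)
        return K_free + C_tot * (p[3] + p[4]) - K_tot

    def solve_key(T_free):
        lo, hi = 0.0, K_tot
        if K_tot == 0.0:
            return 0.0
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            if key_residual(mid, T_free) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def target_residual(T_free):
        K_free = solve_key(T_free)
        p = populations(K_free, T_free)
        return T_free + C_tot * (p[2] + p[4]) - T_tot

    lo, hi = 0.0, T_tot
    if T_tot == 0.0:
        T_free = 0.0
    else:
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            if target_residual(mid) > 0:
                hi = mid
            else:
                lo = mid
        T_free = 0.5 * (lo + hi)
    K_free = solve_key(T_free)
    return K_free, T_free, populations(K_free, T_free)


def oracle_tune(params, library, window, cap, totals, signal_fn, apply_fn):
    """Plain exhaustive enumeration of mutation subsets (bitmask order)."""
    from dataclasses import replace

    T_lo, T_hi = window
    best = None
    for bits in range(2 ** len(library)):
        subset = tuple(e for i, e in enumerate(library) if bits >> i & 1)
        p = apply_fn(params, subset)
        bg = signal_fn(p, replace(totals, T_tot=0.0))
        if bg > cap:
            continue
        obj = signal_fn(p, replace(totals, T_tot=T_hi)) - signal_fn(
            p, replace(totals, T_tot=T_lo)
        )
        names = tuple(sorted(e.name for e in subset))
        key = (-obj, len(subset), names)
        if best is None or key < best[0]:
            best = (key, subset)
    return None if best is None else best[1]
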