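"""Mass-action equilibrium model of a two-component LOCKR switch.

A LOCKR sensor is a Cage protein whose own latch occupies the key-binding
groove, plus a free Key peptide.  A target-binding domain (TBD) embedded in
the latch lets a target protein pry the latch open; the Key then binds the
open groove and reconstitutes the split readout (here a FRET pair).  A single
cage molecule can therefore be in one of five states:

    S1  closed            latch in the groove, TBD occluded
    S2  open, empty       reference state (weight 1)
    S3  open, target      target bound to the exposed TBD
    S4  open, key         Key bound, no target -- the false-positive state
    S5  open, key+target  Key and target both bound -- the signalling state

Relative statistical weights at free concentrations ``K`` (Key) and ``T``
(target)::

    w1 = exp(-dG_close / RT)      w2 = 1
    w3 = T / Kd_target            w4 = K / Kd_key
    w5 = (K / Kd_key) * (T / Kd_target)

``dG_close`` is G(closed) - G(open); negative values favour the closed
state.  The readout-generating quantity is the key-bound fraction
P(S4) + P(S5).  At finite total concentrations the free concentrations are
fixed by mass balance over Cage, Key and target, solved in
:func:`solve_equilibrium`.

Mutations that weaken the latch:cage interface raise ``dG_close``;
mutations that weaken the key:cage interface raise ``Kd_key``.  The model
reproduces the experimentally observed tuning directions: latch weakening
raises background (signal at zero target), key weakening lowers both
background and saturating signal.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT_KCAL",
    "SwitchParams",
    "Totals",
    "MutationEffect",
    "ReadoutModel",
    "DoseResponse",
    "EquilibriumResult",
    "TuneReport",
    "state_weights",
    "solve_equilibrium",
    "signal",
    "ratio",
    "dose_response",
    "dynamic_range",
    "ec50",
    "apply_mutations",
    "tune",
]

#: Gas constant in kcal / (mol K); RT = 0.593 kcal/mol at 298.15 K.
GAS_CONSTANT_KCAL = 1.987204259e-3

# State indices into the 5-vector returned by state_weights.
CLOSED, OPEN_EMPTY, OPEN_TARGET, KEY_ONLY, KEY_TARGET = range(5)


@dataclass(frozen=True)
class SwitchParams:
    """Energetic parameters of the three tunable interfaces.

    Parameters
    ----------
    dG_close:
        Free energy of latch closing, G(closed) - G(open), kcal/mol.
        Negative favours the closed (dark) state.
    Kd_key:
        Dissociation constant of Key for the open cage groove (molar).
    Kd_target:
        Dissociation constant of target for the exposed TBD (molar).
    temperature_K:
        Temperature in kelvin; sets RT.
    """

    dG_close: float
    Kd_key: float
    Kd_target: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.Kd_key <= 0 or self.Kd_target <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def RT(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature_K


@dataclass(frozen=True)
class Totals:
    """Total (bound + free) concentrations in molar."""

    C_tot: float
    K_tot: float
    T_tot: float

    def __post_init__(self) -> None:
        if min(self.C_tot, self.K_tot, self.T_tot) < 0:
            raise ValueError("total concentrations must be non-negative")


@dataclass(frozen=True)
class MutationEffect:
    """A point-mutation destabilisation of one switch interface.

    ``ddG`` (kcal/mol) is positive for weakening.  ``interface`` names the
    contact the mutation perturbs: ``"latch"`` (latch:cage) or ``"key"``
    (key:cage).
    """

    name: str
    interface: str
    ddG: float

    def __post_init__(self) -> None:
        if self.interface not in ("latch", "key"):
            raise ValueError(
                f"interface must be 'latch' or 'key', got {self.interface!r}"
            )


@dataclass(frozen=True)
class ReadoutModel:
    """Linear map from key-bound fraction to a FRET-like ratio."""

    R_min: float
    R_max: float

    def __post_init__(self) -> None:
        if not (self.R_max > self.R_min > 0):
            raise ValueError("require R_max > R_min > 0")

    def ratio(self, key_bound_fraction: float) -> float:
        return self.R_min + (self.R_max - self.R_min) * key_bound_fraction


@dataclass
class DoseResponse:
    """Signal (key-bound fraction) across a target titration."""

    doses: np.ndarray
    signal: np.ndarray
    ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.doses.size and np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        if self.doses.shape != self.signal.shape:
            raise ValueError("doses and signal must align")


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved free concentrations and cage-state populations."""

    K_free: float
    T_free: float
    populations: np.ndarray  # P(S1..S5), sums to 1
    residual: float  # max relative mass-balance residual

    @property
    def key_bound_fraction(self) -> float:
        return float(self.populations[KEY_ONLY] + self.populations[KEY_TARGET])


class SolverError(RuntimeError):
    """Equilibrium solver failed to meet its residual contract."""


def state_weights(params: SwitchParams, K_free: float, T_free: float) -> np.ndarray:
    """Unnormalised statistical weights of the five cage states.

    The open/empty state is the reference (weight 1).  The closed state
    occludes the TBD, so target contributes no weight to S1.
    """
    if K_free < 0 or T_free < 0:
        raise ValueError("free concentrations must be non-negative")
    w = np.empty(5)
    w[CLOSED] = math.exp(-params.dG_close / params.RT)
    w[OPEN_EMPTY] = 1.0
    w[OPEN_TARGET] = T_free / params.Kd_target
    w[KEY_ONLY] = K_free / params.Kd_key
    w[KEY_TARGET] = (K_free / params.Kd_key) * (T_free / params.Kd_target)
    return w


def _populations(params: SwitchParams, K_free: float, T_free: float) -> np.ndarray:
    w = state_weights(params, K_free, T_free)
    return w / w.sum()


def _solve_key_given_target(
    params: SwitchParams, totals: Totals, T_free: float
) -> float:
    # Key balance: K_tot = K + C_tot * K*a / (b + K*a)  with
    #   a = (1 + T/Kd_t) / Kd_k   (coefficient of K in w4 + w5)
    #   b = w1 + 1 + T/Kd_t       (key-free weights)
    # which is a quadratic in K with a single non-negative root.
    a = (1.0 + T_free / params.Kd_target) / params.Kd_key
    b = math.exp(-params.dG_close / params.RT) + 1.0 + T_free / params.Kd_target
    return _positive_quadratic_root(a, b, totals.C_tot, totals.K_tot)


def _solve_target_given_key(
    params: SwitchParams, totals: Totals, K_free: float
) -> float:
    a = (1.0 + K_free / params.Kd_key) / params.Kd_target
    b = math.exp(-params.dG_close / params.RT) + 1.0 + K_free / params.Kd_key
    return _positive_quadratic_root(a, b, totals.C_tot, totals.T_tot)


def _positive_quadratic_root(a: float, b: float, C_tot: float, X_tot: float) -> float:
    """Non-negative root of a*x^2 + (b + a*(C_tot - X_tot))*x - X_tot*b = 0."""
    if X_tot == 0.0:
        return 0.0
    beta = b + a * (C_tot - X_tot)
    # Numerically stable form: the product of roots is -X_tot*b/a <= 0.
    disc = math.sqrt(beta * beta + 4.0 * a * X_tot * b)
    if beta >= 0:
        return 2.0 * X_tot * b / (beta + disc)
    return (disc - beta) / (2.0 * a)


def _mass_balance_residual(
    params: SwitchParams, totals: Totals, K_free: float, T_free: float
) -> float:
    p = _populations(params, K_free, T_free)
    bound_K = totals.C_tot * (p[KEY_ONLY] + p[KEY_TARGET])
    bound_T = totals.C_tot * (p[OPEN_TARGET] + p[KEY_TARGET])
    rK = abs(K_free + bound_K - totals.K_tot) / max(totals.K_tot, 1e-300)
    rT = abs(T_free + bound_T - totals.T_tot) / max(totals.T_tot, 1e-300)
    if totals.K_tot == 0:
        rK = abs(K_free + bound_K)
    if totals.T_tot == 0:
        rT = abs(T_free + bound_T)
    return max(rK, rT)


def solve_equilibrium(
    params: SwitchParams,
    totals: Totals,
    *,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> EquilibriumResult:
    """Solve the coupled Key/target mass balances for free concentrations.

    Each balance, with the other free concentration held fixed, is a
    quadratic with a unique non-negative root, so the solver alternates the
    two exact one-dimensional solves (a monotone fixed-point iteration) and
    falls back to nested bracketing bisection if that stalls.  The returned
    populations satisfy both balances to a relative residual below 1e-9.
    """
    K, T = totals.K_tot, totals.T_tot
    for _ in range(max_iter):
        K_new = _solve_key_given_target(params, totals, T)
        T_new = _solve_target_given_key(params, totals, K_new)
        if abs(K_new - K) <= tol * max(K_new, 1e-300) and abs(
            T_new - T
        ) <= tol * max(T_new, 1e-300):
            K, T = K_new, T_new
            break
        K, T = K_new, T_new
    residual = _mass_balance_residual(params, totals, K, T)
    if residual >= 1e-9:
        K, T = _nested_bisection(params, totals)
        residual = _mass_balance_residual(params, totals, K, T)
        if residual >= 1e-9:
            raise SolverError(
                f"equilibrium solver did not converge (residual {residual:.3e})"
            )
    return EquilibriumResult(K, T, _populations(params, K, T), residual)


def _nested_bisection(params: SwitchParams, totals: Totals) -> tuple[float, float]:
    """Robust fallback: bracketed root find on T with inner exact K solve."""

    def t_residual(T_free: float) -> float:
        K_free = _solve_key_given_target(params, totals, T_free)
        p = _populations(params, K_free, T_free)
        return T_free + totals.C_tot * (p[OPEN_TARGET] + p[KEY_TARGET]) - totals.T_tot

    if totals.T_tot == 0.0:
        T = 0.0
    else:
        T = brentq(t_residual, 0.0, totals.T_tot, xtol=1e-300, rtol=1e-15)
    return _solve_key_given_target(params, totals, T), T


def signal(params: SwitchParams, totals: Totals) -> float:
    """Key-bound cage fraction P(S4) + P(S5) at equilibrium."""
    return solve_equilibrium(params, totals).key_bound_fraction


def ratio(params: SwitchParams, totals: Totals, readout: ReadoutModel) -> float:
    """Predicted FRET-like ratio under a linear readout model."""
    return readout.ratio(signal(params, totals))


def dose_response(
    params: SwitchParams,
    totals_template: Totals,
    dose_grid: Sequence[float],
    readout: ReadoutModel | None = None,
) -> DoseResponse:
    """Evaluate signal over a target titration, C_tot and K_tot held fixed."""
    doses = np.asarray(dose_grid, dtype=float)
    if doses.size and np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly ascending")
    sig = np.array(
        [
            signal(params, replace(totals_template, T_tot=float(d)))
            for d in doses
        ]
    )
    rat = None
    if readout is not None:
        rat = readout.R_min + (readout.R_max - readout.R_min) * sig
    return DoseResponse(doses, sig, rat)


def dynamic_range(dr: DoseResponse, *, use_ratio: bool = False) -> float:
    """Response at the highest dose minus the basal (zero-dose) response."""
    if dr.doses.size == 0:
        raise ValueError("empty dose response")
    if dr.doses[0] != 0.0:
        raise ValueError("dose response lacks a zero-dose basal point")
    y = dr.ratio if use_ratio else dr.signal
    if y is None:
        raise ValueError("no ratio attached to this dose response")
    return float(y[-1] - y[0])


def ec50(dr: DoseResponse) -> float:
    """Dose at half-maximal rise above basal, by log-dose interpolation.

    Returns NaN (with a warning) when the curve does not cross its
    half-rise point, e.g. a basal-only or flat response.
    """
    if dr.doses.size < 2:
        warnings.warn("ec50 undefined: fewer than two doses", stacklevel=2)
        return math.nan
    basal = float(dr.signal[0])
    plateau = float(dr.signal[-1])
    half = basal + 0.5 * (plateau - basal)
    pos = dr.doses > 0
    if plateau <= basal or not np.any(dr.signal[pos] >= half):
        warnings.warn("ec50 undefined: half-rise not crossed", stacklevel=2)
        return math.nan
    logd = np.log10(dr.doses[pos])
    sig = dr.signal[pos]
    # first grid interval straddling the half-rise
    idx = int(np.argmax(sig >= half))
    if idx == 0:
        return float(10 ** logd[0])
    x0, x1 = logd[idx - 1], logd[idx]
    y0, y1 = sig[idx - 1], sig[idx]
    frac = (half - y0) / (y1 - y0)
    return float(10 ** (x0 + frac * (x1 - x0)))


def apply_mutations(
    params: SwitchParams, effects: Sequence[MutationEffect]
) -> SwitchParams:
    """Apply additive interface destabilisations to the parameter set.

    Latch effects raise ``dG_close`` by their ddG (destabilising the closed
    state); key effects scale ``Kd_key`` by exp(ddG/RT) (weakening key:cage
    binding).  Effects at the same interface sum.
    """
    dG = params.dG_close
    Kd_key = params.Kd_key
    for e in effects:
        if e.interface == "latch":
            dG += e.ddG
        elif e.interface == "key":
            Kd_key *= math.exp(e.ddG / params.RT)
        else:  # pragma: no cover - guarded by MutationEffect
            raise ValueError(f"unknown interface {e.interface!r}")
    return replace(params, dG_close=dG, Kd_key=Kd_key)


@dataclass
class TuneReport:
    """Result of the exhaustive mutation-subset search."""

    selected: tuple[MutationEffect, ...]
    params: SwitchParams
    objective: float  # signal(T_hi) - signal(T_lo)
    background: float  # signal at zero target
    feasible: bool  # background cap satisfied
    n_evaluated: int


def tune(
    params: SwitchParams,
    library: Sequence[MutationEffect],
    window: tuple[float, float],
    background_cap: float,
    totals: Totals | None = None,
) -> TuneReport:
    """Exhaustively search mutation subsets for a target concentration window.

    Maximises signal(T_hi) - signal(T_lo) subject to signal(0) <=
    ``background_cap``.  Because per-interface ddG values are additive, the
    objective depends only on the summed (latch, key) ddG, which is cached
    across subsets.  Ties break towards fewer mutations, then lexicographic
    names.  If no subset meets the cap, the lowest-background subset is
    returned flagged infeasible.
    """
    if len(library) > 20:
        raise ValueError("exhaustive search limited to libraries of <= 20 effects")
    T_lo, T_hi = window
    if not T_lo < T_hi:
        raise ValueError("window requires T_lo < T_hi")
    if totals is None:
        totals = Totals(C_tot=1e-6, K_tot=1e-6, T_tot=0.0)

    cache: dict[tuple[float, float], tuple[float, float]] = {}

    def evaluate(subset: tuple[MutationEffect, ...]) -> tuple[float, float]:
        sums = (
            sum(e.ddG for e in subset if e.interface == "latch"),
            sum(e.ddG for e in subset if e.interface == "key"),
        )
        if sums not in cache:
            p = apply_mutations(params, subset)
            bg = signal(p, replace(totals, T_tot=0.0))
            obj = signal(p, replace(totals, T_tot=T_hi)) - signal(
                p, replace(totals, T_tot=T_lo)
            )
            cache[sums] = (obj, bg)
        return cache[sums]

    best: tuple | None = None
    best_subset: tuple[MutationEffect, ...] = ()
    fallback: tuple | None = None
    fallback_subset: tuple[MutationEffect, ...] = ()
    n_eval = 0
    for r in range(len(library) + 1):
        for subset in itertools.combinations(library, r):
            obj, bg = evaluate(subset)
            n_eval += 1
            names = tuple(sorted(e.name for e in subset))
            key = (-obj, len(subset), names)
            if bg <= background_cap and (best is None or key < best):
                best, best_subset = key, subset
            fb_key = (bg, -obj, len(subset), names)
            if fallback is None or fb_key < fallback:
                fallback, fallback_subset = fb_key, subset

    feasible = best is not None
    chosen = best_subset if feasible else fallback_subset
    if not feasible:
        warnings.warn(
            "background cap infeasible for every subset; returning the "
            "lowest-background subset",
            stacklevel=2,
        )
    obj, bg = evaluate(chosen)
    return TuneReport(
        selected=tuple(sorted(chosen, key=lambda e: e.name)),
        params=apply_mutations(params, chosen),
        objective=obj,
        background=bg,
        feasible=feasible,
        n_evaluated=n_eval,
    )
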