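"""Deterministic steady-state expression models for the studied circuits.

Each model maps a cell's plasmid genotype ``(x_m, P)`` to a reporter level
in arbitrary units.  Degradation/dilution rates are absorbed into the
synthesis-rate units, so only ratios and trends across genotypes and copy
numbers are meaningful.  Five architectures are covered:

``constitutive_target``
    The reporter is expressed constitutively from each plasmid copy; only
    corrected (mutated) copies fluoresce, so ``F = a * x_m``.
``iffl_gain``
    An incoherent feedforward loop holds the *total* target synthesis
    constant across copy numbers, making the per-copy rate ``alpha_tot/P``;
    gain-of-function mutants therefore express ``F = alpha_tot * x_m / P``.
``iffl_loss``
    The IFFL dosage-compensates a repressor (LacI).  Loss-of-function
    mutations remove the fraction ``x_m/P`` of functional repressor, and
    the reporter responds through a Hill repression function.
``rep_constitutive``
    Reporter repressed by a constitutively expressed repressor, both on the
    same plasmid.  The mutation target is either the repressor ``coding``
    sequence (intact copies compensate) or its ``promoter``/operator
    (a mutated copy expresses unrepressed, unmaskable by intact copies).
``rep_autoregulated``
    Same two targets, but the repressor represses its own synthesis; its
    steady-state level is the fixed point of the autoregulation balance.

Mutated repressor protein is treated as fully non-functional, and a
promoter/operator mutation as fully unrepressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError

CIRCUIT_KINDS = (
    "constitutive_target",
    "iffl_gain",
    "iffl_loss",
    "rep_constitutive",
    "rep_autoregulated",
)
TARGET_SITES = ("coding", "promoter")

#: Circuits whose mutation target sits in a repressor gene or its promoter.
REPRESSOR_CIRCUITS = ("rep_constitutive", "rep_autoregulated")


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic parameters of one regulatory architecture.

    alpha_tot
        Total dosage-compensated synthesis capacity of the IFFL-controlled
        gene (a.u./time); the per-copy rate is ``alpha_tot / P``.
    a
        Per-copy constitutive synthesis rate of the repressor (a.u./time).
    beta
        Per-copy maximal reporter synthesis rate (a.u./time).
    K
        Repression half-saturation constant (a.u.).
    n
        Hill coefficient (>= 1).
    target_site
        ``"coding"`` or ``"promoter"``; required for the ``rep_*`` circuits.
    """

    circuit: str
    alpha_tot: float = 1.0
    a: float = 1.0
    beta: float = 1.0
    K: float = 1.0
    n: float = 2.0
    target_site: str | None = None

    def __post_init__(self) -> None:
        if self.circuit not in CIRCUIT_KINDS:
            raise ConfigurationError(f"unknown circuit {self.circuit!r}; choose from {CIRCUIT_KINDS}")
        if min(self.alpha_tot, self.a, self.beta, self.K) <= 0:
            raise ConfigurationError("alpha_tot, a, beta and K must be positive")
        if self.n < 1:
            raise ConfigurationError(f"Hill coefficient n={self.n} must be >= 1")
        if self.circuit in REPRESSOR_CIRCUITS and self.target_site not in TARGET_SITES:
            raise ConfigurationError(
                f"circuit {self.circuit!r} requires target_site in {TARGET_SITES}"
            )


def _check_genotype(x_m, P) -> tuple[np.ndarray, int]:
    x_m = np.asarray(x_m)
    if P < 1:
        raise ConfigurationError(f"plasmid copy number P={P} must be >= 1")
    if (x_m < 0).any() or (x_m > P).any():
        raise ConfigurationError("x_m must satisfy 0 <= x_m <= P")
    return x_m, int(P)


def hill_repression(L, K: float, n: float):
    """Fraction of promoter activity remaining under repressor level ``L``."""
    return 1.0 / (1.0 + (np.asarray(L, dtype=float) / K) ** n)


def expr_constitutive_target(x_m, P: int, params: CircuitParams):
    """Reporter level ``a * x_m``: linear in the number of corrected copies."""
    x_m, P = _check_genotype(x_m, P)
    return params.a * x_m.astype(float)


def expr_iffl_gain(x_m, P: int, params: CircuitParams):
    """Gain-of-function reporter under IFFL dosage compensation.

    The per-copy synthesis rate is ``alpha_tot / P`` (total output is
    PCN-independent), so ``F = alpha_tot * x_m / P``.
    """
    x_m, P = _check_genotype(x_m, P)
    return params.alpha_tot * x_m / P


def expr_iffl_loss(x_m, P: int, params: CircuitParams):
    """Reporter repressed by a dosage-compensated repressor.

    Functional repressor ``L = alpha_tot * (P - x_m) / P`` (only intact
    copies contribute); reporter ``F = beta / (1 + (L/K)^n)``.
    """
    x_m, P = _check_genotype(x_m, P)
    L = params.alpha_tot * (P - x_m) / P
    return params.beta * hill_repression(L, params.K, params.n)


def expr_repressor_constitutive(x_m, P: int, params: CircuitParams):
    """Reporter level for a constitutively expressed repressor.

    coding target
        ``L = a * (P - x_m)``; all ``P`` reporter copies stay repressible:
        ``F = P * beta / (1 + (L/K)^n)``.
    promoter target
        The repressor pool is intact, ``L = a * P``, but each mutated copy
        expresses unrepressed: ``F = x_m * beta + (P - x_m) * beta / (1 + (L/K)^n)``.
    """
    x_m, P = _check_genotype(x_m, P)
    if params.target_site == "coding":
        L = params.a * (P - x_m)
        return P * params.beta * hill_repression(L, params.K, params.n)
    if params.target_site == "promoter":
        L = params.a * P
        return params.beta * (x_m + (P - x_m) * hill_repression(L, params.K, params.n))
    raise ConfigurationError("target_site must be 'coding' or 'promoter'")


def solve_repressor_fixed_point(
    rhs: Callable[[float], float],
    rtol: float = 1e-12,
) -> float:
    """Unique root of ``L = rhs(L)`` for continuous, non-increasing ``rhs >= 0``.

    Because ``L - rhs(L)`` is strictly increasing the root is unique and
    bracketed by ``[0, rhs(0)]``; it is located by Brent's method to the
    requested relative tolerance.
    """
    upper = float(rhs(0.0))
    if not np.isfinite(upper) or upper < 0:
        raise ConfigurationError(f"rhs(0)={upper} must be finite and non-negative")
    if upper == 0.0:
        return 0.0
    f = lambda L: L - rhs(L)
    if f(upper) < 0:
        raise ConfigurationError("rhs must be non-increasing: no bracket on [0, rhs(0)]")
    return float(brentq(f, 0.0, upper, rtol=max(rtol, 4e-16), xtol=1e-300))


def _autoreg_level(x_m: int, P: int, params: CircuitParams) -> float:
    """Steady-state functional-repressor level under negative autoregulation."""
    a, K, n = params.a, params.K, params.n
    if params.target_site == "coding":
        intact = P - x_m
        rhs = lambda L: intact * a * float(hill_repression(L, K, n))
    else:  # promoter: mutated copies transcribe the repressor unrepressed
        intact = P - x_m
        rhs = lambda L: x_m * a + intact * a * float(hill_repression(L, K, n))
    return solve_repressor_fixed_point(rhs)


def expr_repressor_autoregulated(x_m, P: int, params: CircuitParams):
    """Reporter level for a self-repressing repressor (polycistronic operon).

    The repressor level solves the autoregulation fixed point
    ``L = (P - x_m) * a * h(L)`` (coding target) or
    ``L = x_m * a + (P - x_m) * a * h(L)`` (promoter target) with
    ``h(L) = 1 / (1 + (L/K)^n)``; the reporter shares each copy's promoter,
    so ``F = P * beta * h(L)`` resp.
    ``F = x_m * beta + (P - x_m) * beta * h(L)``.
    """
    x_m, P = _check_genotype(x_m, P)
    if params.target_site not in TARGET_SITES:
        raise ConfigurationError("target_site must be 'coding' or 'promoter'")
    scalar = x_m.ndim == 0
    values = np.atleast_1d(x_m).astype(np.int64)
    # x_m ranges over at most P+1 integers; solve once per distinct genotype.
    unique, inverse = np.unique(values, return_inverse=True)
    out_unique = np.empty(len(unique))
    for i, xm in enumerate(unique):
        L = _autoreg_level(int(xm), P, params)
        h = float(hill_repression(L, params.K, params.n))
        if params.target_site == "coding":
            out_unique[i] = P * params.beta * h
        else:
            out_unique[i] = xm * params.beta + (P - xm) * params.beta * h
    out = out_unique[inverse]
    return float(out[0]) if scalar else out


_DISPATCH = {
    "constitutive_target": expr_constitutive_target,
    "iffl_gain": expr_iffl_gain,
    "iffl_loss": expr_iffl_loss,
    "rep_constitutive": expr_repressor_constitutive,
    "rep_autoregulated": expr_repressor_autoregulated,
}


def expression(x_m, P: int, params: CircuitParams):
    """Reporter level of ``params.circuit`` for genotype(s) ``x_m`` at copy number ``P``."""
    return _DISPATCH[params.circuit](x_m, P, params)


def baseline_expression(P: int, params: CircuitParams) -> float:
    """Wild-type (``x_m = 0``) reporter level of the same circuit at the same ``P``."""
    return float(np.asarray(expression(0, P, params)))


def expression_by_cell(x_m, x_wt, params: CircuitParams) -> np.ndarray:
    """Per-cell reporter levels using each cell's own total copy number.

    Simulated cells carry ``x_m + x_wt`` copies that fluctuate around the
    average PCN; the dosage entering the expression model is the cell's own
    total.  Cells that hold zero plasmids express nothing.
    """
    x_m = np.asarray(x_m, dtype=np.int64)
    x_wt = np.asarray(x_wt, dtype=np.int64)
    totals = x_m + x_wt
    out = np.zeros(len(x_m))
    for total in np.unique(totals):
        if total == 0:
            continue
        mask = totals == total
        out[mask] = np.asarray(expression(x_m[mask], int(total), params), dtype=float)
    return out
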