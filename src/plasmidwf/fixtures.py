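"""Seeded synthetic fixtures: small genotype populations, expression tables
and fluctuation datasets for testing every module without large simulations.

All generators are bit-reproducible from ``(kind, parameters, seed)``; named
sub-streams are derived by stable hashing of the fixture name so different
fixtures built from one seed are statistically independent.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .circuit_models import CircuitParams, expression
from .errors import ConfigurationError
from .fluctuation import FluctuationDataset, ld_sample
from .wf_sim import NO_MUTATION, Population

FIXTURE_KINDS = ("genotype_grid", "ld_counts", "expression_table")


def fixture_rng(seed: int, name: str) -> np.random.Generator:
    """RNG sub-stream for fixture ``name``, stable across runs and platforms."""
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def make_genotype_grid(P: int) -> pd.DataFrame:
    """All ``P + 1`` genotypes ``(x_m, x_wt)`` with ``x_m + x_wt = P``.

    The exhaustive grid backs brute-force expression and detection oracles.
    """
    if P < 1:
        raise ConfigurationError(f"P={P} must be >= 1")
    x_m = np.arange(P + 1, dtype=np.int64)
    return pd.DataFrame({"x_m": x_m, "x_wt": P - x_m})


def make_binomial_population(
    n_cells: int,
    P: int,
    q: float,
    rng: np.random.Generator,
) -> Population:
    """Population with i.i.d. ``x_m ~ Binomial(P, q)`` per cell.

    A closed-form stand-in for simulator output: the expected mutant-cell
    fraction is ``1 - (1 - q)^P``, usable as an analytic detection oracle.
    """
    if not 0.0 <= q <= 1.0:
        raise ConfigurationError(f"q={q} outside [0, 1]")
    if n_cells < 1 or P < 1:
        raise ConfigurationError("n_cells and P must be >= 1")
    x_m = rng.binomial(P, q, n_cells).astype(np.int64)
    first = np.where(x_m > 0, 0, NO_MUTATION).astype(np.int64)
    return Population(x_m=x_m, x_wt=P - x_m, first_mutation_gen=first)


def make_ld_counts(
    m: float,
    n_cultures: int,
    n_final: float,
    seed: int,
) -> FluctuationDataset:
    """Seeded Luria-Delbruck mutant-count dataset (wraps :func:`ld_sample`)."""
    rng = fixture_rng(seed, f"ld_counts(m={m},r={n_cultures},nt={n_final})")
    return ld_sample(m, n_final, n_cultures, rng)


def make_expression_table(P: int, params: CircuitParams) -> pd.DataFrame:
    """Genotype grid at copy number ``P`` with the circuit's expression level."""
    grid = make_genotype_grid(P)
    grid["expression"] = np.asarray(expression(grid["x_m"].to_numpy(), P, params), dtype=float)
    return grid
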