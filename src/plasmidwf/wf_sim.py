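"""Wright-Fisher simulation of mutation dynamics on multicopy plasmids.

The population consists of ``N`` bacteria, each carrying plasmids at an
average copy number ``P`` (the PCN).  A cell's genotype is the pair
``(x_m, x_wt)`` of mutated and wild-type plasmid copies.  Generations are
discrete and non-overlapping; every generation applies four steps to every
cell:

1. *Mutation* — each wild-type plasmid converts to the mutated state
   independently with probability ``mu``.
2. *Replication* — the cell synthesises ``P' ~ Poisson(PCN)`` new plasmid
   copies; each new copy is mutant with probability equal to the mutated
   proportion ``x_m / (x_m + x_wt)`` within the cell.
3. *Partitioning* — the pooled ``P + P'`` copies are split between two
   daughters without segregational loss: one daughter receives
   ``floor(T/2)`` or ``ceil(T/2)`` copies (fair coin when ``T`` is odd) and
   its mutant count is a hypergeometric draw from the pool.
4. *Selection* — half of the ``2N`` daughters is sampled uniformly without
   replacement to restore the population size.

Mutations are neutral (no fitness difference between genotypes) and one-way
(no reversion).  The per-generation state is reported through
:class:`GenerationSummary`; :func:`run_simulation` drives seeded replicate
runs and :func:`sweep_pcn` repeats them across a list of copy numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError

logger = logging.getLogger(__name__)

#: Sentinel in ``Population.first_mutation_gen`` for lineages never mutated.
NO_MUTATION = -1

# Default study conditions: per-plasmid mutation probability per generation,
# constant population size, 22 h of growth at a 90 min doubling time
# (15 generations), the pSC101 copy-number variants, and replicate count.
DEFAULT_MU = 2.5e-6
DEFAULT_POP_SIZE = 100_000
DEFAULT_GENERATIONS = 15
DEFAULT_PCN_LIST = (3, 5, 9, 17, 25, 39, 79)
DEFAULT_REPLICATES = 50


def generations_from_culture_time(hours: float, doubling_time_min: float = 90.0) -> int:
    """Whole number of generations elapsed in a culture grown for ``hours``.

    With the default 90 min doubling time, a 22 h induction corresponds to
    ``round(22 * 60 / 90) = 15`` generations.
    """
    if hours <= 0 or doubling_time_min <= 0:
        raise ConfigurationError("culture time and doubling time must be positive")
    return int(round(hours * 60.0 / doubling_time_min))


@dataclass
class CellState:
    """Genotype of one cell: mutated and wild-type plasmid copy counts."""

    x_m: int
    x_wt: int
    first_mutation_gen: int | None = None

    def __post_init__(self) -> None:
        if self.x_m < 0 or self.x_wt < 0:
            raise SimulationError("plasmid counts must be non-negative")

    @property
    def total(self) -> int:
        return self.x_m + self.x_wt

    @property
    def is_mutant(self) -> bool:
        """A mutant cell carries at least one mutated plasmid."""
        return self.x_m >= 1


@dataclass
class Population:
    """Vectorised container for a population of :class:`CellState`.

    ``first_mutation_gen`` holds the generation index at which each lineage
    first acquired a mutant plasmid (:data:`NO_MUTATION` if never).  The
    attribute is inherited by both daughters at division, even by a daughter
    that happens to receive zero mutated copies; summaries nonetheless count
    only cells with ``x_m >= 1`` as mutant.
    """

    x_m: np.ndarray
    x_wt: np.ndarray
    first_mutation_gen: np.ndarray

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=np.int64)
        self.x_wt = np.asarray(self.x_wt, dtype=np.int64)
        self.first_mutation_gen = np.asarray(self.first_mutation_gen, dtype=np.int64)
        if not (len(self.x_m) == len(self.x_wt) == len(self.first_mutation_gen)):
            raise SimulationError("population arrays must have equal length")
        if (self.x_m < 0).any() or (self.x_wt < 0).any():
            raise SimulationError("plasmid counts must be non-negative")

    def __len__(self) -> int:
        return len(self.x_m)

    @classmethod
    def wild_type(cls, n_cells: int, pcn: int) -> "Population":
        """All-wild-type founder population with ``x_wt = pcn`` per cell."""
        return cls(
            x_m=np.zeros(n_cells, dtype=np.int64),
            x_wt=np.full(n_cells, pcn, dtype=np.int64),
            first_mutation_gen=np.full(n_cells, NO_MUTATION, dtype=np.int64),
        )

    @classmethod
    def from_cells(cls, cells: Sequence[CellState]) -> "Population":
        return cls(
            x_m=np.array([c.x_m for c in cells], dtype=np.int64),
            x_wt=np.array([c.x_wt for c in cells], dtype=np.int64),
            first_mutation_gen=np.array(
                [NO_MUTATION if c.first_mutation_gen is None else c.first_mutation_gen for c in cells],
                dtype=np.int64,
            ),
        )

    def to_cells(self) -> list[CellState]:
        return [
            CellState(int(m), int(w), None if g == NO_MUTATION else int(g))
            for m, w, g in zip(self.x_m, self.x_wt, self.first_mutation_gen)
        ]

    def copy(self) -> "Population":
        return Population(self.x_m.copy(), self.x_wt.copy(), self.first_mutation_gen.copy())

    @property
    def is_mutant(self) -> np.ndarray:
        return self.x_m >= 1

    @property
    def total(self) -> np.ndarray:
        return self.x_m + self.x_wt


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    mu
        Per-plasmid mutation probability per generation.  An editing window
        spanning ``w`` nucleotides with a per-nucleotide rate can be modelled
        by scaling ``mu`` with ``site_multiplier``.
    pop_size
        Constant number of cells ``N`` (must be even: selection keeps half
        of the ``2N`` daughters).
    generations
        Number of generations ``G`` to iterate.
    pcn
        Average plasmid copy number ``P``; also the founder ``x_wt``.
    n_replicates
        Independent replicate runs; replicate ``r`` uses an RNG stream
        derived deterministically from ``(seed, r)``.
    """

    mu: float = DEFAULT_MU
    pop_size: int = DEFAULT_POP_SIZE
    generations: int = DEFAULT_GENERATIONS
    pcn: int = 3
    n_replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    site_multiplier: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.effective_mu <= 1.0:
            problems.append(f"mu*site_multiplier={self.effective_mu} outside [0, 1]")
        if self.pop_size < 2 or self.pop_size % 2:
            problems.append(f"pop_size={self.pop_size} must be even and >= 2")
        if self.generations < 1:
            problems.append(f"generations={self.generations} must be >= 1")
        if self.pcn < 1:
            problems.append(f"pcn={self.pcn} must be >= 1")
        if self.n_replicates < 1:
            problems.append(f"n_replicates={self.n_replicates} must be >= 1")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @property
    def effective_mu(self) -> float:
        return self.mu * self.site_multiplier


@dataclass
class GenerationSummary:
    """Post-selection population statistics for one generation.

    ``emergence_histogram`` maps the generation of first mutation to the
    number of currently mutant cells descending from lineages that first
    mutated then.
    """

    gen: int
    n_mutant_cells: int
    mean_xm_per_mutant: float
    mean_frac_per_mutant: float
    total_mutant_plasmid_frac: float
    emergence_histogram: dict[int, int] = field(default_factory=dict)


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic, independent RNG stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


# ---------------------------------------------------------------------------
# The four per-generation steps


def mutation_step(pop: Population, mu: float, rng: np.random.Generator, gen: int = 0) -> Population:
    """STEP 1: convert wild-type plasmids to mutant with probability ``mu``.

    The number of conversions per cell is ``Binomial(x_wt, mu)``, which is
    the exact bounded form of the low-rate Poisson mutation process and can
    never exceed the available wild-type copies.  Records the generation of
    first mutation per lineage.  Updates ``pop`` in place and returns it.
    """
    if not 0.0 <= mu <= 1.0:
        raise ConfigurationError(f"mu={mu} outside [0, 1]")
    dx = rng.binomial(pop.x_wt, mu)
    pop.x_wt -= dx
    pop.x_m += dx
    newly = (dx > 0) & (pop.first_mutation_gen == NO_MUTATION)
    pop.first_mutation_gen[newly] = gen
    return pop


def replication_step(cell: CellState, pcn: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """STEP 2: draw ``P' ~ Poisson(pcn)`` new copies for one cell.

    Each new copy is mutant with probability equal to the mutated proportion
    ``x_m / (x_m + x_wt)`` within the cell.  Returns
    ``(p_new, new_m, new_wt)`` with ``new_m + new_wt == p_new``.
    """
    total = cell.total
    if total < 1:
        raise SimulationError("cannot replicate a cell with zero plasmids")
    p_new = int(rng.poisson(pcn))
    new_m = int(rng.binomial(p_new, cell.x_m / total)) if p_new else 0
    return p_new, new_m, p_new - new_m


def partition_step(total_m: int, total_wt: int, rng: np.random.Generator) -> tuple[CellState, CellState]:
    """STEP 3: split the pooled ``P + P'`` copies between two daughters.

    No segregational loss: every copy goes to one daughter.  With an odd
    pool a fair coin decides which daughter receives the extra copy; the
    daughter's mutant count is hypergeometric in the pool composition.
    """
    if total_m < 0 or total_wt < 0:
        raise SimulationError("negative plasmid counts in partition")
    pool = total_m + total_wt
    if pool < 1:
        raise SimulationError("cannot partition an empty plasmid pool")
    size_a = pool // 2 + (int(rng.integers(0, 2)) if pool % 2 else 0)
    a_m = int(rng.hypergeometric(total_m, total_wt, size_a)) if size_a else 0
    daughter_a = CellState(a_m, size_a - a_m)
    daughter_b = CellState(total_m - a_m, (pool - size_a) - (total_m - a_m))
    return daughter_a, daughter_b


def selection_step(pop: Population, rng: np.random.Generator) -> Population:
    """STEP 4: keep a uniform half of the ``2N`` daughters, discard the rest."""
    if len(pop) % 2:
        raise SimulationError(f"selection input size {len(pop)} is odd")
    keep = rng.permutation(len(pop))[: len(pop) // 2]
    return Population(
        x_m=pop.x_m[keep].copy(),
        x_wt=pop.x_wt[keep].copy(),
        first_mutation_gen=pop.first_mutation_gen[keep].copy(),
    )


def run_generation(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    gen: int = 0,
) -> tuple[Population, GenerationSummary]:
    """Advance the population by one full generation (steps 1-4), vectorised.

    Cells that (pathologically) hold zero plasmids neither replicate nor
    mutate; each division then simply passes the empty state on.
    """
    n = len(pop)
    mutation_step(pop, config.effective_mu, rng, gen)

    # STEP 2, vectorised over cells.
    total = pop.total
    p_new = rng.poisson(config.pcn, n)
    if (total < 1).any():
        p_new = np.where(total >= 1, p_new, 0)
        frac = np.divide(pop.x_m, np.maximum(total, 1), dtype=np.float64)
    else:
        frac = pop.x_m / total
    new_m = rng.binomial(p_new, frac)
    pool_m = pop.x_m + new_m
    pool_wt = pop.x_wt + (p_new - new_m)

    # STEP 3: daughter A size is floor(T/2) plus a fair coin for odd pools.
    pool = pool_m + pool_wt
    size_a = pool // 2 + (pool & 1) * rng.integers(0, 2, n)
    nonempty = pool >= 1
    a_m = np.zeros(n, dtype=np.int64)
    if nonempty.all():
        a_m = rng.hypergeometric(pool_m, pool_wt, size_a)
    elif nonempty.any():
        a_m[nonempty] = rng.hypergeometric(pool_m[nonempty], pool_wt[nonempty], size_a[nonempty])
    daughters = Population(
        x_m=np.concatenate([a_m, pool_m - a_m]),
        x_wt=np.concatenate([size_a - a_m, (pool - size_a) - (pool_m - a_m)]),
        first_mutation_gen=np.concatenate([pop.first_mutation_gen, pop.first_mutation_gen]),
    )

    new_pop = selection_step(daughters, rng)
    return new_pop, summarize_population(new_pop, gen)


def summarize_population(pop: Population, gen: int) -> GenerationSummary:
    """Compute the per-generation mutant statistics of a population."""
    if len(pop) == 0:
        raise SimulationError("cannot summarise an empty population")
    mutant = pop.is_mutant
    n_mutant = int(mutant.sum())
    total = pop.total
    total_plasmids = int(total.sum())
    total_frac = float(pop.x_m.sum() / total_plasmids) if total_plasmids else 0.0
    if n_mutant:
        xm_mut = pop.x_m[mutant]
        mean_xm = float(xm_mut.mean())
        mean_frac = float((xm_mut / total[mutant]).mean())
        gens, counts = np.unique(pop.first_mutation_gen[mutant], return_counts=True)
        hist = {int(g): int(c) for g, c in zip(gens, counts)}
    else:
        mean_xm = float("nan")
        mean_frac = float("nan")
        hist = {}
    return GenerationSummary(
        gen=gen,
        n_mutant_cells=n_mutant,
        mean_xm_per_mutant=mean_xm,
        mean_frac_per_mutant=mean_frac,
        total_mutant_plasmid_frac=total_frac,
        emergence_histogram=hist,
    )


# ---------------------------------------------------------------------------
# Whole-run drivers


@dataclass
class SimulationResult:
    """Per-replicate, per-generation summaries of one simulation run."""

    config: SimConfig
    summaries: list[list[GenerationSummary]]
    final_populations: list[Population] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-generation summary table."""
        rows = [
            {
                "replicate": rep,
                "gen": s.gen,
                "pcn": self.config.pcn,
                "n_mutant_cells": s.n_mutant_cells,
                "mean_xm_per_mutant": s.mean_xm_per_mutant,
                "mean_frac_per_mutant": s.mean_frac_per_mutant,
                "total_mutant_plasmid_frac": s.total_mutant_plasmid_frac,
            }
            for rep, gens in enumerate(self.summaries)
            for s in gens
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "replicate",
                "gen",
                "pcn",
                "n_mutant_cells",
                "mean_xm_per_mutant",
                "mean_frac_per_mutant",
                "total_mutant_plasmid_frac",
            ],
        )

    def emergence_frame(self) -> pd.DataFrame:
        """Long-format emergence histograms (replicate, gen, emergence_gen, count)."""
        rows = [
            {"replicate": rep, "gen": s.gen, "emergence_gen": g, "count": c}
            for rep, gens in enumerate(self.summaries)
            for s in gens
            for g, c in sorted(s.emergence_histogram.items())
        ]
        return pd.DataFrame(rows, columns=["replicate", "gen", "emergence_gen", "count"])

    def final_summaries(self) -> list[GenerationSummary]:
        return [gens[-1] for gens in self.summaries]


def run_simulation(config: SimConfig, keep_final_population: bool = False) -> SimulationResult:
    """Run ``config.n_replicates`` seeded replicates of the full simulation.

    Each replicate starts from ``pop_size`` all-wild-type cells carrying
    ``pcn`` plasmids and iterates ``generations`` rounds of
    :func:`run_generation`.  Fully reproducible: replicate ``r`` draws from
    the stream seeded by ``(config.seed, r)``.
    """
    log_every = max(1, config.generations // 10)
    summaries: list[list[GenerationSummary]] = []
    finals: list[Population] = []
    for rep in range(config.n_replicates):
        rng = replicate_rng(config.seed, rep)
        logger.debug("replicate %d: seed stream (%d, %d)", rep, config.seed, rep)
        pop = Population.wild_type(config.pop_size, config.pcn)
        per_gen: list[GenerationSummary] = []
        for gen in range(1, config.generations + 1):
            pop, summary = run_generation(pop, config, rng, gen)
            per_gen.append(summary)
            if gen % log_every == 0:
                logger.info(
                    "pcn=%d replicate=%d gen=%d/%d mutants=%d",
                    config.pcn, rep, gen, config.generations, summary.n_mutant_cells,
                )
        summaries.append(per_gen)
        if keep_final_population:
            finals.append(pop)
    return SimulationResult(config, summaries, finals if keep_final_population else None)


def sweep_pcn(
    config: SimConfig,
    pcn_list: Sequence[int] = DEFAULT_PCN_LIST,
    keep_final_population: bool = False,
) -> dict[int, SimulationResult]:
    """Repeat :func:`run_simulation` for each plasmid copy number in the list."""
    results: dict[int, SimulationResult] = {}
    for pcn in pcn_list:
        results[int(pcn)] = run_simulation(
            replace(config, pcn=int(pcn)), keep_final_population=keep_final_population
        )
    return results


def sweep_to_frame(results: Mapping[int, SimulationResult]) -> pd.DataFrame:
    """Concatenate per-PCN summary tables into one tidy frame."""
    return pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
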