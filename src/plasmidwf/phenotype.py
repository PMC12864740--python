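"""Threshold-based detection of phenotypic mutants.

A cell is *detected* as mutant when its reporter expression exceeds the
wild-type baseline of the same circuit at the same copy number by more than
a detection threshold (strict inequality), mirroring a flow-cytometry gate.
Thresholds are most usefully given in relative units — fractions of the
dosage-compensated total ``alpha_tot`` for gain circuits or of the maximal
per-copy rate ``beta`` for repressor-based circuits — so that sweeps are
comparable across copy numbers; :func:`threshold_scale` supplies the
conversion.

:func:`sweep_threshold_pcn` joins final-generation genotype populations
from the Wright-Fisher simulator with a circuit model and tabulates the
detected-mutant ratio per (PCN, threshold, replicate);
:func:`phenotypic_rate_by_pcn` pushes per-replicate detected counts through
fluctuation analysis to obtain the phenotypic mutation rate, the pipeline
used for the experimental rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_models import CircuitParams, expression_by_cell
from .errors import ConfigurationError
from .fluctuation import FluctuationDataset, estimate
from .wf_sim import SimulationResult


@dataclass(frozen=True)
class DetectionConfig:
    """Detection gate: strictly-greater comparison above baseline.

    threshold
        Absolute detection limit in the expression units of the circuit.
    noise_sigma
        Optional log-normal measurement noise (sigma of ln expression,
        default 0 = off) for robustness checks.
    """

    threshold: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError(f"threshold={self.threshold} must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


def threshold_scale(params: CircuitParams) -> float:
    """Expression unit used for relative thresholds of a given circuit."""
    if params.circuit == "iffl_gain":
        return params.alpha_tot
    if params.circuit == "constitutive_target":
        return params.a
    return params.beta


def detect_mutant_ratio(
    expressions: np.ndarray,
    baseline: float,
    config: DetectionConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of cells with ``expression - baseline > threshold``."""
    expressions = np.asarray(expressions, dtype=float)
    if expressions.size == 0:
        raise ConfigurationError("cannot compute a detected ratio for an empty population")
    if (expressions < 0).any():
        raise ConfigurationError("expression levels must be non-negative")
    if config.noise_sigma > 0:
        if rng is None:
            raise ConfigurationError("measurement noise requires an rng")
        expressions = expressions * rng.lognormal(0.0, config.noise_sigma, expressions.shape)
    return float(np.mean(expressions - baseline > config.threshold))


def mutation_expression_shift(pop, params: CircuitParams) -> np.ndarray:
    """Per-cell expression shift attributable to mutated copies.

    Each cell is compared with a wild-type cell at the *same* total copy
    number, so stochastic copy-number variation alone never produces a
    signal; only the replacement of wild-type by mutated copies does.  This
    mirrors gating against the wild-type distribution: dosage noise is part
    of the baseline.
    """
    totals = pop.x_m + pop.x_wt
    expr = expression_by_cell(pop.x_m, pop.x_wt, params)
    base = expression_by_cell(np.zeros_like(totals), totals, params)
    # expression is non-decreasing in x_m, so the shift is non-negative up
    # to solver round-off; clip to keep downstream validation exact
    return np.maximum(expr - base, 0.0)


def _final_populations(results: Mapping[int, SimulationResult], pcn: int):
    if pcn not in results:
        raise ConfigurationError(f"no simulation output for pcn={pcn}")
    result = results[pcn]
    if not result.final_populations:
        raise ConfigurationError(
            "simulation results lack final populations; rerun with keep_final_population=True"
        )
    return result.final_populations


def sweep_threshold_pcn(
    results: Mapping[int, SimulationResult],
    params: CircuitParams,
    thresholds: Sequence[float],
    pcn_list: Sequence[int] | None = None,
    relative: bool = True,
) -> pd.DataFrame:
    """Detected-mutant ratio per (pcn, threshold, replicate).

    ``thresholds`` are interpreted in relative units (see
    :func:`threshold_scale`) unless ``relative=False``.  Expression is the
    deterministic circuit output of each cell's final-generation genotype
    at the cell's own copy number, gated against the wild-type level at
    that same copy number (:func:`mutation_expression_shift`).
    """
    pcns = list(pcn_list) if pcn_list is not None else sorted(results)
    scale = threshold_scale(params) if relative else 1.0
    rows = []
    for pcn in pcns:
        populations = _final_populations(results, pcn)
        for rep, pop in enumerate(populations):
            shift = mutation_expression_shift(pop, params)
            for thr in thresholds:
                config = DetectionConfig(threshold=float(thr) * scale)
                rows.append(
                    {
                        "pcn": pcn,
                        "threshold": float(thr),
                        "replicate": rep,
                        "detected_ratio": detect_mutant_ratio(shift, 0.0, config),
                    }
                )
    return pd.DataFrame(rows, columns=["pcn", "threshold", "replicate", "detected_ratio"])


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean detected ratio with normal-approximation 95% CI over replicates."""
    def _agg(g: pd.Series) -> pd.Series:
        mean = g.mean()
        sem = g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
        return pd.Series({"mean": mean, "ci_low": mean - 1.96 * sem, "ci_high": mean + 1.96 * sem})

    out = (
        table.groupby(["pcn", "threshold"])["detected_ratio"].apply(_agg).unstack().reset_index()
    )
    return out


def detected_counts(
    results: Mapping[int, SimulationResult],
    params: CircuitParams,
    threshold: float,
    pcn_list: Sequence[int] | None = None,
    relative: bool = True,
) -> pd.DataFrame:
    """Per-replicate detected-mutant cell counts (pcn, replicate, count, n_cells)."""
    pcns = list(pcn_list) if pcn_list is not None else sorted(results)
    scale = threshold_scale(params) if relative else 1.0
    config_thr = float(threshold) * scale
    rows = []
    for pcn in pcns:
        for rep, pop in enumerate(_final_populations(results, pcn)):
            shift = mutation_expression_shift(pop, params)
            rows.append(
                {
                    "pcn": pcn,
                    "replicate": rep,
                    "count": int(np.sum(shift > config_thr)),
                    "n_cells": len(pop),
                }
            )
    return pd.DataFrame(rows, columns=["pcn", "replicate", "count", "n_cells"])


def phenotypic_rate_by_pcn(
    results: Mapping[int, SimulationResult],
    params: CircuitParams,
    threshold: float,
    pcn_list: Sequence[int] | None = None,
    relative: bool = True,
    method: str = "mle",
) -> pd.DataFrame:
    """Fluctuation-analysis phenotypic mutation rate per copy number.

    Treats each simulation replicate as one parallel culture whose
    detected-mutant count feeds the Luria-Delbruck estimator; returns one
    row per PCN with ``m_hat``, ``rate`` and its 95% CI.
    """
    table = detected_counts(results, params, threshold, pcn_list, relative)
    rows = []
    for pcn, group in table.groupby("pcn"):
        data = FluctuationDataset(
            counts=group["count"].to_numpy(), n_final=float(group["n_cells"].iloc[0])
        )
        est = estimate(data, method=method)
        rows.append(
            {
                "pcn": int(pcn),
                "m_hat": est.m_hat,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows, columns=["pcn", "m_hat", "rate", "ci_low", "ci_high", "method"])
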