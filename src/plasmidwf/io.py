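"""Configuration loading, result serialisation and run manifests.

A run is configured by a flat YAML (or JSON) mapping whose keys mirror the
dataclasses in :mod:`plasmidwf.wf_sim` and :mod:`plasmidwf.circuit_models`;
CLI flags override file values.  Every CLI run writes tidy CSV tables
(floats at 10 significant digits, stable column order) plus one
``manifest.json`` recording the configuration snapshot, seed, package
version and SHA-256 digests of the outputs, so that identically seeded
runs can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .circuit_models import CircuitParams
from .errors import ConfigurationError
from .phenotype import DetectionConfig
from .wf_sim import DEFAULT_PCN_LIST, SimConfig

logger = logging.getLogger(__name__)

_SIM_KEYS = {"mu", "pop_size", "generations", "pcn", "n_replicates", "seed", "site_multiplier"}
_CIRCUIT_KEYS = {"circuit", "alpha_tot", "a", "beta", "K", "n", "target_site"}
_OTHER_KEYS = {"pcn_list", "thresholds", "noise_sigma"}
_ALLOWED_KEYS = _SIM_KEYS | _CIRCUIT_KEYS | _OTHER_KEYS

DEFAULT_THRESHOLDS = (0.0, 0.05, 0.1, 0.2)


@dataclass(frozen=True)
class RunSettings:
    """Validated, defaulted configuration for one CLI run."""

    sim: SimConfig
    pcn_list: tuple[int, ...]
    circuit: CircuitParams
    thresholds: tuple[float, ...]
    noise_sigma: float = 0.0


def _dedup_pcn(values) -> tuple[int, ...]:
    seen: dict[int, None] = {}
    for v in values:
        v = int(v)
        if v in seen:
            logger.warning("duplicate pcn value %d dropped from pcn_list", v)
        seen[v] = None
    return tuple(seen)


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, object] | None = None,
) -> RunSettings:
    """Load and validate a run configuration.

    ``path`` may be absent (all defaults) or a YAML/JSON file with a flat
    mapping; ``overrides`` (e.g. parsed CLI flags, ``None`` values ignored)
    take precedence over file values.  Unknown keys and out-of-range values
    raise :class:`ConfigurationError` naming the offending fields.
    """
    raw: dict[str, object] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            raw[key] = value

    unknown = sorted(set(raw) - _ALLOWED_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration keys: {', '.join(unknown)}; "
            f"allowed: {', '.join(sorted(_ALLOWED_KEYS))}"
        )

    pcn_list = _dedup_pcn(raw.get("pcn_list", DEFAULT_PCN_LIST))
    if not pcn_list:
        raise ConfigurationError("pcn_list must not be empty")
    sim_kwargs = {k: raw[k] for k in _SIM_KEYS if k in raw}
    sim_kwargs.setdefault("pcn", pcn_list[0])
    sim = SimConfig(**sim_kwargs)

    circuit_kwargs = {k: raw[k] for k in _CIRCUIT_KEYS if k in raw}
    circuit_kwargs.setdefault("circuit", "iffl_gain")
    circuit = CircuitParams(**circuit_kwargs)

    thresholds = tuple(float(t) for t in raw.get("thresholds", DEFAULT_THRESHOLDS))
    noise_sigma = float(raw.get("noise_sigma", 0.0))
    DetectionConfig(threshold=thresholds[0] if thresholds else 0.0, noise_sigma=noise_sigma)
    if any(t < 0 for t in thresholds):
        raise ConfigurationError("thresholds must be non-negative")
    return RunSettings(
        sim=sim, pcn_list=pcn_list, circuit=circuit,
        thresholds=thresholds, noise_sigma=noise_sigma,
    )


def settings_to_dict(settings: RunSettings) -> dict:
    out = asdict(settings.sim)
    out["pcn_list"] = list(settings.pcn_list)
    out.update(asdict(settings.circuit))
    out["thresholds"] = list(settings.thresholds)
    out["noise_sigma"] = settings.noise_sigma
    return out


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    command: str
    seed: int
    config: dict
    version: str = __version__
    created_utc: str = ""
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    command: str,
    seed: int,
    config: Mapping[str, object],
) -> RunManifest:
    """Write tidy CSV tables plus a ``manifest.json`` into ``outdir``.

    CSVs always carry a header row (even when empty), use 10-significant-
    digit floats, and identically seeded re-runs are byte-identical.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output directory {outdir}: {exc}") from exc
    manifest = RunManifest(command=command, seed=int(seed), config=dict(config))
    for name, table in tables.items():
        dest = outdir / f"{name}.csv"
        try:
            table.to_csv(dest, index=False, float_format="%.10g")
        except OSError as exc:
            raise ConfigurationError(f"failed writing {dest}: {exc}") from exc
        manifest.outputs[dest.name] = _sha256(dest)
    manifest.created_utc = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
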