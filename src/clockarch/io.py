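"""Configuration, archive serialization and test-fixture generation.

A run is fully determined by a :class:`RunConfig` plus its seed: the
global seed is split (via ``numpy.random.SeedSequence.spawn``) into
independent child streams for the random phase, the GA phase, and fixture
generation, so each subsystem is independently reproducible.

Archives round-trip through JSON at full double precision; the CSV export
is a flat human-readable table (17 significant digits, documented lossy
for provenance fields).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dynamics, search
from .models import (
    Architecture,
    ConfigurationError,
    ParameterSet,
    build_model,
)
from .search import ArchiveEntry, SearchConfig, SolutionArchive

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_archive",
    "load_archive",
    "archive_to_csv",
    "fixture_oscillator",
    "FixtureError",
]

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT = "clockarch-archive"
ARCHIVE_VERSION = 1

_FIXED_PARAMETER_KEYS = {"h", "hill_coefficient"}


class FixtureError(RuntimeError):
    """A test-fixture search failed; dependent tests must not silently pass."""


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

_SEARCH_KEYS = {
    "fold_range", "rho", "y_level_constraint", "period_window",
    "amplitude_window", "n_solutions", "random_phase_trials",
    "population_size", "max_generations", "crossover_rate", "blx_alpha",
    "mutation_rate", "mutation_sigma", "elite_count", "min_distance",
    "horizon", "transient",
}
_QMPS_KEYS = {"delta", "targets"}
_ENTRAIN_KEYS = {"zeta", "delta", "cycles", "discard"}
_TOP_KEYS = {"model", "seed", "search", "qmps", "entrainment", "output_dir",
             "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Validated, defaults-filled configuration of a full pipeline run."""

    model: Architecture
    seed: int = 0
    search: SearchConfig = None  # type: ignore[assignment]
    qmps_delta: float = 0.001
    qmps_targets: tuple[str, ...] = ("period", "amplitude")
    zeta_grid: tuple[float, float, int] = (16.0, 32.0, 33)   # lo, hi, n
    delta_grid: tuple[float, float, int] = (1.1, 11.0, 33)
    forcing_cycles: int = 80
    discard_cycles: int = 40
    output_dir: str = "results"
    log_level: str = "INFO"

    def zeta_values(self) -> np.ndarray:
        lo, hi, n = self.zeta_grid
        return np.linspace(lo, hi, int(n))

    def delta_values(self) -> np.ndarray:
        lo, hi, n = self.delta_grid
        return np.geomspace(lo, hi, int(n))


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}"
        )


def _parse_interval(value, name: str) -> Optional[tuple[float, float]]:
    if value is None:
        return None
    if not (isinstance(value, (list, tuple)) and len(value) == 2):
        raise ConfigurationError(f"{name} must be a [low, high] pair")
    lo = float(value[0]) if value[0] is not None else 0.0
    hi = float(value[1]) if value[1] is not None else math.inf
    if not lo < hi:
        raise ConfigurationError(f"{name}: low must be below high")
    return (lo, hi)


def build_run_config(raw: dict) -> RunConfig:
    """Validate a raw (YAML/JSON) mapping into a RunConfig with defaults."""
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    model = Architecture.from_name(raw.get("model", "single"))
    seed = int(raw.get("seed", 0))

    s = dict(raw.get("search") or {})
    bad = _FIXED_PARAMETER_KEYS & set(s)
    if bad:
        raise ConfigurationError(
            f"the Hill coefficient is fixed and cannot be searched "
            f"(remove {', '.join(sorted(bad))} from search)"
        )
    _check_keys(s, _SEARCH_KEYS, "search")
    for key in ("fold_range", "period_window", "amplitude_window"):
        if key in s:
            s[key] = tuple(float(v) for v in s[key])
    if "y_level_constraint" in s:
        s["y_level_constraint"] = _parse_interval(
            s["y_level_constraint"], "search.y_level_constraint"
        )
    search_cfg = SearchConfig(architecture=model, seed=seed, **s)

    q = dict(raw.get("qmps") or {})
    _check_keys(q, _QMPS_KEYS, "qmps")
    qmps_delta = float(q.get("delta", 0.001))
    if not (0.0 < qmps_delta <= 0.01):
        raise ConfigurationError("qmps.delta must be in (0, 0.01]")
    qmps_targets = tuple(q.get("targets", ("period", "amplitude")))
    for t in qmps_targets:
        if t not in ("period", "amplitude"):
            raise ConfigurationError(f"unknown qmps target {t!r}")

    e = dict(raw.get("entrainment") or {})
    _check_keys(e, _ENTRAIN_KEYS, "entrainment")

    def _grid(key, default):
        if key not in e:
            return default
        lo, hi, n = e[key]
        if not (0 < float(lo) < float(hi)) or int(n) < 1:
            raise ConfigurationError(f"entrainment.{key}: bad grid spec")
        return (float(lo), float(hi), int(n))

    return RunConfig(
        model=model,
        seed=seed,
        search=search_cfg,
        qmps_delta=qmps_delta,
        qmps_targets=qmps_targets,
        zeta_grid=_grid("zeta", RunConfig.zeta_grid),
        delta_grid=_grid("delta", RunConfig.delta_grid),
        forcing_cycles=int(e.get("cycles", 80)),
        discard_cycles=int(e.get("discard", 40)),
        output_dir=str(raw.get("output_dir", "results")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return build_run_config(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    # architecture and seed live at the top level of the document
    sc = dataclasses.asdict(cfg.search)
    sc.pop("architecture")
    sc.pop("seed")
    return {
        "model": cfg.model.value,
        "seed": cfg.seed,
        "search": sc,
        "qmps": {"delta": cfg.qmps_delta, "targets": list(cfg.qmps_targets)},
        "entrainment": {
            "zeta": list(cfg.zeta_grid),
            "delta": list(cfg.delta_grid),
            "cycles": cfg.forcing_cycles,
            "discard": cfg.discard_cycles,
        },
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }


def save_config(cfg: RunConfig, path: "str | Path") -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg)))


# ---------------------------------------------------------------------------
# Archive serialization
# ---------------------------------------------------------------------------


def _features_to_dict(f: dynamics.OscillationFeatures) -> dict:
    return {
        "sustained": bool(f.sustained),
        "period": f.period,
        "amplitude": f.amplitude,
        "period_cv": f.period_cv,
        "amplitude_cv": f.amplitude_cv,
        "n_peaks": int(f.n_peaks),
        "mean_levels": {k: float(v) for k, v in f.mean_levels.items()},
    }


def _features_from_dict(d: dict) -> dynamics.OscillationFeatures:
    return dynamics.OscillationFeatures(
        sustained=bool(d["sustained"]),
        period=d.get("period"),
        amplitude=d.get("amplitude"),
        period_cv=d.get("period_cv"),
        amplitude_cv=d.get("amplitude_cv"),
        n_peaks=int(d.get("n_peaks", 0)),
        mean_levels=dict(d.get("mean_levels", {})),
    )


def _search_config_to_dict(cfg: SearchConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["architecture"] = cfg.architecture.value
    return d


def _search_config_from_dict(d: dict) -> SearchConfig:
    d = dict(d)
    for key in ("fold_range", "period_window", "amplitude_window"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("y_level_constraint") is not None:
        d["y_level_constraint"] = tuple(
            math.inf if v is None else float(v)
            for v in d["y_level_constraint"]
        )
    return SearchConfig(**d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_archive(archive: SolutionArchive, path: "str | Path") -> None:
    """Write an archive to JSON at full double precision."""
    doc = {
        "format": ARCHIVE_FORMAT,
        "version": ARCHIVE_VERSION,
        "config": _search_config_to_dict(archive.config),
        "n_evaluations": archive.n_evaluations,
        "complete": archive.complete,
        "entries": [
            {
                "params": e.params.to_dict(),
                "features": _features_to_dict(e.features),
                "gamma": e.gamma,
                "total_y": e.total_y,
                "provenance": e.provenance,
            }
            for e in archive.entries
        ],
    }

    def _clean(obj):  # JSON has no Infinity; encode as null (open interval)
        if isinstance(obj, float) and math.isinf(obj):
            return None
        return obj

    cfg = doc["config"]
    if cfg.get("y_level_constraint") is not None:
        cfg["y_level_constraint"] = [
            _clean(v) for v in cfg["y_level_constraint"]
        ]
    Path(path).write_text(json.dumps(doc, default=_json_default))


def load_archive(
    path: "str | Path", revalidate: int = 0, seed: int = 0
) -> SolutionArchive:
    """Load an archive; a truncated/invalid file raises, never a partial
    archive.

    ``revalidate > 0`` re-simulates that many randomly chosen entries and
    checks their features against the stored config's windows.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != ARCHIVE_FORMAT:
        raise ConfigurationError(f"{path}: not a {ARCHIVE_FORMAT} file")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ConfigurationError(
            f"{path}: archive version {doc.get('version')} "
            f"!= supported {ARCHIVE_VERSION}"
        )
    config = _search_config_from_dict(doc["config"])
    entries = []
    for raw in doc["entries"]:
        params = dict(raw["params"])
        params.pop("h", None)
        entries.append(
            ArchiveEntry(
                params=ParameterSet(config.architecture, params),
                features=_features_from_dict(raw["features"]),
                gamma=raw.get("gamma"),
                total_y=raw.get("total_y"),
                provenance=dict(raw.get("provenance", {})),
            )
        )
    archive = SolutionArchive(
        config=config,
        entries=entries,
        n_evaluations=int(doc.get("n_evaluations", 0)),
        complete=bool(doc.get("complete", True)),
    )
    if revalidate > 0 and entries:
        rng = np.random.default_rng(seed)
        picks = rng.choice(
            len(entries), size=min(revalidate, len(entries)), replace=False
        )
        for k in picks:
            entry = entries[int(k)]
            model = build_model(config.architecture, entry.params)
            traj = dynamics.integrate(
                model, horizon=config.horizon, transient=config.transient
            )
            feats = dynamics.oscillation_features(traj)
            lo, hi = config.period_window
            alo, ahi = config.amplitude_window
            if not (
                feats.sustained
                and lo <= feats.period <= hi
                and alo <= feats.amplitude <= ahi
            ):
                raise ConfigurationError(
                    f"{path}: entry {k} fails re-validation against the "
                    f"stored fitness windows"
                )
    return archive


def archive_to_csv(archive: SolutionArchive, path: "str | Path") -> None:
    """Flat CSV: one row per solution (parameters + features)."""
    rows = []
    for e in archive.entries:
        row = dict(e.params.to_dict())
        row.update(
            period=e.features.period,
            amplitude=e.features.amplitude,
            sustained=e.features.sustained,
            gamma=e.gamma,
            total_y=e.total_y,
            phase=e.provenance.get("phase"),
            generation=e.provenance.get("generation"),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_FIXTURE_VERSION = 1  # bump when model equations or search defaults change


def _default_cache_dir() -> Path:
    env = os.environ.get("CLOCKARCH_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "clockarch"


def fixture_oscillator(
    architecture: "str | Architecture",
    seed: int = 1,
    rho: Optional[float] = None,
    cache_dir: "str | Path | None" = None,
):
    """One known-good oscillating parameter set per architecture.

    Runs a tiny TPS (archive size 1) and caches the result on disk keyed
    by (architecture, rho, seed, fixture version).  Returns
    ``(ParameterSet, OscillationFeatures)``; raises :class:`FixtureError`
    when the search fails, so dependent tests error instead of silently
    passing.
    """
    arch = Architecture.from_name(architecture)
    cache_dir = Path(cache_dir) if cache_dir else _default_cache_dir()
    rho_tag = "none" if rho is None else f"{rho:g}"
    cache = cache_dir / (
        f"fixture_v{_FIXTURE_VERSION}_{arch.value}_rho{rho_tag}_s{seed}.json"
    )
    if cache.exists():
        doc = json.loads(cache.read_text())
        params = dict(doc["params"])
        params.pop("h", None)
        return (
            ParameterSet(arch, params),
            _features_from_dict(doc["features"]),
        )
    cfg = SearchConfig(
        architecture=arch,
        rho=rho,
        n_solutions=1,
        random_phase_trials=300,
        population_size=40,
        max_generations=80,
        seed=seed,
    )
    try:
        archive = search.run_tps(cfg)
    except search.SearchError as exc:
        raise FixtureError(f"fixture search failed: {exc}") from exc
    if len(archive) < 1:
        raise FixtureError(
            f"fixture search for {arch.value} (seed {seed}) found no "
            f"acceptable oscillator"
        )
    entry = archive.entries[0]
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache.write_text(
        json.dumps(
            {
                "params": entry.params.to_dict(),
                "features": _features_to_dict(entry.features),
            }
        )
    )
    return entry.params, entry.features
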