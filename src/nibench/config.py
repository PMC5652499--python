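"""Scenario-grid configuration parsing, results writing and run manifests.

A simulation run is described by a small YAML (or JSON) document::

    n: [100, 200, 400, 800, 1600, 3200, 6400]
    dgp: [NCR, CR]
    failure:   {scale: 0.01,  shape: 0.71}
    mortality: {scale: 0.017, shape: 1.32}
    horizon: 10
    reps: 1000
    seed: 1
    benchmark:
      p_bm: 0.05
      margins: [0.01, 0.02, 0.03, 0.04, 0.05]
      alpha_one_sided: 0.025

Only ``n`` is required.  ``dgp`` defaults to NCR alone; mortality parameters
have no default and must be given whenever CR is requested.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    DEFAULT_FAILURE_PARAMS,
    DEFAULT_HORIZON,
    Dgp,
    ScenarioConfig,
    WeibullParams,
)
from .design import DEFAULT_MARGINS, BenchmarkSpec
from .engine import PerformanceSummary, summaries_to_frame

__all__ = ["ConfigError", "RunManifest", "parse_config", "parse_config_text", "write_results"]


class ConfigError(ValueError):
    """A configuration document failed validation; message carries the field path."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def _weibull(doc, path: str) -> WeibullParams:
    _require(isinstance(doc, dict), path, f"expected a mapping with scale/shape, got {doc!r}")
    unknown = set(doc) - {"scale", "shape"}
    _require(not unknown, path, f"unknown keys {sorted(unknown)}")
    _require("scale" in doc and "shape" in doc, path, "both scale and shape are required")
    try:
        return WeibullParams(scale=float(doc["scale"]), shape=float(doc["shape"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_TOP_KEYS = {"n", "dgp", "failure", "mortality", "horizon", "reps", "seed", "benchmark"}
_BM_KEYS = {"p_bm", "margins", "alpha_one_sided"}


def parse_config_text(text: str) -> tuple[list[ScenarioConfig], BenchmarkSpec]:
    """Parse and validate a YAML/JSON scenario-grid document."""
    doc = yaml.safe_load(text)
    _require(isinstance(doc, dict), "<root>", "config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    _require(not unknown, "<root>", f"unknown keys {sorted(unknown)}")
    _require("n" in doc, "n", "required")

    n_values = doc["n"] if isinstance(doc["n"], (list, tuple)) else [doc["n"]]
    _require(len(n_values) > 0, "n", "must be non-empty")
    for i, n in enumerate(n_values):
        _require(isinstance(n, int) and n >= 1, f"n[{i}]", f"must be a positive integer, got {n!r}")

    raw_dgps = doc.get("dgp", ["NCR"])
    if not isinstance(raw_dgps, (list, tuple)):
        raw_dgps = [raw_dgps]
    dgps: list[Dgp] = []
    for i, d in enumerate(raw_dgps):
        try:
            dgps.append(Dgp(str(d).upper()))
        except ValueError as exc:
            raise ConfigError(f"dgp[{i}]: must be NCR or CR, got {d!r}") from exc

    failure = (
        _weibull(doc["failure"], "failure") if "failure" in doc else DEFAULT_FAILURE_PARAMS
    )
    mortality = _weibull(doc["mortality"], "mortality") if "mortality" in doc else None
    if Dgp.CR in dgps:
        _require(mortality is not None, "mortality", "required when dgp includes CR")

    horizon = float(doc.get("horizon", DEFAULT_HORIZON))
    _require(horizon > 0, "horizon", f"must be positive, got {horizon}")
    reps = doc.get("reps", 1000)
    _require(isinstance(reps, int) and reps >= 1, "reps", f"must be a positive integer, got {reps!r}")
    seed = doc.get("seed", 0)
    _require(isinstance(seed, int), "seed", f"must be an integer, got {seed!r}")

    bm_doc = doc.get("benchmark", {}) or {}
    _require(isinstance(bm_doc, dict), "benchmark", "must be a mapping")
    unknown = set(bm_doc) - _BM_KEYS
    _require(not unknown, "benchmark", f"unknown keys {sorted(unknown)}")
    try:
        spec = BenchmarkSpec(
            p_bm=float(bm_doc.get("p_bm", 0.05)),
            margins=tuple(bm_doc.get("margins", DEFAULT_MARGINS)),
            alpha_one_sided=float(bm_doc.get("alpha_one_sided", 0.025)),
            horizon=horizon,
        )
    except ValueError as exc:
        raise ConfigError(f"benchmark: {exc}") from exc

    scenarios = [
        ScenarioConfig(
            n=int(n),
            dgp=dgp,
            failure_params=failure,
            mortality_params=mortality if dgp is Dgp.CR else None,
            horizon=horizon,
            reps=reps,
            seed=seed,
        )
        for dgp in dgps
        for n in n_values
    ]
    return scenarios, spec


def parse_config(path) -> tuple[list[ScenarioConfig], BenchmarkSpec]:
    """Read and validate a scenario-grid YAML/JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"<file>: config file not found: {path}")
    return parse_config_text(path.read_text())


def _grid_hash(scenarios: Sequence[ScenarioConfig]) -> str:
    canon = json.dumps(
        [dataclasses.asdict(s) for s in scenarios], sort_keys=True, default=str
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility metadata written next to every results file."""

    version: str
    grid_hash: str
    master_seed: int
    timestamp: str
    per_scenario_seeds: dict[str, int]

    @classmethod
    def for_run(
        cls, scenarios: Sequence[ScenarioConfig], master_seed: int
    ) -> "RunManifest":
        return cls(
            version=__version__,
            grid_hash=_grid_hash(scenarios),
            master_seed=int(master_seed),
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            per_scenario_seeds={s.scenario_id: s.seed for s in scenarios},
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_results(
    summaries: Sequence[PerformanceSummary],
    path,
    fmt: str = "csv",
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Write performance summaries as CSV or JSON with full float precision.

    Column order is fixed; percentages are on the 0-100 scale, probabilities on
    0-1 (column names disambiguate).  When a manifest is given, a
    ``<path>.manifest.json`` sidecar is written alongside.
    """
    path = Path(path)
    frame = summaries_to_frame(summaries)
    try:
        if fmt == "csv":
            frame.to_csv(path, index=False, float_format=None)
        elif fmt == "json":
            path.write_text(frame.to_json(orient="records", indent=2))
        else:
            raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    if manifest is not None:
        Path(f"{path}.manifest.json").write_text(manifest.to_json())
    return frame
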