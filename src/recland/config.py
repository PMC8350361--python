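"""Run configuration (TOML) and a small dependency-ordered stage runner."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field, fields

logger = logging.getLogger("recland")

FORMAT_VERSION = "1"


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Stage parameters with the published defaults.

    Defaults: intensity threshold lambda >= 4 for HRI calling, 1,000
    assignment replicates, 1,000 permutation simulations, 4 Mb comparison
    windows, 3% minor-allele-frequency floor. Every stochastic stage needs
    an explicit seed.
    """

    lambda_threshold: float = 4.0
    n_rep: int = 1000
    n_sim: int = 1000
    window_bp: int = 4_000_000
    maf: float = 0.03
    min_hri_bp: int = 1_000
    max_hri_bp: int = 200_000
    seeds: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        errors = []
        if self.n_rep < 1:
            errors.append("n_rep must be >= 1")
        if self.n_sim < 1:
            errors.append("n_sim must be >= 1")
        if self.window_bp <= 0:
            errors.append("window_bp must be positive")
        if not 0 <= self.maf <= 0.5:
            errors.append("maf must be in [0, 0.5]")
        if self.lambda_threshold <= 0:
            errors.append("lambda_threshold must be positive")
        if not 0 < self.min_hri_bp < self.max_hri_bp:
            errors.append("need 0 < min_hri_bp < max_hri_bp")
        if errors:
            raise ConfigError("; ".join(errors))

    def seed_for(self, stage: str) -> int:
        if stage not in self.seeds:
            raise ConfigError(f"stochastic stage {stage!r} has no seed")
        return int(self.seeds[stage])


def validate_config(path) -> RunConfig:
    """Parse and validate a TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e


@dataclass
class Stage:
    name: str
    deps: list[str]
    fn: object  # callable(config, state: dict) -> dict of outputs
    stochastic: bool = False


def _checksum(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: list[Stage]) -> dict:
    """Execute stages in dependency order, recording a run manifest.

    The manifest records per stage the parameter checksum, produced output
    keys, wall-clock seconds and warnings; partial failure leaves the
    manifest with the completed stages. Cyclic or unsatisfiable
    dependencies fail before execution.
    """
    order = []
    done = set()
    pending = {s.name: s for s in stages}
    while pending:
        ready = [s for s in pending.values() if all(d in done for d in s.deps)]
        if not ready:
            raise ConfigError(
                f"cyclic or unsatisfied stage dependencies among {sorted(pending)}")
        for s in ready:
            order.append(s)
            done.add(s.name)
            del pending[s.name]
    for s in order:
        missing = [d for d in s.deps if d not in done]
        if missing:
            raise ConfigError(f"stage {s.name}: unsatisfied deps {missing}")
    manifest = {"format_version": FORMAT_VERSION, "stages": []}
    state: dict = {}
    for s in order:
        if s.stochastic:
            config.seed_for(s.name)  # pre-flight: seed must exist
        t0 = time.perf_counter()
        logger.info("stage %s: start", s.name)
        try:
            outputs = s.fn(config, state) or {}
        except Exception:
            manifest["stages"].append(
                {"name": s.name, "status": "failed",
                 "wall_s": round(time.perf_counter() - t0, 3)})
            raise
        state.update(outputs)
        manifest["stages"].append({
            "name": s.name, "status": "ok",
            "params_checksum": _checksum(sorted(
                (k, v) for k, v in vars(config).items() if not isinstance(v, dict))),
            "outputs": sorted(outputs),
            "output_checksums": {k: _checksum(outputs[k]) for k in sorted(outputs)},
            "wall_s": round(time.perf_counter() - t0, 3),
        })
        logger.info("stage %s: done", s.name)
    state["manifest"] = manifest
    return state


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def setup_logging(level: int = logging.INFO, logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level, handlers=handlers,
        format="%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s", force=True)
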