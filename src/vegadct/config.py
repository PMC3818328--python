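"""Run configuration: one flat, validated record tying every knob together.

A run is exactly reproducible from its persisted configuration plus the
master seed; all randomness flows from that one seed through
``numpy.random.Generator`` objects, with no hidden global state.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass, fields

import yaml

from .evolve import EvolutionLog, GAConfig, VEGAConfig
from .fitness import TaskConfig
from .rules import write_rule

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_results"]


class ConfigError(ValueError):
    """A configuration file or flag named an unknown key or an invalid value."""


@dataclass(frozen=True)
class RunConfig:
    """Union of task, GA and VEGA parameters plus run plumbing."""

    # task / environment
    N: int = 149
    rho: float = 0.6
    eta: float = 0.0
    T: int | None = None
    R: int = 100
    swap_fraction: float = 0.1
    # classical GA
    P: int = 100
    elite_fraction: float = 0.2
    per_bit_mutation_rate: float | None = None
    fitness_threshold: float = 0.98
    max_generations: int = 1000
    # VEGA schedule
    k_start: int = 5
    k_step: int = 2
    k_max: int = 11
    eta_increment: float = 0.01
    eta_start: float = 0.0
    patience_generations: int = 50
    # plumbing
    seed: int = 0
    out: str = "vega_out"

    def task_config(self, eta: float | None = None) -> TaskConfig:
        return TaskConfig(
            N=self.N, rho=self.rho,
            eta=self.eta if eta is None else eta,
            T=self.T, R=self.R, swap_fraction=self.swap_fraction,
        )

    def ga_config(self) -> GAConfig:
        return GAConfig(
            P=self.P, elite_fraction=self.elite_fraction,
            per_bit_mutation_rate=self.per_bit_mutation_rate,
            fitness_threshold=self.fitness_threshold,
            max_generations=self.max_generations,
        )

    def vega_config(self) -> VEGAConfig:
        return VEGAConfig(
            k_start=self.k_start, k_step=self.k_step, k_max=self.k_max,
            fitness_threshold=self.fitness_threshold,
            eta_increment=self.eta_increment, eta_start=self.eta_start,
            patience_generations=self.patience_generations,
            max_generations=self.max_generations,
        )


_FIELD_TYPES = {f.name: f for f in fields(RunConfig)}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML key-value file and/or
    override flags; flags win over the file, defaults fill the rest.
    Unknown keys are errors naming the offending key."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path!r} must be a key-value mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        cfg = RunConfig(**values)
        # validate the derived configs eagerly so errors surface at load time
        cfg.task_config()
        cfg.ga_config()
        cfg.vega_config()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_config(cfg: RunConfig, path) -> None:
    _atomic_write(str(path), yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def write_results(log: EvolutionLog, out_dir, cfg: RunConfig | None = None) -> None:
    """Persist a run: ``evolution.csv`` (one row per generation), the best
    genome at every mastered (k, eta) milestone as rule files, the
    effective config, and a plain-text summary.  All writes are atomic
    (temp file + rename)."""
    os.makedirs(out_dir, exist_ok=True)
    df = log.to_dataframe()
    _atomic_write(os.path.join(out_dir, "evolution.csv"), df.to_csv(index=False))

    milestones: dict[tuple[int, float], object] = {}
    for r in log.records:
        if r.event == "eta_increment":
            milestones[(r.k, r.eta)] = r.best_rule
    for (k, eta), rule in milestones.items():
        path = os.path.join(out_dir, f"rule_k{k}_eta{eta:.2f}.txt")
        tmp = path + ".tmp"
        write_rule(rule, tmp)
        os.replace(tmp, path)

    if cfg is not None:
        save_config(cfg, os.path.join(out_dir, "config.yaml"))

    lines = [f"generations: {len(log)}"]
    if log.records:
        last = log.records[-1]
        lines += [
            f"final k: {last.k}",
            f"final eta: {last.eta}",
            f"final best fitness: {last.best_fitness}",
            f"milestones: {len(milestones)}",
            f"seed: {log.seed}",
        ]
    _atomic_write(os.path.join(out_dir, "summary.txt"), "\n".join(lines) + "\n")
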