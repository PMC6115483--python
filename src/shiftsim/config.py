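"""Run configuration: validation, YAML round-trip and experiment dispatch.

A :class:`RunConfig` captures every knob of a run — pool parameters,
recruitment policy, experiment selector, grids, replication and the
base seed — and serializes losslessly to YAML. :func:`run` executes the
selected experiment, writes tidy CSV results plus a JSON/YAML config
snapshot beside them, and logs the seed, config hash and wall time to
stderr. Identical configs produce byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chronicity as _chronicity
from . import experiments as _experiments
from .exceptions import ConfigError
from .pool import generate_pool
from .recruitment import POLICY_KINDS, RecruitmentPolicy
from .rotation import simulate_rotation

__all__ = ["RunConfig", "run"]

logger = logging.getLogger("shiftsim")

EXPERIMENTS = ("load_sweep", "strength_sweep", "bias_comparison", "chronicity", "single_run")


def _default_load_fractions() -> list[float]:
    return [float(x) for x in _experiments.DEFAULT_LOAD_FRACTIONS]


def _default_strength_multipliers() -> list[float]:
    return [float(x) for x in _experiments.DEFAULT_STRENGTH_MULTIPLIERS]


@dataclass
class RunConfig:
    """Complete, serializable description of one reproducible run."""

    experiment: str = "load_sweep"
    # pool
    n_units: int = 100
    force_range_ratio: float = 100.0
    shape_exponent: float = 1.0
    jitter: float = 0.0
    pool_seed: int = 0
    # recruitment policy
    policy_kind: str = "uniform"
    bias_strength: float = 1.0
    # grids
    load_fractions: list[float] = field(default_factory=_default_load_fractions)
    strength_multipliers: list[float] = field(default_factory=_default_strength_multipliers)
    fixed_load_fraction: float = 0.2
    load_fraction: float = 0.5  # single_run
    sweep_kind: str = "load"  # bias_comparison
    # chronicity
    critical_ratio: float | None = None
    decline_rate: float = 0.005
    decay: str = "exponential"
    n_steps: int = 300
    # replication
    n_replicates: int = 100
    n_shifts: int = 1000
    base_seed: int = 0
    # output
    outdir: str = "results"
    make_plots: bool = False

    # -- validation -----------------------------------------------------

    def validate(self) -> "RunConfig":
        """Check every field against the preconditions it will feed."""
        c = self
        if c.experiment not in EXPERIMENTS:
            raise ConfigError("experiment", f"must be one of {EXPERIMENTS}")
        if not isinstance(c.n_units, int) or c.n_units < 1:
            raise ConfigError("n_units", "must be a positive integer")
        if not c.force_range_ratio > 1:
            raise ConfigError("force_range_ratio", "must be > 1")
        if not c.shape_exponent > 0:
            raise ConfigError("shape_exponent", "must be positive")
        if c.jitter < 0:
            raise ConfigError("jitter", "must be non-negative")
        if c.policy_kind not in POLICY_KINDS:
            raise ConfigError("policy_kind", f"must be one of {POLICY_KINDS}")
        if c.bias_strength < 0:
            raise ConfigError("bias_strength", "must be non-negative")
        if not c.load_fractions or any(not 0 < f <= 1 for f in c.load_fractions):
            raise ConfigError("load_fractions", "every value must lie in (0, 1]")
        if not c.strength_multipliers or any(m <= 0 for m in c.strength_multipliers):
            raise ConfigError("strength_multipliers", "every value must be positive")
        if not 0 < c.fixed_load_fraction <= 1:
            raise ConfigError("fixed_load_fraction", "must lie in (0, 1]")
        if not 0 < c.load_fraction <= 1:
            raise ConfigError("load_fraction", "must lie in (0, 1]")
        if c.sweep_kind not in ("load", "strength"):
            raise ConfigError("sweep_kind", "must be 'load' or 'strength'")
        if c.experiment == "chronicity":
            if c.critical_ratio is None or not c.critical_ratio > 0:
                raise ConfigError(
                    "critical_ratio",
                    "required for the chronicity experiment and must be positive",
                )
            if c.decline_rate < 0:
                raise ConfigError("decline_rate", "must be non-negative")
            if c.decay not in ("exponential", "linear"):
                raise ConfigError("decay", "must be 'exponential' or 'linear'")
            if c.n_steps < 1:
                raise ConfigError("n_steps", "must be >= 1")
        if c.n_replicates < 1:
            raise ConfigError("n_replicates", "must be >= 1")
        if c.n_shifts < 1:
            raise ConfigError("n_shifts", "must be >= 1")
        return c

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown config field")
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("<root>", "config file must contain a mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def policy(self) -> RecruitmentPolicy:
        return RecruitmentPolicy(self.policy_kind, self.bias_strength)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the configured experiment; return paths of files written."""
    config.validate()
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run: experiment=%s seed=%d config_hash=%s",
        config.experiment, config.base_seed, config.hash(),
    )

    pool = generate_pool(
        config.n_units, config.force_range_ratio, config.shape_exponent,
        jitter=config.jitter, seed=config.pool_seed,
    )
    policy = config.policy()
    paths: dict[str, Path] = {}

    def save_config():
        p = outdir / f"{config.experiment}_config.yaml"
        config.to_yaml(p)
        paths["config"] = p

    if config.experiment == "load_sweep":
        res = _experiments.load_sweep(
            pool, config.load_fractions, policy,
            config.n_replicates, config.n_shifts, config.base_seed,
        )
        paths["results"] = outdir / "load_sweep.csv"
        res.export(paths["results"])
        if config.make_plots:
            from .plotting import plot_sweep

            paths["plot"] = outdir / "load_sweep.png"
            plot_sweep(res, paths["plot"])
    elif config.experiment == "strength_sweep":
        res = _experiments.strength_sweep(
            pool, config.strength_multipliers, config.fixed_load_fraction,
            policy, config.n_replicates, config.n_shifts, config.base_seed,
        )
        n_infeasible = int((~res.feasible).sum())
        if n_infeasible:
            logger.warning(
                "%d infeasible grid point(s): load exceeds scaled muscle strength",
                n_infeasible,
            )
        paths["results"] = outdir / "strength_sweep.csv"
        res.export(paths["results"])
        if config.make_plots:
            from .plotting import plot_sweep

            paths["plot"] = outdir / "strength_sweep.png"
            plot_sweep(res, paths["plot"])
    elif config.experiment == "bias_comparison":
        grid = config.load_fractions if config.sweep_kind == "load" else config.strength_multipliers
        uni, biased = _experiments.bias_comparison(
            pool, config.sweep_kind, grid, config.bias_strength,
            config.fixed_load_fraction, config.n_replicates,
            config.n_shifts, config.base_seed,
        )
        import pandas as pd

        df = pd.concat([uni.to_frame(), biased.to_frame()], ignore_index=True)
        paths["results"] = outdir / "bias_comparison.csv"
        df.to_csv(paths["results"], index=False)
        sim = _experiments.sweep_similarity(uni, biased)
        paths["similarity"] = outdir / "bias_comparison_similarity.json"
        paths["similarity"].write_text(json.dumps(sim, indent=2) + "\n")
        if config.make_plots:
            from .plotting import plot_sweep

            paths["plot"] = outdir / "bias_comparison.png"
            plot_sweep(uni, paths["plot"], second=biased)
    elif config.experiment == "chronicity":
        traj = _chronicity.simulate_chronicity(
            pool, config.decline_rate, config.critical_ratio, config.n_steps,
            rng=config.base_seed, decay=config.decay, policy=policy,
            threshold_kwargs={"n_shifts": config.n_shifts},
        )
        paths["results"] = outdir / "chronicity.csv"
        paths["summary"] = outdir / "chronicity_summary.json"
        traj.export(paths["results"], paths["summary"])
        if config.make_plots:
            from .plotting import plot_chronicity

            paths["plot"] = outdir / "chronicity.png"
            plot_chronicity(traj, paths["plot"])
    else:  # single_run
        res = simulate_rotation(
            pool, config.load_fraction * pool.max_strength, policy,
            config.n_shifts, rng=config.base_seed,
        )
        paths["results"] = outdir / "single_run.csv"
        paths["summary"] = outdir / "single_run_summary.json"
        res.export(paths["results"], paths["summary"])

    save_config()
    logger.info("run finished in %.2f s; wrote %s",
                time.perf_counter() - t0,
                ", ".join(str(p) for p in paths.values()))
    return paths
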