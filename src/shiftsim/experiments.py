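"""Replicate Monte-Carlo sweeps over load and muscle strength.

Three experiments, each summarizing the mean relative relaxation time
(mean over replicates of the per-replicate mean per-unit t_r / t_c)
with its between-replicate standard deviation:

* load sweep — one muscle contracts under a grid of loads expressed as
  fractions of its maximum loading capacity;
* strength sweep — muscles of different maximum strength (scaled copies
  of a reference pool) contract under one constant absolute load, by
  default 20% of the reference maximum;
* bias comparison — either sweep run under both recruitment policies
  (uniform and small-unit-biased) with matched seeds, to check that the
  trends do not depend on the recruitment probability distribution.

Replicate k of any sweep uses seed ``base_seed + k``, so the same
replicate seeds recur at every grid point (common random numbers) and a
sweep is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError
from .pool import MotorUnitPool, scale_pool
from .recruitment import RecruitmentPolicy
from .rotation import simulate_rotation

__all__ = [
    "SweepResult",
    "load_sweep",
    "strength_sweep",
    "bias_comparison",
    "sweep_similarity",
]

DEFAULT_N_REPLICATES = 100
DEFAULT_N_SHIFTS = 1000
DEFAULT_LOAD_FRACTIONS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))
DEFAULT_STRENGTH_MULTIPLIERS = tuple(np.round(np.arange(0.2, 2.001, 0.1), 10))
DEFAULT_FIXED_LOAD_FRACTION = 0.2


@dataclass(frozen=True)
class SweepResult:
    """Mean ± SD of the relative relaxation time along one condition grid.

    ``feasible`` marks grid points where the constant load does not
    exceed the (scaled) muscle's maximum strength; infeasible points are
    kept in the grid with NaN statistics rather than silently dropped.
    """

    condition_name: str  # "load_fraction" | "strength_multiplier"
    condition_values: np.ndarray = field(repr=False)
    mean_ratio: np.ndarray = field(repr=False)
    sd_ratio: np.ndarray = field(repr=False)
    feasible: np.ndarray = field(repr=False)
    n_replicates: int = DEFAULT_N_REPLICATES
    n_shifts: int = DEFAULT_N_SHIFTS
    policy: RecruitmentPolicy = RecruitmentPolicy.uniform()
    base_seed: int = 0
    config_snapshot: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-grid-point table."""
        return pd.DataFrame(
            {
                "condition_name": self.condition_name,
                "condition_value": self.condition_values,
                "mean_ratio": self.mean_ratio,
                "sd_ratio": self.sd_ratio,
                "feasible": self.feasible,
                "policy": self.policy.kind,
                "bias_strength": self.policy.bias_strength,
                "n_replicates": self.n_replicates,
                "n_shifts": self.n_shifts,
                "base_seed": self.base_seed,
            }
        )

    def export(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(self.config_snapshot, indent=2, sort_keys=True) + "\n"
            )


def _replicate_means(
    pool: MotorUnitPool,
    load: float,
    policy: RecruitmentPolicy,
    n_replicates: int,
    n_shifts: int,
    base_seed: int,
) -> np.ndarray:
    """Per-replicate mean per-unit ratios; replicate k seeded base_seed + k."""
    out = np.empty(n_replicates)
    for k in range(n_replicates):
        res = simulate_rotation(pool, load, policy, n_shifts, rng=base_seed + k)
        out[k] = res.mean_ratio
    return out


def _summarize(reps: np.ndarray) -> tuple[float, float]:
    sd = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return float(reps.mean()), sd


def load_sweep(
    pool: MotorUnitPool,
    load_fractions=DEFAULT_LOAD_FRACTIONS,
    policy: RecruitmentPolicy = RecruitmentPolicy.uniform(),
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_shifts: int = DEFAULT_N_SHIFTS,
    base_seed: int = 0,
) -> SweepResult:
    """Sweep the load on one muscle over fractions of its maximum strength.

    The mean relative relaxation time is non-increasing in load fraction
    (up to Monte-Carlo noise): heavier loads recruit more units per
    shift, leaving each unit less relaxation time.
    """
    fractions = np.asarray(load_fractions, dtype=float)
    if fractions.size == 0 or np.any(fractions <= 0) or np.any(fractions > 1):
        raise InvalidParameterError(
            "load_fractions must be non-empty with every value in (0, 1]"
        )
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    means = np.empty(fractions.size)
    sds = np.empty(fractions.size)
    for j, frac in enumerate(fractions):
        reps = _replicate_means(
            pool, frac * pool.max_strength, policy, n_replicates, n_shifts, base_seed
        )
        means[j], sds[j] = _summarize(reps)
    snapshot = {
        "experiment": "load_sweep",
        "n_units": pool.n,
        "load_fractions": fractions.tolist(),
        "policy": policy.kind,
        "bias_strength": policy.bias_strength,
        "n_replicates": n_replicates,
        "n_shifts": n_shifts,
        "base_seed": base_seed,
    }
    return SweepResult(
        "load_fraction", fractions, means, sds, np.ones(fractions.size, dtype=bool),
        n_replicates, n_shifts, policy, base_seed, snapshot,
    )


def strength_sweep(
    reference_pool: MotorUnitPool,
    strength_multipliers=DEFAULT_STRENGTH_MULTIPLIERS,
    fixed_load_fraction_of_reference: float = DEFAULT_FIXED_LOAD_FRACTION,
    policy: RecruitmentPolicy = RecruitmentPolicy.uniform(),
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_shifts: int = DEFAULT_N_SHIFTS,
    base_seed: int = 0,
) -> SweepResult:
    """Sweep maximum muscle strength under one constant absolute load.

    The load is ``fixed_load_fraction_of_reference`` times the reference
    pool's maximum strength; each grid point simulates a scaled copy of
    the reference pool under that same load. Weaker muscles must recruit
    a larger fraction of their units, so the mean relative relaxation
    time is non-decreasing in the multiplier; at multiplier equal to the
    load fraction the muscle is fully recruited every shift and the
    ratio is exactly 0. Multipliers too weak to carry the load at all
    are flagged infeasible (NaN statistics), not dropped.
    """
    multipliers = np.asarray(strength_multipliers, dtype=float)
    if multipliers.size == 0 or np.any(multipliers <= 0):
        raise InvalidParameterError("strength_multipliers must be positive")
    if not 0 < fixed_load_fraction_of_reference <= 1:
        raise InvalidParameterError(
            "fixed_load_fraction_of_reference must lie in (0, 1]"
        )
    load = fixed_load_fraction_of_reference * reference_pool.max_strength
    means = np.full(multipliers.size, np.nan)
    sds = np.full(multipliers.size, np.nan)
    feasible = np.zeros(multipliers.size, dtype=bool)
    for j, m in enumerate(multipliers):
        scaled = scale_pool(reference_pool, m)
        if load > scaled.max_strength * (1.0 + 1e-9):
            continue  # infeasible: the muscle cannot generate the load
        feasible[j] = True
        reps = _replicate_means(scaled, load, policy, n_replicates, n_shifts, base_seed)
        means[j], sds[j] = _summarize(reps)
    snapshot = {
        "experiment": "strength_sweep",
        "n_units": reference_pool.n,
        "strength_multipliers": multipliers.tolist(),
        "fixed_load_fraction_of_reference": fixed_load_fraction_of_reference,
        "policy": policy.kind,
        "bias_strength": policy.bias_strength,
        "n_replicates": n_replicates,
        "n_shifts": n_shifts,
        "base_seed": base_seed,
    }
    return SweepResult(
        "strength_multiplier", multipliers, means, sds, feasible,
        n_replicates, n_shifts, policy, base_seed, snapshot,
    )


def bias_comparison(
    pool: MotorUnitPool,
    sweep_kind: str = "load",
    grid=None,
    bias_strength: float = 1.0,
    fixed_load_fraction_of_reference: float = DEFAULT_FIXED_LOAD_FRACTION,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_shifts: int = DEFAULT_N_SHIFTS,
    base_seed: int = 0,
) -> tuple[SweepResult, SweepResult]:
    """Run one sweep under both recruitment policies with matched seeds.

    Returns ``(uniform_result, small_biased_result)``. Qualitative
    similarity between the two curves can be quantified with
    :func:`sweep_similarity`.
    """
    if sweep_kind not in ("load", "strength"):
        raise InvalidParameterError(
            f"sweep_kind must be 'load' or 'strength', got {sweep_kind!r}"
        )
    results = []
    for policy in (RecruitmentPolicy.uniform(), RecruitmentPolicy.small_biased(bias_strength)):
        if sweep_kind == "load":
            res = load_sweep(
                pool,
                DEFAULT_LOAD_FRACTIONS if grid is None else grid,
                policy, n_replicates, n_shifts, base_seed,
            )
        else:
            res = strength_sweep(
                pool,
                DEFAULT_STRENGTH_MULTIPLIERS if grid is None else grid,
                fixed_load_fraction_of_reference,
                policy, n_replicates, n_shifts, base_seed,
            )
        results.append(res)
    return results[0], results[1]


def sweep_similarity(a: SweepResult, b: SweepResult) -> dict:
    """Qualitative similarity of two sweep curves on a shared grid.

    Computes the Spearman rank correlation between the two mean-ratio
    vectors (over jointly feasible, finite grid points) and whether both
    curves trend in the same monotone direction against the condition.
    """
    mask = a.feasible & b.feasible & np.isfinite(a.mean_ratio) & np.isfinite(b.mean_ratio)
    xa, xb = a.mean_ratio[mask], b.mean_ratio[mask]
    cond = a.condition_values[mask]
    rho = float(stats.spearmanr(xa, xb).statistic)
    dir_a = float(stats.spearmanr(cond, xa).statistic)
    dir_b = float(stats.spearmanr(cond, xb).statistic)
    return {
        "spearman_rho": rho,
        "trend_a": dir_a,
        "trend_b": dir_b,
        "same_direction": bool(np.sign(dir_a) == np.sign(dir_b)),
    }
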