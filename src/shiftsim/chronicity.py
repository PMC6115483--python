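"""Energy-crisis threshold loads and the path to chronic overload.

If the energy crisis behind myofascial trigger points is a threshold
phenomenon — occurring once the relaxation/contraction duty-cycle ratio
falls below some critical value — then every muscle has a threshold
load above which that critical ratio is violated. Because the ratio
depends on the load only through the load *fraction* of maximum
strength, the threshold load scales exactly with muscle strength: as a
muscle weakens (age, immobility, disease) its threshold load declines,
everyday loads cross it more and more often, and episodes grow more
frequent until chronic overload ensues.

This module computes the threshold load for a pool by monotone
bisection on the simulated mean ratio, and generates illustrative
declining-strength trajectories with episode detection. The critical
ratio itself is unknown physiology and is a required user parameter —
no default is offered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BisectionError, InvalidParameterError
from .pool import MotorUnitPool
from .recruitment import RecruitmentPolicy, _as_rng
from .rotation import simulate_rotation

__all__ = ["ChronicityTrajectory", "threshold_load_for", "simulate_chronicity"]

#: minimum load fraction probed by the bisection bracket
_MIN_FRACTION = 1e-6


def _mean_ratio_at_fraction(
    pool: MotorUnitPool,
    fraction: float,
    policy: RecruitmentPolicy,
    n_shifts: int,
    n_replicates: int,
    seed: int,
) -> float:
    """Simulated mean ratio at a load fraction, common random numbers.

    Every call with the same seed reuses the same shift draws, so the
    empirical curve is monotone in the fraction (a larger load extends
    each shift's recruited prefix) and depends on the load only through
    the fraction — exact scale invariance under pool scaling.
    """
    reps = [
        simulate_rotation(
            pool, fraction * pool.max_strength, policy, n_shifts, rng=seed + k
        ).mean_ratio
        for k in range(n_replicates)
    ]
    return float(np.mean(reps))


def threshold_load_for(
    pool: MotorUnitPool,
    critical_ratio: float,
    policy: RecruitmentPolicy = RecruitmentPolicy.uniform(),
    tolerance: float = 0.005,
    seed: int = 0,
    n_shifts: int = 1000,
    n_replicates: int = 4,
    max_iter: int = 60,
) -> float:
    """Load at which the simulated mean ratio falls to ``critical_ratio``.

    Bisects on the load fraction over (0, 1]; the analytic inverse of
    the duty-cycle relation, R* = 1 / (1 + critical_ratio), initializes
    the bracket around fraction R* before falling back to the full
    interval. Returns the threshold in force units, resolved to within
    ``tolerance * pool.max_strength``.

    Raises
    ------
    InvalidParameterError
        If ``critical_ratio <= 0`` or ``tolerance <= 0``.
    BisectionError
        If the bracket fails to shrink below tolerance within
        ``max_iter`` iterations (carries the last bracket).
    """
    if not critical_ratio > 0:
        raise InvalidParameterError(
            f"critical_ratio must be positive, got {critical_ratio!r}"
        )
    if not tolerance > 0:
        raise InvalidParameterError(f"tolerance must be positive, got {tolerance!r}")

    def f(fraction: float) -> float:
        return _mean_ratio_at_fraction(
            pool, fraction, policy, n_shifts, n_replicates, seed
        )

    r_star = 1.0 / (1.0 + critical_ratio)  # analytic bracket initializer
    lo = max(_MIN_FRACTION, r_star - 0.15)
    hi = min(1.0, r_star + 0.15)
    if f(lo) < critical_ratio:
        lo = _MIN_FRACTION
    if f(hi) > critical_ratio:
        hi = 1.0
    # f is non-increasing: f(lo) >= critical_ratio >= f(hi)
    for _ in range(max_iter):
        if hi - lo <= tolerance:
            return 0.5 * (lo + hi) * pool.max_strength
        mid = 0.5 * (lo + hi)
        if f(mid) >= critical_ratio:
            lo = mid
        else:
            hi = mid
    raise BisectionError(
        f"threshold bisection did not converge to tolerance {tolerance}",
        bracket=(lo * pool.max_strength, hi * pool.max_strength),
    )


@dataclass(frozen=True)
class ChronicityTrajectory:
    """A declining-strength muscle and its overload episodes.

    All vectors share one length. An episode is flagged at step t
    exactly when ``applied_load[t] > threshold_load[t]``; the threshold
    load is the fixed threshold *fraction* times the current strength,
    so it declines with the muscle.
    """

    time: np.ndarray = field(repr=False)
    strength: np.ndarray = field(repr=False)
    threshold_load: np.ndarray = field(repr=False)
    applied_load: np.ndarray = field(repr=False)
    episode_flags: np.ndarray = field(repr=False)
    critical_ratio: float = np.nan
    threshold_fraction: float = np.nan

    @property
    def n_steps(self) -> int:
        return int(self.time.size)

    @property
    def n_episodes(self) -> int:
        return int(self.episode_flags.sum())

    def quartile_episode_rates(self) -> np.ndarray:
        """Episode frequency in each temporal quartile of the trajectory."""
        quarters = np.array_split(self.episode_flags, 4)
        return np.array([q.mean() if q.size else np.nan for q in quarters])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "strength": self.strength,
                "threshold_load": self.threshold_load,
                "applied_load": self.applied_load,
                "episode": self.episode_flags,
            }
        )

    def export(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(
                    {
                        "critical_ratio": self.critical_ratio,
                        "threshold_fraction": self.threshold_fraction,
                        "n_steps": self.n_steps,
                        "n_episodes": self.n_episodes,
                        "quartile_episode_rates": self.quartile_episode_rates().tolist(),
                    },
                    indent=2,
                )
                + "\n"
            )


def simulate_chronicity(
    initial_pool: MotorUnitPool,
    decline_rate: float,
    critical_ratio: float,
    n_steps: int,
    load_series: Sequence[float] | Callable[[np.random.Generator, int], np.ndarray] | None = None,
    rng: int | np.random.Generator | None = None,
    decay: str = "exponential",
    policy: RecruitmentPolicy = RecruitmentPolicy.uniform(),
    load_median_fraction_of_threshold: float = 0.5,
    load_sigma: float = 0.4,
    threshold_seed: int = 0,
    threshold_kwargs: dict | None = None,
) -> ChronicityTrajectory:
    """Simulate a weakening muscle under a stream of loads.

    Strength declines from the initial maximum as
    ``exp(-decline_rate * t)`` (or linearly, ``max(1 - decline_rate *
    t, eps)``, with ``decay='linear'``). The energy-crisis threshold is
    computed once for the initial pool via :func:`threshold_load_for`
    and propagated by exact scale invariance — threshold fraction times
    current strength — avoiding per-step re-simulation.

    ``load_series`` may be an explicit vector of loads, a callable
    ``(rng, n_steps) -> array``, or None for the default illustrative
    generator: i.i.d. lognormal loads with median
    ``load_median_fraction_of_threshold`` times the *initial* threshold
    load and log-scale sigma ``load_sigma``. With a stationary load
    stream and positive decline rate, episodes grow more frequent as
    the muscle weakens.
    """
    if decline_rate < 0:
        raise InvalidParameterError(
            f"decline_rate must be non-negative, got {decline_rate!r}"
        )
    if n_steps < 1:
        raise InvalidParameterError(f"n_steps must be >= 1, got {n_steps!r}")
    if decay not in ("exponential", "linear"):
        raise InvalidParameterError(
            f"decay must be 'exponential' or 'linear', got {decay!r}"
        )

    rng = _as_rng(rng)
    s0 = initial_pool.max_strength
    t = np.arange(n_steps, dtype=float)
    if decay == "exponential":
        strength = s0 * np.exp(-decline_rate * t)
    else:
        strength = s0 * np.maximum(1.0 - decline_rate * t, _MIN_FRACTION)

    threshold0 = threshold_load_for(
        initial_pool, critical_ratio, policy, seed=threshold_seed,
        **(threshold_kwargs or {}),
    )
    threshold_fraction = threshold0 / s0
    threshold = threshold_fraction * strength

    if load_series is None:
        median = load_median_fraction_of_threshold * threshold0
        loads = rng.lognormal(np.log(median), load_sigma, size=n_steps)
    elif callable(load_series):
        loads = np.asarray(load_series(rng, n_steps), dtype=float)
    else:
        loads = np.asarray(load_series, dtype=float)
    if loads.shape != (n_steps,):
        raise InvalidParameterError(
            f"load_series must provide {n_steps} values, got shape {loads.shape}"
        )
    if np.any(loads < 0):
        raise InvalidParameterError("loads must be non-negative")

    return ChronicityTrajectory(
        time=t,
        strength=strength,
        threshold_load=threshold,
        applied_load=loads,
        episode_flags=loads > threshold,
        critical_ratio=float(critical_ratio),
        threshold_fraction=float(threshold_fraction),
    )
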