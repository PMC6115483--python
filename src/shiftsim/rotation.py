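"""Multi-shift rotation simulation and the analytic duty-cycle ratio.

Each of ``n_shifts`` epochs redraws an independent recruited set
(memoryless rotation). A unit in the shift accrues one ``shift_duration``
of contraction time; all others accrue relaxation time. The per-unit
relaxation/contraction ratio t_r / t_c is the model's proxy for a unit's
energetic replenishment opportunity; analytically, a steady recruitment
ratio R gives t_r / t_c = (1 - R) / R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .pool import MotorUnitPool
from .recruitment import RecruitmentPolicy, _as_rng, _draw_orders, selection_weights

__all__ = ["RotationResult", "analytic_ratio", "simulate_rotation"]


def analytic_ratio(R):
    """Relaxation/contraction time ratio implied by recruitment ratio R.

    Under rotation at a steady recruitment ratio R, a unit contracts a
    fraction R of the time, so t_r / t_c = (1 - R) / R. Defined for
    0 < R <= 1; R = 1 (constant contraction) gives 0.

    Accepts a scalar or array; raises for values outside (0, 1].
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R > 1):
        raise InvalidParameterError("R must lie in (0, 1]")
    out = (1.0 - R) / R
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RotationResult:
    """Per-unit contraction/relaxation tallies over one simulation.

    ``per_unit_ratio`` is t_r / t_c per unit, +inf for units never
    recruited during the run. ``mean_ratio`` (the headline statistic)
    averages the per-unit ratios over units with positive contraction
    time; ``pooled_ratio`` is the ratio-of-means alternative,
    total relaxation time / total contraction time over all units.
    """

    n_shifts: int
    shift_duration: float
    contraction_time: np.ndarray = field(repr=False)
    relaxation_time: np.ndarray = field(repr=False)
    mean_R: float
    twitch_forces: np.ndarray = field(repr=False)

    @property
    def per_unit_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(
                self.contraction_time > 0,
                self.relaxation_time / np.where(self.contraction_time > 0, self.contraction_time, 1.0),
                np.inf,
            )

    @property
    def never_contracted(self) -> int:
        """Units never recruited during this (finite) run."""
        return int((self.contraction_time == 0).sum())

    @property
    def mean_ratio(self) -> float:
        """Mean over units of t_r / t_c (never-contracted units excluded)."""
        mask = self.contraction_time > 0
        return float(self.per_unit_ratio[mask].mean())

    @property
    def pooled_ratio(self) -> float:
        """Total relaxation time / total contraction time (all units)."""
        return float(self.relaxation_time.sum() / self.contraction_time.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.twitch_forces.size),
                "twitch_force": self.twitch_forces,
                "contraction_time": self.contraction_time,
                "relaxation_time": self.relaxation_time,
                "ratio": self.per_unit_ratio,
            }
        )

    def summary(self) -> dict:
        return {
            "n_shifts": self.n_shifts,
            "shift_duration": self.shift_duration,
            "mean_R": self.mean_R,
            "mean_ratio": self.mean_ratio,
            "pooled_ratio": self.pooled_ratio,
            "never_contracted": self.never_contracted,
        }

    def export(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        """Write the per-unit table as CSV and (optionally) a JSON summary."""
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def simulate_rotation(
    pool: MotorUnitPool,
    load: float,
    policy: RecruitmentPolicy,
    n_shifts: int,
    rng: int | np.random.Generator | None = None,
    shift_duration: float = 1.0,
) -> RotationResult:
    """Run ``n_shifts`` independent shifts and tally per-unit times.

    Per unit, contraction_time + relaxation_time == n_shifts *
    shift_duration exactly. All reported ratios are dimensionless and
    invariant to ``shift_duration``. Deterministic given the rng seed.

    Raises
    ------
    InvalidParameterError
        If ``load <= 0``, ``n_shifts < 1`` or ``shift_duration <= 0``.
    InfeasibleLoadError
        If ``load`` exceeds ``pool.max_strength``.
    """
    if not load > 0:
        raise InvalidParameterError(f"load must be positive, got {load!r}")
    if n_shifts < 1:
        raise InvalidParameterError(f"n_shifts must be >= 1, got {n_shifts!r}")
    if not shift_duration > 0:
        raise InvalidParameterError(
            f"shift_duration must be positive, got {shift_duration!r}"
        )
    rng = _as_rng(rng)
    weights = selection_weights(pool, policy)
    orders, counts = _draw_orders(pool.forces, weights, load, n_shifts, rng)
    n = pool.n
    in_shift = np.arange(n)[None, :] < counts[:, None]  # ordered-position mask
    recruit_counts = np.bincount(orders[in_shift].ravel(), minlength=n)
    contraction = recruit_counts * shift_duration
    # computed as the complement so that contraction + relaxation equals
    # n_shifts * shift_duration exactly, float rounding included
    relaxation = n_shifts * shift_duration - contraction
    return RotationResult(
        n_shifts=n_shifts,
        shift_duration=shift_duration,
        contraction_time=contraction,
        relaxation_time=relaxation,
        mean_R=float(counts.mean() / n),
        twitch_forces=np.asarray(pool.forces),
    )
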