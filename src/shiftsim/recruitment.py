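"""Stochastic shift recruitment.

During one rotation epoch ("shift") units are recruited one at a time,
without replacement, with probabilities proportional to the policy
weights renormalized among the not-yet-recruited units, accumulating
twitch force until the accumulated force meets the load (the force
balance F = sum of recruited f_i, read as a stopping condition). The
recruitment ratio R is the recruited *count* fraction |recruited| / n.

Sequential renormalized sampling is realized with the exponential-race
construction: give unit i an independent clock Exp(1) / w_i and recruit
in order of increasing clock. The order so produced has exactly the
sequential sample-renormalize-repeat distribution (the race between
exponential clocks is memoryless), and it vectorizes across shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleLoadError, InvalidParameterError
from .pool import MotorUnitPool

__all__ = [
    "RecruitmentPolicy",
    "ShiftRecord",
    "selection_weights",
    "draw_shift",
    "expected_recruitment_ratio",
]

#: relative slack for load-feasibility comparisons (float summation order)
_REL_TOL = 1e-9

POLICY_KINDS = ("uniform", "small_biased")


@dataclass(frozen=True)
class RecruitmentPolicy:
    """How units are chosen for a shift.

    ``uniform`` gives every unit equal selection weight; ``small_biased``
    weights unit i proportional to ``twitch_force ** -bias_strength``, so
    weight decreases strictly with force (for ``bias_strength > 0``).
    ``bias_strength = 0`` reduces to uniform exactly.
    """

    kind: str = "uniform"
    bias_strength: float = 1.0

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise InvalidParameterError(
                f"policy kind must be one of {POLICY_KINDS}, got {self.kind!r}"
            )
        if self.bias_strength < 0:
            raise InvalidParameterError(
                f"bias_strength must be non-negative, got {self.bias_strength!r}"
            )

    @classmethod
    def uniform(cls) -> "RecruitmentPolicy":
        return cls(kind="uniform")

    @classmethod
    def small_biased(cls, bias_strength: float = 1.0) -> "RecruitmentPolicy":
        return cls(kind="small_biased", bias_strength=bias_strength)


@dataclass(frozen=True)
class ShiftRecord:
    """One rotation epoch.

    ``order`` lists recruited unit indices in the order they were
    sampled; ``recruited`` is the same set. ``recruitment_ratio`` is
    ``len(recruited) / n`` exactly, 0 for the empty (zero-load) shift.
    """

    recruited: frozenset[int]
    recruitment_ratio: float
    total_force: float
    order: tuple[int, ...] = ()


def selection_weights(pool: MotorUnitPool, policy: RecruitmentPolicy) -> np.ndarray:
    """Per-unit selection probabilities (positive, summing to 1)."""
    n = pool.n
    if policy.kind == "uniform" or policy.bias_strength == 0:
        return np.full(n, 1.0 / n)
    w = pool.forces ** (-policy.bias_strength)
    return w / w.sum()


def _draw_orders(
    forces: np.ndarray,
    weights: np.ndarray,
    load: float,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n_draws`` shifts; return (orders, counts).

    ``orders`` is ``(n_draws, n)`` — each row a full sampling order of
    unit indices — and ``counts[d]`` is the number of recruited units in
    draw d (the shortest prefix whose force sum meets the load).
    """
    n = forces.size
    total = float(forces.sum())
    if load < 0:
        raise InvalidParameterError(f"load must be non-negative, got {load!r}")
    if load > total * (1.0 + _REL_TOL):
        raise InfeasibleLoadError(
            f"load {load!r} exceeds maximum strength {total!r}"
        )
    clocks = rng.exponential(size=(n_draws, n)) / weights
    orders = np.argsort(clocks, axis=1)
    if load <= 0:
        return orders, np.zeros(n_draws, dtype=np.int64)
    cum = np.cumsum(forces[orders], axis=1)
    # first index with cum >= load; clip handles summation-order epsilon
    # when load == max_strength
    counts = np.minimum((cum < load).sum(axis=1) + 1, n)
    return orders, counts


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_shift(
    pool: MotorUnitPool,
    load: float,
    policy: RecruitmentPolicy,
    rng: int | np.random.Generator | None = None,
) -> ShiftRecord:
    """Sample the recruited set for one shift at the given load.

    Accumulates twitch forces in sampling order and stops as soon as the
    accumulated force meets the load, so ``total_force >= load`` and
    dropping the last-sampled unit would violate the force balance.
    ``load = 0`` returns the empty shift with ratio 0 by convention.

    Raises
    ------
    InfeasibleLoadError
        If ``load`` exceeds ``pool.max_strength``.
    """
    rng = _as_rng(rng)
    weights = selection_weights(pool, policy)
    orders, counts = _draw_orders(pool.forces, weights, load, 1, rng)
    k = int(counts[0])
    order = tuple(int(i) for i in orders[0, :k])
    return ShiftRecord(
        recruited=frozenset(order),
        recruitment_ratio=k / pool.n,
        total_force=float(pool.forces[list(order)].sum()),
        order=order,
    )


def expected_recruitment_ratio(
    pool: MotorUnitPool,
    load: float,
    policy: RecruitmentPolicy,
    n_draws: int,
    rng: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of the recruitment ratio R over shifts."""
    if n_draws < 1:
        raise InvalidParameterError(f"n_draws must be >= 1, got {n_draws!r}")
    rng = _as_rng(rng)
    weights = selection_weights(pool, policy)
    _, counts = _draw_orders(pool.forces, weights, load, n_draws, rng)
    ratios = counts / pool.n
    sd = float(ratios.std(ddof=1)) if n_draws > 1 else 0.0
    return float(ratios.mean()), sd
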