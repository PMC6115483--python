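"""Motor-unit pool construction.

A model muscle is a pool of *n* motor units, each contributing a fixed
twitch force ``f_i`` when recruited. The muscle's maximum strength is the
sum of all twitch forces (full recruitment). Twitch forces follow the
standard many-small/few-large construction used in motor-unit pool models:
exponential spacing over a configurable force range, so that the pool has
a predilection towards small units (right-skewed force distribution).

Force units are arbitrary: loads are always expressed as fractions of a
reference maximum strength, so units cancel everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["MotorUnit", "MotorUnitPool", "generate_pool", "scale_pool", "load_pool"]

#: default pool size (units)
DEFAULT_N_UNITS = 100
#: default ratio of largest to smallest attainable twitch force
DEFAULT_FORCE_RANGE_RATIO = 100.0
#: default curvature of the exponential force spacing
DEFAULT_SHAPE_EXPONENT = 1.0


@dataclass(frozen=True)
class MotorUnit:
    """One motor unit: an index and a positive twitch force."""

    index: int
    twitch_force: float


@dataclass(frozen=True)
class MotorUnitPool:
    """A muscle: motor-unit twitch forces sorted ascending.

    Parameters
    ----------
    forces
        Positive twitch forces, one per unit. Stored sorted ascending
        (the canonical order, required for deterministic serialization
        and for the small-unit-biased recruitment policy).
    """

    forces: np.ndarray = field(repr=False)

    def __post_init__(self):
        forces = np.asarray(self.forces, dtype=float)
        if forces.ndim != 1 or forces.size < 1:
            raise InvalidParameterError("forces must be a non-empty 1-D array")
        if not np.all(forces > 0):
            raise InvalidParameterError("twitch forces must all be positive")
        if np.any(np.diff(forces) < 0):
            forces = np.sort(forces)
        forces = forces.copy()
        forces.setflags(write=False)
        object.__setattr__(self, "forces", forces)

    @property
    def n(self) -> int:
        """Number of motor units."""
        return int(self.forces.size)

    @property
    def max_strength(self) -> float:
        """Maximum muscle strength: sum of all twitch forces."""
        return float(self.forces.sum())

    @property
    def units(self) -> tuple[MotorUnit, ...]:
        return tuple(MotorUnit(i, float(f)) for i, f in enumerate(self.forces))

    def __len__(self) -> int:
        return self.n

    def to_csv(self, path: str | Path) -> None:
        """Write the pool as two-column CSV (index, twitch_force).

        Forces are written with 17 significant digits so the round-trip
        through text is exact for float64.
        """
        with open(path, "w") as fh:
            fh.write("index,twitch_force\n")
            for i, f in enumerate(self.forces):
                fh.write(f"{i},{f:.17g}\n")


def load_pool(path: str | Path) -> MotorUnitPool:
    """Read a pool written by :meth:`MotorUnitPool.to_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"index", "twitch_force"} <= set(df.columns):
        raise InvalidParameterError(
            f"{path}: expected columns 'index' and 'twitch_force'"
        )
    return MotorUnitPool(df["twitch_force"].to_numpy(dtype=float))


def generate_pool(
    n: int = DEFAULT_N_UNITS,
    force_range_ratio: float = DEFAULT_FORCE_RANGE_RATIO,
    shape_exponent: float = DEFAULT_SHAPE_EXPONENT,
    *,
    jitter: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> MotorUnitPool:
    """Generate a pool with power-distributed twitch forces.

    Twitch force of unit ``i`` (of ``n``, zero-based) is::

        f_i = force_range_ratio ** ((i / (n - 1)) ** shape_exponent)

    spanning ``[1, force_range_ratio]`` force units with many small and
    few large units — the standard exponential-spacing construction of
    the motor-unit modelling literature. ``shape_exponent`` controls the
    curvature (values >= 1 preserve the small-unit predilection; 1 is the
    classic form). ``jitter`` applies optional multiplicative lognormal
    noise with the given sigma; the result is re-sorted ascending. With
    ``jitter=0`` (default) the pool is deterministic and ``seed`` is
    ignored.

    Raises
    ------
    InvalidParameterError
        If ``n < 1``, ``force_range_ratio <= 1``, ``shape_exponent <= 0``
        or ``jitter < 0``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"n must be a positive integer, got {n!r}")
    if not force_range_ratio > 1:
        raise InvalidParameterError(
            f"force_range_ratio must be > 1, got {force_range_ratio!r}"
        )
    if not shape_exponent > 0:
        raise InvalidParameterError(
            f"shape_exponent must be positive, got {shape_exponent!r}"
        )
    if jitter < 0:
        raise InvalidParameterError(f"jitter must be non-negative, got {jitter!r}")

    if n == 1:
        forces = np.ones(1)
    else:
        x = np.arange(n) / (n - 1)
        forces = force_range_ratio ** (x**shape_exponent)
    if jitter > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        forces = np.sort(forces * rng.lognormal(0.0, jitter, size=n))
    return MotorUnitPool(forces)


def scale_pool(pool: MotorUnitPool, multiplier: float) -> MotorUnitPool:
    """Return a copy of ``pool`` with every twitch force multiplied.

    Scaling preserves unit count, ordering and all pairwise force ratios;
    ``max_strength`` scales by exactly the multiplier.
    """
    if not multiplier > 0:
        raise InvalidParameterError(f"multiplier must be positive, got {multiplier!r}")
    return MotorUnitPool(pool.forces * multiplier)
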