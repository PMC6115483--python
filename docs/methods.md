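# Methods

## Model

A muscle is a pool of `n` motor units with fixed twitch forces
`f_0 <= … <= f_{n-1}` (arbitrary units; loads are always fractions of a
reference maximum strength, so units cancel). Holding an isometric load
`F` means recruiting a subset whose forces sum to at least `F`. Time is
discretized into shifts of equal duration; each shift draws a fresh
recruited set, units inside the set accrue contraction time, all others
relaxation time. The quantity of interest is the per-unit
relaxation/contraction time ratio `t_r / t_c`; at a steady recruitment
ratio `R` (recruited count fraction) it equals `(1 − R)/R`.

Assumptions baked in:

- **No rate coding.** A unit is either contracting or relaxed; firing
  rate modulation is out of scope.
- **Memoryless rotation.** Each shift's recruited set is redrawn
  independently — no substitution schedule, no refractoriness. This is
  the simplest stochastic realization of rotation; any scheduler that
  spreads work more evenly would only reduce between-unit dispersion.
- **A unit is a scalar force.** No twitch dynamics, tetanus curves,
  fatigue, or fibre types.
- **R is a count fraction**, `|recruited| / n`, not a force fraction.

## Pool construction

Twitch force of unit `i` is
`force_range_ratio ** ((i/(n−1)) ** shape_exponent)`, spanning
`[1, force_range_ratio]`. Defaults: `n = 100`,
`force_range_ratio = 100` (the typical ~100-fold twitch-force range in
motor-unit pool models), `shape_exponent = 1` (the classic exponential
spacing). This produces many small and few large units: the mean force
exceeds the median, and units below the median force outnumber units
above the mean. `shape_exponent > 1` sharpens the small-unit
predilection; values below 1 weaken it and are not recommended.
Optional multiplicative lognormal jitter (`jitter` = log-sigma,
default 0) randomizes forces; with the default of 0 the pool is
deterministic and seed-independent.

## Shift sampling

Within a shift, units are recruited sequentially without replacement
with probability proportional to policy weights renormalized over the
not-yet-recruited units, stopping as soon as the accumulated force
meets the load. The implementation uses the exponential-race
construction: unit `i` gets an independent clock `Exp(1)/w_i` and units
are taken in order of increasing clock. By the memorylessness of the
exponential race this order has exactly the sequential
sample-renormalize-repeat distribution, and it vectorizes across
shifts; a test checks Monte-Carlo `E[R]` against exhaustive enumeration
of all sampling paths for pools of up to 6 units.

Policies: `uniform` (equal weights) and `small_biased` (weight
proportional to `f_i ** −bias_strength`, default `bias_strength = 1` —
the simplest monotone family that contains uniform as the
`bias_strength → 0` limit; the bias's true functional form in real
muscle is unknown).

Edge conventions: load 0 recruits nothing (`R = 0`; the duty-cycle
ratio is undefined there and never reported as a number); a load above
maximum strength raises an infeasibility error; a load exactly equal to
maximum strength recruits every unit (an explicit clamp absorbs the
float summation-order epsilon).

**Overshoot bias.** Because recruitment stops at the first unit that
*meets* the load, the recruited force overshoots the load by part of
one twitch force. With the default pool this makes the mean recruitment
ratio at a 50% load about 0.505 rather than 0.500, and since
`(1 − R)/R` is steep at `R = 0.5`, the grand mean ratio at exactly half
load is ≈ 0.98, not 1.00. The half-load/unit-ratio statement is
therefore accurate to the "~" with which it is usually stated: the
ratio reaches 1 near, not exactly at, a 50% load. The bias shrinks as
`1/n`.

## Statistics reported

The headline statistic is the mean over units of the per-unit
`t_r / t_c` (units never recruited during a finite run are excluded
from the mean and counted separately); the ratio-of-means alternative
(total relaxation over total contraction) is exposed as
`pooled_ratio` — the two coincide at convergence under uniform
rotation. Sweeps report the mean and the between-replicate standard
deviation of the per-replicate mean ratio. Replicate `k` always uses
seed `base_seed + k`, so grid points share common random numbers and
every result is reproducible byte-for-byte from its config snapshot.

Defaults: 100 replicates × 1000 shifts per grid point (per-replicate
Monte-Carlo error is then well below the between-replicate SD); load
grid 0.05–0.95 in steps of 0.05; strength multipliers 0.2–2.0 in steps
of 0.1 with the constant load fixed at 20% of the reference maximum.
Grid points whose scaled muscle cannot carry the constant load at all
are flagged infeasible and kept in the output as NaN.

## Threshold load and chronicity

If an energy crisis occurs once `t_r / t_c` falls below a critical
value, the corresponding threshold load is found by monotone bisection
on the *load fraction*, using the analytic inverse
`R* = 1/(1 + critical_ratio)` to initialize the bracket and common
random numbers (the same seeds at every probed fraction) so the
empirical curve is monotone and depends on the load only through the
fraction. This makes `threshold / max_strength` exactly scale-invariant
under pool scaling, so a declining-strength trajectory needs only one
threshold computation: `threshold(t) = threshold_fraction ×
strength(t)`. Default bisection tolerance: 0.005 of maximum strength,
4 replicates × 1000 shifts per evaluation.

The critical ratio itself is unknown physiology: it is a **required**
argument with no default.

Chronicity trajectories are illustrations, not fitted models. Strength
declines exponentially (or linearly) at a user-set rate; loads are
user-supplied or drawn i.i.d. lognormal with median 0.5× the initial
threshold load and log-sigma 0.4 — illustrative values chosen so that
episodes start rare and become frequent as the muscle weakens, not
physiological claims. An episode is flagged whenever the applied load
exceeds the current threshold load.

## What the synthetic conditions do and do not show

Everything here is simulation of the model itself; there is no data.
Passing tests show that the implementation realizes the model's
internal logic — the force-balance stopping rule, the duty-cycle
relation, monotone trends in load and strength, robustness of those
trends to the recruitment bias, and threshold scale invariance. They
say nothing about real muscle, where recruitment is neither memoryless
nor schedule-free, firing rates modulate force, and twitch forces,
fatigue and recovery interact.

## Numerical choices

- Feasibility comparisons use a relative slack of 1e-9 to absorb float
  summation-order differences (e.g. a scaled pool carrying exactly its
  proportional load).
- Per-unit time conservation is exact by construction: relaxation time
  is computed as `n_shifts × shift_duration − contraction_time`.
- Pool CSV serialization writes 17 significant digits and reads with
  round-trip float parsing, so save/load is bit-exact.
- Ties in twitch force need no tie-break: stopping is on the
  accumulated-force inequality, and equal-force units are ordered by
  their sampled clocks.

## Problem sizes

The shipped test suite and the acceptance script run the full default
conditions (100-unit pool; 100 replicates × 1000 shifts per sweep
point; 19- and 19-point default grids; 20 × 5000 shifts for the
duty-cycle equivalence check), completing in well under a minute per
experiment on a single core.
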