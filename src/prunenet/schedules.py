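"""Pruning-rate schedules.

Network construction by elimination divides the developmental period into
``K`` discrete intervals (10 by default); after interval ``i`` a fraction
``r_i`` of the *currently existing* edges is removed.  Four canonical shapes
are supported:

constant
    ``r_1 = ... = r_K``, solving ``(1 - r)^K * E0 = B``.
decreasing / increasing
    Geometric family ``r_i = c * gamma^(i-1)`` with ``gamma < 1``
    (aggressive early elimination, the biologically observed shape) or
    ``gamma > 1`` (elimination deferred to late intervals); the constant
    ``c`` is solved numerically so survivors land exactly on the budget.
increasing uses ``gamma > 1``.
ending
    No elimination until the final interval, which cuts straight from the
    initial edge count to the budget.

Integer rounding removes ``round(r_i * current)`` edges per interval, with
the final interval forced to land exactly on ``B``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

SHAPES = ("constant", "increasing", "decreasing", "ending")

__all__ = ["PruneSchedule", "make_schedule", "edges_after", "energy", "SHAPES"]


@dataclass(frozen=True)
class PruneSchedule:
    """Per-interval removal fractions that take ``E0`` edges down to ``B``."""

    rates: tuple[float, ...]
    E0: int
    B: int
    shape: str
    shape_param: float | None = None

    @property
    def K(self) -> int:
        return len(self.rates)

    def removal_counts(self) -> list[int]:
        """Integer number of edges removed after each interval.

        Rounds ``r_i * current`` per interval; the final interval is forced
        to leave exactly ``B`` survivors.
        """
        current = self.E0
        removed = []
        for i, r in enumerate(self.rates):
            if i == self.K - 1:
                k = current - self.B
            else:
                k = int(round(r * current))
                k = min(k, current - self.B)  # never overshoot the budget
            removed.append(k)
            current -= k
        return removed


def _geometric_survivors(c: float, gamma: float, K: int, E0: int) -> float:
    rates = c * gamma ** np.arange(K)
    return E0 * np.prod(1.0 - rates)


def make_schedule(
    shape: str,
    E0: int,
    B: int,
    K: int = 10,
    shape_param: float | None = None,
    rng: np.random.Generator | None = None,
) -> PruneSchedule:
    """Build a budget-exact schedule of the requested shape.

    Parameters
    ----------
    shape : {'constant', 'increasing', 'decreasing', 'ending'}
    E0 : int
        Initial edge count (a clique start gives ``n(n-1)``).
    B : int
        Budget: exact surviving edge count, ``0 < B < E0``.
    K : int
        Number of pruning intervals (default 10).
    shape_param : float, optional
        Geometric ratio ``gamma`` for the monotone shapes; defaults to 0.5
        (decreasing) and 2.0 (increasing).
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown schedule shape {shape!r}")
    if not (0 < B < E0):
        raise ValueError(f"need 0 < B < E0, got B={B}, E0={E0}")
    if K < 1:
        raise ValueError(f"need K >= 1, got K={K}")

    if K == 1:
        # any shape degenerates to a single cut down to the budget
        return PruneSchedule((1.0 - B / E0,), E0, B, shape, shape_param)

    if shape == "ending":
        rates = (0.0,) * (K - 1) + (1.0 - B / E0,)
        return PruneSchedule(rates, E0, B, shape, shape_param)

    if shape == "constant":
        r = 1.0 - (B / E0) ** (1.0 / K)
        return PruneSchedule((r,) * K, E0, B, shape, shape_param)

    gamma = shape_param
    if gamma is None:
        gamma = 0.5 if shape == "decreasing" else 2.0
    if shape == "decreasing" and not (0 < gamma < 1):
        raise ValueError(f"decreasing shape needs 0 < gamma < 1, got {gamma}")
    if shape == "increasing" and not (gamma > 1):
        raise ValueError(f"increasing shape needs gamma > 1, got {gamma}")

    c_max = 1.0 / max(gamma ** (K - 1), 1.0)  # keep every r_i <= 1
    target = float(B)
    f = lambda c: _geometric_survivors(c, gamma, K, E0) - target
    # survivors decrease monotonically in c; at c -> c_max some rate hits 1
    # and survivors hit 0 < B, so a root exists whenever f(0) = E0 - B > 0.
    lo, hi = 1e-12, c_max * (1.0 - 1e-12)
    if f(hi) > 0:
        raise ValueError(
            f"{shape} schedule with gamma={gamma} cannot reach B={B} from E0={E0}"
        )
    c = brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
    rates = tuple(float(c * gamma**i) for i in range(K))
    return PruneSchedule(rates, E0, B, shape, gamma)


def edges_after(schedule: PruneSchedule, E0: int | None = None) -> list[int]:
    """Edge counts remaining after each interval (length K, last = B)."""
    if E0 is not None and E0 != schedule.E0:
        raise ValueError("schedule was built for a different initial edge count")
    counts = []
    current = schedule.E0
    for k in schedule.removal_counts():
        current -= k
        counts.append(current)
    return counts


def energy(schedule: PruneSchedule, E0: int | None = None) -> int:
    """Cumulative edge maintenance cost over the construction period.

    Interval ``i`` contributes the number of edges present while its block
    of training pairs is processed, i.e. before interval ``i``'s pruning
    step.  Later-removing schedules therefore cost more: for fixed (E0, B),
    decreasing < constant < increasing < ending.
    """
    after = edges_after(schedule, E0)
    return schedule.E0 + sum(after[:-1])
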