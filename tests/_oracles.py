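"""Independent brute-force oracles for the composition constraints.

`grid_bounds` enumerates the constrained simplex {p >= 0, sum = 100,
p_i >= p_{i+1} on enforced pairs, declared fixed} on a regular grid
(default 0.1 percentage-point resolution) and records the attained min/max
per coordinate.  It shares no code with the linear-programming bounds it is
used to check.
"""

from __future__ import annotations

import math


def grid_bounds(
    declared: list[float | None],
    step: float = 0.1,
    enforced_pairs: set[int] | None = None,
) -> tuple[list[float], list[float]] | None:
    """Brute-force per-coordinate bounds, or ``None`` if infeasible.

    ``declared[i]`` fixes coordinate i (values snapped to the grid);
    ``enforced_pairs`` lists indices i where p_i >= p_{i+1} must hold
    (default: all adjacent pairs).
    """
    n = len(declared)
    units = round(100.0 / step)
    fixed = {
        i: round(v / step) for i, v in enumerate(declared) if v is not None
    }
    if enforced_pairs is None:
        enforced_pairs = set(range(n - 1))
    free = [i for i in range(n) if i not in fixed]
    target = units - sum(fixed.values())
    if target < 0:
        return None
    # fixed-fixed adjacent pairs must already satisfy the ordering
    for i in enforced_pairs:
        if i in fixed and i + 1 in fixed and fixed[i] < fixed[i + 1]:
            return None
    if not free:
        if target != 0:
            return None
        return (
            [fixed[i] * step for i in range(n)],
            [fixed[i] * step for i in range(n)],
        )

    lo = [math.inf] * n
    hi = [-math.inf] * n
    feasible = [False]

    def cap_at(pos: int, prev: int | None) -> int:
        if pos == 0 or (pos - 1) not in enforced_pairs or prev is None:
            return units
        return prev

    def floor_at(pos: int) -> int:
        # a free coordinate directly above an (enforced) fixed neighbour
        if pos + 1 < n and pos in enforced_pairs and (pos + 1) in fixed:
            return fixed[pos + 1]
        return 0

    def suffix_fully_chained(pos: int) -> bool:
        return all(i in enforced_pairs for i in range(pos, n - 1))

    def record(values: dict[int, int]) -> None:
        feasible[0] = True
        for i, v in values.items():
            lo[i] = min(lo[i], v)
            hi[i] = max(hi[i], v)

    def walk(pos: int, rem: int, prev: int | None, values: dict[int, int]) -> None:
        if pos == n:
            if rem == 0:
                record(values)
            return
        if pos in fixed:
            v = fixed[pos]
            if (pos - 1) in enforced_pairs and prev is not None and v > prev:
                return
            walk(pos + 1, rem, v, values)
            return
        remaining_free = [i for i in range(pos, n) if i not in fixed]
        cap = cap_at(pos, prev)
        if len(remaining_free) == 1 and remaining_free == [pos]:
            v = rem
            if 0 <= v <= cap and v >= floor_at(pos):
                # validate pairs among trailing fixed coords vs v handled by
                # floor_at; deeper fixed-fixed pairs were pre-validated
                values[pos] = v
                walk(pos + 1, 0, v, values)
                del values[pos]
            return
        # analytic tail: the last two coordinates, both free, chained
        if (
            pos == n - 2
            and remaining_free == [n - 2, n - 1]
            and (n - 2) in enforced_pairs
        ):
            vmin = max((rem + 1) // 2, 0)
            vmax = min(cap, rem)
            if vmin > vmax:
                return
            for v in (vmin, vmax):
                values[pos] = v
                values[pos + 1] = rem - v
                record(dict(values))
            # interior of the interval only widens pos/pos+1 bounds, which
            # the two endpoints already attain (rem - v is monotone in v)
            del values[pos], values[pos + 1]
            return
        k = len(remaining_free) - 1
        vmin = floor_at(pos)
        if suffix_fully_chained(pos):
            vmin = max(vmin, math.ceil(rem / (k + 1)))
        vmax = min(cap, rem)
        for v in range(vmin, vmax + 1):
            values[pos] = v
            walk(pos + 1, rem - v, v, values)
        values.pop(pos, None)

    walk(0, target, None, {})
    if not feasible[0]:
        return None
    for i, v in fixed.items():
        lo[i] = hi[i] = v
    return [v * step for v in lo], [v * step for v in hi]


def check_composition(
    percents,
    declared: list[float | None],
    lo,
    hi,
    enforced_pairs: set[int] | None = None,
    tol: float = 1e-6,
) -> list[str]:
    """Independent constraint check of an inferred composition; returns a
    list of violation descriptions (empty = all constraints hold)."""
    n = len(percents)
    problems = []
    if abs(sum(percents) - 100.0) > tol:
        problems.append(f"sum {sum(percents)!r} != 100")
    if enforced_pairs is None:
        enforced_pairs = set(range(n - 1))
    for i in range(n):
        if percents[i] < lo[i] - tol or percents[i] > hi[i] + tol:
            problems.append(
                f"p[{i}]={percents[i]} outside [{lo[i]}, {hi[i]}]"
            )
    for i in enforced_pairs:
        both_small = percents[i] <= 2.0 + tol and percents[i + 1] <= 2.0 + tol
        if percents[i + 1] > percents[i] + tol and not both_small:
            problems.append(f"order violated at pair ({i}, {i + 1})")
    return problems
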