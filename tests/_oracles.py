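"""Independent brute-force re-implementations used as test oracles.

Every function here scans day-by-day (or subject-by-subject) with no shared
code with the package; they are deliberately naive.
"""

from __future__ import annotations

import numpy as np


def brute_inactive(measured: set[int], t: int, first_day: int, threshold: int = 28) -> bool:
    if t < first_day:
        return False
    return all(d not in measured for d in range(t - threshold + 1, t + 1))


def brute_gaps(measured: list[int], cutoff: int) -> list[tuple[int, int]]:
    """(gap_start, gap_length) for maximal unmeasured runs after a measured day."""
    mset = set(measured)
    first = min(measured)
    gaps = []
    d = first
    while d <= cutoff:
        if d not in mset and (d - 1) in mset:
            g = 0
            while d + g <= cutoff and (d + g) not in mset:
                g += 1
            gaps.append((d, g))
            d += g
        else:
            d += 1
    return gaps


def brute_resumption(measured: list[int], after_day: int, cutoff: int) -> int | None:
    mset = set(measured)
    for r in sorted(mset):
        if r <= after_day:
            continue
        if r + 27 > cutoff:
            return None
        if all(
            any((r + 7 * w + i) in mset for i in range(7)) for w in range(4)
        ):
            return r
    return None


def brute_product_limit(times: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(event times, cumulative incidence) via the textbook product formula."""
    times = np.asarray(times, dtype=float)
    flags = np.asarray(flags, dtype=int)
    uniq = np.unique(times[flags == 1])
    surv = 1.0
    out = []
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & (flags == 1)))
        surv *= 1.0 - deaths / at_risk
        out.append(1.0 - surv)
    return uniq, np.asarray(out)


def random_series_pattern(rng: np.random.Generator) -> tuple[list[int], int]:
    """A random short measurement pattern: sorted measured days and a cutoff."""
    cutoff = int(rng.integers(20, 121))
    first = int(rng.integers(0, max(1, cutoff - 10)))
    p = rng.uniform(0.02, 0.9)
    days = [d for d in range(first, cutoff + 1) if rng.random() < p]
    if not days:
        days = [first]
    if days[0] != first:
        days.insert(0, first)
    return days, cutoff
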