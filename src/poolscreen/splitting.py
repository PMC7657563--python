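"""Adaptive binary-splitting strategies: Halving and Generalized Binary Splitting.

Binary Splitting by Halving needs no estimate of the number of positives.
It repeatedly pools every unresolved sample; on a positive result it binary
searches for a single positive by testing the first half of the active
group: a positive tested half narrows the search into it (the untested half
returns to the unresolved pot), a negative tested half clears those samples
and transfers the search to the untested half, which is then positive by
elimination.  Exactly one test runs per sequential step, so tests == steps.

Hwang's Generalized Binary Splitting sizes the initial group as 2**alpha
with alpha = floor(log2((N_remaining - k_hat + 1) / k_hat)), recomputed with
the current unresolved count and estimate after each isolation.  When the
unresolved count drops to 2*k_hat - 2 or below the remainder is tested
individually (one parallel step); when the estimate reaches zero a halving
sweep over the unresolved samples guarantees completeness.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

from .core import (
    DEFAULT_CHANNELS,
    Pool,
    SampleStatusVector,
    ScreenOutcome,
    pipettings_for_pool,
    pooled_test,
)

__all__ = ["halving_step", "run_halving", "gbs_alpha", "run_gbs"]


def halving_step(active: Sequence[int]) -> tuple[list[int], list[int]]:
    """Split the active group: tested half = first ceil(m/2) indices."""
    if len(active) < 2:
        raise ValueError("cannot split a group of fewer than two samples")
    h = -(-len(active) // 2)
    return list(active[:h]), list(active[h:])


class _Tracer:
    """Per-test tally with an optional JSON-lines-able trace."""

    def __init__(self, channels: Sequence[int], trace: list | None):
        self.tests = 0
        self.steps = 0
        self.pipettings = {int(c): 0 for c in channels}
        self.max_pool = 0
        self.trace = trace

    def test(self, statuses: SampleStatusVector, members: Sequence[int],
             note: str = "") -> bool:
        pool = Pool(tuple(members))
        result = pooled_test(statuses, pool)
        self.tests += 1
        self.steps += 1
        self.max_pool = max(self.max_pool, pool.size)
        for c in self.pipettings:
            self.pipettings[c] += pipettings_for_pool(pool.size, c)
        if self.trace is not None:
            self.trace.append(
                {
                    "test": self.tests,
                    "pool": list(pool.members),
                    "result": "positive" if result else "negative",
                    "note": note,
                }
            )
        return result


def _isolate_one(
    statuses: SampleStatusVector, active: list[int], tracer: _Tracer
) -> tuple[int, list[int]]:
    """Binary-descend an active group known to contain a positive.

    Returns the isolated positive index and the samples returned untested
    to the unresolved pot.  Tested-negative halves are classified negative
    and simply dropped; a size-1 tested group classifies directly.
    """
    returned: list[int] = []
    while len(active) > 1:
        tested, untested = halving_step(active)
        if tracer.test(statuses, tested, "descent"):
            returned.extend(untested)
            active = tested
        else:
            # tested half cleared; the untested half holds a positive
            # by elimination
            assert any(statuses.statuses[m] for m in untested)
            active = untested
    return active[0], returned


def _halving_rounds(
    statuses: SampleStatusVector, unresolved: list[int], tracer: _Tracer
) -> set[int]:
    """Repeated pool-all-then-descend rounds until the pot tests negative."""
    decoded: set[int] = set()
    while unresolved:
        if not tracer.test(statuses, unresolved, "pool all unresolved"):
            break
        if len(unresolved) == 1:
            decoded.add(unresolved[0])
            break
        positive, returned = _isolate_one(statuses, unresolved, tracer)
        decoded.add(positive)
        unresolved = sorted(returned)
    return decoded


def run_halving(
    statuses: SampleStatusVector,
    channels: Sequence[int] = DEFAULT_CHANNELS,
    trace: list | None = None,
) -> ScreenOutcome:
    """Simulate Binary Splitting by Halving; no k-hat is needed.

    After each isolation every still-unclassified sample (including
    untested halves never descended into) returns to the unresolved pot.
    One test per step, so tests always equals steps.
    """
    tracer = _Tracer(channels, trace)
    decoded = _halving_rounds(statuses, list(range(statuses.n)), tracer)
    return ScreenOutcome(
        tests=tracer.tests,
        steps=tracer.steps,
        pipettings=tracer.pipettings,
        max_pool_size=tracer.max_pool,
        decoded_positives=frozenset(decoded),
    )


def gbs_alpha(n_remaining: int, k_hat_remaining: int) -> int:
    """alpha = floor(log2((N_remaining - k_hat + 1) / k_hat)), clamped >= 0.

    The initial pooled group holds 2**alpha samples.
    """
    if k_hat_remaining < 1:
        raise ValueError("k_hat_remaining must be >= 1")
    if n_remaining <= 2 * k_hat_remaining - 2:
        raise ValueError("individual testing applies when N <= 2*k_hat - 2")
    ratio = (n_remaining - k_hat_remaining + 1) / k_hat_remaining
    return max(0, math.floor(math.log2(ratio)))


def run_gbs(
    statuses: SampleStatusVector,
    k_hat: int,
    channels: Sequence[int] = DEFAULT_CHANNELS,
    trace: list | None = None,
) -> ScreenOutcome:
    """Simulate Generalized Binary Splitting designed for ``k_hat`` positives.

    Pooled tests count one step each; a batch of individual tests counts as
    a single step because those tests can run in parallel.  When the
    running estimate reaches zero, a plain halving sweep over the
    unresolved samples guarantees that positives beyond the estimate are
    still found.
    """
    if k_hat < 1:
        warnings.warn("k_hat < 1 is undefined for this design; using 1", stacklevel=2)
        k_hat = 1
    tracer = _Tracer(channels, trace)
    unresolved = list(range(statuses.n))
    k_rem = k_hat
    decoded: set[int] = set()
    while unresolved:
        if k_rem == 0:
            # completeness sweep (the estimate is exhausted)
            decoded |= _halving_rounds(statuses, unresolved, tracer)
            break
        if len(unresolved) <= 2 * k_rem - 2:
            # test the remainder individually, in parallel: one step
            tracer.steps += 1
            for m in unresolved:
                pool = Pool((m,))
                tracer.tests += 1
                tracer.max_pool = max(tracer.max_pool, 1)
                for c in tracer.pipettings:
                    tracer.pipettings[c] += 1
                if pooled_test(statuses, pool):
                    decoded.add(m)
                if tracer.trace is not None:
                    tracer.trace.append(
                        {"test": tracer.tests, "pool": [m],
                         "result": "positive" if m in decoded else "negative",
                         "note": "individual batch"}
                    )
            break
        group_size = 2 ** gbs_alpha(len(unresolved), k_rem)
        group, rest = unresolved[:group_size], unresolved[group_size:]
        if not tracer.test(statuses, group, "initial group"):
            unresolved = rest  # whole group cleared, estimate unchanged
            continue
        if len(group) == 1:
            positive, returned = group[0], []
        else:
            positive, returned = _isolate_one(statuses, group, tracer)
        decoded.add(positive)
        k_rem -= 1
        unresolved = sorted(returned + rest)
    return ScreenOutcome(
        tests=tracer.tests,
        steps=tracer.steps,
        pipettings=tracer.pipettings,
        max_pool_size=tracer.max_pool,
        decoded_positives=frozenset(decoded),
    )
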