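"""Multi-stage adaptive pooling: Li's S-Stage and the Modified 3-Stage scheme.

Both schemes test batches of pools in sequential stages.  Stage counts and
pool sizes come from the classical formulas

    S   = ceil(ln(N / k_hat))            (capped at 3 for the modified scheme)
    n_i = ceil((N / k_hat)^((S - i) / S))    with n_S = 1,

with the integer policy: ceiling for n_i, floor for the group count, then an
even partition across groups (group sizes differ by at most one, larger
groups first).

The two schemes differ in how survivors are re-pooled.  S-Stage collects
*all* samples from positive pools and redivides them collectively at the
next stage.  The Modified 3-Stage scheme instead subdivides each positive
pool independently into floor(m / n_next) contiguous subgroups, which keeps
pooled samples physically adjacent on a plate (multichannel-pipette
friendly) and caps the screen at three sequential steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core import (
    DEFAULT_CHANNELS,
    Pool,
    SampleStatusVector,
    ScreenOutcome,
    even_partition,
    pipettings_for_pool,
    pooled_test,
)

__all__ = [
    "StagePlan",
    "stage_count",
    "stage_pool_size",
    "form_stage_pools",
    "run_s_stage",
    "run_modified_3stage",
    "s_stage_upper_bound",
]


def stage_count(n: int, k_hat: int, cap: int | None = None) -> int:
    """Number of sequential stages, S = ceil(ln(N / k_hat)), at least 1.

    ``cap`` bounds the count (3 for the modified scheme).
    """
    if k_hat < 1:
        raise ValueError("k_hat must be >= 1")
    if k_hat > n:
        raise ValueError("k_hat cannot exceed N")
    s = max(1, math.ceil(math.log(n / k_hat)))
    if cap is not None:
        s = min(cap, s)
    return s


def _int_ceil(value: float) -> int:
    # guard against float representation noise before taking the ceiling
    nearest = round(value)
    if abs(value - nearest) < 1e-9:
        return int(nearest)
    return math.ceil(value)


def stage_pool_size(n: int, k_hat: int, s: int, i: int) -> int:
    """Samples per pool at stage ``i``: n_i = ceil((N/k_hat)^((S-i)/S))."""
    if not 1 <= i <= s:
        raise ValueError("stage index must be in [1, S]")
    if i == s:
        return 1
    return _int_ceil((n / k_hat) ** ((s - i) / s))


@dataclass(frozen=True)
class StagePlan:
    """Stage-by-stage pool sizes for one scheme design."""

    n: int
    k_hat: int
    origin: str  # "s_stage" | "modified_3stage"
    s: int
    stage_pool_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = self.stage_pool_sizes
        if self.stage_pool_sizes[-1] != 1:
            raise ValueError("the final stage must test individually (n_S = 1)")
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("stage pool sizes must be non-increasing")
        if self.origin == "modified_3stage" and self.s > 3:
            raise ValueError("the modified scheme is capped at three stages")

    @classmethod
    def design(cls, n: int, k_hat: int, origin: str) -> "StagePlan":
        cap = 3 if origin == "modified_3stage" else None
        s = stage_count(n, k_hat, cap)
        sizes = tuple(stage_pool_size(n, k_hat, s, i) for i in range(1, s + 1))
        return cls(n, k_hat, origin, s, sizes)

    def to_json_dict(self) -> dict[str, object]:
        g1 = max(1, self.n // self.stage_pool_sizes[0])
        return {"S": self.s, "n": list(self.stage_pool_sizes), "g1": g1}


def form_stage_pools(
    remaining: Sequence[int], n_i: int, stage: int = 1, label_prefix: str = "S"
) -> list[Pool]:
    """Divide the remaining samples into g = max(1, floor(m / n_i)) pools.

    Pools are contiguous runs of the remaining-sample ordering with
    even-partition sizes.
    """
    if not remaining:
        raise ValueError("remaining samples must be non-empty")
    g = max(1, len(remaining) // n_i)
    sizes = even_partition(len(remaining), g)
    pools = []
    start = 0
    for j, size in enumerate(sizes):
        pools.append(
            Pool(tuple(remaining[start:start + size]), stage, f"{label_prefix}{stage}-P{j}")
        )
        start += size
    return pools


class _Tally:
    """Accumulates tests / steps / pipettings / max pool over a run."""

    def __init__(self, channels: Sequence[int]):
        self.tests = 0
        self.steps = 0
        self.pipettings = {int(c): 0 for c in channels}
        self.max_pool = 0

    def record_stage(self, pools: Sequence[Pool]) -> None:
        self.steps += 1
        for pool in pools:
            self.tests += 1
            self.max_pool = max(self.max_pool, pool.size)
            for c in self.pipettings:
                self.pipettings[c] += pipettings_for_pool(pool.size, c)

    def outcome(self, decoded: frozenset[int]) -> ScreenOutcome:
        return ScreenOutcome(
            tests=self.tests,
            steps=self.steps,
            pipettings=self.pipettings,
            max_pool_size=self.max_pool,
            decoded_positives=decoded,
        )


def run_s_stage(
    statuses: SampleStatusVector,
    k_hat: int,
    channels: Sequence[int] = DEFAULT_CHANNELS,
) -> ScreenOutcome:
    """Simulate an S-Stage screen designed for ``k_hat`` expected positives.

    At every stage all samples surviving from positive pools are collected
    (preserving index order) and collectively redivided; the final stage
    tests individually.  Testing stops early if every pool at some stage is
    negative.
    """
    plan = StagePlan.design(statuses.n, k_hat, "s_stage")
    tally = _Tally(channels)
    remaining = list(range(statuses.n))
    decoded: frozenset[int] = frozenset()
    for i in range(1, plan.s + 1):
        pools = form_stage_pools(remaining, plan.stage_pool_sizes[i - 1], stage=i)
        tally.record_stage(pools)
        survivors = [
            m for pool in pools if pooled_test(statuses, pool) for m in pool.members
        ]
        if not survivors:
            break
        if i == plan.s:
            decoded = frozenset(survivors)
        remaining = survivors
    return tally.outcome(decoded)


def run_modified_3stage(
    statuses: SampleStatusVector,
    k_hat: int,
    channels: Sequence[int] = DEFAULT_CHANNELS,
) -> ScreenOutcome:
    """Simulate a Modified 3-Stage screen designed for ``k_hat`` positives.

    Stage 1 divides all samples; afterwards each positive pool of actual
    size ``m`` is independently subdivided into max(1, floor(m / n_next))
    contiguous even subgroups.  At most three sequential steps.
    """
    plan = StagePlan.design(statuses.n, k_hat, "modified_3stage")
    tally = _Tally(channels)
    pools = form_stage_pools(
        list(range(statuses.n)), plan.stage_pool_sizes[0], stage=1
    )
    decoded: frozenset[int] = frozenset()
    for i in range(1, plan.s + 1):
        tally.record_stage(pools)
        positive_pools = [p for p in pools if pooled_test(statuses, p)]
        if not positive_pools:
            break
        if i == plan.s:
            decoded = frozenset(m for p in positive_pools for m in p.members)
            break
        n_next = plan.stage_pool_sizes[i]
        pools = [
            sub
            for p in positive_pools
            for sub in form_stage_pools(
                p.members, n_next, stage=i + 1, label_prefix=f"{p.label}/S"
            )
        ]
    return tally.outcome(decoded)


def s_stage_upper_bound(n: int, k: int) -> float:
    """Worst-case S-Stage test count, e*log2(e)*k*log2(N/k) (for overlays)."""
    if not 1 <= k < n:
        raise ValueError("requires 1 <= k < N")
    return math.e * math.log2(math.e) * k * math.log2(n / k)
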