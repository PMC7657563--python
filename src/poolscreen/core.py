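"""Shared domain types and primitives for pooled (group) testing.

Every pooling strategy in this package operates on the same three
abstractions: a ground-truth :class:`SampleStatusVector`, a :class:`Pool`
(an ordered subset of sample indices tested together), and a
:class:`ScreenOutcome` tallying the cost of a complete screen (tests,
sequential steps, pipettings per pipette channel count, maximum pool size).

The assay model is noiseless: a pooled test is positive if and only if at
least one member of the pool is positive.  No dilution, limit-of-detection
or error model is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SampleStatusVector",
    "Pool",
    "PoolingDesign",
    "ScreenOutcome",
    "EstimateContext",
    "pooled_test",
    "place_positives",
    "even_partition",
    "pipettings_for_pool",
    "control_adjusted_tests",
    "child_seed",
    "DEFAULT_CHANNELS",
]

#: Pipette channel counts tracked by default (single, 8- and 16-channel).
DEFAULT_CHANNELS: tuple[int, ...] = (1, 8, 16)


@dataclass(frozen=True)
class SampleStatusVector:
    """Ordered true positive/negative status of ``N`` samples.

    ``statuses`` is a boolean array; ``True`` marks a positive sample.
    Indices are 0-based and strategy-agnostic (96-well plate semantics live
    in :mod:`poolscreen.plate`).
    """

    statuses: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.statuses, dtype=bool)
        object.__setattr__(self, "statuses", arr)
        if arr.ndim != 1:
            raise ValueError("statuses must be one-dimensional")

    @classmethod
    def from_positives(cls, n: int, positives: Iterable[int]) -> "SampleStatusVector":
        arr = np.zeros(n, dtype=bool)
        idx = np.asarray(list(positives), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("positive index out of range")
        arr[idx] = True
        return cls(arr)

    @property
    def n(self) -> int:
        return int(self.statuses.size)

    @property
    def k(self) -> int:
        """Realized number of positive samples."""
        return int(self.statuses.sum())

    @property
    def positives(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.statuses))


@dataclass(frozen=True)
class Pool:
    """An ordered group of distinct sample indices tested together."""

    members: tuple[int, ...]
    stage: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        members = tuple(int(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("pool must be non-empty")
        if len(set(members)) != len(members):
            raise ValueError("pool members must be distinct")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PoolingDesign:
    """A strategy-specific plan: pools organised by stage.

    Serialises to the shared design-dump JSON format
    ``{"strategy", "N", "params", "pools": [...]}``.
    """

    strategy: str
    n: int
    params: Mapping[str, object]
    pools: tuple[Pool, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "strategy": self.strategy,
                "N": self.n,
                "params": dict(self.params),
                "pools": [
                    {"stage": p.stage, "label": p.label, "members": list(p.members)}
                    for p in self.pools
                ],
            }
        )


@dataclass(frozen=True)
class EstimateContext:
    """The expected number of positives, k-hat, used to design a scheme."""

    k_hat: int

    def __post_init__(self) -> None:
        if self.k_hat < 1:
            raise ValueError("k_hat must be >= 1")


@dataclass(frozen=True)
class ScreenOutcome:
    """Per-run tally for one complete screen of ``N`` samples.

    ``pipettings`` maps pipette channel count ``c`` to the number of draws
    needed to assemble every pool tested.  ``ambiguous_retest_count`` is the
    number of individual second-round tests a non-adaptive design needed
    (always 0 for adaptive strategies).
    """

    tests: int
    steps: int
    pipettings: Mapping[int, int]
    max_pool_size: int
    decoded_positives: frozenset[int]
    ambiguous_retest_count: int = 0

    def __post_init__(self) -> None:
        if self.tests < 1 or self.steps < 1:
            raise ValueError("a completed screen performs at least one test/step")
        object.__setattr__(self, "pipettings", dict(self.pipettings))
        object.__setattr__(
            self, "decoded_positives", frozenset(int(i) for i in self.decoded_positives)
        )
        counts = [self.pipettings[c] for c in sorted(self.pipettings)]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("pipettings must be non-increasing in channel count")

    def to_row(self, **meta: object) -> dict[str, object]:
        """Flatten to one CSV/JSON record (see the documented schema)."""
        row: dict[str, object] = dict(meta)
        row.update(
            tests=self.tests,
            steps=self.steps,
            max_pool=self.max_pool_size,
            ambiguous_retests=self.ambiguous_retest_count,
        )
        for c, p in sorted(self.pipettings.items()):
            row[f"pipettings_c{c}"] = p
        return row


def pooled_test(statuses: SampleStatusVector, pool: Pool) -> bool:
    """Noiseless pooled assay: positive iff any member is positive (OR)."""
    members = np.asarray(pool.members, dtype=int)
    if members.min() < 0 or members.max() >= statuses.n:
        raise IndexError("pool contains a sample index outside [0, N)")
    return bool(statuses.statuses[members].any())


def place_positives(n: int, k: int, seed: int) -> SampleStatusVector:
    """Place ``k`` positives uniformly at random among ``n`` samples.

    Reproducible for a fixed seed.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, N]; got k={k}, N={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return SampleStatusVector.from_positives(n, idx)


def even_partition(m: int, g: int) -> list[int]:
    """Split ``m`` items into ``g`` groups of size floor(m/g) or ceil(m/g).

    Larger groups are listed first; sizes sum to ``m`` and differ by at
    most one.
    """
    if m < 1 or g < 1:
        raise ValueError("m and g must be >= 1")
    if g > m:
        raise ValueError(f"cannot split {m} items into {g} non-empty groups")
    q, r = divmod(m, g)
    return [q + 1] * r + [q] * (g - r)


def pipettings_for_pool(pool_size: int, channels: int) -> int:
    """Draws needed to assemble one pool with a ``channels``-channel pipette.

    Plain ceil(pool_size / channels); the dispense into the destination
    well is not counted, only sample draws.
    """
    if pool_size < 1 or channels < 1:
        raise ValueError("pool_size and channels must be >= 1")
    return -(-pool_size // channels)


def control_adjusted_tests(outcome: ScreenOutcome, mode: str) -> int:
    """Test count including positive/negative assay controls.

    ``per_pool`` adds two control tests alongside every pool tested (the
    convention for purely adaptive methods, where pools run one at a time,
    tripling the count).  ``per_stage`` adds two controls per sequential
    step (multi-stage and non-adaptive methods run many pools per batch).
    """
    if mode == "per_pool":
        return 3 * outcome.tests
    if mode == "per_stage":
        return outcome.tests + 2 * outcome.steps
    raise ValueError("mode must be 'per_pool' or 'per_stage'")


def child_seed(root: int, *keys: int) -> int:
    """Derive an independent, reproducible child seed from a root seed.

    Each (root, keys) combination maps to a stable value below 2**31, so
    replicates are individually reproducible.
    """
    ss = np.random.SeedSequence([int(root), *(int(k) for k in keys)])
    return int(ss.generate_state(1)[0] % (2**31))
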