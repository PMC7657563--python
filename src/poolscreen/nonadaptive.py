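"""Non-adaptive pooling designs: CRT window pooling (DNA Sudoku) and 2D grids.

Both designs fix every pool in advance so all first-round tests can run in
parallel.  Decoding happens once all pool results are known; when the
results are ambiguous the candidate samples are retested individually in a
single second round.

DNA Sudoku assigns sample ``s`` to pool ``s mod W_i`` for each of ``w``
window sizes ``W_i``.  Windows exceed sqrt(N) and are pairwise co-prime, so
by the Chinese remainder theorem any two samples share at most one pool;
with weight ``w`` up to ``w - 1`` positives decode unambiguously.

2D pooling arranges samples in ``M`` square ``D x D`` grids (row-major fill,
grids filled sequentially) and pools every non-empty row and column.
Positives sit at intersections of positive rows and columns; a grid is
ambiguous when more than one row *and* more than one column are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import (
    DEFAULT_CHANNELS,
    Pool,
    PoolingDesign,
    SampleStatusVector,
    ScreenOutcome,
    pipettings_for_pool,
    pooled_test,
)

__all__ = [
    "PUBLISHED_WINDOWS",
    "select_windows",
    "SudokuDesign",
    "sudoku_assign",
    "sudoku_decode",
    "run_sudoku",
    "GridDesign",
    "grid_layout",
    "run_grid2d",
    "DecodeResult",
]

#: Published window sets for the three preset sample sizes.  These are the
#: validated design constants for 96-, 384- and 1536-sample screens; the
#: greedy co-prime scan below reproduces the 384 and 1536 sets exactly but
#: for 96 it would admit 21 (= 3*7, co-prime to every predecessor) before 23.
#: The published constants take precedence for these sizes.
PUBLISHED_WINDOWS: dict[int, tuple[int, ...]] = {
    96: (10, 11, 13, 17, 19, 23),
    384: (20, 21, 23, 29, 31, 37, 41, 43, 47, 53),
    1536: (
        40, 41, 43, 47, 49, 51, 53, 59, 61, 67, 71,
        73, 79, 83, 89, 97, 101, 103, 107, 109, 113,
    ),
}


def _greedy_extend(n: int, selected: list[int], w: int) -> list[int]:
    """Greedily append integers > sqrt(N), pairwise co-prime with all chosen."""
    candidate = (selected[-1] + 1) if selected else (math.isqrt(n) + 1)
    while len(selected) < w:
        if all(math.gcd(candidate, s) == 1 for s in selected):
            selected.append(candidate)
        candidate += 1
    return selected


def select_windows(n: int, w: int) -> list[int]:
    """Choose ``w`` window sizes for an N-sample CRT pooling design.

    For the preset sizes (96, 384, 1536) the published window sets are
    returned (extended greedily if ``w`` exceeds the published weight).
    Otherwise windows are the ``w`` smallest integers greater than sqrt(N)
    that are pairwise co-prime, scanned upward greedily.  Deterministic.
    """
    if w < 2:
        raise ValueError("weight must be >= 2")
    published = PUBLISHED_WINDOWS.get(n, ())
    selected = list(published[:w])
    return _greedy_extend(n, selected, w)


@dataclass(frozen=True)
class SudokuDesign:
    """CRT window-pooling design: ``w`` windows, one pool per residue."""

    n: int
    windows: tuple[int, ...]

    def __post_init__(self) -> None:
        windows = tuple(int(x) for x in self.windows)
        object.__setattr__(self, "windows", windows)
        if len(windows) < 2:
            raise ValueError("a window design needs weight >= 2")
        if any(wi * wi <= self.n for wi in windows):
            raise ValueError("every window must exceed sqrt(N)")
        for i, a in enumerate(windows):
            for b in windows[i + 1:]:
                if math.gcd(a, b) != 1:
                    raise ValueError(f"windows {a} and {b} are not co-prime")

    @property
    def weight(self) -> int:
        return len(self.windows)

    def pools_of(self, sample: int) -> list[tuple[int, int]]:
        """The (window ordinal, residue) pools containing ``sample``."""
        return [(i + 1, sample % wi) for i, wi in enumerate(self.windows)]


def sudoku_assign(n: int, windows: Sequence[int]) -> PoolingDesign:
    """Materialise the pools of a window design.

    Sample ``s`` joins pool ``(i, s mod W_i)`` for every window, so each
    sample appears in exactly ``w`` pools and the total pool count is the
    sum of the window sizes.
    """
    design = SudokuDesign(n, tuple(windows))
    pools = []
    for i, wi in enumerate(design.windows, start=1):
        for residue in range(wi):
            members = tuple(range(residue, n, wi))
            if members:
                pools.append(Pool(members, stage=1, label=f"W{i}-{residue}"))
    return PoolingDesign("sudoku", n, {"windows": list(design.windows)}, tuple(pools))


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of decoding one round of non-adaptive pool results."""

    candidates: frozenset[int]
    ambiguous: bool
    retest_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.ambiguous != bool(self.retest_indices):
            raise ValueError("retest_indices must be non-empty iff ambiguous")


def sudoku_decode(
    pool_results: Mapping[tuple[int, int], bool], design: SudokuDesign
) -> DecodeResult:
    """Decode window-pool results.

    Candidates are the samples all of whose ``w`` pools are positive.  The
    result is ambiguous when there are more than ``w - 1`` candidates (the
    design only guarantees decoding of up to ``w - 1`` positives); ambiguous
    candidates are slated for individual retest.
    """
    for i, wi in enumerate(design.windows, start=1):
        for residue in range(wi):
            if residue < design.n and (i, residue) not in pool_results:
                raise KeyError(f"missing result for pool (window {i}, residue {residue})")
    candidates = frozenset(
        s
        for s in range(design.n)
        if all(pool_results[key] for key in design.pools_of(s))
    )
    ambiguous = len(candidates) > design.weight - 1
    retest = tuple(sorted(candidates)) if ambiguous else ()
    return DecodeResult(candidates, ambiguous, retest)


def run_sudoku(
    statuses: SampleStatusVector,
    k_hat: int | None = None,
    weight: int | None = None,
    channels: Sequence[int] = DEFAULT_CHANNELS,
) -> ScreenOutcome:
    """Simulate a full DNA Sudoku screen.

    The weight defaults to ``k_hat + 1`` (one more window than the expected
    number of positives).  First-round tests equal the sum of the window
    sizes; an ambiguous decode adds one individual test per candidate in a
    second round.  Staggered pool membership means multichannel pipettes
    give no benefit: every channel count needs ``N*w`` draws plus one per
    retest.
    """
    if weight is None:
        if k_hat is None:
            raise ValueError("provide k_hat (weight defaults to k_hat + 1) or weight")
        weight = k_hat + 1
    n = statuses.n
    design = SudokuDesign(n, tuple(select_windows(n, weight)))
    results: dict[tuple[int, int], bool] = {}
    max_pool = 0
    for i, wi in enumerate(design.windows, start=1):
        for residue in range(wi):
            members = tuple(range(residue, n, wi))
            if not members:
                results[(i, residue)] = False
                continue
            max_pool = max(max_pool, len(members))
            results[(i, residue)] = pooled_test(statuses, Pool(members, 1))

    decode = sudoku_decode(results, design)
    retests = len(decode.retest_indices)
    if decode.ambiguous:
        decoded = frozenset(s for s in decode.retest_indices if statuses.statuses[s])
    else:
        decoded = decode.candidates
    tests = sum(design.windows) + retests
    pipettings = {int(c): n * design.weight + retests for c in channels}
    return ScreenOutcome(
        tests=tests,
        steps=2 if decode.ambiguous else 1,
        pipettings=pipettings,
        max_pool_size=max_pool,
        decoded_positives=decoded,
        ambiguous_retest_count=retests,
    )


@dataclass(frozen=True)
class GridDesign:
    """Layout of ``N`` samples across ``M`` square ``D x D`` grids."""

    n: int
    d: int
    m: int
    occupancy: tuple[int, ...]  # filled cells per grid; only the last partial

    def __post_init__(self) -> None:
        if sum(self.occupancy) != self.n:
            raise ValueError("occupancy must sum to N")


def grid_layout(n: int, d: int) -> GridDesign:
    """Arrange ``N`` samples into ceil(N / D^2) grids, filled sequentially.

    Each grid is filled row-major; only the last grid may be partial.
    """
    if d < 2:
        raise ValueError("grid dimension must be >= 2")
    cells = d * d
    m = -(-n // cells)
    occupancy = [cells] * (m - 1) + [n - cells * (m - 1)]
    return GridDesign(n, d, m, tuple(occupancy))


def _grid_pools(layout: GridDesign) -> list[list[Pool]]:
    """Non-empty row and column pools per grid (empty lines are not tested)."""
    d = layout.d
    per_grid = []
    offset = 0
    for g, occ in enumerate(layout.occupancy):
        rows: list[list[int]] = [[] for _ in range(d)]
        cols: list[list[int]] = [[] for _ in range(d)]
        for p in range(occ):
            rows[p // d].append(offset + p)
            cols[p % d].append(offset + p)
        pools = [
            Pool(tuple(line), 1, f"G{g}-R{i}")
            for i, line in enumerate(rows)
            if line
        ] + [
            Pool(tuple(line), 1, f"G{g}-C{i}")
            for i, line in enumerate(cols)
            if line
        ]
        per_grid.append(pools)
        offset += occ
    return per_grid


def run_grid2d(
    statuses: SampleStatusVector,
    d: int,
    channels: Sequence[int] = DEFAULT_CHANNELS,
) -> ScreenOutcome:
    """Simulate a full 2D-grid pooling screen with dimension ``d``.

    Per grid, candidates are the occupied cells at intersections of
    positive rows and positive columns; a grid is ambiguous iff it has more
    than one positive row and more than one positive column.  Candidates of
    ambiguous grids are retested individually (single-channel) in one
    shared second step.
    """
    layout = grid_layout(statuses.n, d)
    base_tests = 0
    max_pool = 0
    pipettings = {int(c): 0 for c in channels}
    decoded: set[int] = set()
    retest: list[int] = []
    for pools in _grid_pools(layout):
        row_res: dict[str, bool] = {}
        for pool in pools:
            res = pooled_test(statuses, pool)
            row_res[pool.label] = res
            base_tests += 1
            max_pool = max(max_pool, pool.size)
            for c in pipettings:
                pipettings[c] += pipettings_for_pool(pool.size, c)
        pos_rows = {p.label for p in pools if "-R" in p.label and row_res[p.label]}
        pos_cols = {p.label for p in pools if "-C" in p.label and row_res[p.label]}
        row_members = set().union(
            *(set(p.members) for p in pools if p.label in pos_rows), set()
        )
        col_members = set().union(
            *(set(p.members) for p in pools if p.label in pos_cols), set()
        )
        candidates = sorted(row_members & col_members)
        if len(pos_rows) > 1 and len(pos_cols) > 1:
            retest.extend(candidates)
        else:
            decoded.update(candidates)

    tests = base_tests + len(retest)
    for c in pipettings:
        pipettings[c] += len(retest)  # retests drawn with a single channel
    decoded.update(s for s in retest if statuses.statuses[s])
    return ScreenOutcome(
        tests=tests,
        steps=2 if retest else 1,
        pipettings=pipettings,
        max_pool_size=max_pool,
        decoded_positives=frozenset(decoded),
        ambiguous_retest_count=len(retest),
    )
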