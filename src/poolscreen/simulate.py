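"""Monte-Carlo simulation driver: replicates, summaries, robustness sweeps.

Reproduces the simulation study design used to compare the six strategies:
for each cell (strategy, N, k, k_hat, params) a fixed number of replicates
is generated by placing ``k`` positives uniformly at random, the strategy
is executed under the noiseless assay, and tests / steps / pipettings /
max pool size are recorded.  Per-cell means and standard deviations feed
the comparison tables; robustness sweeps measure the extra tests and steps
incurred when the design estimate k_hat misses the true k.

By default replicates share placements across k_hat values (common random
numbers), so misestimation deltas isolate the design effect from sampling
noise; per-cell resampling is available via ``common_random=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CHANNELS,
    SampleStatusVector,
    ScreenOutcome,
    child_seed,
    place_positives,
)
from .nonadaptive import run_grid2d, run_sudoku
from .splitting import run_gbs, run_halving
from .staged import run_modified_3stage, run_s_stage

__all__ = [
    "STRATEGIES",
    "NEEDS_K_HAT",
    "PRESET_SIZES",
    "ExperimentSpec",
    "OutcomeRecord",
    "SummaryRecord",
    "RobustnessRecord",
    "run_experiment",
    "outcomes_frame",
    "summarize",
    "summarize_cells",
    "robustness_sweep",
    "min_max_normalize",
    "write_records",
]

#: Paper-preset sample sizes (whole 96-well plates).
PRESET_SIZES = (96, 384, 1536)

STRATEGIES = ("sudoku", "grid2d", "s_stage", "modified3", "halving", "gbs")

#: Strategies whose design depends on the expected number of positives.
NEEDS_K_HAT = ("sudoku", "s_stage", "modified3", "gbs")


@dataclass(frozen=True)
class ExperimentSpec:
    """One simulation experiment: a grid of (k, k_hat) cells for a strategy.

    ``k_hat`` may be an explicit sequence, the string ``"match_k"`` (design
    each cell for the true k, coerced to at least 1), or ``None`` for the
    halving strategy.  ``params`` carries strategy extras: ``weight`` for
    the window design (overriding k_hat + 1), ``grid_dim`` for 2D pooling.
    """

    strategy: str
    n: int
    k_values: tuple[int, ...]
    k_hat: object = "match_k"
    params: dict = field(default_factory=dict)
    replicates: int = 100
    seed: int = 0
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    common_random: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; valid: {', '.join(STRATEGIES)}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.k_values:
            raise ValueError("k range must be non-empty")

    def k_hat_values(self, k: int) -> tuple[int | None, ...]:
        if self.k_hat == "match_k":
            return (max(1, k),)
        if self.k_hat is None:
            return (None,)
        if isinstance(self.k_hat, int):
            return (self.k_hat,)
        return tuple(self.k_hat)


@dataclass(frozen=True)
class OutcomeRecord:
    """One replicate's outcome plus its cell coordinates."""

    strategy: str
    n: int
    k: int
    k_hat: int | None
    params: tuple[tuple[str, object], ...]
    replicate: int
    seed: int
    outcome: ScreenOutcome
    correct: bool

    @property
    def cell(self) -> tuple:
        return (self.strategy, self.n, self.k, self.k_hat, self.params)

    def to_row(self) -> dict[str, object]:
        return self.outcome.to_row(
            strategy=self.strategy,
            N=self.n,
            k=self.k,
            k_hat=self.k_hat,
            replicate=self.replicate,
            seed=self.seed,
            correct=self.correct,
            **dict(self.params),
        )


def _execute(
    strategy: str,
    statuses: SampleStatusVector,
    k_hat: int | None,
    params: dict,
    channels: Sequence[int],
) -> ScreenOutcome:
    if strategy == "sudoku":
        return run_sudoku(
            statuses, k_hat=k_hat, weight=params.get("weight"), channels=channels
        )
    if strategy == "grid2d":
        return run_grid2d(statuses, d=params["grid_dim"], channels=channels)
    if strategy == "s_stage":
        return run_s_stage(statuses, k_hat, channels=channels)
    if strategy == "modified3":
        return run_modified_3stage(statuses, k_hat, channels=channels)
    if strategy == "halving":
        return run_halving(statuses, channels=channels)
    if strategy == "gbs":
        return run_gbs(statuses, k_hat, channels=channels)
    raise ValueError(f"unknown strategy {strategy!r}")


def run_experiment(spec: ExperimentSpec) -> list[OutcomeRecord]:
    """Run every replicate of every (k, k_hat) cell of the spec.

    Deterministic given the root seed.  Each replicate's placement seed is
    derived from (root, N, k, replicate) — independent of k_hat and
    strategy when ``common_random`` is set, so matched cells share
    placements.  Every outcome is hard-checked to decode exactly the true
    positive set.
    """
    records: list[OutcomeRecord] = []
    params_key = tuple(sorted(spec.params.items()))
    for k in spec.k_values:
        for k_hat in spec.k_hat_values(k):
            for rep in range(spec.replicates):
                if spec.common_random:
                    seed = child_seed(spec.seed, spec.n, k, rep)
                else:
                    seed = child_seed(
                        spec.seed, spec.n, k, rep, 0 if k_hat is None else k_hat
                    )
                statuses = place_positives(spec.n, k, seed)
                outcome = _execute(
                    spec.strategy, statuses, k_hat, spec.params, spec.channels
                )
                if outcome.decoded_positives != statuses.positives:
                    raise AssertionError(
                        f"{spec.strategy} failed to decode the true positives "
                        f"(N={spec.n}, k={k}, k_hat={k_hat}, replicate={rep})"
                    )
                records.append(
                    OutcomeRecord(
                        spec.strategy, spec.n, k, k_hat, params_key, rep, seed,
                        outcome, True,
                    )
                )
    return records


def outcomes_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


@dataclass(frozen=True)
class SummaryRecord:
    """Per-cell summary statistics over replicates."""

    strategy: str
    n: int
    k: int
    k_hat: int | None
    params: tuple[tuple[str, object], ...]
    replicates: int
    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    fraction_ambiguous: float

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "strategy": self.strategy,
            "N": self.n,
            "k": self.k,
            "k_hat": self.k_hat,
            "replicates": self.replicates,
            "fraction_ambiguous": self.fraction_ambiguous,
            **dict(self.params),
        }
        for stat, values in (
            ("mean", self.mean), ("sd", self.sd), ("min", self.min), ("max", self.max)
        ):
            for metric, v in values.items():
                row[f"{metric}_{stat}"] = v
        return row


def summarize(records: Sequence[OutcomeRecord]) -> SummaryRecord:
    """Aggregate one cell's replicates (means, SDs, min/max, ambiguity share)."""
    if not records:
        raise ValueError("cannot summarize an empty set of outcomes")
    cells = {r.cell for r in records}
    if len(cells) > 1:
        raise ValueError(f"mixed cells in summarize input: {sorted(map(str, cells))}")
    metrics: dict[str, list[float]] = {"tests": [], "steps": [], "max_pool": []}
    for c in records[0].outcome.pipettings:
        metrics[f"pipettings_c{c}"] = []
    ambiguous = 0
    for r in records:
        metrics["tests"].append(r.outcome.tests)
        metrics["steps"].append(r.outcome.steps)
        metrics["max_pool"].append(r.outcome.max_pool_size)
        for c, p in r.outcome.pipettings.items():
            metrics[f"pipettings_c{c}"].append(p)
        ambiguous += r.outcome.ambiguous_retest_count > 0
    mean = {m: float(np.mean(v)) for m, v in metrics.items()}
    sd = {
        m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        for m, v in metrics.items()
    }
    lo = {m: float(np.min(v)) for m, v in metrics.items()}
    hi = {m: float(np.max(v)) for m, v in metrics.items()}
    first = records[0]
    return SummaryRecord(
        first.strategy, first.n, first.k, first.k_hat, first.params,
        len(records), mean, sd, lo, hi, ambiguous / len(records),
    )


def summarize_cells(records: Iterable[OutcomeRecord]) -> list[SummaryRecord]:
    """Group records by cell and summarize each (in first-seen order)."""
    by_cell: dict[tuple, list[OutcomeRecord]] = {}
    for r in records:
        by_cell.setdefault(r.cell, []).append(r)
    return [summarize(cell) for cell in by_cell.values()]


@dataclass(frozen=True)
class RobustnessRecord:
    """Extra tests/steps when the design assumes k_hat but k is true."""

    strategy: str
    n: int
    k_true: int
    k_hat: int
    delta_tests: float
    delta_steps: float

    def to_row(self) -> dict[str, object]:
        return {
            "strategy": self.strategy,
            "N": self.n,
            "k_true": self.k_true,
            "k_hat": self.k_hat,
            "delta_tests": self.delta_tests,
            "delta_steps": self.delta_steps,
        }


def robustness_sweep(
    strategy: str,
    n: int,
    k_values: Sequence[int],
    k_hat_values: Sequence[int],
    replicates: int = 100,
    seed: int = 0,
    params: dict | None = None,
    common_random: bool = True,
) -> list[RobustnessRecord]:
    """Mean test/step deltas of each (k, k_hat) cell vs the k_hat = k baseline.

    With common random numbers (the default) baseline and misestimated
    cells share placements, so the deltas are exactly zero at k_hat == k
    and Halving's deltas are identically zero.
    """
    params = params or {}
    out: list[RobustnessRecord] = []
    for k in k_values:
        baseline_hats = [max(1, k)]
        hats = sorted(set(k_hat_values) | set(baseline_hats))
        spec = ExperimentSpec(
            strategy, n, (k,),
            k_hat=tuple(hats) if strategy in NEEDS_K_HAT else None,
            params=params, replicates=replicates, seed=seed,
            common_random=common_random,
        )
        records = run_experiment(spec)
        means: dict[int | None, tuple[float, float]] = {}
        for summary in summarize_cells(records):
            means[summary.k_hat] = (summary.mean["tests"], summary.mean["steps"])
        base = means[baseline_hats[0]] if strategy in NEEDS_K_HAT else means[None]
        for k_hat in k_hat_values:
            cur = means[k_hat] if strategy in NEEDS_K_HAT else base
            out.append(
                RobustnessRecord(
                    strategy, n, k, k_hat,
                    cur[0] - base[0], cur[1] - base[1],
                )
            )
    return out


def min_max_normalize(
    table: pd.DataFrame, features: Sequence[str]
) -> pd.DataFrame:
    """Min-max normalise each feature column across strategies.

    The best strategy per feature maps to 0 and the worst to 1; a constant
    (degenerate) feature maps to 0 everywhere.
    """
    if len(table) < 2:
        raise ValueError("normalization needs at least two strategies")
    out = table.copy()
    for col in features:
        lo, hi = table[col].min(), table[col].max()
        if hi == lo:
            out[col] = 0.0
        else:
            out[col] = (table[col] - lo) / (hi - lo)
    return out


def write_records(
    records: Sequence[OutcomeRecord],
    out_dir: str | Path,
    fmt: str = "csv",
    stem: str = "outcomes",
) -> Path:
    """Write per-replicate rows (and a summary) as CSV or JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = outcomes_frame(records)
    summaries = pd.DataFrame([s.to_row() for s in summarize_cells(records)])
    if fmt == "csv":
        path = out_dir / f"{stem}.csv"
        frame.to_csv(path, index=False)
        summaries.to_csv(out_dir / "summary.csv", index=False)
    elif fmt == "json":
        path = out_dir / f"{stem}.json"
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
        (out_dir / "summary.json").write_text(
            json.dumps(summaries.to_dict(orient="records"), indent=1)
        )
    else:
        raise ValueError("format must be 'csv' or 'json'")
    return path
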