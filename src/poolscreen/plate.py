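"""96-well plate semantics and bench protocols for the Modified 3-Stage screen.

Samples are addressed column-major within a plate (A1, B1, ..., H1, A2,
..., H12), plates sequential, so linear index = plate*96 + (column-1)*8 +
row-offset.  Under this convention the stage-1 pools of the Modified
3-Stage design for k_hat = 2 are exactly the six column pairs (16 wells
each, two draws with an 8-channel pipette), and stage-2 subgroups are
contiguous half-columns of 4 wells — the layout used in the wet-lab
validation of the method, where ten spiked wells across eight plates were
recovered exactly.

A :class:`ProtocolSession` drives an interactive screen: it emits
stage-by-stage pipetting instructions and consumes the observed per-pool
positive/negative results until the positive wells are decoded.  Sessions
are pure given the observed results, hence resumable and replayable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import Pool, SampleStatusVector, pipettings_for_pool
from .staged import StagePlan, form_stage_pools, run_modified_3stage

__all__ = [
    "PlateCoordinate",
    "index_to_well",
    "well_to_index",
    "ProtocolInstruction",
    "ProtocolSession",
    "generate_protocol",
    "replay_validation",
    "VALIDATION_SPIKE_MAP",
]

_ROWS = "ABCDEFGH"
_PLATE_SIZE = 96

#: Spike-in layout of the wet-lab validation experiment: eight 96-well
#: plates of cow-milk microbiome background, ten wells spiked with
#: C. burnetii DNA (~1.3% carriage), screened with the Modified 3-Stage
#: protocol designed for k_hat = 2.
VALIDATION_SPIKE_MAP: dict[int, tuple[str, ...]] = {
    1: ("F1", "A4", "G9"),
    2: ("H2",),
    3: ("D9",),
    4: ("E11",),
    5: (),
    6: ("F3", "A10", "C10"),
    7: (),
    8: ("D4",),
}


@dataclass(frozen=True)
class PlateCoordinate:
    """A well address: 0-based plate ordinal, row letter A-H, column 1-12."""

    plate: int
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _ROWS:
            raise ValueError(f"row must be one of {_ROWS}")
        if not 1 <= self.column <= 12:
            raise ValueError("column must be in 1..12")
        if self.plate < 0:
            raise ValueError("plate ordinal must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"


def index_to_well(index: int) -> PlateCoordinate:
    """Map a linear sample index to its well, column-major within a plate."""
    if index < 0:
        raise ValueError("index must be >= 0")
    plate, within = divmod(index, _PLATE_SIZE)
    column, row_offset = divmod(within, 8)
    return PlateCoordinate(plate, _ROWS[row_offset], column + 1)


def well_to_index(well: str | PlateCoordinate, plate: int = 0) -> int:
    """Inverse of :func:`index_to_well`; accepts "F1"-style labels."""
    if isinstance(well, PlateCoordinate):
        coord = well
    else:
        label = well.strip().upper()
        if len(label) < 2 or label[0] not in _ROWS or not label[1:].isdigit():
            raise ValueError(f"malformed well label: {well!r}")
        coord = PlateCoordinate(plate, label[0], int(label[1:]))
    return coord.plate * _PLATE_SIZE + (coord.column - 1) * 8 + _ROWS.index(coord.row)


@dataclass(frozen=True)
class ProtocolInstruction:
    """One pooling action: draw the source wells into a destination well."""

    stage: int
    pool_label: str
    source_wells: tuple[str, ...]
    destination: str
    channels: int  # recommended pipette

    def __post_init__(self) -> None:
        if len(set(self.source_wells)) != len(self.source_wells):
            raise ValueError("source wells must be distinct")

    def text(self) -> str:
        pipette = f"{self.channels}-channel" if self.channels > 1 else "single-channel"
        return (
            f"Stage {self.stage} / pool {self.pool_label}: combine "
            f"{', '.join(self.source_wells)} into {self.destination} ({pipette})"
        )


def _recommend_channels(pool: Pool) -> int:
    # full column segments (aligned runs of >= 8 wells) suit an 8-channel
    start = pool.members[0] % _PLATE_SIZE
    if pool.size >= 8 and pool.size % 8 == 0 and start % 8 == 0:
        return 8
    return 1


class ProtocolSession:
    """Interactive Modified 3-Stage screen of one 96-well plate.

    Create a session, hand out :meth:`instructions`, run the bench work,
    then feed the observed per-pool results to :meth:`submit_results` and
    repeat until :attr:`finished`.  Identical observed results always
    yield identical next instructions.
    """

    def __init__(self, k_hat: int, n: int = _PLATE_SIZE, destination_start: int = 0):
        if k_hat < 1:
            raise ValueError("k_hat must be >= 1")
        self.plan = StagePlan.design(n, k_hat, "modified_3stage")
        self.n = n
        self.stage = 1
        self.tests = 0
        self.pipettings_8ch = 0
        self.finished = False
        self.decoded_wells: tuple[str, ...] = ()
        self._destination = destination_start
        self._pending = form_stage_pools(
            list(range(n)), self.plan.stage_pool_sizes[0], stage=1
        )

    def instructions(self) -> list[ProtocolInstruction]:
        """Pipetting instructions for the pools awaiting results."""
        out = []
        for pool in self._pending:
            dest = index_to_well(self._destination + len(out))
            out.append(
                ProtocolInstruction(
                    stage=pool.stage,
                    pool_label=pool.label,
                    source_wells=tuple(
                        index_to_well(m).label for m in pool.members
                    ),
                    destination=f"D{dest.plate}-{dest.label}",
                    channels=_recommend_channels(pool),
                )
            )
        return out

    def pending_labels(self) -> list[str]:
        return [p.label for p in self._pending]

    def submit_results(self, results: Mapping[str, bool]) -> list[ProtocolInstruction]:
        """Consume observed pool results; return next-stage instructions.

        Returns an empty list when the session is finished, at which point
        :attr:`decoded_wells` holds the positive wells.
        """
        if self.finished:
            raise RuntimeError("session already finished")
        unknown = set(results) - set(self.pending_labels())
        if unknown:
            raise KeyError(f"results for unknown pool labels: {sorted(unknown)}")
        missing = set(self.pending_labels()) - set(results)
        if missing:
            raise KeyError(f"missing results for pools: {sorted(missing)}")

        self.tests += len(self._pending)
        self.pipettings_8ch += sum(
            pipettings_for_pool(p.size, 8) for p in self._pending
        )
        self._destination += len(self._pending)
        positive = [p for p in self._pending if results[p.label]]
        if not positive or self.stage == self.plan.s:
            self.finished = True
            self.decoded_wells = tuple(
                index_to_well(m).label for p in positive for m in p.members
            )
            self._pending = []
            return []
        n_next = self.plan.stage_pool_sizes[self.stage]
        self.stage += 1
        self._pending = [
            sub
            for p in positive
            for sub in form_stage_pools(
                p.members, n_next, stage=self.stage, label_prefix=f"{p.label}/S"
            )
        ]
        return self.instructions()

    def state_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "tests": self.tests,
                "pipettings_8ch": self.pipettings_8ch,
                "finished": self.finished,
                "pending": self.pending_labels(),
                "decoded_wells": list(self.decoded_wells),
                "plan": self.plan.to_json_dict(),
            }
        )


def generate_protocol(
    k_hat: int, n: int = _PLATE_SIZE
) -> tuple[ProtocolSession, list[ProtocolInstruction]]:
    """Start a bench protocol; returns the session and stage-1 instructions."""
    session = ProtocolSession(k_hat, n)
    return session, session.instructions()


def replay_validation(
    spike_map: Mapping[int, Sequence[str]] | None = None,
    k_hat: int = 2,
) -> list[dict[str, object]]:
    """Replay a spiked multi-plate screen through the bench protocol.

    Each plate runs its own Modified 3-Stage session with noiseless pool
    results derived from the spike map.  Returns one record per plate with
    the test count, the 8-channel pipetting count (by the ceil(m/8)
    accounting), and the decoded wells, plus a cross-check against the
    index-level simulator.  ``pipettings_printed_divergence`` flags plates
    where an externally reported pipetting tally is known to disagree with
    this arithmetic (see docs).
    """
    spike_map = VALIDATION_SPIKE_MAP if spike_map is None else spike_map
    out = []
    for plate in sorted(spike_map):
        wells = tuple(spike_map[plate])
        positives = sorted(well_to_index(w) for w in wells)
        statuses = SampleStatusVector.from_positives(_PLATE_SIZE, positives)
        session = ProtocolSession(k_hat)
        pending = session.instructions()
        while pending and not session.finished:
            results = {}
            for pool_label, pool in zip(session.pending_labels(), session._pending):
                results[pool_label] = any(
                    statuses.statuses[m] for m in pool.members
                )
            session.submit_results(results)
            pending = session.instructions()
        # cross-module consistency with the index-level simulator
        outcome = run_modified_3stage(statuses, k_hat)
        if (outcome.tests, outcome.pipettings[8]) != (
            session.tests, session.pipettings_8ch
        ):
            raise AssertionError("protocol session disagrees with the simulator")
        out.append(
            {
                "plate": plate,
                "k": len(wells),
                "k_hat": k_hat,
                "N": _PLATE_SIZE,
                "positive_wells": wells,
                "tests": session.tests,
                "pipettings_8ch": session.pipettings_8ch,
                "decoded_wells": tuple(sorted(session.decoded_wells)),
                "recovered": tuple(sorted(session.decoded_wells))
                == tuple(sorted(wells)),
            }
        )
    return out
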