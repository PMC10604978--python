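"""Block-design experimental paradigms.

A paradigm is an ordered, gap-free tiling of the run by labelled blocks
(``rest`` interleaved with task conditions such as ``MIL``/``MIR``), all
onsets and durations being integer multiples of the repetition time (TR).
Paradigms round-trip through BIDS-style events tables (onset / duration /
trial_type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical label of the resting condition.
REST = "rest"


@dataclass(frozen=True)
class Block:
    """One constant-condition span of the run."""

    label: str
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Paradigm:
    """A block design sampled once per TR.

    Parameters
    ----------
    tr_seconds
        Volume acquisition time (s).
    blocks
        Non-overlapping blocks sorted by onset, jointly covering
        ``[0, total_duration_s)``. Onsets/durations must be integer
        multiples of ``tr_seconds``.
    total_duration_s
        Span covered by the blocks.
    """

    tr_seconds: float
    blocks: list[Block] = field(default_factory=list)
    total_duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.blocks:
            raise ValueError("paradigm needs at least one block")
        cursor = 0.0
        for b in self.blocks:
            if b.duration_s <= 0:
                raise ValueError(f"block {b.label!r} has non-positive duration")
            for value, what in ((b.onset_s, "onset"), (b.duration_s, "duration")):
                if not _is_multiple(value, self.tr_seconds):
                    raise ValueError(
                        f"block {b.label!r}: {what} {value} s is not an integer "
                        f"multiple of TR {self.tr_seconds} s"
                    )
            if not np.isclose(b.onset_s, cursor):
                raise ValueError(
                    f"blocks must tile the run: expected onset {cursor}, got {b.onset_s}"
                )
            cursor = b.end_s
        if not np.isclose(cursor, self.total_duration_s):
            raise ValueError(
                f"total_duration_s {self.total_duration_s} != covered span {cursor}"
            )

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration_s / self.tr_seconds))

    def condition_labels(self) -> np.ndarray:
        """Per-volume condition label (length ``n_volumes``)."""
        labels = np.empty(self.n_volumes, dtype=object)
        for b in self.blocks:
            i0 = int(round(b.onset_s / self.tr_seconds))
            i1 = int(round(b.end_s / self.tr_seconds))
            labels[i0:i1] = b.label
        return labels.astype(str)

    def task_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.label != REST]

    def volumes_per_task_block(self) -> int:
        """Number of volumes in each task block; raises if blocks are ragged."""
        counts = {int(round(b.duration_s / self.tr_seconds)) for b in self.task_blocks()}
        if len(counts) != 1:
            raise ValueError(f"task blocks have unequal volume counts: {sorted(counts)}")
        return counts.pop()

    # ---------------------------------------------------------------- I/O
    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in self.blocks],
                "duration": [b.duration_s for b in self.blocks],
                "trial_type": [b.label for b in self.blocks],
            }
        )

    def to_events_tsv(self, path: str | Path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events(cls, events: pd.DataFrame, tr_seconds: float) -> "Paradigm":
        ev = events.sort_values("onset")
        blocks = [
            Block(str(r.trial_type), float(r.onset), float(r.duration))
            for r in ev.itertuples()
        ]
        # fill any gaps with rest so every instant carries a label
        filled: list[Block] = []
        cursor = 0.0
        for b in blocks:
            if b.onset_s > cursor + 1e-9:
                filled.append(Block(REST, cursor, b.onset_s - cursor))
            filled.append(b)
            cursor = b.end_s
        return cls(tr_seconds=tr_seconds, blocks=filled, total_duration_s=cursor)

    @classmethod
    def from_events_tsv(cls, path: str | Path, tr_seconds: float) -> "Paradigm":
        return cls.from_events(pd.read_csv(path, sep="\t"), tr_seconds)


def _is_multiple(value: float, tr: float) -> bool:
    ratio = value / tr
    return abs(ratio - round(ratio)) < 1e-9


def generate_paradigm(
    tr_seconds: float,
    block_duration_s: float,
    rest_duration_s: float,
    conditions: Sequence[str],
    n_blocks: int,
    seed: int = 0,
) -> Paradigm:
    """Generate a randomized block design: initial rest, then task/rest pairs.

    The condition order is a seeded shuffle of a balanced deck (each condition
    repeated ``ceil(n_blocks / n_conditions)`` times, truncated), so designs
    whose block count divides evenly are exactly balanced.

    Parameters
    ----------
    tr_seconds, block_duration_s, rest_duration_s
        Timing in seconds; both durations must be positive integer multiples
        of the TR.
    conditions
        Task condition labels to draw from (must not contain ``rest``).
    n_blocks
        Number of task blocks (>= 1).
    seed
        Seed for the condition-order shuffle.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one task condition")
    if REST in conditions:
        raise ValueError("'rest' is implicit and may not be a task condition")
    for value, name in (
        (block_duration_s, "block_duration_s"),
        (rest_duration_s, "rest_duration_s"),
    ):
        if value <= 0 or not _is_multiple(value, tr_seconds):
            raise ValueError(
                f"{name}={value} must be a positive integer multiple of TR {tr_seconds}"
            )

    rng = np.random.default_rng(seed)
    reps = -(-n_blocks // len(conditions))  # ceil
    deck = np.array(conditions * reps)[:n_blocks]
    rng.shuffle(deck)

    blocks = [Block(REST, 0.0, rest_duration_s)]
    cursor = rest_duration_s
    for label in deck:
        blocks.append(Block(str(label), cursor, block_duration_s))
        cursor += block_duration_s
        blocks.append(Block(REST, cursor, rest_duration_s))
        cursor += rest_duration_s
    return Paradigm(tr_seconds=tr_seconds, blocks=blocks, total_duration_s=cursor)
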