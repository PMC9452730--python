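"""Block-design paradigm: condition schedule and per-volume labels.

The default protocol is a 7-minute run at TR = 2 s: 20 s of rest followed by
four repetitions of (40 s happy autobiographical imagery, 40 s motor imagery,
20 s rest), i.e. 420 s = 210 volumes, with 80 volumes per task condition and
50 rest volumes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Condition(str, enum.Enum):
    """Task condition shown to the participant ('+', 'H' or 'M' cue)."""

    REST = "REST"
    HAPPY = "HAPPY"
    MOTOR = "MOTOR"


@dataclass(frozen=True)
class Block:
    condition: Condition
    onset_seconds: float
    duration_seconds: float

    @property
    def end_seconds(self) -> float:
        return self.onset_seconds + self.duration_seconds


#: (condition, duration s) sequence of the default 7-minute protocol.
DEFAULT_SCHEME: tuple[tuple[Condition, float], ...] = (
    (Condition.REST, 20.0),
) + 4 * (
    (Condition.HAPPY, 40.0),
    (Condition.MOTOR, 40.0),
    (Condition.REST, 20.0),
)

DEFAULT_TR_SECONDS = 2.0


@dataclass(frozen=True)
class Paradigm:
    """A timed block schedule plus the volume grid it induces.

    Blocks are contiguous, start at 0 and tile the run exactly; every block
    duration is a positive multiple of the TR so each volume belongs to
    exactly one block.
    """

    tr_seconds: float
    blocks: tuple[Block, ...]
    n_volumes: int

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        t = 0.0
        for b in self.blocks:
            if not math.isclose(b.onset_seconds, t, abs_tol=1e-9):
                raise ValueError(
                    f"blocks must be contiguous from 0; block at {b.onset_seconds}"
                    f" s does not follow previous end {t} s"
                )
            t = b.end_seconds
        if not math.isclose(t, self.n_volumes * self.tr_seconds, abs_tol=1e-9):
            raise ValueError(
                f"total block duration {t} s != n_volumes * TR "
                f"({self.n_volumes} * {self.tr_seconds} s)"
            )

    @property
    def total_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    def volume_labels(self) -> list[Condition]:
        """Condition of each volume; volume v spans [v*TR, (v+1)*TR)."""
        labels: list[Condition] = []
        for b in self.blocks:
            n = round(b.duration_seconds / self.tr_seconds)
            labels.extend([b.condition] * n)
        assert len(labels) == self.n_volumes
        return labels

    def volume_block_index(self) -> list[int]:
        """Index into ``blocks`` for each volume."""
        idx: list[int] = []
        for i, b in enumerate(self.blocks):
            idx.extend([i] * round(b.duration_seconds / self.tr_seconds))
        return idx

    def label_counts(self) -> dict[Condition, int]:
        counts = {c: 0 for c in Condition}
        for lab in self.volume_labels():
            counts[lab] += 1
        return counts


def build_paradigm(
    tr_seconds: float = DEFAULT_TR_SECONDS,
    scheme: tuple[tuple[Condition, float], ...] = DEFAULT_SCHEME,
) -> Paradigm:
    """Build a :class:`Paradigm` from (condition, duration) pairs.

    Parameters
    ----------
    tr_seconds:
        Volume repetition time, seconds. Must be positive.
    scheme:
        Ordered (condition, duration s) pairs. Each duration must be a
        positive multiple of the TR so the schedule lands on volume
        boundaries.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if not scheme:
        raise ValueError("scheme must contain at least one block")
    blocks: list[Block] = []
    onset = 0.0
    for cond, dur in scheme:
        cond = Condition(cond)
        if dur <= 0:
            raise ValueError(f"block duration must be positive, got {dur}")
        ratio = dur / tr_seconds
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"block duration {dur} s is not a multiple of TR {tr_seconds} s"
            )
        blocks.append(Block(cond, onset, dur))
        onset += dur
    n_volumes = round(onset / tr_seconds)
    return Paradigm(tr_seconds=tr_seconds, blocks=tuple(blocks), n_volumes=n_volumes)
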