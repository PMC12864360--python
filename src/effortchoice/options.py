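"""Task options: three cognitive tasks crossed with two demand levels.

The experiment offers six options — a memory (same–different), a motor, and a
hybrid (memory + motor) task, each at a low- and a high-demand level. Every
unordered pair of distinct options defines one choice pair; with six options
there are 15 pairs, and at six presentations per pair a participant makes
90 binary choices.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

__all__ = [
    "Task",
    "Level",
    "OptionId",
    "ALL_OPTIONS",
    "ALL_PAIRS",
    "canonical_pair",
    "parse_option",
]


class Task(str, enum.Enum):
    MEMORY = "memory"
    MOTOR = "motor"
    HYBRID = "hybrid"


class Level(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


_TASK_ORDER = {Task.MEMORY: 0, Task.MOTOR: 1, Task.HYBRID: 2}
_LEVEL_ORDER = {Level.LOW: 0, Level.HIGH: 1}


@dataclass(frozen=True, order=False)
class OptionId:
    """One of the six task options, identified by (task, demand level)."""

    task: Task
    level: Level

    @property
    def key(self) -> str:
        """Stable serialization key, e.g. ``memory_low``."""
        return f"{self.task.value}_{self.level.value}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key

    @property
    def sort_index(self) -> int:
        return _TASK_ORDER[self.task] * 2 + _LEVEL_ORDER[self.level]

    def __lt__(self, other: "OptionId") -> bool:
        return self.sort_index < other.sort_index


#: The six options in canonical order (memory, motor, hybrid) x (low, high).
ALL_OPTIONS: tuple[OptionId, ...] = tuple(
    OptionId(task, level) for task in Task for level in Level
)

#: The 15 unordered option pairs, each in canonical (sorted) orientation.
ALL_PAIRS: tuple[tuple[OptionId, OptionId], ...] = tuple(
    itertools.combinations(ALL_OPTIONS, 2)
)


def canonical_pair(a: OptionId, b: OptionId) -> tuple[OptionId, OptionId]:
    """Return the unordered pair {a, b} in canonical orientation."""
    if a == b:
        raise ValueError(f"a pair requires two distinct options, got {a} twice")
    return (a, b) if a < b else (b, a)


def parse_option(key: str) -> OptionId:
    """Parse a ``task_level`` key (e.g. ``"hybrid_high"``) into an OptionId."""
    try:
        task_s, level_s = key.rsplit("_", 1)
        return OptionId(Task(task_s), Level(level_s))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unknown option id {key!r}") from exc
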