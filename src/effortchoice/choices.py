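"""Pairwise binary choice data: counts per unordered option pair."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .options import ALL_PAIRS, OptionId, canonical_pair

__all__ = ["PairwiseChoiceData"]


@dataclass(frozen=True)
class PairwiseChoiceData:
    """Choice counts for one participant over the 15 option pairs.

    ``counts`` maps each canonical pair ``(a, b)`` (with ``a < b`` in the
    canonical option order) to ``(n, k)``: the pair was presented ``n`` times
    and ``a`` was chosen ``k`` of those times. The experiment presents every
    pair six times, for 90 choices in total.
    """

    participant: str
    counts: dict[tuple[OptionId, OptionId], tuple[int, int]]

    def __post_init__(self):
        missing = [p for p in ALL_PAIRS if p not in self.counts]
        if missing:
            raise ValidationError(
                "incomplete choice data: missing pair(s) "
                + ", ".join(f"{a}/{b}" for a, b in missing)
            )
        for (a, b), (n, k) in self.counts.items():
            if canonical_pair(a, b) != (a, b):
                raise ValidationError(f"pair {a}/{b} not in canonical orientation")
            if n < 0 or not 0 <= k <= n:
                raise ValidationError(f"pair {a}/{b}: invalid counts k={k}, n={n}")

    @property
    def n_choices(self) -> int:
        """Total number of choice trials across all pairs."""
        return sum(n for n, _ in self.counts.values())

    def wins(self, winner: OptionId, loser: OptionId) -> tuple[int, int]:
        """Return (k, n): times ``winner`` was chosen over ``loser``."""
        a, b = canonical_pair(winner, loser)
        n, k = self.counts[(a, b)]
        return (k, n) if winner == a else (n - k, n)
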