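"""Winning- and usage-rate statistics built on rally state sequences.

Six rate families describe how effective the first offensive shot (FOS)
and its follow-up window are, stratified by the FOS category (the shot
number on which the FOS occurred: 2, 3, or >= 4):

- *direct winning rate of FOS#i*: rallies where the FOS itself scored,
  over rallies containing a category-i FOS;
- *overall winning rate of FOS#i*: rallies the FOS player wins inside the
  four-shot window FOS..FOS+3, over rallies containing a category-i FOS;
- *usage rate of FOS#i*: category-i rallies over the whole rally sample;
- *direct winning / usage rate of each window state* (FOS, FOS+1, FOS+2,
  FOS+3) within a category;
- *connection winning rate*: the FOS player's two consecutive attack
  shots (FOS and FOS+2) pooled.

A rally "won inside the window" is credited to the FOS player when the
rally ends there in the FOS player's favour: a direct point from their
own shots (FOS, FOS+2) or an opponent error on the replies (FOS+1,
FOS+3).  A literal reading — only direct points, whoever hit them — is
available behind ``policy="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .model import FOS_STATES, ShotState, StateSequence

FosCategory = Literal["2", "3", "GE4"]

FOS_CATEGORIES: tuple[FosCategory, ...] = ("2", "3", "GE4")

_CATEGORY_STATE: dict[FosCategory, ShotState] = {
    "2": ShotState.FOS2,
    "3": ShotState.FOS3,
    "GE4": ShotState.FOS_GE4,
}

#: Window states by offset from the FOS for a given category.
_WINDOW_OFFSETS: tuple[ShotState, ...] = (
    ShotState.FOS_P1,
    ShotState.FOS_P2,
    ShotState.FOS_P3,
)


@dataclass(frozen=True)
class RateEntry:
    """One rate with its exact integer numerator and denominator.

    ``value`` is None (undefined, never 0) when the denominator is 0.
    """

    scope: str
    category: FosCategory | None
    offset: int | None  # shots after the FOS (0 = the FOS itself)
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None


def _category_rallies(
    sequences: Iterable[StateSequence], category: FosCategory
) -> list[StateSequence]:
    target = _CATEGORY_STATE[category]
    return [s for s in sequences if s.fos_state is target]


def _fos_actor(seq: StateSequence) -> str:
    for shot in seq.shots:
        if shot.state in FOS_STATES:
            return shot.actor
    raise ValueError("rally contains no FOS")


def window_states(category: FosCategory) -> tuple[ShotState, ...]:
    """The four window states FOS..FOS+3 for a category."""
    return (_CATEGORY_STATE[category],) + _WINDOW_OFFSETS


def fos_direct_winning_rate(
    sequences: Sequence[StateSequence], category: FosCategory
) -> RateEntry:
    """Share of category-i rallies whose FOS scored directly (FOS#i -> P)."""
    rallies = _category_rallies(sequences, category)
    fos_state = _CATEGORY_STATE[category]
    wins = sum(
        1 for s in rallies if s.terminal_state is fos_state and s.outcome is ShotState.P
    )
    return RateEntry("fos_direct_win", category, 0, wins, len(rallies))


def fos_overall_winning_rate(
    sequences: Sequence[StateSequence],
    category: FosCategory,
    policy: Literal["fos_player", "literal"] = "fos_player",
) -> RateEntry:
    """Share of category-i rallies won within the FOS..FOS+3 window.

    ``fos_player`` (default): the rally ends in the window and the FOS
    player is the winner (own point on FOS/FOS+2, opponent error on
    FOS+1/FOS+3).  ``literal``: any direct point from a window state.
    """
    rallies = _category_rallies(sequences, category)
    window = window_states(category)
    if policy == "fos_player":
        wins = sum(
            1
            for s in rallies
            if s.terminal_state in window and s.credited_actor == _fos_actor(s)
        )
    else:
        wins = sum(
            1
            for s in rallies
            if s.terminal_state in window and s.outcome is ShotState.P
        )
    return RateEntry("fos_overall_win", category, None, wins, len(rallies))


def fos_usage_rate(
    sequences: Sequence[StateSequence],
    category: FosCategory,
    total_rallies: int | None = None,
) -> RateEntry:
    """Category-i rallies over the whole rally sample."""
    total = len(sequences) if total_rallies is None else total_rallies
    n = len(_category_rallies(sequences, category))
    if n > total:
        raise ValueError(f"total_rallies = {total} below category count {n}")
    return RateEntry("fos_usage", category, 0, n, total)


def state_rates(
    sequences: Sequence[StateSequence],
    offset: int,
    category: FosCategory,
    total_rallies: int | None = None,
) -> tuple[RateEntry, RateEntry]:
    """Direct winning rate and usage rate of the window state FOS+offset.

    ``offset`` 0 is the FOS itself, 1..3 the following shots.  Both rates
    are stratified by the FOS category; occurrences count category-i
    rallies that reach the state, usage divides by the full sample.
    """
    if offset not in (0, 1, 2, 3):
        raise ValueError(f"offset must be 0..3, got {offset}")
    total = len(sequences) if total_rallies is None else total_rallies
    rallies = _category_rallies(sequences, category)
    state = window_states(category)[offset]
    occurrences = sum(1 for s in rallies if any(sh.state is state for sh in s.shots))
    wins = sum(
        1 for s in rallies if s.terminal_state is state and s.outcome is ShotState.P
    )
    return (
        RateEntry("state_direct_win", category, offset, wins, occurrences),
        RateEntry("state_usage", category, offset, occurrences, total),
    )


def connection_winning_rate(
    sequences: Sequence[StateSequence], category: FosCategory
) -> RateEntry:
    """Pooled direct winning rate of the FOS player's two attack shots.

    Numerator: direct points from FOS#i or FOS+2 (category-i rallies);
    denominator: total occurrences of the two states.
    """
    rallies = _category_rallies(sequences, category)
    fos_state = _CATEGORY_STATE[category]
    attack = (fos_state, ShotState.FOS_P2)
    occurrences = sum(
        sum(1 for sh in s.shots if sh.state in attack) for s in rallies
    )
    wins = sum(
        1 for s in rallies if s.terminal_state in attack and s.outcome is ShotState.P
    )
    return RateEntry("connection_win", category, None, wins, occurrences)


def rate_table(
    sequences: Sequence[StateSequence],
    total_rallies: int | None = None,
    policy: Literal["fos_player", "literal"] = "fos_player",
) -> pd.DataFrame:
    """All rate families for all categories as one tidy frame.

    Columns: scope, category, offset, numerator, denominator, value
    (NaN where undefined).
    """
    entries: list[RateEntry] = []
    for cat in FOS_CATEGORIES:
        entries.append(fos_direct_winning_rate(sequences, cat))
        entries.append(fos_overall_winning_rate(sequences, cat, policy=policy))
        entries.append(fos_usage_rate(sequences, cat, total_rallies))
        for offset in (0, 1, 2, 3):
            entries.extend(state_rates(sequences, offset, cat, total_rallies))
        entries.append(connection_winning_rate(sequences, cat))
    return pd.DataFrame(
        {
            "scope": [e.scope for e in entries],
            "category": [e.category for e in entries],
            "offset": [e.offset for e in entries],
            "numerator": [e.numerator for e in entries],
            "denominator": [e.denominator for e in entries],
            "value": [e.value if e.defined else float("nan") for e in entries],
        }
    )
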