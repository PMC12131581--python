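"""Rally state space and deterministic record-to-sequence derivation.

The enhanced first-offensive-shot (EFOS) model describes a table tennis
rally as a walk through a small absorbing state machine.  Every rally
starts with the serve (``SER``); zero or more defensive returns (``DEF``)
may follow until one player plays the first offensive shot (FOS) — the
first shot after the serve without backspin.  The FOS is split by the
shot number on which it occurs (``FOS#2`` attacks the serve, ``FOS#3``
attacks the first defensive return, ``FOS#>=4`` any later shot); the
next three shots are tracked individually (``FOS+1..FOS+3``); everything
later is a generic offensive exchange (``OFF``).  Each shot either keeps
the rally alive, scores directly (``P``) or misses (``E``) — ``P`` and
``E`` are the chain's absorbing outcomes.

A rally is fully determined by six observed criteria (server, rally
length, FOS number, FOS player, winner, gender), so the state sequence
can be derived deterministically from one observation record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable


class ShotState(str, Enum):
    """A shot-level state of the rally chain.

    ``P`` (point) and ``E`` (error) are the only absorbing states.
    """

    SER = "SER"
    DEF = "DEF"
    FOS2 = "FOS#2"
    FOS3 = "FOS#3"
    FOS_GE4 = "FOS#>=4"
    FOS_P1 = "FOS+1"
    FOS_P2 = "FOS+2"
    FOS_P3 = "FOS+3"
    OFF = "OFF"
    P = "P"
    E = "E"

    @property
    def is_absorbing(self) -> bool:
        return self in (ShotState.P, ShotState.E)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Phase(str, Enum):
    """Rally phase: pre-offensive, initial-offensive, final-offensive."""

    POP = "POP"
    IOP = "IOP"
    FOP = "FOP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Non-absorbing states in structural (row) order.
TRANSIENT_STATES: tuple[ShotState, ...] = (
    ShotState.SER,
    ShotState.DEF,
    ShotState.FOS2,
    ShotState.FOS3,
    ShotState.FOS_GE4,
    ShotState.FOS_P1,
    ShotState.FOS_P2,
    ShotState.FOS_P3,
    ShotState.OFF,
)

ABSORBING_STATES: tuple[ShotState, ...] = (ShotState.P, ShotState.E)

#: FOS category states (one-time transient states entered at most once).
FOS_STATES: tuple[ShotState, ...] = (ShotState.FOS2, ShotState.FOS3, ShotState.FOS_GE4)

#: Initial-offensive-phase states.
IOP_STATES: tuple[ShotState, ...] = FOS_STATES + (
    ShotState.FOS_P1,
    ShotState.FOS_P2,
    ShotState.FOS_P3,
)

_PHASE_OF: dict[ShotState, Phase] = {
    ShotState.SER: Phase.POP,
    ShotState.DEF: Phase.POP,
    **{s: Phase.IOP for s in IOP_STATES},
    ShotState.OFF: Phase.FOP,
}

#: Structurally legal transitions (edges of the rally chain).
LEGAL_TRANSITIONS: dict[ShotState, tuple[ShotState, ...]] = {
    ShotState.SER: (ShotState.DEF, ShotState.FOS2, ShotState.P, ShotState.E),
    ShotState.DEF: (
        ShotState.DEF,
        ShotState.FOS3,
        ShotState.FOS_GE4,
        ShotState.P,
        ShotState.E,
    ),
    ShotState.FOS2: (ShotState.FOS_P1, ShotState.P, ShotState.E),
    ShotState.FOS3: (ShotState.FOS_P1, ShotState.P, ShotState.E),
    ShotState.FOS_GE4: (ShotState.FOS_P1, ShotState.P, ShotState.E),
    ShotState.FOS_P1: (ShotState.FOS_P2, ShotState.P, ShotState.E),
    ShotState.FOS_P2: (ShotState.FOS_P3, ShotState.P, ShotState.E),
    ShotState.FOS_P3: (ShotState.OFF, ShotState.P, ShotState.E),
    ShotState.OFF: (ShotState.OFF, ShotState.P, ShotState.E),
}


class RecordValidationError(ValueError):
    """A rally record violates an invariant of the observation instrument.

    ``invariant`` names the violated rule so batch readers can aggregate
    failures per rule.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}")


def phase_of(state: ShotState) -> Phase:
    """Phase of a non-absorbing state.

    Absorbing outcomes have no intrinsic phase — a rally "ends in" the
    phase of the state it was absorbed from — so ``P``/``E`` are rejected.
    """
    if state.is_absorbing:
        raise ValueError(
            f"{state.value} is absorbing; its phase is inherited from the "
            "state absorption occurred from"
        )
    return _PHASE_OF[state]


_OTHER = {"first": "second", "second": "first"}


@dataclass(frozen=True)
class RallyRecord:
    """One scoring rally coded by the six-criteria observation instrument.

    ``server``/``fos_player``/``winner`` use the sides ``first``/``second``
    (order of player entry for the match).  ``fos_number`` is the 1-based
    shot number of the first offensive shot, 0 when the rally never left
    defensive play.  ``ranking_*`` are world-ranking positions and
    ``result_first`` records whether the first-listed player won the
    *match* (a match-level covariate, independent of the rally winner).
    """

    match_id: str
    set_no: int
    rally_no: int
    gender: str  # "M" | "F"
    server: str  # "first" | "second"
    rally_length: int
    fos_number: int
    fos_player: str  # "no" | "first" | "second"
    winner: str  # "first" | "second"
    ranking_first: int = 1
    ranking_second: int = 1
    result_first: str = "W"  # "W" | "L"

    def actor_at(self, position: int) -> str:
        """Side executing shot ``position`` (serves are odd shots)."""
        return self.server if position % 2 == 1 else _OTHER[self.server]


def validate_record(record: RallyRecord) -> RallyRecord:
    """Check every invariant of the observation instrument; return the record.

    Raises :class:`RecordValidationError` naming the first violated
    invariant.
    """
    if record.gender not in ("M", "F"):
        raise RecordValidationError("gender_code", f"gender must be M or F, got {record.gender!r}")
    if record.server not in ("first", "second"):
        raise RecordValidationError("server_code", f"server must be first/second, got {record.server!r}")
    if record.winner not in ("first", "second"):
        raise RecordValidationError("winner_code", f"winner must be first/second, got {record.winner!r}")
    if record.fos_player not in ("no", "first", "second"):
        raise RecordValidationError(
            "fos_player_code", f"fos_player must be no/first/second, got {record.fos_player!r}"
        )
    if record.result_first not in ("W", "L"):
        raise RecordValidationError("result_code", f"result_first must be W or L, got {record.result_first!r}")
    if record.set_no < 1 or record.rally_no < 1:
        raise RecordValidationError("numbering", "set_no and rally_no must be positive")
    if record.rally_length < 1:
        raise RecordValidationError("rally_length", f"rally_length must be >= 1, got {record.rally_length}")
    if record.ranking_first < 1 or record.ranking_second < 1:
        raise RecordValidationError("ranking", "ranking positions must be positive integers")

    if record.fos_number == 0:
        if record.fos_player != "no":
            raise RecordValidationError(
                "fos_consistency",
                "fos_number = 0 (no FOS) is incompatible with fos_player "
                f"= {record.fos_player!r}",
            )
    else:
        if record.fos_player == "no":
            raise RecordValidationError(
                "fos_consistency", f"fos_number = {record.fos_number} requires a fos_player"
            )
        if record.fos_number < 2:
            raise RecordValidationError(
                "fos_number_range",
                f"fos_number must be 0 or >= 2 (the serve cannot be the FOS), got {record.fos_number}",
            )
        if record.fos_number > record.rally_length:
            raise RecordValidationError(
                "fos_number_range",
                f"fos_number = {record.fos_number} exceeds rally_length = {record.rally_length}",
            )
        implied = record.actor_at(record.fos_number)
        if record.fos_player != implied:
            raise RecordValidationError(
                "fos_player_parity",
                f"shot {record.fos_number} is executed by the {implied!r} player "
                f"(server = {record.server!r}), but fos_player = {record.fos_player!r}",
            )
    return record


def state_at_position(position: int, fos_number: int) -> ShotState:
    """State of shot ``position`` in a rally whose FOS occurred at ``fos_number``.

    Total over ``position >= 1`` and ``fos_number in {0} | {2,3,...}``:
    position 1 is the serve; positions before the FOS (all positions > 1
    when there is no FOS) are defensive returns; the FOS position maps to
    its category state; the next three shots are ``FOS+1..FOS+3``; later
    shots are generic offense.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if fos_number == 1 or fos_number < 0:
        raise ValueError(f"fos_number must be 0 or >= 2, got {fos_number}")
    if position == 1:
        return ShotState.SER
    if fos_number == 0 or position < fos_number:
        return ShotState.DEF
    if position == fos_number:
        if fos_number == 2:
            return ShotState.FOS2
        if fos_number == 3:
            return ShotState.FOS3
        return ShotState.FOS_GE4
    offset = position - fos_number
    if offset == 1:
        return ShotState.FOS_P1
    if offset == 2:
        return ShotState.FOS_P2
    if offset == 3:
        return ShotState.FOS_P3
    return ShotState.OFF


@dataclass(frozen=True)
class Shot:
    position: int  # 1-based
    actor: str  # "first" | "second"
    state: ShotState


@dataclass(frozen=True)
class StateSequence:
    """Ordered shot states of one rally plus its absorbing outcome.

    ``outcome`` is ``P`` when the final shot's actor won the rally (the
    shot scored directly) and ``E`` otherwise (the final recorded shot
    was the losing attempt).  ``credited_actor`` is the rally winner in
    both cases; ``terminal_state`` is the non-absorbing state absorption
    occurred from.
    """

    shots: tuple[Shot, ...]
    outcome: ShotState  # P | E
    credited_actor: str  # rally winner

    @property
    def terminal_state(self) -> ShotState:
        return self.shots[-1].state

    @property
    def ending_phase(self) -> Phase:
        return phase_of(self.terminal_state)

    @property
    def fos_state(self) -> ShotState | None:
        """The FOS category state of this rally, or None for FOS-free rallies."""
        for shot in self.shots:
            if shot.state in FOS_STATES:
                return shot.state
        return None

    def transitions(self) -> Iterable[tuple[ShotState, ShotState, str]]:
        """Yield (from_state, to_state, origin_actor) for every step,
        including the final step into the absorbing outcome."""
        for a, b in zip(self.shots, self.shots[1:]):
            yield a.state, b.state, a.actor
        last = self.shots[-1]
        yield last.state, self.outcome, last.actor


def derive_state_sequence(record: RallyRecord) -> StateSequence:
    """Derive the full state sequence of a validated rally record.

    Shots ``1..rally_length`` get states from :func:`state_at_position`
    with parity actors; the absorbing outcome is ``P`` when the last
    shot's actor is the rally winner, else ``E``.
    """
    validate_record(record)
    shots = tuple(
        Shot(position=k, actor=record.actor_at(k), state=state_at_position(k, record.fos_number))
        for k in range(1, record.rally_length + 1)
    )
    last_actor = shots[-1].actor
    outcome = ShotState.P if last_actor == record.winner else ShotState.E
    return StateSequence(shots=shots, outcome=outcome, credited_actor=record.winner)
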