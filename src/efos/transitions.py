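"""Transition counting and probability estimation for rally chains.

A transition matrix row is the empirical distribution of what happens to
a shot in a given state: P(X -> Y) = (transitions X -> Y) / (shots
originating from X).  Matrices can be built per player-side (for group
comparisons), per match, or pooled, and averaged unweighted across
units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ABSORBING_STATES,
    LEGAL_TRANSITIONS,
    TRANSIENT_STATES,
    RallyRecord,
    ShotState,
    StateSequence,
    derive_state_sequence,
)

#: Column order of a wide matrix: possible destination states.
DEST_STATES: tuple[ShotState, ...] = TRANSIENT_STATES[1:] + ABSORBING_STATES

ROW_LABELS = [s.value for s in TRANSIENT_STATES]
COL_LABELS = [s.value for s in DEST_STATES]

#: Boolean mask of structurally legal cells, rows x cols.
STRUCTURAL_MASK = pd.DataFrame(
    [[dest in LEGAL_TRANSITIONS[src] for dest in DEST_STATES] for src in TRANSIENT_STATES],
    index=ROW_LABELS,
    columns=COL_LABELS,
)


def _empty_frame(dtype=float) -> pd.DataFrame:
    return pd.DataFrame(0, index=ROW_LABELS, columns=COL_LABELS, dtype=dtype)


class IllegalTransitionError(ValueError):
    """A state pair outside the rally chain's structural edges was seen.

    Cannot arise from sequences produced by ``derive_state_sequence``;
    guards corrupted external input.
    """


@dataclass
class TransitionCounts:
    """Integer transition tallies for one unit (player-side, match, pool)."""

    unit_id: str
    counts: pd.DataFrame  # rows TRANSIENT_STATES, cols DEST_STATES, int

    @property
    def origin_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(
            unit_id=f"{self.unit_id}+{other.unit_id}", counts=self.counts + other.counts
        )


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities with their denominators.

    Rows whose ``origin_totals`` entry is 0 are *undefined* and hold NaN
    (never silently zero).  ``provenance`` records how the matrix was
    obtained: an empirical unit, an unweighted average of units, or a
    packaged fixture.  For averaged matrices ``origin_totals`` holds the
    per-row count of contributing units.
    """

    probs: pd.DataFrame  # rows TRANSIENT_STATES, cols DEST_STATES, float, NaN = undefined
    origin_totals: pd.Series
    provenance: Literal["empirical_unit", "averaged", "fixture"] = "empirical_unit"

    def defined_rows(self) -> list[str]:
        return [r for r in ROW_LABELS if self.origin_totals.loc[r] > 0]

    def row(self, state: ShotState | str) -> pd.Series:
        key = state.value if isinstance(state, ShotState) else state
        return self.probs.loc[key]

    def cell(self, src: ShotState | str, dst: ShotState | str) -> float:
        s = src.value if isinstance(src, ShotState) else src
        d = dst.value if isinstance(dst, ShotState) else dst
        return float(self.probs.loc[s, d])

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.probs.copy(), self.origin_totals.copy(), self.provenance)


def count_transitions(
    sequences: Iterable[StateSequence],
    unit_id: str = "pooled",
    actor: str | None = None,
) -> TransitionCounts:
    """Tally every consecutive state pair (including the absorbing step).

    With ``actor`` set to ``"first"``/``"second"``, only transitions whose
    origin shot was executed by that side are counted — the attribution
    used for player-side matrices in group comparisons.
    """
    counts = _empty_frame(dtype=int)
    arr = counts.to_numpy()
    row_ix = {s: i for i, s in enumerate(TRANSIENT_STATES)}
    col_ix = {s: j for j, s in enumerate(DEST_STATES)}
    for seq in sequences:
        for src, dst, origin_actor in seq.transitions():
            if actor is not None and origin_actor != actor:
                continue
            if dst not in LEGAL_TRANSITIONS[src]:
                raise IllegalTransitionError(
                    f"structurally illegal transition {src.value} -> {dst.value}"
                )
            arr[row_ix[src], col_ix[dst]] += 1
    counts.iloc[:, :] = arr
    return TransitionCounts(unit_id=unit_id, counts=counts)


def normalize(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalize tallies into probabilities (undefined rows -> NaN)."""
    totals = counts.origin_totals
    probs = counts.counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = probs.div(totals.replace(0, np.nan), axis=0)
    return TransitionMatrix(probs=probs, origin_totals=totals, provenance="empirical_unit")


def average_matrices(matrices: Sequence[TransitionMatrix]) -> TransitionMatrix:
    """Unweighted arithmetic mean of unit matrices, skipping undefined rows.

    Each cell averages over the units whose row is defined; a row defined
    in no unit stays undefined.  ``origin_totals`` of the result holds
    the per-row contributing-unit counts.
    """
    if not matrices:
        raise ValueError("average_matrices requires at least one matrix")
    stack = np.stack([m.probs.to_numpy() for m in matrices])  # units x rows x cols
    defined = np.stack([(m.origin_totals.to_numpy() > 0) for m in matrices])  # units x rows
    support = defined.sum(axis=0)  # rows
    with np.errstate(invalid="ignore"):
        mean = np.where(defined[:, :, None], stack, 0.0).sum(axis=0)
        mean = mean / np.where(support[:, None] > 0, support[:, None], np.nan)
    probs = pd.DataFrame(mean, index=ROW_LABELS, columns=COL_LABELS)
    return TransitionMatrix(
        probs=probs,
        origin_totals=pd.Series(support, index=ROW_LABELS),
        provenance="averaged",
    )


def pool_counts(units: Sequence[TransitionCounts], unit_id: str = "pooled") -> TransitionCounts:
    total = _empty_frame(dtype=int)
    for u in units:
        total += u.counts
    return TransitionCounts(unit_id=unit_id, counts=total)


def match_matrices(records: Sequence[RallyRecord]) -> dict[str, TransitionMatrix]:
    """One matrix per match, pooling both players' shots."""
    by_match: dict[str, list[StateSequence]] = {}
    for rec in records:
        by_match.setdefault(rec.match_id, []).append(derive_state_sequence(rec))
    return {
        mid: normalize(count_transitions(seqs, unit_id=mid))
        for mid, seqs in by_match.items()
    }


def player_side_matrices(
    records: Sequence[RallyRecord],
) -> dict[tuple[str, str], TransitionMatrix]:
    """One matrix per player-side (match, side) under actor attribution."""
    by_match: dict[str, list[StateSequence]] = {}
    for rec in records:
        by_match.setdefault(rec.match_id, []).append(derive_state_sequence(rec))
    out: dict[tuple[str, str], TransitionMatrix] = {}
    for mid, seqs in by_match.items():
        for side in ("first", "second"):
            out[(mid, side)] = normalize(
                count_transitions(seqs, unit_id=f"{mid}:{side}", actor=side)
            )
    return out


def pooled_matrix(records: Sequence[RallyRecord]) -> TransitionMatrix:
    """Single matrix over all rallies of all matches."""
    seqs = (derive_state_sequence(r) for r in records)
    return normalize(count_transitions(seqs, unit_id="pooled"))
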