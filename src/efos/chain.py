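"""Absorbing-chain analytics of a rally transition matrix.

The rally chain is a DAG over the one-time transient states with two
self-looping transient sets (``DEF`` and ``OFF``) and two absorbing
outcomes (``P``, ``E``).  That structure makes absorption quantities
available in closed form by first-step analysis: self-loops contribute
geometric series, and reach probabilities chain multiplicatively down
the structural order

    SER -> (DEF)* -> FOS#i -> FOS+1 -> FOS+2 -> FOS+3 -> (OFF)*

Because the matrix lumps all defensive returns into one ``DEF`` row
while structurally only the *first* defensive return can exit to
``FOS#3`` (and later ones to ``FOS#>=4``), DEF exits are split
proportionally to the lumped row — the same convention the rally
simulator realises exactly (see :mod:`efos.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import FOS_STATES, IOP_STATES, TRANSIENT_STATES, Phase, ShotState
from .transitions import ROW_LABELS, TransitionMatrix


class RowSumError(ValueError):
    """A matrix row's probabilities do not sum to 1 within tolerance."""


class NotAbsorbingError(ValueError):
    """A transient-set self-loop is (numerically) 1: the chain never ends."""


_SELF_LOOP_TOL = 1e-9


def renormalize_rows(matrix: TransitionMatrix, tolerance: float = 0.005) -> TransitionMatrix:
    """Scale each defined row to sum exactly to 1.

    Printed matrices carry 3-significant-figure cells, so rows sum to
    1 +/- ~0.001; ``tolerance`` (absolute, default 0.005) bounds the
    rounding slack accepted before renormalizing.  A row further from 1
    than that indicates corrupted input and raises :class:`RowSumError`.
    """
    out = matrix.copy()
    for row in out.defined_rows():
        s = out.probs.loc[row].sum()
        if abs(s - 1.0) > tolerance:
            raise RowSumError(f"row {row} sums to {s:.6f}, outside 1 +/- {tolerance}")
        out.probs.loc[row] = out.probs.loc[row] / s
    return out


@dataclass(frozen=True)
class AbsorptionProfile:
    """Closed-form absorption quantities of one rally chain.

    ``reach[s]``: probability a rally ever visits state ``s``.
    ``end_share[s]``: probability the rally is absorbed directly from ``s``
    (these sum to 1).  ``phase_share``: probability of ending in each
    phase.  ``fos_containing``: probability the rally contains any first
    offensive shot; ``fos_category_share``: distribution of the FOS
    category among FOS-containing rallies.
    """

    reach: pd.Series  # index: transient state labels
    end_share: pd.Series
    phase_share: pd.Series  # index: POP, IOP, FOP
    fos_containing: float
    fos_category_share: pd.Series  # index: FOS#2, FOS#3, FOS#>=4

    def summary(self) -> pd.DataFrame:
        """One row per transient state: reach, end share, phase."""
        from .model import phase_of

        return pd.DataFrame(
            {
                "reach": self.reach,
                "end_share": self.end_share,
                "phase": [phase_of(s).value for s in TRANSIENT_STATES],
            }
        )


def _require_analysable(matrix: TransitionMatrix) -> None:
    undefined = [r for r in ROW_LABELS if matrix.origin_totals.loc[r] == 0]
    if undefined:
        raise ValueError(
            f"absorption analytics need all nine transient rows defined; missing: {undefined}"
        )
    for looped in (ShotState.DEF, ShotState.OFF):
        if matrix.cell(looped, looped) >= 1.0 - _SELF_LOOP_TOL:
            raise NotAbsorbingError(
                f"self-loop P({looped.value} -> {looped.value}) = "
                f"{matrix.cell(looped, looped)} leaves no absorption mass"
            )


def _reach_probabilities(matrix: TransitionMatrix) -> pd.Series:
    """First-step reach probabilities along the structural order."""
    m = matrix
    reach = pd.Series(0.0, index=ROW_LABELS)
    reach[ShotState.SER.value] = 1.0
    reach[ShotState.DEF.value] = m.cell(ShotState.SER, ShotState.DEF)
    # Exits from the DEF set: geometric series over the self-loop; the
    # lumped exit mass splits proportionally between FOS#3 / FOS#>=4.
    stay = m.cell(ShotState.DEF, ShotState.DEF)
    per_entry = reach[ShotState.DEF.value] / (1.0 - stay)  # expected DEF visits
    reach[ShotState.FOS2.value] = m.cell(ShotState.SER, ShotState.FOS2)
    reach[ShotState.FOS3.value] = per_entry * m.cell(ShotState.DEF, ShotState.FOS3)
    reach[ShotState.FOS_GE4.value] = per_entry * m.cell(ShotState.DEF, ShotState.FOS_GE4)
    reach[ShotState.FOS_P1.value] = sum(
        reach[f.value] * m.cell(f, ShotState.FOS_P1) for f in FOS_STATES
    )
    reach[ShotState.FOS_P2.value] = reach[ShotState.FOS_P1.value] * m.cell(
        ShotState.FOS_P1, ShotState.FOS_P2
    )
    reach[ShotState.FOS_P3.value] = reach[ShotState.FOS_P2.value] * m.cell(
        ShotState.FOS_P2, ShotState.FOS_P3
    )
    reach[ShotState.OFF.value] = reach[ShotState.FOS_P3.value] * m.cell(
        ShotState.FOS_P3, ShotState.OFF
    )
    return reach


def absorption_profile(matrix: TransitionMatrix) -> AbsorptionProfile:
    """Compute reach, ending shares and phase distribution analytically.

    Requires an exactly row-stochastic matrix (apply
    :func:`renormalize_rows` first for printed 3-s.f. matrices) with all
    nine transient rows defined.
    """
    _require_analysable(matrix)
    m = matrix
    reach = _reach_probabilities(m)

    def absorb_mass(state: ShotState) -> float:
        return m.cell(state, ShotState.P) + m.cell(state, ShotState.E)

    end = pd.Series(0.0, index=ROW_LABELS)
    end[ShotState.SER.value] = absorb_mass(ShotState.SER)
    stay = m.cell(ShotState.DEF, ShotState.DEF)
    end[ShotState.DEF.value] = (
        reach[ShotState.DEF.value] * absorb_mass(ShotState.DEF) / (1.0 - stay)
    )
    for s in IOP_STATES:
        end[s.value] = reach[s.value] * absorb_mass(s)
    # Once in OFF the rally is eventually absorbed with probability 1.
    end[ShotState.OFF.value] = reach[ShotState.OFF.value]

    phase = pd.Series(
        {
            Phase.POP.value: end[ShotState.SER.value] + end[ShotState.DEF.value],
            Phase.IOP.value: sum(end[s.value] for s in IOP_STATES),
            Phase.FOP.value: end[ShotState.OFF.value],
        }
    )
    fos_reaches = pd.Series({s.value: reach[s.value] for s in FOS_STATES})
    fos_containing = float(fos_reaches.sum())
    return AbsorptionProfile(
        reach=reach,
        end_share=end,
        phase_share=phase,
        fos_containing=fos_containing,
        fos_category_share=fos_reaches / fos_containing,
    )


def expected_visits(matrix: TransitionMatrix) -> pd.Series:
    """Expected number of visits per rally to each transient state.

    Equals the reach probability for one-time states; for the
    self-looping sets the geometric series gives reach/(1 - self-loop).
    """
    _require_analysable(matrix)
    reach = _reach_probabilities(matrix)
    visits = reach.copy()
    for looped in (ShotState.DEF, ShotState.OFF):
        visits[looped.value] = reach[looped.value] / (1.0 - matrix.cell(looped, looped))
    return visits
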