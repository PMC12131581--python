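"""Synthetic rally generation from a transition matrix.

Simulates rallies as walks through the rally chain so that every
pipeline stage (record validation, sequence derivation, counting,
estimation, group tests) can be exercised without observational data.
Defaults mirror the study conditions the analysis assumes: 105 singles
matches (56 men's / 49 women's), ~95 rallies per match (9,925 total),
alternating service, world rankings drawn so that ~46% of player-sides
fall in the top-40 class, and the packaged averaged transition matrix
as the generating process.

Position-aware defensive play
-----------------------------
The lumped ``DEF`` row of a transition matrix cannot be sampled naively:
structurally only the *first* defensive return (shot 2) can exit to
``FOS#3``, later ones to ``FOS#>=4``.  The default policy therefore uses
two calibrated per-position DEF rows

    first DEF:  exit a = p3 / (1 - d),   continue c1 = T - a
    later DEF:  exit b = p4 / d,         continue c2 = T - b

with ``d, p3, p4`` the lumped self-loop / FOS#3 / FOS#>=4 cells,
``T = d + p3 + p4`` and the lumped point/error cells unchanged.  These
are the unique per-position rows (holding P/E fixed) whose visit-
weighted pool equals the lumped row exactly — so pooled re-estimation
is unbiased — and they realise precisely the proportional DEF-exit
split the closed-form absorption profile assumes.  Explicit per-position
rows can be supplied instead via ``def_split_policy="position_resolved"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .chain import NotAbsorbingError, renormalize_rows
from .model import (
    FOS_STATES,
    RallyRecord,
    Shot,
    ShotState,
    StateSequence,
    validate_record,
)
from .transitions import (
    COL_LABELS,
    ROW_LABELS,
    TransitionMatrix,
    count_transitions,
    normalize,
    pooled_matrix,
)

_SELF_LOOP_TOL = 1e-9

CellShift = tuple[Literal["mul", "add"], float]


@dataclass
class SimulationConfig:
    """Generating process and sampling plan for a synthetic dataset.

    ``base_matrix`` defaults to the packaged averaged matrix
    (renormalized).  ``group_effects`` maps ``(factor, level)`` to cell
    shifts ``{(from, to): ("mul", x) | ("add", x)}``; the shifted row is
    rebalanced by scaling its unshifted cells so it stays a probability
    row.  Only the per-match factor ``gender`` alters the dynamics — the
    chain is shared by both players of a rally, so per-side factors
    (ranking, result) have no well-defined single-chain analogue.
    """

    base_matrix: TransitionMatrix | None = None
    def_split_policy: Literal["lumped_proportional", "position_resolved"] = (
        "lumped_proportional"
    )
    first_def_row: Mapping[str, float] | None = None  # position_resolved only
    later_def_row: Mapping[str, float] | None = None
    group_effects: Mapping[tuple[str, str], Mapping[tuple[str, str], CellShift]] = field(
        default_factory=dict
    )
    n_matches: int = 105
    rallies_per_match: int = 95
    gender_ratio: tuple[int, int] = (56, 49)  # men's : women's matches
    top40_share: float = 0.462  # share of player-sides ranked <= 40
    max_ranking: int = 400
    server_alternation: bool = True
    seed: int = 0


@dataclass
class SimulatedDataset:
    """Records plus the ground-truth event log they were derived from."""

    records: list[RallyRecord]
    event_log: list[StateSequence]
    config: SimulationConfig
    generating_matrix: TransitionMatrix


def _base_matrix(config: SimulationConfig) -> TransitionMatrix:
    if config.base_matrix is not None:
        return renormalize_rows(config.base_matrix, tolerance=0.005)
    from .io import load_reference_matrix

    return renormalize_rows(load_reference_matrix(), tolerance=0.005)


def apply_group_effects(
    matrix: TransitionMatrix,
    effects: Mapping[tuple[str, str], CellShift],
) -> TransitionMatrix:
    """Shift selected cells and rebalance the unshifted cells of each row."""
    out = matrix.copy()
    shifted_rows: dict[str, list[str]] = {}
    for (src, dst), (kind, amount) in effects.items():
        old = out.probs.loc[src, dst]
        new = old * amount if kind == "mul" else old + amount
        if not 0.0 <= new <= 1.0:
            raise ValueError(f"shifted cell P({src} -> {dst}) = {new:.4f} outside [0, 1]")
        out.probs.loc[src, dst] = new
        shifted_rows.setdefault(src, []).append(dst)
    for src, dsts in shifted_rows.items():
        row = out.probs.loc[src]
        fixed = row[dsts].sum()
        rest = row.drop(dsts)
        rest_sum = rest.sum()
        if fixed > 1.0 or (rest_sum == 0 and not np.isclose(fixed, 1.0)):
            raise ValueError(f"row {src} cannot be rebalanced after shifting {dsts}")
        if rest_sum > 0:
            out.probs.loc[src, rest.index] = rest * (1.0 - fixed) / rest_sum
    return out


def _def_rows(config: SimulationConfig, matrix: TransitionMatrix) -> tuple[dict, dict]:
    """Per-position DEF rows: {target label: prob} for first / later visits."""
    if config.def_split_policy == "position_resolved":
        if config.first_def_row is None or config.later_def_row is None:
            raise ValueError("position_resolved policy needs first_def_row and later_def_row")
        return dict(config.first_def_row), dict(config.later_def_row)
    row = matrix.row(ShotState.DEF)
    d = row[ShotState.DEF.value]
    p3 = row[ShotState.FOS3.value]
    p4 = row[ShotState.FOS_GE4.value]
    p_pt, p_err = row[ShotState.P.value], row[ShotState.E.value]
    t = d + p3 + p4
    if d >= 1.0 - _SELF_LOOP_TOL:
        raise NotAbsorbingError("P(DEF -> DEF) leaves no exit mass")
    a = p3 / (1.0 - d)
    if p4 == 0:
        b = 0.0
    elif d == 0:
        raise ValueError(
            "P(DEF -> FOS#>=4) > 0 requires P(DEF -> DEF) > 0: a later defensive "
            "return can only exist after a continued first one"
        )
    else:
        b = p4 / d
    c1, c2 = t - a, t - b
    if min(a, b, c1, c2) < -1e-12:
        raise ValueError(
            "lumped DEF row is infeasible for a position-calibrated split "
            f"(a={a:.4f}, b={b:.4f}, c1={c1:.4f}, c2={c2:.4f}); supply explicit "
            "rows via def_split_policy='position_resolved'"
        )
    first = {
        ShotState.DEF.value: max(c1, 0.0),
        ShotState.FOS3.value: a,
        ShotState.P.value: p_pt,
        ShotState.E.value: p_err,
    }
    later = {
        ShotState.DEF.value: max(c2, 0.0),
        ShotState.FOS_GE4.value: b,
        ShotState.P.value: p_pt,
        ShotState.E.value: p_err,
    }
    return first, later


class _Sampler:
    """Cumulative-probability samplers for every walk context."""

    def __init__(self, config: SimulationConfig, matrix: TransitionMatrix):
        for looped in (ShotState.DEF, ShotState.OFF):
            if matrix.origin_totals.loc[looped.value] > 0 and matrix.cell(
                looped, looped
            ) >= 1.0 - _SELF_LOOP_TOL:
                raise NotAbsorbingError(
                    f"P({looped.value} -> {looped.value}) >= 1 - 1e-9: chain never absorbs"
                )
        first_def, later_def = _def_rows(config, matrix)
        self.contexts: dict[str, tuple[list[ShotState], np.ndarray]] = {}
        for label, row in (("DEF_first", first_def), ("DEF_later", later_def)):
            self._add(label, row)
        for state in (
            ShotState.SER,
            ShotState.FOS2,
            ShotState.FOS3,
            ShotState.FOS_GE4,
            ShotState.FOS_P1,
            ShotState.FOS_P2,
            ShotState.FOS_P3,
            ShotState.OFF,
        ):
            row = matrix.row(state)
            self._add(state.value, {k: v for k, v in row.items() if v > 0})

    def _add(self, label: str, row: Mapping[str, float]) -> None:
        targets = [ShotState(k) for k, v in row.items() if v > 0]
        probs = np.array([row[t.value] for t in targets], dtype=float)
        total = probs.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"sampling row {label} sums to {total:.6f}, expected 1")
        self.contexts[label] = (targets, np.cumsum(probs / total))

    def draw(self, label: str, rng: np.random.Generator) -> ShotState:
        targets, cum = self.contexts[label]
        return targets[int(np.searchsorted(cum, rng.random(), side="right").clip(0, len(targets) - 1))]


def _walk(sampler: _Sampler, rng: np.random.Generator) -> tuple[list[ShotState], ShotState]:
    """One rally: list of shot states plus the absorbing outcome."""
    states = [ShotState.SER]
    nxt = sampler.draw(ShotState.SER.value, rng)
    first_def_pending = True
    while not nxt.is_absorbing:
        states.append(nxt)
        if nxt is ShotState.DEF:
            label = "DEF_first" if first_def_pending else "DEF_later"
            first_def_pending = False
            nxt = sampler.draw(label, rng)
        else:
            nxt = sampler.draw(nxt.value, rng)
    return states, nxt


def _to_sequence(states: list[ShotState], outcome: ShotState, server: str) -> StateSequence:
    other = {"first": "second", "second": "first"}
    shots = tuple(
        Shot(position=k + 1, actor=server if k % 2 == 0 else other[server], state=s)
        for k, s in enumerate(states)
    )
    last_actor = shots[-1].actor
    winner = last_actor if outcome is ShotState.P else other[last_actor]
    return StateSequence(shots=shots, outcome=outcome, credited_actor=winner)


def _to_record(
    seq: StateSequence,
    match_id: str,
    set_no: int,
    rally_no: int,
    gender: str,
    server: str,
    rankings: tuple[int, int],
    result_first: str,
) -> RallyRecord:
    fos_number, fos_player = 0, "no"
    for shot in seq.shots:
        if shot.state in FOS_STATES:
            fos_number, fos_player = shot.position, shot.actor
            break
    return RallyRecord(
        match_id=match_id,
        set_no=set_no,
        rally_no=rally_no,
        gender=gender,
        server=server,
        rally_length=len(seq.shots),
        fos_number=fos_number,
        fos_player=fos_player,
        winner=seq.credited_actor,
        ranking_first=rankings[0],
        ranking_second=rankings[1],
        result_first=result_first,
    )


def simulate_rally(
    config: SimulationConfig,
    rng: np.random.Generator,
    server: str = "first",
) -> tuple[RallyRecord, StateSequence]:
    """Simulate a single rally (standalone record with unit metadata stubs)."""
    matrix = _base_matrix(config)
    sampler = _Sampler(config, matrix)
    states, outcome = _walk(sampler, rng)
    seq = _to_sequence(states, outcome, server)
    record = _to_record(seq, "sim", 1, 1, "M", server, (1, 2), "W")
    validate_record(record)
    return record, seq


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Simulate a full dataset of matches with covariates.

    Gender is assigned per match in the configured ratio; each match
    uses the base matrix with that gender's group effects applied.
    Rankings are drawn per player-side (top-40 with probability
    ``top40_share``); the match result is emergent — the side winning
    more simulated rallies is ``W``, ties broken by extra rallies.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    base = _base_matrix(config)

    n_m = round(config.n_matches * config.gender_ratio[0] / sum(config.gender_ratio))
    genders = ["M"] * n_m + ["F"] * (config.n_matches - n_m)

    samplers: dict[str, _Sampler] = {}
    for g in ("M", "F"):
        effects = config.group_effects.get(("gender", g), {})
        samplers[g] = _Sampler(config, apply_group_effects(base, effects) if effects else base)

    records: list[RallyRecord] = []
    event_log: list[StateSequence] = []
    rallies_per_set = 16
    for m_ix, gender in enumerate(genders):
        match_id = f"m{m_ix + 1:03d}"
        rankings = tuple(
            int(rng.integers(1, 41)) if rng.random() < config.top40_share
            else int(rng.integers(41, config.max_ranking + 1))
            for _ in range(2)
        )
        sampler = samplers[gender]
        match_seqs: list[StateSequence] = []
        match_servers: list[str] = []
        wins = {"first": 0, "second": 0}
        rally_ix = 0
        while rally_ix < config.rallies_per_match or wins["first"] == wins["second"]:
            server = (
                ("first", "second")[rally_ix % 2] if config.server_alternation else "first"
            )
            states, outcome = _walk(sampler, rng)
            seq = _to_sequence(states, outcome, server)
            wins[seq.credited_actor] += 1
            match_seqs.append(seq)
            match_servers.append(server)
            rally_ix += 1
        result_first = "W" if wins["first"] > wins["second"] else "L"
        for r_ix, (seq, server) in enumerate(zip(match_seqs, match_servers)):
            rec = _to_record(
                seq,
                match_id,
                set_no=r_ix // rallies_per_set + 1,
                rally_no=r_ix % rallies_per_set + 1,
                gender=gender,
                server=server,
                rankings=rankings,
                result_first=result_first,
            )
            records.append(validate_record(rec))
            event_log.append(seq)
    return SimulatedDataset(
        records=records, event_log=event_log, config=config, generating_matrix=base
    )


def recover_parameters(dataset: SimulatedDataset) -> tuple[TransitionMatrix, float]:
    """Re-estimate the pooled matrix through the full pipeline.

    Returns the estimate and its maximum absolute deviation from the
    generating matrix over cells whose row is defined in the estimate.
    Meaningful for effect-free configs (with group effects the pool
    mixes two generating matrices).
    """
    estimated = pooled_matrix(dataset.records)
    gen = dataset.generating_matrix.probs
    est = estimated.probs
    max_dev = 0.0
    for row in estimated.defined_rows():
        dev = (est.loc[row] - gen.loc[row]).abs().max()
        max_dev = max(max_dev, float(dev))
    return estimated, max_dev
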