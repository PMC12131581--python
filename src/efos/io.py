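"""CSV readers/writers for rally records and transition matrices.

Record schema (one row per scoring rally, UTF-8, header required)::

    match_id,set_no,rally_no,gender,server,rally_length,fos_number,
    fos_player,winner,ranking_first,ranking_second,result_first

Category codes are matched case-insensitively and normalized.  Matrices
travel either long (unit_id, from_state, to_state, probability,
origin_total) or wide (states x states, percent or probability).

The packaged reference matrix is the published averaged transition
matrix of 105 elite singles matches (9,925 rallies) from the Tokyo 2020
Olympic tournament, stored exactly as printed (percent,
3 significant figures); its rows therefore sum to 99.9-100.1% and must
be renormalized before chain analytics.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import RallyRecord, RecordValidationError, validate_record
from .transitions import COL_LABELS, ROW_LABELS, STRUCTURAL_MASK, TransitionMatrix

RECORD_COLUMNS = [
    "match_id",
    "set_no",
    "rally_no",
    "gender",
    "server",
    "rally_length",
    "fos_number",
    "fos_player",
    "winner",
    "ranking_first",
    "ranking_second",
    "result_first",
]


class RecordBatchError(ValueError):
    """One or more rows of a record file failed validation.

    ``errors`` lists ``(line_number, message)`` pairs (line 1 = header).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "\n".join(f"  line {ln}: {msg}" for ln, msg in errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} invalid record row(s):\n{lines}{more}")


class FixtureError(RuntimeError):
    """The packaged reference matrix failed its structural validation."""


def _normalize_row(raw: dict) -> RallyRecord:
    return RallyRecord(
        match_id=str(raw["match_id"]),
        set_no=int(raw["set_no"]),
        rally_no=int(raw["rally_no"]),
        gender=str(raw["gender"]).strip().upper(),
        server=str(raw["server"]).strip().lower(),
        rally_length=int(raw["rally_length"]),
        fos_number=int(raw["fos_number"]),
        fos_player=str(raw["fos_player"]).strip().lower(),
        winner=str(raw["winner"]).strip().lower(),
        ranking_first=int(raw["ranking_first"]),
        ranking_second=int(raw["ranking_second"]),
        result_first=str(raw["result_first"]).strip().upper(),
    )


def read_records(path: str | Path, fail_fast: bool = False) -> list[RallyRecord]:
    """Read and validate a rally-record CSV.

    Row-level failures are aggregated with their line numbers into one
    :class:`RecordBatchError` (or raised at the first bad row with
    ``fail_fast``).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record file {path} is missing column(s): {missing}")
    records: list[RallyRecord] = []
    errors: list[tuple[int, str]] = []
    for ix, raw in enumerate(frame.to_dict("records")):
        line = ix + 2  # header is line 1
        try:
            records.append(validate_record(_normalize_row(raw)))
        except (RecordValidationError, ValueError) as exc:
            if fail_fast:
                raise RecordValidationError("row", f"line {line}: {exc}") from exc
            errors.append((line, str(exc)))
    if errors:
        raise RecordBatchError(errors)
    return records


def write_records(records: Iterable[RallyRecord], path: str | Path) -> None:
    frame = pd.DataFrame([{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records])
    frame.to_csv(path, index=False)


# -- matrices -----------------------------------------------------------


def matrix_to_long(matrix: TransitionMatrix, unit_id: str = "") -> pd.DataFrame:
    """Long form: one row per structurally legal cell."""
    rows = []
    for src in ROW_LABELS:
        for dst in COL_LABELS:
            if STRUCTURAL_MASK.loc[src, dst]:
                rows.append(
                    {
                        "unit_id": unit_id,
                        "from_state": src,
                        "to_state": dst,
                        "probability": matrix.probs.loc[src, dst],
                        "origin_total": matrix.origin_totals.loc[src],
                    }
                )
    return pd.DataFrame(rows)


def write_matrix_long(matrix: TransitionMatrix, path: str | Path, unit_id: str = "") -> None:
    matrix_to_long(matrix, unit_id).to_csv(path, index=False)


def write_matrix_wide(matrix: TransitionMatrix, path: str | Path, percent: bool = False) -> None:
    probs = matrix.probs * (100.0 if percent else 1.0)
    out = probs.where(STRUCTURAL_MASK)  # blank the structural zeros
    out.index.name = "state"
    out.to_csv(path)


def read_matrix_wide(
    path: str | Path, provenance: str = "empirical_unit"
) -> TransitionMatrix:
    """Read a square states-by-states CSV (probabilities or percent).

    Percent input (any cell > 1.5) is scaled down; blank cells are
    structural zeros.  Rows that are entirely blank are undefined.
    """
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != ROW_LABELS or list(frame.columns) != COL_LABELS:
        raise ValueError(
            f"matrix file {path} must have rows {ROW_LABELS} and columns {COL_LABELS}"
        )
    defined = frame.notna().any(axis=1)
    values = frame.astype(float)
    if np.nanmax(values.to_numpy()) > 1.5:
        values = values / 100.0
    values = values.fillna(0.0)
    values[~STRUCTURAL_MASK & (values != 0)] = 0.0
    probs = values.where(pd.DataFrame(np.tile(defined.to_numpy()[:, None], (1, len(COL_LABELS))),
                                      index=ROW_LABELS, columns=COL_LABELS))
    return TransitionMatrix(
        probs=probs,
        origin_totals=pd.Series(np.where(defined, 1, 0), index=ROW_LABELS),
        provenance=provenance,  # type: ignore[arg-type]
    )


def load_reference_matrix() -> TransitionMatrix:
    """The packaged averaged transition matrix (percent -> probability).

    Validated structurally on load: exact state labels, values only in
    legal cells, every row defined and summing to within 0.005 of 1.
    Apply :func:`efos.chain.renormalize_rows` before chain analytics.
    """
    ref = resources.files("efos.data").joinpath("reference_matrix.csv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != ROW_LABELS or list(frame.columns) != COL_LABELS:
        raise FixtureError("reference matrix has unexpected state labels")
    illegal = frame.notna() & ~STRUCTURAL_MASK
    if illegal.to_numpy().any():
        raise FixtureError("reference matrix holds values in structurally illegal cells")
    probs = frame.fillna(0.0).astype(float) / 100.0
    sums = probs.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 0.005]
    if not bad.empty:
        raise FixtureError(f"reference matrix rows off unity beyond rounding: {dict(bad)}")
    return TransitionMatrix(
        probs=probs,
        origin_totals=pd.Series(1, index=ROW_LABELS),
        provenance="fixture",
    )


# -- covariates ---------------------------------------------------------


def derive_covariates(
    records: Sequence[RallyRecord], threshold: int = 40
) -> pd.DataFrame:
    """Player-side units with their grouping covariates.

    One row per (match, side): gender, world ranking, ranking class
    (``<=T`` inclusive of the threshold itself, else ``>T``), and match
    result for that side.
    """
    if threshold < 1:
        raise ValueError("ranking threshold must be positive")
    seen: dict[tuple[str, str], dict] = {}
    for rec in records:
        for side in ("first", "second"):
            key = (rec.match_id, side)
            if key in seen:
                continue
            ranking = rec.ranking_first if side == "first" else rec.ranking_second
            result = rec.result_first if side == "first" else (
                "L" if rec.result_first == "W" else "W"
            )
            seen[key] = {
                "match_id": rec.match_id,
                "side": side,
                "gender": rec.gender,
                "ranking": ranking,
                "ranking_class": f"<={threshold}" if ranking <= threshold else f">{threshold}",
                "result": result,
            }
    return pd.DataFrame(seen.values())
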