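"""Tabular I/O for recordings, trial windows, and tidy result tables.

The on-disk dialect is one wide CSV per person per session: a block of
``# key: value`` metadata comment lines, then a header row, then one row
per sample with a ``t`` column (seconds) and the 42 ``<tracker>_<dof>``
data columns.  Column order in the file is free; the reader maps columns
by header name and normalizes to the canonical order.  Positions are mm
and orientations degrees at this boundary; device-native units are
converted on read via ``position_scale``.

Missing samples are not supported: the source device streams continuously,
so the reader rejects non-finite cells rather than imputing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CHANNELS,
    DOFS,
    POSITION_DOFS,
    TRACKERS,
    Difficulty,
    Feedback,
    Recording,
    Role,
    TrialWindow,
)

log = logging.getLogger(__name__)

_MAGIC = "dyadkin-recording v1"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a metadata-commented wide CSV.

    Refuses non-finite values: the format has no missing-data convention.
    Numeric payload is written with 17 significant digits, so a read-back
    reproduces the values exactly.
    """
    rec.validate()
    path = Path(path)
    sp = " ".join(repr(float(v)) for v in rec.start_point)
    header = [
        f"# {_MAGIC}",
        f"# person_id: {rec.person_id}",
        f"# role: {rec.role.value}",
        f"# feedback: {rec.feedback.value}",
        f"# difficulty: {rec.difficulty.value}",
        f"# sample_rate: {rec.sample_rate!r}",
        f"# start_point: {sp}",
    ]
    out = rec.data.copy()
    out.insert(0, "t", np.arange(len(out)) / rec.sample_rate)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        out.to_csv(fh, index=False, float_format="%.17g")
    return path


def _parse_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_recording(
    path: str | Path,
    *,
    person_id: str | None = None,
    role: Role | str | None = None,
    feedback: Feedback | str | None = None,
    difficulty: Difficulty | str | None = None,
    sample_rate: float | None = None,
    start_point: Sequence[float] | None = None,
    position_scale: float = 1.0,
) -> Recording:
    """Read a Recording CSV, validating structure and finiteness.

    Keyword arguments override metadata stored in the file; they are
    required when the file carries none (e.g. data exported from another
    tool).  ``position_scale`` converts device-native position units to mm
    (applied to x/y/z channels and the start point).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_meta(path)
    n_meta = sum(1 for line in open(path) if line.startswith("#"))

    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed CSV: {exc}") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    for tracker in TRACKERS:
        missing = [f"{tracker}_{d}" for d in DOFS if f"{tracker}_{d}" not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing columns for tracker '{tracker}': {missing} "
                f"(header line {n_meta + 1})"
            )

    data = df.loc[:, list(CHANNELS)]
    for col in data.columns:
        if not np.issubdtype(data[col].dtype, np.number):
            coerced = pd.to_numeric(data[col], errors="coerce")
            bad_row = int(coerced.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric cell in column '{col}' at line "
                f"{bad_row + n_meta + 2} (value {data[col].iloc[bad_row]!r})"
            )
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite value in column '{CHANNELS[c]}' at line "
            f"{int(r) + n_meta + 2}"
        )

    sp = start_point if start_point is not None else meta.get("start_point")
    if sp is None:
        raise ValueError(f"{path}: no start_point in file metadata or arguments")
    if isinstance(sp, str):
        sp = [float(v) for v in sp.split()]
    sp = np.asarray(sp, dtype=float)

    def pick(arg, key, default=None):
        if arg is not None:
            return arg
        if key in meta:
            return meta[key]
        if default is not None:
            return default
        raise ValueError(f"{path}: '{key}' not in file metadata or arguments")

    rec = Recording(
        person_id=str(pick(person_id, "person_id", "unknown")),
        role=Role(pick(role, "role")),
        feedback=Feedback(pick(feedback, "feedback")),
        difficulty=Difficulty(pick(difficulty, "difficulty")),
        data=data.astype(float),
        start_point=sp,
        sample_rate=float(pick(sample_rate, "sample_rate", 240.0)),
    )
    if position_scale != 1.0:
        pos_cols = [f"{t}_{d}" for t in TRACKERS for d in POSITION_DOFS]
        rec.data[pos_cols] *= position_scale
        rec.start_point = rec.start_point * position_scale
    return rec.validate()


def write_trials(windows: Iterable[TrialWindow], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"trial": i, "start_sample": w.start, "end_sample": w.end}
         for i, w in enumerate(windows)]
    )
    df.to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> list[TrialWindow]:
    df = pd.read_csv(path)
    return [
        TrialWindow(int(r.start_sample), int(r.end_sample))
        for r in df.itertuples()
    ]
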