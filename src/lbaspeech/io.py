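"""CSV/JSON artifact input-output with schema validation.

Trial-level data, preference counts and posterior draws travel as plain
CSV (diff-able and language-neutral); structured summaries and generating
populations travel as JSON.  Every artifact written here carries a leading
``# lbaspeech-meta: {...}`` comment line with the package version, seed and
a config hash, so a run can be traced back to its configuration; readers
skip comment lines.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .lba import MODES, RESPONSES
from .synthetic import TruePopulation

TRIALS_COLUMNS = [
    "participant_id", "group", "trial_id", "mode", "keyword_index",
    "response", "rt_seconds", "kw1_correct", "kw2_correct",
]
COUNTS_COLUMNS = ["group", "conversation", "mode", "count"]


class SchemaError(ValueError):
    """An input table does not match the documented schema."""


class IntegrityError(ValueError):
    """Stored context flags contradict the response sequence."""


def _meta_line(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("format", "lbaspeech-csv-v1")
    return "# lbaspeech-meta: " + json.dumps(meta, sort_keys=True) + "\n"


def read_meta(path) -> dict | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# lbaspeech-meta:"):
        return json.loads(first.split(":", 1)[1])
    return None


def write_trials(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    missing = set(TRIALS_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"trial table missing columns: {sorted(missing)}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        table[TRIALS_COLUMNS + [c for c in table.columns
                                if c not in TRIALS_COLUMNS]] \
            .to_csv(fh, index=False)


def read_trials(path, check_context: bool = True) -> pd.DataFrame:
    """Read and validate a trial table.

    RTs are parsed as seconds and must be positive; the serial-dependency
    context flags are recomputed from the response sequence and compared
    with the stored values — any contradiction raises an
    :class:`IntegrityError` naming the offending trials.  Unknown extra
    columns are kept with a warning (forward compatibility).
    """
    table = pd.read_csv(path, comment="#")
    missing = set(TRIALS_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in table.columns if c not in TRIALS_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    bad_resp = ~table["response"].isin(RESPONSES)
    if bad_resp.any():
        raise SchemaError(
            f"{path}: invalid response values at rows "
            f"{table.index[bad_resp].tolist()[:10]}"
        )
    bad_mode = ~table["mode"].isin(MODES)
    if bad_mode.any():
        raise SchemaError(
            f"{path}: invalid mode values at rows "
            f"{table.index[bad_mode].tolist()[:10]}"
        )
    rt = pd.to_numeric(table["rt_seconds"], errors="coerce")
    bad_rt = rt.isna() | (rt <= 0)
    if bad_rt.any():
        raise SchemaError(
            f"{path}: non-positive or unparsable rt_seconds at rows "
            f"{table.index[bad_rt].tolist()[:10]}"
        )
    table["rt_seconds"] = rt
    for col in ("kw1_correct", "kw2_correct"):
        table[col] = table[col].astype(bool)
    if check_context:
        bad = check_context_flags(table)
        if bad:
            raise IntegrityError(
                "context flags inconsistent with responses for "
                f"(participant, trial) pairs: {bad[:10]}"
            )
    return table


def check_context_flags(table: pd.DataFrame) -> list:
    """Return (participant, trial) pairs whose stored context flags
    contradict the recorded responses of earlier keywords."""
    bad = []
    for (pid, tid), trial in table.groupby(["participant_id", "trial_id"]):
        trial = trial.sort_values("keyword_index")
        ok = {int(r["keyword_index"]): r["response"] == "correct"
              for _, r in trial.iterrows()}
        for _, r in trial.iterrows():
            kw = int(r["keyword_index"])
            exp1 = ok.get(1, False) if kw >= 2 else False
            exp2 = ok.get(2, False) if kw >= 3 else False
            if bool(r["kw1_correct"]) != exp1 or bool(r["kw2_correct"]) != exp2:
                bad.append((pid, tid))
                break
    return bad


def write_counts(counts: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        counts[COUNTS_COLUMNS].to_csv(fh, index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, comment="#")
    missing = set(COUNTS_COLUMNS) - set(counts.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    c = pd.to_numeric(counts["count"], errors="coerce")
    if c.isna().any() or (c < 0).any() or not np.allclose(c, np.round(c)):
        raise SchemaError(f"{path}: counts must be non-negative integers")
    counts["count"] = c.astype(int)
    return counts


def write_population(pop: TruePopulation, path, meta: dict | None = None) -> None:
    payload = {"meta": dict(meta or {}), "population": pop.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_population(path) -> TruePopulation:
    payload = json.loads(Path(path).read_text())
    return TruePopulation.from_dict(payload["population"])


def write_draws_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a long-format (chain, iteration, parameter, value) draws CSV."""
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        df.to_csv(fh, index=False)


def read_draws_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    need = {"chain", "iteration", "parameter", "value"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return df


def write_json(obj: dict, path, meta: dict | None = None) -> None:
    payload = dict(obj)
    if meta:
        payload["_meta"] = dict(meta)
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
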