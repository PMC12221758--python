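"""Reading, writing and validating trial tables.

The on-disk dialect is UTF-8 comma-delimited text with a header row and
empty fields for missing values (dialect version 1).  Unknown columns are
accepted and preserved, so simulated tables (with internal quantities like
``m_v``) and behavioural exports share one reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = ["DIALECT_VERSION", "read_trial_table", "write_trial_table",
           "validate_trial_table"]

DIALECT_VERSION = 1

#: columns every trial table must provide
REQUIRED_COLUMNS = ("block", "task", "G", "stimulus")

_VALID_TASKS = {"classification", "scaling", "reproduction"}


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Schema validation; raises :class:`SchemaError` naming rows/columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    problems = []
    tasks = df["task"].astype(str)
    bad_task = ~tasks.isin(_VALID_TASKS)
    if bad_task.any():
        rows = df.index[bad_task].tolist()[:10]
        problems.append(f"unknown task values at rows {rows}")
    g = pd.to_numeric(df["G"], errors="coerce")
    if g.isna().any():
        problems.append(
            f"non-numeric G at rows {df.index[g.isna()].tolist()[:10]}")
    if "choice" in df.columns:
        choice = pd.to_numeric(df["choice"], errors="coerce")
        is_cls = tasks == "classification"
        # a missing choice on a classification trial is allowed (missed
        # trial); it simply breaks the history chain downstream
        over = choice.notna() & (choice > g)
        if over.any():
            problems.append(
                f"choice exceeds G at rows {df.index[over].tolist()[:10]}")
        under = choice.notna() & (choice < 1)
        if under.any():
            problems.append(
                f"choice below 1 at rows {df.index[under].tolist()[:10]}")
        if "second_task" not in df.columns:
            misplaced = ~is_cls & choice.notna()
            if misplaced.any():
                problems.append("choice present on non-classification rows "
                                f"{df.index[misplaced].tolist()[:10]}")
    elif (tasks == "classification").any():
        problems.append("classification trials without a choice column")
    if "rt" in df.columns:
        rt = pd.to_numeric(df["rt"], errors="coerce")
        neg = rt.notna() & (rt < 0)
        if neg.any():
            problems.append(
                f"negative response times at rows {df.index[neg].tolist()[:10]}")
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_trial_table(path, dialect: int = DIALECT_VERSION) -> pd.DataFrame:
    if dialect != DIALECT_VERSION:
        raise SchemaError(f"unsupported dialect version {dialect}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such trial table: {path}")
    df = pd.read_csv(path)
    if df.columns.size == 0:
        raise SchemaError("trial table has no header")
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path,
                      dialect: int = DIALECT_VERSION) -> None:
    if dialect != DIALECT_VERSION:
        raise SchemaError(f"unsupported dialect version {dialect}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
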