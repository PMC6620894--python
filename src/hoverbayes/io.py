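"""Delimited-text I/O and per-participant record assembly.

The participant table is a delimited file with header
(participant_id, study, format, base_num, base_den, tpr_num, tpr_den,
far_num, far_den, answer_num, answer_den) plus optional columns
(numeracy, adblocker_disabled, strategy).  Event logs are handled by
:mod:`hoverbayes.interaction`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .bayes import (
    Answer,
    Format,
    build_frequency_tree,
    build_probability_tree,
    performance_metrics,
)
from .errors import SchemaError

__all__ = ["read_participants", "write_participants", "participant_records"]

_REQUIRED = (
    "participant_id",
    "study",
    "format",
    "base_num",
    "base_den",
    "tpr_num",
    "tpr_den",
    "far_num",
    "far_den",
    "answer_num",
    "answer_den",
)


def read_participants(path: str | Path | pd.DataFrame, *, sep: str = ",") -> pd.DataFrame:
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise SchemaError(f"participant table missing columns: {sorted(missing)}")
    bad_fmt = set(df["format"].astype(str).unique()) - {"frequency", "probability"}
    if bad_fmt:
        raise SchemaError(f"unknown formats: {sorted(bad_fmt)}")
    return df


def write_participants(df: pd.DataFrame, path: str | Path, *, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def participant_records(
    participants: pd.DataFrame,
    *,
    population: int = 1000,
    fixed_triple: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Attach the task tree and all performance metrics to each participant row.

    In experience-matched rows (study == 'experience_matched') the task triple
    is the participant's own reported triple; in fixed-values rows the task is
    built from ``fixed_triple`` (supplied as structured config, since the
    table only stores what participants reported).  The subjective posterior
    always derives from the reported triple, so in experience-matched cohorts
    the log-experience-deviation is identically zero.
    """
    rows = []
    for row in participants.itertuples(index=False):
        fmt = Format(row.format)
        reported = (
            row.base_num / row.base_den,
            row.tpr_num / row.tpr_den,
            row.far_num / row.far_den,
        )
        if str(row.study) == "fixed_values":
            if fixed_triple is None:
                raise SchemaError(
                    "fixed_triple is required for fixed-values (study-2) rows"
                )
            task_triple = tuple(fixed_triple)
        else:
            task_triple = reported
        if fmt is Format.FREQUENCY:
            tree = build_frequency_tree(*task_triple, population=population)
        else:
            tree = build_probability_tree(*task_triple)
        answer = Answer(float(row.answer_num), float(row.answer_den))
        metrics = performance_metrics(answer, tree, reported)
        rows.append(
            {
                "participant_id": row.participant_id,
                "study": row.study,
                "format": row.format,
                "numeracy": getattr(row, "numeracy", float("nan")),
                "true_posterior": metrics.true_posterior,
                "estimated_posterior": metrics.estimated_posterior,
                "subjective_posterior": metrics.subjective_posterior,
                "correct": metrics.correct,
                "log_relative_error": metrics.log_relative_error,
                "log_experience_deviation": metrics.log_experience_deviation,
                "floored": metrics.floored,
                "strategy_label": metrics.strategy.label.value,
            }
        )
    return pd.DataFrame(rows)
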