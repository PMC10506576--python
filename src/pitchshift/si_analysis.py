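"""Shift Index computation and cohort summaries.

For each participant and condition, responses over repeated presentations
are tallied as ``sp`` (spectral responses — tone A judged higher, or the
melody judged off-key) and ``f0`` (fundamental responses).  The Shift Index

    SI = (sp − f0) / (sp + f0)

lies in [−1, +1]; with the study's two repetitions it can only take the
values −1, 0, +1, and SI = 0 is exactly the *ambiguous* case where the two
repetitions of the same task received different responses.
"""

from __future__ import annotations

import pandas as pd

from .errors import UndefinedScoreError, UnsupportedDesignError
from .stimulus import CONDITION_NAMES

__all__ = [
    "shift_index",
    "classify_ambiguous",
    "tally_responses",
    "score_responses",
    "cohort_summary",
]

SPECTRAL = "spectral"
F0 = "f0"


def shift_index(sp: int, f0: int) -> float:
    """(sp − f0)/(sp + f0) for one participant-condition tally.

    Defined for any repetition count with at least one response; the study
    design uses two repetitions, restricting the value to {−1, 0, +1}.
    """
    if sp < 0 or f0 < 0:
        raise UndefinedScoreError("response counts must be non-negative")
    total = sp + f0
    if total == 0:
        raise UndefinedScoreError("Shift Index undefined for an empty tally")
    return (sp - f0) / total


def classify_ambiguous(sp: int, f0: int) -> bool:
    """True iff the two repetitions of a task received different responses.

    Ambiguity is defined only for the two-repetition design; any other
    repetition count raises rather than silently extending the definition.
    """
    if sp + f0 != 2:
        raise UnsupportedDesignError(
            f"ambiguity is defined for exactly 2 repetitions, got {sp + f0}"
        )
    return sp == 1 and f0 == 1


def tally_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long response table to per-(participant, condition) tallies.

    Expects the response-table schema (columns ``participant_id``,
    ``condition``, ``repetition``, ``response`` and optionally
    ``age_group``/``experiment``); returns one row per cell with ``sp``,
    ``f0`` counts.  Missing responses are rejected: every cell must contain
    the same number of repetitions as the rest of the table.
    """
    required = {"participant_id", "condition", "repetition", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise UnsupportedDesignError(f"response table missing columns: {sorted(missing)}")
    bad = set(responses["response"].unique()) - {SPECTRAL, F0}
    if bad:
        raise UnsupportedDesignError(f"unknown response labels: {sorted(bad)}")

    keys = ["participant_id", "condition"]
    extra = [c for c in ("age_group", "experiment") if c in responses.columns]
    is_sp = (responses["response"] == SPECTRAL).astype(int).rename("_sp")
    grouped = responses.assign(_sp=is_sp).groupby(keys + extra, observed=True)["_sp"]
    tally = grouped.agg(sp="sum", _n="size").reset_index()
    tally["f0"] = tally.pop("_n") - tally["sp"]
    reps = tally["sp"] + tally["f0"]
    if reps.nunique() > 1:
        raise UnsupportedDesignError(
            "unbalanced design: repetition counts per cell are "
            f"{sorted(reps.unique())}; missing responses are not imputed"
        )
    return tally


def score_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition SI scores with ambiguity flags.

    Adds ``si`` to the tally table; ``ambiguous`` is included when the
    design has two repetitions (the study design), otherwise omitted.
    """
    tally = tally_responses(responses)
    total = tally["sp"] + tally["f0"]
    if (total == 0).any():
        raise UndefinedScoreError("empty tally cell encountered")
    tally["si"] = (tally["sp"] - tally["f0"]) / total
    if (total == 2).all():
        tally["ambiguous"] = (tally["sp"] == 1) & (tally["f0"] == 1)
    return tally


def cohort_summary(scores: pd.DataFrame, by_age: bool = False) -> pd.DataFrame:
    """Per-condition summary: mean SI and response-pattern percentages.

    ``pct_ambiguous`` + ``pct_spectral`` + ``pct_f0`` = 100 per condition
    (unambiguous-spectral and unambiguous-F0 percentages).  Requires the
    two-repetition design (an ``ambiguous`` column from score_responses).
    """
    if "ambiguous" not in scores.columns:
        raise UnsupportedDesignError("cohort_summary requires the two-repetition design")
    keys = ["condition"]
    if by_age:
        if "age_group" not in scores.columns:
            raise UnsupportedDesignError("scores lack an age_group column")
        keys = ["age_group", "condition"]

    rows = []
    for key, g in scores.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        rows.append(
            dict(zip(keys, key))
            | {
                "n": n,
                "mean_si": g["si"].mean(),
                "pct_ambiguous": 100.0 * g["ambiguous"].mean(),
                "pct_spectral": 100.0 * (g["si"] == 1.0).mean(),
                "pct_f0": 100.0 * (g["si"] == -1.0).mean(),
            }
        )
    out = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(CONDITION_NAMES)}
    out["_o"] = out["condition"].map(lambda c: order.get(c, len(order)))
    out = out.sort_values(keys[:-1] + ["_o"]).drop(columns="_o").reset_index(drop=True)
    return out
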