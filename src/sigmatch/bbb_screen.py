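"""Blood-brain-barrier (BBB) re-ranking of reversal candidates.

The screen consumes an externally produced BBB-penetration probability
table (QSAR classifier output, scores in [-1, 1]; higher means more
likely to cross the barrier) — the classifier itself is third-party work
and is not reimplemented here. Candidates from the reversal ranking are
re-sorted by BBB probability and the top n retained. A candidate missing
from the score table is excluded with a warning, never silently dropped:
a missing prediction is not evidence of impermeability.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .data_io import read_score_table

logger = logging.getLogger(__name__)

BBB_BOUNDS = (-1.0, 1.0)


def read_bbb_table(
    path: str | Path,
    id_column: str = "compound_id",
    score_column: str = "bbb_probability",
) -> dict[str, float]:
    """Read a compound -> BBB-probability TSV, enforcing scores in [-1, 1]."""
    return read_score_table(path, id_column, score_column, bounds=BBB_BOUNDS)


def screen_by_bbb(
    candidates: pd.DataFrame,
    scores: Mapping[str, float],
    n: int,
) -> pd.DataFrame:
    """Retain the n candidates with the highest BBB probability.

    ``candidates`` is a ranked reversal-score table (columns drug_id,
    average_score, ...). Ties in BBB probability are broken by higher
    average reversal score, then drug_id. Returns columns rank, drug_id,
    average_score, bbb_probability.
    """
    for col in ("drug_id", "average_score"):
        if col not in candidates.columns:
            raise ValueError(f"candidate table missing column {col!r}")
    if n < 1:
        raise ValueError("n must be positive")
    df = candidates[["drug_id", "average_score"]].copy()
    df["drug_id"] = df["drug_id"].astype(str)
    missing = [d for d in df["drug_id"] if d not in scores]
    if missing:
        logger.warning(
            "excluding %d candidate(s) without a BBB score: %s",
            len(missing),
            ", ".join(missing[:10]),
        )
    df = df[df["drug_id"].isin(scores)].copy()
    if df.empty:
        raise ValueError("no candidate has a BBB score")
    if n > len(df):
        raise ValueError(f"n={n} exceeds the {len(df)} scoreable candidates")
    df["bbb_probability"] = [scores[d] for d in df["drug_id"]]
    df = df.sort_values(
        ["bbb_probability", "average_score", "drug_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(n)
    df.insert(0, "rank", range(1, n + 1))
    return df.reset_index(drop=True)


def write_bbb_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
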