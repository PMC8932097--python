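"""Survey-weighted food-insecurity prevalence from 8-item responses.

The eight items, in ascending severity, ask whether the respondent (1)
worried about food, (2) could not eat healthy food, (3) ate few kinds of
food, (4) skipped a meal, (5) ate less than they should, (6) ran out of
food, (7) was hungry but did not eat, (8) went a whole day without eating.

Two classification dialects are supported:

``item`` (default)
    moderate-to-severe = any of items 4–8 affirmed; severe = item 7 or 8.
``rawscore``
    moderate-to-severe = at least 4 of 8 affirmed; severe = at least 7.

On Guttman-structured responses (affirming a harder item implies affirming
all easier ones) the two dialects coincide.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ITEM_COLUMNS = tuple(f"q{i}" for i in range(1, 9))
MSFI_ITEMS = ("q4", "q5", "q6", "q7", "q8")
SFI_ITEMS = ("q7", "q8")
DIALECTS = ("item", "rawscore")


def classify_responses(responses: pd.DataFrame, dialect: str = "item") -> pd.DataFrame:
    """Per-respondent moderate-to-severe and severe flags.

    Returns float columns ``msfi_flag, sfi_flag`` (1.0/0.0); a record with
    any classification-relevant item missing gets NaN flags, left for the
    aggregation step to drop.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    missing = [c for c in ITEM_COLUMNS if c not in responses.columns]
    if missing:
        raise ValueError(f"responses table is missing item columns {missing}")
    items = responses.loc[:, list(ITEM_COLUMNS)].astype(float)
    bad = ~(items.isin([0.0, 1.0]) | items.isna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-binary answer {items.iloc[r, c]!r} in column {bad.columns[c]} at row {items.index[r]}"
        )
    if dialect == "item":
        msfi = items[list(MSFI_ITEMS)].max(axis=1, skipna=False)
        sfi = items[list(SFI_ITEMS)].max(axis=1, skipna=False)
    else:
        score = items.sum(axis=1, skipna=False)
        msfi = (score >= 4).astype(float).where(score.notna())
        sfi = (score >= 7).astype(float).where(score.notna())
    return pd.DataFrame({"msfi_flag": msfi, "sfi_flag": sfi}, index=responses.index)


def weighted_prevalence(
    responses: pd.DataFrame,
    dialect: str = "item",
    by: Sequence[str] = ("region_id", "year"),
) -> pd.DataFrame:
    """Survey-weighted prevalence (%) per group of ``by`` columns.

    prevalence = 100 * sum(w_i * flag_i) / sum(w_i);
    effective_n = (sum w)^2 / sum(w^2).  Records with missing
    classification-relevant items are dropped with a logged count.
    """
    by = list(by)
    for col in by + ["weight"]:
        if col not in responses.columns:
            raise ValueError(f"responses table is missing column {col!r}")
    w = responses["weight"].to_numpy(dtype=float)
    if (w <= 0).any() or np.isnan(w).any():
        i = int(np.argwhere(~(w > 0))[0][0])
        raise ValueError(f"non-positive survey weight {w[i]!r} at row {responses.index[i]}")

    flags = classify_responses(responses, dialect)
    valid = flags.notna().all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("dropped %d records with missing classification items", n_dropped)
    df = pd.concat([responses[by + ["weight"]], flags], axis=1)[valid]
    if df.empty:
        raise ValueError("no valid respondents after dropping incomplete records")

    def _agg(g: pd.DataFrame) -> pd.Series:
        ws = g["weight"].to_numpy()
        total = ws.sum()
        if total <= 0:
            raise ValueError("zero total survey weight in a group")
        return pd.Series(
            {
                "msfi": 100.0 * (ws * g["msfi_flag"].to_numpy()).sum() / total,
                "sfi": 100.0 * (ws * g["sfi_flag"].to_numpy()).sum() / total,
                "n_respondents": float(len(g)),
                "effective_n": total * total / (ws * ws).sum(),
            }
        )

    out = df.groupby(by, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_respondents"] = out["n_respondents"].astype(int)
    out.attrs["n_dropped"] = n_dropped
    return out
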