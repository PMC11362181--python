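"""Scoring of proximity-triggered questionnaire responses.

Each completed questionnaire first asks whether the pair actually spoke; if
not, no item follow-ups exist.  Item scales (all 1-7 Likert):

* positive affect = mean(happy, relaxed)
* negative affect = mean(sad, irritated, guilty)
* parental warmth = mean(listen, understand)
* parental criticism = mean(critical, dominant)

plus the single pleasantness item.  A scale is computed only when all of its
items are present (listwise per scale, no imputation).  Person means average
a person's per-interaction scores, unweighted.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

REPORTERS = (
    "adolescent_about_mother",
    "adolescent_about_father",
    "mother_self",
    "father_self",
)

SCALE_ITEMS: dict[str, tuple[str, ...]] = {
    "pleasantness": ("pleasantness",),
    "positive_affect": ("happy", "relaxed"),
    "negative_affect": ("sad", "irritated", "guilty"),
    "warmth": ("listen", "understand"),
    "criticism": ("critical", "dominant"),
}
SCALES = tuple(SCALE_ITEMS)
ITEMS = tuple(dict.fromkeys(i for items in SCALE_ITEMS.values() for i in items))


def _round(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def score_response(response: dict) -> dict[str, float]:
    """Scale scores for one spoken interaction; missing items -> scale NaN.

    ``response`` maps item names to values in 1..7 (or None/NaN).  Scores are
    unrounded arithmetic means.  A response with ``spoke`` false has no items
    and yields all-NaN scores.
    """
    out: dict[str, float] = {}
    spoke = bool(response.get("spoke", False))
    for scale, items in SCALE_ITEMS.items():
        vals = []
        ok = spoke
        for item in items:
            v = response.get(item)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                ok = False
                break
            v = float(v)
            if not 1 <= v <= 7:
                raise ValueError(f"item {item}={v} outside the 1-7 scale")
            vals.append(v)
        out[scale] = sum(vals) / len(vals) if ok else math.nan
    return out


def score_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Add scale-score columns to a response table (one row per questionnaire)."""
    scored = responses.copy()
    scores = [
        score_response({k: row.get(k) for k in ("spoke", *ITEMS)})
        for _, row in responses.iterrows()
    ]
    for scale in SCALES:
        scored[scale] = [s[scale] for s in scores]
    return scored


def person_means(scored: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-person mean of each scale, by reporter.

    Output is long: person_id, reporter, scale, mean, n_obs.  Persons with
    zero scored responses for a scale are omitted.
    """
    rows = []
    for (person, reporter), grp in scored.groupby(["person_id", "reporter"], sort=True):
        for scale in SCALES:
            vals = grp[scale].dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "person_id": person,
                    "reporter": reporter,
                    "scale": scale,
                    "mean": float(vals.mean()),
                    "n_obs": int(len(vals)),
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "reporter", "scale", "mean", "n_obs"])


def summary_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Descriptives per reporter x scale: N persons, Obs, M, SD, Min, Max.

    M/SD are over individual interactions (rounded to 2 decimals at report
    time); Min/Max are observed interaction-level scores.
    """
    rows = []
    for reporter in REPORTERS:
        grp = scored[scored["reporter"] == reporter]
        for scale in SCALES:
            vals = grp[scale].dropna()
            if len(vals) == 0:
                continue
            persons = grp.loc[grp[scale].notna(), "person_id"].nunique()
            rows.append(
                {
                    "reporter": reporter,
                    "scale": scale,
                    "N": int(persons),
                    "Obs": int(len(vals)),
                    "M": _round(float(vals.mean()), 2),
                    "SD": _round(float(vals.std(ddof=1)), 2) if len(vals) > 1 else math.nan,
                    "Min": float(vals.min()),
                    "Max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows, columns=["reporter", "scale", "N", "Obs", "M", "SD", "Min", "Max"])


def interaction_rate(responses: pd.DataFrame, group: str | None = None) -> float:
    """Percent of answered questionnaires reporting an actual interaction.

    ``group`` filters on the ``recipient_group`` column when given.  Returns
    100 * spoke / answered at one decimal; NaN when nothing was answered.
    """
    df = responses
    if group is not None:
        df = df[df["recipient_group"] == group]
    answered = len(df)
    if answered == 0:
        return math.nan
    spoke = int(df["spoke"].astype(bool).sum())
    return _round(100.0 * spoke / answered, 1)
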