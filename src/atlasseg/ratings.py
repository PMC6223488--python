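"""Ordinal physician-rating analysis: agreement categories and score summaries.

Contours are rated on a three-level ordinal scale — needing no edits,
minor edits, or major edits for use in dose-volume-histogram-based
planning.  Pairs of ratings (primary physician vs outside physician) are
grouped into three agreement categories:

* **Category I** — identical ratings (agreement on the degree of editing).
* **Category II** — non-identical, but both no-worse-than-minor (both
  physicians judged the contour acceptable).
* **Category III** — exactly one rating is "major edits": the physicians
  disagree on the contour's acceptability.

Identical major-major pairs are Category I (identity takes precedence),
so the three categories partition the 3 x 3 rating space as 3 / 2 / 4
pairs respectively.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "EditRating",
    "AgreementCategory",
    "categorize_pair",
    "summarize_agreement",
    "score_distribution",
    "read_ratings_csv",
]


class EditRating(Enum):
    NO_EDITS = 0
    MINOR_EDITS = 1
    MAJOR_EDITS = 2

    @classmethod
    def parse(cls, value) -> "EditRating":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            key = value.strip().upper()
            if key in cls.__members__:
                return cls[key]
        if isinstance(value, (int, np.integer)) and value in (0, 1, 2):
            return cls(int(value))
        raise ValueError(f"invalid edit rating: {value!r}")


class AgreementCategory(Enum):
    I = "I"
    II = "II"
    III = "III"


def categorize_pair(primary, outside) -> AgreementCategory:
    """Classify one (primary, outside) rating pair; symmetric in its arguments."""
    a = EditRating.parse(primary)
    b = EditRating.parse(outside)
    if a == b:
        return AgreementCategory.I
    if EditRating.MAJOR_EDITS in (a, b):
        return AgreementCategory.III
    return AgreementCategory.II


def read_ratings_csv(path) -> pd.DataFrame:
    """Read a paired-rating CSV, validating every row.

    Expected columns: case_id, structure, rating_primary, rating_outside.
    Malformed rows raise with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    required = {"case_id", "structure", "rating_primary", "rating_outside"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = []
    for i, row in df.iterrows():
        try:
            EditRating.parse(row["rating_primary"])
            EditRating.parse(row["rating_outside"])
        except ValueError:
            bad.append(i + 2)  # header is line 1
    if bad:
        raise ValueError(f"{path}: malformed ratings on lines {bad}")
    return df


def summarize_agreement(pairs: pd.DataFrame) -> dict:
    """Category I/II/III counts and percentages, overall and per structure.

    ``pairs`` needs columns rating_primary and rating_outside (and
    optionally structure for the per-structure breakdown).  Exact
    percentages are retained alongside the rounded display values.
    """
    if len(pairs) == 0:
        raise ValueError("empty rating table")
    cats = [
        categorize_pair(p, o).value
        for p, o in zip(pairs["rating_primary"], pairs["rating_outside"])
    ]
    pairs = pairs.assign(category=cats)
    n = len(pairs)

    def tally(df):
        counts = {c: int((df["category"] == c).sum()) for c in ("I", "II", "III")}
        total = len(df)
        return {
            "n": total,
            "counts": counts,
            "percent": {c: 100.0 * counts[c] / total for c in counts},
            "percent_rounded": {c: int(round(100.0 * counts[c] / total)) for c in counts},
        }

    out = {"overall": tally(pairs)}
    if "structure" in pairs.columns:
        out["per_structure"] = {
            name: tally(grp) for name, grp in pairs.groupby("structure")
        }
    assert sum(out["overall"]["counts"].values()) == n
    return out


def score_distribution(ratings: pd.DataFrame, rating_column: str = "rating_primary") -> dict:
    """Per-structure level counts, mean numeric rating, and acceptability.

    The mean uses the encoding NO_EDITS=0 / MINOR_EDITS=1 / MAJOR_EDITS=2.
    ``fraction_no_edits`` is the share rated acceptable without edit;
    ``fraction_minor_or_better`` the share needing at most minor edits.
    Unknown structure names pass through untouched; denominators count
    only the ratings actually present for each structure.
    """
    if len(ratings) == 0:
        raise ValueError("empty rating table")
    vals = ratings[rating_column].map(lambda v: EditRating.parse(v))
    codes = vals.map(lambda r: r.value)
    df = ratings.assign(_code=codes)

    def tally(grp):
        n = len(grp)
        counts = {r.name: int((grp["_code"] == r.value).sum()) for r in EditRating}
        return {
            "n": n,
            "counts": counts,
            "mean_rating": float(grp["_code"].mean()),
            "fraction_no_edits": counts["NO_EDITS"] / n,
            "fraction_minor_or_better": (counts["NO_EDITS"] + counts["MINOR_EDITS"]) / n,
        }

    out = {"overall": tally(df)}
    if "structure" in df.columns:
        out["per_structure"] = {name: tally(grp) for name, grp in df.groupby("structure")}
    return out
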