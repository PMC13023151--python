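"""Per-eye iris scores to five-category animal phenotypes and prevalence.

Each eye is scored with a primary color (dark brown, medium brown,
light brown, or pale) and optionally a secondary color when a single
iris shows more than one color. Medium brown is merged into dark brown
because the two shades are not reliably distinguishable under field
conditions. An animal is then classified as:

* *heterochromia iridis* — any eye carries a secondary color
  (unilateralis if one eye, bilateralis if both);
* *heterochromia iridum* — the two single-colored eyes differ;
* otherwise the shared single color (dark brown, light brown, pale).

Animals with only one scored eye are excluded, not classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EyeScore",
    "IrisCategory",
    "IncompleteRecordError",
    "merge_medium_dark",
    "classify_animal",
    "classify_table",
    "prevalence_table",
    "sex_contrast_test",
    "cross_category_table",
    "round_half_up",
]

EYE_COLORS = ("dark brown", "medium brown", "light brown", "pale")

#: Prevalence-table row order: the four base single colors (post-merge),
#: heterochromia iridum, then the two iridis subtypes.
TABLE_ROWS = (
    "dark brown",
    "light brown",
    "pale",
    "iridum",
    "iridis unilateralis",
    "iridis bilateralis",
)


class IncompleteRecordError(ValueError):
    """Raised when an animal cannot be classified (e.g. one eye missing)."""


@dataclass(frozen=True)
class EyeScore:
    """One scored eye: dominant color first, secondary color if present."""

    animal_id: str
    eye: str  # "left" | "right"
    primary: str
    secondary: str | None = None

    def __post_init__(self):
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be left/right, got {self.eye!r}")
        if self.primary not in EYE_COLORS:
            raise ValueError(f"unknown primary color {self.primary!r}")
        if self.secondary is not None:
            if self.secondary not in EYE_COLORS:
                raise ValueError(f"unknown secondary color {self.secondary!r}")
            if self.secondary == self.primary:
                raise ValueError("secondary color must differ from primary")


@dataclass(frozen=True)
class IrisCategory:
    """Animal-level phenotype with iridis subtype flag."""

    category: str  # dark brown | light brown | pale | iridum | iridis
    iridis_subtype: str = "none"  # unilateralis | bilateralis | none

    def __post_init__(self):
        if (self.iridis_subtype != "none") != (self.category == "iridis"):
            raise ValueError("iridis subtype set iff category is iridis")


def merge_medium_dark(score: EyeScore) -> EyeScore:
    """Replace every 'medium brown' by 'dark brown', componentwise. Idempotent."""
    primary = "dark brown" if score.primary == "medium brown" else score.primary
    secondary = (
        "dark brown" if score.secondary == "medium brown" else score.secondary
    )
    if secondary == primary:
        # a medium/dark pair collapses to a single dark color
        secondary = None
    return replace(score, primary=primary, secondary=secondary)


def classify_animal(left: EyeScore | None, right: EyeScore | None) -> IrisCategory:
    """Five-category animal phenotype from two merged eye scores.

    Symmetric in left/right exchange. Raises
    :class:`IncompleteRecordError` if either eye is missing.
    """
    if left is None or right is None:
        raise IncompleteRecordError("both eyes required for classification")
    left = merge_medium_dark(left)
    right = merge_medium_dark(right)
    n_multicolor = sum(e.secondary is not None for e in (left, right))
    if n_multicolor:
        subtype = "bilateralis" if n_multicolor == 2 else "unilateralis"
        return IrisCategory("iridis", subtype)
    if left.primary != right.primary:
        return IrisCategory("iridum")
    return IrisCategory(left.primary)


def classify_table(records: pd.DataFrame) -> pd.DataFrame:
    """Classify a per-animal score table; excluded animals are dropped.

    Expects columns ``animal_id, breed, sex, farm_date, left_primary,
    left_secondary, right_primary, right_secondary`` (secondary columns
    may hold NaN). Returns a frame with ``category`` and
    ``iridis_subtype`` columns; animals with an incomplete record are
    excluded with a warning.
    """
    out_rows = []
    n_excluded = 0
    for row in records.itertuples(index=False):
        def eye(side):
            prim = getattr(row, f"{side}_primary", None)
            if prim is None or (isinstance(prim, float) and np.isnan(prim)):
                return None
            sec = getattr(row, f"{side}_secondary", None)
            if isinstance(sec, float) and np.isnan(sec):
                sec = None
            return EyeScore(str(row.animal_id), side, prim, sec)

        try:
            cat = classify_animal(eye("left"), eye("right"))
        except IncompleteRecordError:
            n_excluded += 1
            continue
        out_rows.append(
            {
                "animal_id": row.animal_id,
                "breed": getattr(row, "breed", None),
                "sex": getattr(row, "sex", None),
                "farm_date": getattr(row, "farm_date", None),
                "category": cat.category,
                "iridis_subtype": cat.iridis_subtype,
            }
        )
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} animals with incomplete eye records")
    return pd.DataFrame(out_rows)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching printed-table conventions."""
    factor = 10.0 ** decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


def _table_row(cat: str, subtype: str) -> str:
    return f"iridis {subtype}" if cat == "iridis" else cat


def prevalence_table(classified: pd.DataFrame, breeds: list[str] | None = None) -> pd.DataFrame:
    """Counts and percentages per breed per category.

    ``classified`` needs columns ``breed``, ``category`` and (for iridis
    rows) ``iridis_subtype``. Percentages are count / breed total x 100,
    printed to one decimal with half-up rounding. Aggregate rows
    (``any brown`` = dark + light brown; ``iridis`` = unilateralis +
    bilateralis) report the sum of the rounded component percentages,
    the convention of the published table.
    """
    if len(classified) == 0:
        raise ValueError("empty phenotype table")
    if breeds is not None:
        unknown = set(classified["breed"]) - set(breeds)
        if unknown:
            raise ValueError(f"unknown breed labels: {sorted(unknown)}")
    else:
        breeds = sorted(set(classified["breed"]))

    subtype = classified.get("iridis_subtype", pd.Series("none", index=classified.index))
    rows = [
        _table_row(c, s) for c, s in zip(classified["category"], subtype)
    ]
    work = pd.DataFrame({"breed": classified["breed"], "row": rows})

    out = {}
    for breed in breeds:
        sub = work[work["breed"] == breed]
        total = len(sub)
        counts = {r: int((sub["row"] == r).sum()) for r in TABLE_ROWS}
        pcts = {
            r: round_half_up(100.0 * c / total) if total else 0.0
            for r, c in counts.items()
        }
        counts["any brown"] = counts["dark brown"] + counts["light brown"]
        pcts["any brown"] = round_half_up(pcts["dark brown"] + pcts["light brown"])
        counts["iridis"] = counts["iridis unilateralis"] + counts["iridis bilateralis"]
        pcts["iridis"] = round_half_up(
            pcts["iridis unilateralis"] + pcts["iridis bilateralis"]
        )
        counts["total"] = total
        pcts["total"] = 100.0
        out[(breed, "count")] = counts
        out[(breed, "pct")] = pcts

    index = list(TABLE_ROWS) + ["any brown", "iridis", "total"]
    table = pd.DataFrame(out).loc[index]
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["breed", "stat"])
    return table


def sex_contrast_test(classified: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of category distribution across sexes.

    Returns ``(statistic, df, p_value)`` from the sex x category
    contingency table without continuity correction; zero-margin rows or
    columns are dropped with a warning.
    """
    tab = pd.crosstab(classified["sex"], classified["category"])
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    zero_cols = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero-margin levels: rows {list(zero_rows)}, cols {list(zero_cols)}"
        )
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 sex levels and >= 2 categories with nonzero margins")
    res = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cross_category_table(
    pairs: pd.DataFrame, row: str = "sow_category", col: str = "offspring_category"
) -> pd.DataFrame:
    """Row-category x column-category cross table with row percentages.

    Generic incidence summary (e.g. sow category vs offspring category):
    counts plus within-row percentages at one decimal, half-up.
    """
    counts = pd.crosstab(pairs[row], pairs[col])
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct = pct.map(round_half_up)
    return pd.concat({"count": counts, "pct": pct}, axis=1)
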