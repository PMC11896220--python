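"""Cohort construction: exclusion cascade, weight-change phenotype, covariates.

Participants contribute four annual clinic weights (Years 1-4).  The Year-2
visit is the metabolomic baseline; the phenotype is the pattern of annual
percent weight change over Years 2-4, expressed relative to the Year-2
weight.  Participants unstable before baseline (Year 1 to 2 change beyond
the threshold), non-fasting at the blood draw, missing both follow-up
weights, or with an extreme (>40%) computed change are excluded, each
tallied under the first matching reason.

The three-level phenotype (stable / gain / loss at a 3% annual threshold)
is subdivided for losers by the self-reported intention to lose weight into
intentional vs unintentional weight loss, giving the four-level outcome
used by the association screen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationConfig",
    "ExclusionTally",
    "EXCLUSION_REASONS",
    "annual_changes",
    "prior_year_change",
    "classify_weight_change",
    "assign_four_groups",
    "apply_exclusion_cascade",
    "bmi_category",
    "energy_expenditure",
    "residual_adjust",
    "prepare_cohort",
    "group_percent",
]

EXCLUSION_REASONS = (
    "non_fasting",
    "missing_both_weights",
    "prior_year_unstable",
    "extreme_change",
)

PACE_KCAL_PER_KG_H = {"brisk": 4.0, "moderate": 3.0, "strolling": 2.0}
STAIR_KCAL_PER_KG_H = 4.0
LOAD_BONUS_KCAL_PER_KG_H = 1.0


@dataclass
class ClassificationConfig:
    """Thresholds and strategy for the weight-change phenotype.

    threshold_pct: the annual percent-change cut separating stable from
    gain/loss (3% by default, chosen to exceed DXA soft-tissue CV).
    extreme_pct: computed changes beyond this magnitude mark data errors.
    strategy: 'any-interval' classifies on the per-interval changes;
    'final-visit-annualized' classifies on the single annualized change to
    the last available visit.
    """

    threshold_pct: float = 3.0
    extreme_pct: float = 40.0
    strategy: str = "any-interval"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_pct < self.extreme_pct:
            raise ValueError("need 0 < threshold_pct < extreme_pct")
        if self.strategy not in {"any-interval", "final-visit-annualized"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class ExclusionTally:
    """Audit of the exclusion funnel: first-matching-reason counts."""

    counts: dict = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    n_input: int = 0
    n_included: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def check(self) -> None:
        if self.n_input != self.n_included + self.n_excluded:
            raise AssertionError("exclusion tally does not conserve records")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_included": self.n_included,
                    "n_excluded": self.n_excluded,
                    "counts": self.counts,
                },
                fh,
                indent=2,
            )


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def annual_changes(w2: float, w3: float, w4: float) -> list[float]:
    """Per-interval percent weight changes relative to the Year-2 weight.

    Both intervals are expressed against W2: 100*(W3-W2)/W2 and
    100*(W4-W3)/W2.  If W3 is missing but W4 present, the single
    annualized change 100*(W4-W2)/(2*W2) is returned.  Empty list when
    neither follow-up weight exists.
    """
    if _missing(w2) or w2 <= 0:
        raise ValueError("Year-2 weight required (record should be excluded)")
    if _missing(w3):
        if _missing(w4):
            return []
        return [100.0 * (w4 - w2) / (2.0 * w2)]
    changes = [100.0 * (w3 - w2) / w2]
    if not _missing(w4):
        changes.append(100.0 * (w4 - w3) / w2)
    return changes


def prior_year_change(w1: float, w2: float) -> float | None:
    """Percent change from Year 1 to Year 2, relative to Year 1."""
    if _missing(w1) or _missing(w2):
        return None
    return 100.0 * (w2 - w1) / w1


def classify_weight_change(
    changes: list[float],
    config: ClassificationConfig | None = None,
    net_change: float | None = None,
) -> str:
    """Three-level label from the annual percent changes.

    any-interval: loss if some change < -t and none > +t; gain mirrored;
    all |change| <= t -> stable.  A trajectory with both a gain and a loss
    interval is resolved by the sign of the net Year-2-to-last change
    (|net| <= t -> stable).  final-visit-annualized: classify the single
    annualized change to the last visit.
    """
    config = config or ClassificationConfig()
    t = config.threshold_pct
    if not changes:
        raise ValueError("no follow-up changes to classify")
    if config.strategy == "final-visit-annualized":
        if net_change is None:
            # changes relative to W2: net to last visit is their sum,
            # annualized over the number of intervals observed
            net_change = sum(changes) / len(changes)
        c = net_change
        return "loss" if c < -t else "gain" if c > t else "stable"
    has_loss = any(c < -t for c in changes)
    has_gain = any(c > t for c in changes)
    if has_loss and has_gain:
        net = sum(changes) if net_change is None else net_change
        return "loss" if net < -t else "gain" if net > t else "stable"
    if has_loss:
        return "loss"
    if has_gain:
        return "gain"
    return "stable"


def assign_four_groups(group: str, intention) -> str | None:
    """Subdivide loss by the baseline intention-to-lose-weight flag.

    Losers with a missing intention cannot be placed and return None
    (complete-case in four-group analyses).
    """
    if group != "loss":
        return group
    if _missing(intention):
        return None
    return "intentional_loss" if bool(intention) else "unintentional_loss"


def _first_reason(row: pd.Series, config: ClassificationConfig) -> str | None:
    if not bool(row["fasting"]):
        return "non_fasting"
    if _missing(row.get("weight_y3")) and _missing(row.get("weight_y4")):
        return "missing_both_weights"
    prior = prior_year_change(row.get("weight_y1"), row.get("weight_y2"))
    if prior is not None and abs(prior) > config.threshold_pct:
        return "prior_year_unstable"
    changes = annual_changes(
        row.get("weight_y2"), row.get("weight_y3"), row.get("weight_y4")
    )
    if any(abs(c) > config.extreme_pct for c in changes):
        return "extreme_change"
    return None


def apply_exclusion_cascade(
    records: pd.DataFrame, config: ClassificationConfig | None = None
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Drop ineligible records; tally each under its first matching reason.

    Order: non-fasting; missing both Year-3 and Year-4 weights; prior-year
    (Year 1 to 2) change beyond threshold_pct; any computed follow-up
    change beyond extreme_pct.
    """
    config = config or ClassificationConfig()
    tally = ExclusionTally(n_input=len(records))
    reasons = records.apply(_first_reason, axis=1, args=(config,))
    for r in EXCLUSION_REASONS:
        tally.counts[r] = int((reasons == r).sum())
    included = records.loc[reasons.isna()].copy()
    tally.n_included = len(included)
    tally.check()
    return included, tally


def bmi_category(weight_kg: float, height_cm: float) -> str:
    """BMI class: '<25', '25-30' (half-open [25,30)), or '>=30' kg/m^2."""
    if _missing(weight_kg) or _missing(height_cm):
        return None
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    if bmi < 25.0:
        return "<25"
    if bmi < 30.0:
        return "25-30"
    return ">=30"


def energy_expenditure(
    walk_pace: str,
    walk_hours_per_week: float,
    stair_hours_per_week: float,
    carries_load: bool,
) -> float:
    """Weekly walking + stair-climbing energy expenditure in kcal/kg/week.

    MET-style coefficients: 4.0 kcal/kg/h brisk walking, 3.0 moderate,
    2.0 strolling; stair climbing 4.0 plus 1.0 when routinely carrying a
    load (laundry, groceries, an infant).
    """
    if walk_hours_per_week < 0 or stair_hours_per_week < 0:
        raise ValueError("hours must be non-negative")
    if walk_pace not in PACE_KCAL_PER_KG_H:
        raise ValueError(f"unknown walking pace {walk_pace!r}")
    stair_coef = STAIR_KCAL_PER_KG_H + (
        LOAD_BONUS_KCAL_PER_KG_H if carries_load else 0.0
    )
    return (
        PACE_KCAL_PER_KG_H[walk_pace] * walk_hours_per_week
        + stair_coef * stair_hours_per_week
    )


def residual_adjust(nutrient: pd.Series, energy: pd.Series) -> pd.Series:
    """Energy-adjust a nutrient intake by the residual method.

    OLS of nutrient (g/day) on total energy (kcal/day) with intercept over
    complete pairs; the adjusted value is the residual re-centered at the
    sample mean of the nutrient.  Missing pairs stay missing.
    """
    ok = nutrient.notna() & energy.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    x = energy[ok].to_numpy(float)
    y = nutrient[ok].to_numpy(float)
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("energy has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    out = pd.Series(np.nan, index=nutrient.index, dtype=float)
    out[ok] = y - (intercept + slope * x) + y.mean()
    return out


def prepare_cohort(
    records: pd.DataFrame, config: ClassificationConfig | None = None
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Full preparation: exclusions, phenotype labels, derived covariates.

    Returns the labeled analysis table (group, four_group, bmi, bmi_cat,
    ee_kcal_kg_wk, energy-adjusted protein/fat) and the exclusion tally.
    """
    config = config or ClassificationConfig()
    included, tally = apply_exclusion_cascade(records, config)
    cohort = included.copy()

    groups, four = [], []
    for _, row in cohort.iterrows():
        changes = annual_changes(
            row.get("weight_y2"), row.get("weight_y3"), row.get("weight_y4")
        )
        g = classify_weight_change(changes, config)
        groups.append(g)
        four.append(assign_four_groups(g, row.get("intention")))
    cohort["group"] = groups
    cohort["four_group"] = four

    cohort["bmi"] = cohort["weight_y2"] / (cohort["height_cm"] / 100.0) ** 2
    cohort["bmi_cat"] = [
        bmi_category(w, h)
        for w, h in zip(cohort["weight_y2"], cohort["height_cm"])
    ]
    if {"walk_pace", "walk_hours", "stair_hours", "carries_load"} <= set(
        cohort.columns
    ):
        cohort["ee_kcal_kg_wk"] = [
            energy_expenditure(p, wh, sh, bool(cl))
            for p, wh, sh, cl in zip(
                cohort["walk_pace"],
                cohort["walk_hours"],
                cohort["stair_hours"],
                cohort["carries_load"],
            )
        ]
    if {"protein_g", "calories_kcal"} <= set(cohort.columns):
        cohort["protein_adj_g"] = residual_adjust(
            cohort["protein_g"], cohort["calories_kcal"]
        )
    if {"fat_g", "calories_kcal"} <= set(cohort.columns):
        cohort["fat_adj_g"] = residual_adjust(
            cohort["fat_g"], cohort["calories_kcal"]
        )
    return cohort, tally


def group_percent(
    cohort: pd.DataFrame, group: str, column: str, level
) -> float:
    """Percent of a four-group category with the given covariate level.

    E.g. the share of unintentional-loss participants in the '<25' BMI
    class, as printed in a characteristics table.
    """
    sub = cohort.loc[cohort["four_group"] == group, column].dropna()
    if len(sub) == 0:
        raise ValueError(f"no participants in group {group!r}")
    return 100.0 * float((sub == level).sum()) / float(len(sub))
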