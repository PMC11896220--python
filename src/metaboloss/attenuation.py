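"""Confounder attenuation of metabolite-weight-change associations.

For each metabolite significantly associated with a contrast (by default
unintentional weight loss vs weight stable) in the age/sex/race/BMI model,
the difference-of-coefficients ledger quantifies how much of the
association each candidate risk-factor block explains:

    percent attenuation = 100 * (b1 - b2) / b1,

where b1 is the metabolite's log-odds per SD from the base (M_bmi) model
and b2 the coefficient after additionally adjusting for the block.  Both
models are refit on the intersection of their complete cases so b1 and b2
always come from the same participants.  Values can be negative
(adjustment strengthens the association) or exceed 100 (sign flip); they
are reported unclipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multinomial_mwas import screen_metabolites

__all__ = [
    "ConfounderSet",
    "CONFOUNDER_SETS",
    "percent_attenuation",
    "attenuation_ledger",
    "summarize_attenuation",
]


@dataclass(frozen=True)
class ConfounderSet:
    name: str
    columns: tuple


_BLOCKS = {
    "smoking": ("smoking",),
    "energy_expenditure": ("ee_kcal_kg_wk",),
    "pct_body_fat": ("pct_body_fat",),
    "total_body_fat": ("total_body_fat_kg",),
    "thigh_muscle_area": ("thigh_muscle_cm2",),
    "appetite": ("appetite",),
    "hei": ("hei",),
    "calories": ("calories_kcal",),
    "protein_fat_residuals": ("protein_adj_g", "fat_adj_g"),
    "crp": ("crp_ug_ml",),
    "il6": ("il6_pg_ml",),
    "crp_il6": ("crp_ug_ml", "il6_pg_ml"),
    "diseases": ("cvd", "hypertension", "cancer", "diabetes", "pulmonary"),
    "diabetes": ("diabetes",),
    "medications": ("n_medications",),
}
# the fully adjusted block: everything except total body fat, which is too
# collinear with the BMI categories already in the base model
_FULL = tuple(
    dict.fromkeys(
        c
        for name, cols in _BLOCKS.items()
        if name != "total_body_fat"
        for c in cols
    )
)

CONFOUNDER_SETS: dict[str, ConfounderSet] = {
    **{n: ConfounderSet(n, cols) for n, cols in _BLOCKS.items()},
    "full": ConfounderSet("full", _FULL),
}


def percent_attenuation(beta1: float, beta2: float) -> float:
    """100*(b1-b2)/b1; undefined (ZeroDivisionError) when |b1| < 1e-6."""
    if abs(beta1) < 1e-6:
        raise ZeroDivisionError("base coefficient ~0: attenuation undefined")
    return 100.0 * (beta1 - beta2) / beta1


def attenuation_ledger(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    significant: list[str],
    sets: list[ConfounderSet] | None = None,
    contrast: str = "unintentional_loss",
    base_set: str = "M_bmi",
) -> pd.DataFrame:
    """(metabolite, confounder set) table of b1, b2 and percent attenuation.

    For each pair, the base model and the base+block model are refit on
    the intersection of their complete cases.  Non-converged pairs are
    flagged and excluded from summaries.
    """
    if sets is None:
        sets = list(CONFOUNDER_SETS.values())
    rows = []
    n_failed = 0
    for cs in sets:
        cols = [c for c in cs.columns if c in cohort.columns]
        if len(cols) < len(cs.columns):
            missing = set(cs.columns) - set(cols)
            warnings.warn(f"set {cs.name!r}: missing columns {missing}; skipped")
            continue
        subset = cohort[cols].notna().all(axis=1) if cols else None
        base = screen_metabolites(
            processed[significant], cohort, covariate_set=base_set,
            subset=subset,
        )
        adj = screen_metabolites(
            processed[significant], cohort, covariate_set=base_set,
            extra_terms=cols, subset=subset,
        )
        b1 = base[base["contrast"] == contrast].set_index("metabolite")
        b2 = adj[adj["contrast"] == contrast].set_index("metabolite")
        for met in significant:
            beta1 = float(b1.loc[met, "beta"])
            beta2 = float(b2.loc[met, "beta"])
            ok = bool(b1.loc[met, "converged"] and b2.loc[met, "converged"])
            undefined = abs(beta1) < 1e-6
            if not ok:
                n_failed += 1
            rows.append(
                {
                    "metabolite": met,
                    "set": cs.name,
                    "beta1": beta1,
                    "beta2": beta2,
                    "pct": (
                        np.nan
                        if undefined or not ok
                        else percent_attenuation(beta1, beta2)
                    ),
                    "n": int(b1.loc[met, "n"]),
                    "undefined": undefined,
                    "converged": ok,
                }
            )
    if n_failed:
        warnings.warn(f"{n_failed} attenuation fits did not converge")
    return pd.DataFrame(rows)


def summarize_attenuation(
    entries: pd.DataFrame, flag_threshold: float = 20.0
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-set median and IQR of percent attenuation, plus flagged lists.

    Quartiles use linear interpolation between order statistics.  The
    flagged list per set holds metabolites with pct > flag_threshold,
    sorted by pct descending.  Sets with no defined entries are omitted
    with a warning.
    """
    summaries = []
    flagged: dict[str, list[str]] = {}
    for name, grp in entries.groupby("set", sort=False):
        vals = grp["pct"].dropna()
        if len(vals) == 0:
            warnings.warn(f"set {name!r}: no defined attenuations; omitted")
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        over = grp.dropna(subset=["pct"])
        over = over[over["pct"] > flag_threshold].sort_values(
            "pct", ascending=False
        )
        flagged[name] = list(over["metabolite"])
        summaries.append(
            {
                "set": name,
                "median": med,
                "q25": q25,
                "q75": q75,
                "n_defined": len(vals),
                "n_flagged": len(over),
            }
        )
    return pd.DataFrame(summaries), flagged
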