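"""Metabolite feature QC, LOD imputation, duplicate resolution, scaling.

LC-MS peak-area features pass a two-part filter — quantified in at least
90% of participants and a QC-pool coefficient of variation of at most 10%
— then blanks (below detection) are imputed as half the feature's minimum
detected value.  Metabolites measured on more than one chromatography
platform are collapsed to one column (lipid-platform copy preferred for
lipids, lowest-CV copy otherwise), and the retained columns are
log-transformed and z-scored over the analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLATFORM_ORDER",
    "QCThresholds",
    "compute_feature_qc",
    "filter_features",
    "impute_lod",
    "resolve_duplicates",
    "log_standardize",
    "process_metabolites",
]

PLATFORM_ORDER = ("lipid", "polar-pos", "polar-neg", "intermediate-polarity")


@dataclass
class QCThresholds:
    min_detect: float = 0.90
    max_cv: float = 0.10


def compute_feature_qc(
    matrix: pd.DataFrame, qc_replicates: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature detection fraction (participants) and CV (QC pool).

    CV = sample SD / mean over the QC replicates (ddof=1).  Requires at
    least two replicates and a positive replicate mean per feature.
    """
    if len(qc_replicates) < 2:
        raise ValueError("need >=2 QC replicates per feature")
    missing_qc = [c for c in matrix.columns if c not in qc_replicates.columns]
    if missing_qc:
        raise KeyError(f"features without QC replicates: {missing_qc[:5]}")
    detect = matrix.notna().mean(axis=0)
    reps = qc_replicates[matrix.columns]
    means = reps.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"non-positive QC replicate mean for {bad[:5]}")
    cv = reps.std(axis=0, ddof=1) / means
    return pd.DataFrame(
        {
            "detect_frac": detect,
            "cv": cv,
            "n_missing": matrix.isna().sum(axis=0),
            "min_detected": matrix.min(axis=0),
        }
    )


def filter_features(
    qc: pd.DataFrame, min_detect: float = 0.90, max_cv: float = 0.10
) -> list:
    """Features kept iff detect_frac >= min_detect and cv <= max_cv."""
    keep = (qc["detect_frac"] >= min_detect) & (qc["cv"] <= max_cv)
    return list(qc.index[keep])


def impute_lod(values: pd.Series | pd.DataFrame):
    """Replace blanks with 50% of the lowest detected value per feature."""
    if isinstance(values, pd.DataFrame):
        return values.apply(impute_lod, axis=0)
    if values.notna().sum() == 0:
        raise ValueError(f"feature {values.name!r} has no detected values")
    return values.fillna(0.5 * values.min())


def resolve_duplicates(
    meta: pd.DataFrame, significant_set: set | None = None
) -> list:
    """Pick one platform copy per metabolite name.

    Lipids keep the lipid-platform copy when one exists; otherwise the
    lowest-CV copy wins, with ties broken by the fixed platform order.
    ``meta`` is indexed by feature_id with columns metabolite_name,
    platform, is_lipid and cv.  ``significant_set``, when given, restricts
    resolution to those names (others resolved identically for
    determinism — resolution is applied to all names regardless).
    """
    rank = {p: i for i, p in enumerate(PLATFORM_ORDER)}
    kept = []
    for _, grp in meta.groupby("metabolite_name", sort=True):
        if len(grp) == 1:
            kept.append(grp.index[0])
            continue
        cand = grp
        if bool(grp["is_lipid"].any()):
            on_lipid = grp[grp["platform"] == "lipid"]
            if len(on_lipid):
                cand = on_lipid
        order = cand.assign(_rank=cand["platform"].map(rank)).sort_values(
            ["cv", "_rank"], kind="mergesort"
        )
        kept.append(order.index[0])
    return kept


def log_standardize(values: pd.Series | pd.DataFrame):
    """Natural log then z-score (mean 0, SD 1 with ddof=1) per feature."""
    if isinstance(values, pd.DataFrame):
        return values.apply(log_standardize, axis=0)
    x = values.astype(float)
    if (x <= 0).any():
        raise ValueError(f"non-positive peak area in {values.name!r}")
    logged = np.log(x)
    sd = logged.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"degenerate (zero-variance) feature {values.name!r}")
    return (logged - logged.mean()) / sd


def process_metabolites(
    matrix: pd.DataFrame,
    feature_meta: pd.DataFrame,
    qc_replicates: pd.DataFrame,
    min_detect: float = 0.90,
    max_cv: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC pipeline: filter -> impute -> resolve duplicates -> z-score.

    Returns (processed matrix with one column per retained unique
    metabolite name, feature QC table annotated with retention flags).
    """
    qc = compute_feature_qc(matrix, qc_replicates)
    retained = filter_features(qc, min_detect, max_cv)
    qc["passed_filter"] = qc.index.isin(retained)
    imputed = impute_lod(matrix[retained])
    qc["n_imputed"] = 0
    qc.loc[retained, "n_imputed"] = matrix[retained].isna().sum(axis=0)
    meta = feature_meta.loc[retained].join(qc[["cv"]])
    resolved = resolve_duplicates(meta)
    qc["resolved"] = qc.index.isin(resolved)
    processed = log_standardize(imputed[resolved])
    processed.columns = [
        feature_meta.loc[f, "metabolite_name"] for f in resolved
    ]
    processed = processed.reindex(sorted(processed.columns), axis=1)
    return processed, qc
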