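"""Synthetic cohort generator with planted ground truth.

Emulates the data structures of a longitudinal aging cohort with LC-MS
plasma metabolomics: four annual weights with group-consistent
trajectories, a baseline intention-to-lose-weight flag, log-normal peak
areas with feature-specific below-detection censoring, duplicate features
across chromatography platforms, QC-pool replicates with controlled CV,
latent confounders loading on both metabolites and outcome, and planted
per-metabolite log-odds effects.

Generative model
----------------
Confounders C_ic are standard normal.  Feature j on the log scale is
``log m_ij = mu_j + sum_c lambda_cj C_ic + eps_ij`` with eps ~ N(0,1); the
standardized latent value is ``z_ij = (log m_ij - mu_j)/sd_j``.  The
four-level outcome (reference: weight stable) follows a multinomial logit
with linear predictor for category k

    eta_ik = base_k + sum_j beta_jk z_ij + sum_c gamma_ck C_ic,

and the weight trajectory is then drawn to be consistent with the assigned
group (stable: both annual changes uniform in (-2,+2)%; loss: one change
uniform in (-8,-3.2)% and the other within (-2,+2)%; gain mirrored).  The
Year-1-to-2 change is kept within +/-3% so every participant passes the
prior-stability screen unless the config plants exclusions.

Every table gets its own pseudo-random stream keyed by (seed, table), and
metabolite features get per-feature substreams, so enlarging the feature
panel never perturbs participant draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort_prep
from .multinomial_mwas import fit_multinomial

__all__ = [
    "CONTRAST_ORDER",
    "Confounder",
    "SyntheticConfig",
    "TruthRecord",
    "generate_cohort",
    "write_tables",
    "attenuation_oracle",
    "null_config",
]

GROUPS = ("stable", "gain", "intentional_loss", "unintentional_loss")
CONTRAST_ORDER = ("gain", "intentional_loss", "unintentional_loss")

# stream keys: one stream per output table
_STREAM = {
    "participants": 0,
    "groups": 1,
    "metabolites": 2,
    "qc": 3,
    "intention": 4,
    "exclusions": 5,
}

#: base logits vs weight stable implied by the reference cohort's group
#: sizes (980 stable / 237 gain / 99 intentional / 220 unintentional)
DEFAULT_BASE_LOGITS = {
    "gain": float(np.log(237 / 980)),
    "intentional_loss": float(np.log(99 / 980)),
    "unintentional_loss": float(np.log(220 / 980)),
}

_PLATFORM_CYCLE = ("lipid", "polar-pos", "polar-neg", "intermediate-polarity")
_LIPID_SUBCLASSES = (
    "Triradylcglycerols",
    "Glycerophosphocholines",
    "Phosphosphingolipids",
    "Steryl esters",
)
_POLAR_CLASSES = (
    ("Organic acids and derivatives", "Amino acids, peptides, and analogues"),
    ("Organic oxygen compounds", "Carbohydrates and conjugates"),
    ("Nucleosides, nucleotides, and analogues", "Purine nucleotides"),
    ("Organoheterocyclic compounds", "Xanthines"),
)


@dataclass
class Confounder:
    """A latent factor loading on designated features and on the outcome.

    loading is the per-feature lambda on the log-metabolite scale; gamma
    maps contrast labels to the factor's log-odds effect per SD.
    """

    name: str
    features: tuple = ()
    loading: float = 0.0
    gamma: dict = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated cohort.

    planted_effects: (feature index, contrast label, log-odds per SD).
    lod_quantile: default per-feature censoring quantile; features meant
    to fail the >=90% detection filter take an override >= 0.10.
    duplicate_spec: (feature index, second platform, extra CV) tuples.
    weight_noise_sd: percent spread (lognormal SD x100) of baseline BMI
    across participants.
    """

    n_participants: int = 2000
    n_features: int = 150
    n_causal: int | None = None
    planted_effects: tuple = ()
    confounders: tuple = ()
    group_base_logits: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOGITS)
    )
    intention_prob_given_loss: float = 0.31
    lod_quantile: float = 0.02
    lod_overrides: dict = field(default_factory=dict)
    duplicate_spec: tuple = ()
    qc_replicates: int = 6
    qc_cv_range: tuple = (0.01, 0.08)
    qc_cv_overrides: dict = field(default_factory=dict)
    weight_noise_sd: float = 17.0
    planted_exclusions: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal is None:
            self.n_causal = len(
                {f for f, _, _ in self.planted_effects}
            )
        self.validate()

    def validate(self) -> None:
        if self.n_causal > self.n_features:
            raise ValueError("n_causal exceeds n_features")
        for f, contrast, beta in self.planted_effects:
            if not 0 <= f < self.n_features:
                raise ValueError(f"planted feature index {f} out of range")
            if contrast not in CONTRAST_ORDER:
                raise ValueError(f"unknown contrast {contrast!r}")
            if not np.isfinite(beta):
                raise ValueError(f"non-finite planted effect for feature {f}")
        for c in self.confounders:
            for f in c.features:
                if not 0 <= f < self.n_features:
                    raise ValueError(
                        f"confounder {c.name!r} loads on feature {f} "
                        "out of range"
                    )
        if not 0 <= self.intention_prob_given_loss <= 1:
            raise ValueError("intention probability outside [0,1]")
        for qv in [self.lod_quantile, *self.lod_overrides.values()]:
            if not 0 <= qv < 1:
                raise ValueError("lod quantiles must lie in [0,1)")
        lo, hi = self.qc_cv_range
        if not 0 <= lo <= hi:
            raise ValueError("bad qc_cv_range")


@dataclass
class TruthRecord:
    """Ground truth for one generated cohort."""

    assigned_group: pd.Series
    planted: dict  # (feature_id, contrast) -> beta
    confounders: pd.DataFrame
    censor_thresholds: pd.Series
    latent_z: pd.DataFrame  # tracked (planted/confounded) features only
    intention: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "planted": {f"{fid}|{c}": b for (fid, c), b in self.planted.items()},
            "censor_thresholds": self.censor_thresholds.to_dict(),
            "group_counts": self.assigned_group.value_counts().to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rng(seed: int, table: str, sub: int | None = None) -> np.random.Generator:
    key = [seed, _STREAM[table]]
    if sub is not None:
        key.append(sub)
    return np.random.default_rng(np.random.SeedSequence(key))


def _feature_names(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for j in range(config.n_features):
        platform = _PLATFORM_CYCLE[j % 4]
        if platform == "lipid":
            cls = "Lipids and lipid-like molecules"
            sub = _LIPID_SUBCLASSES[(j // 4) % len(_LIPID_SUBCLASSES)]
        else:
            cls, sub = _POLAR_CLASSES[(j // 4) % len(_POLAR_CLASSES)]
        name = f"met_{j:04d}"
        rows.append(
            {
                "feature_id": f"{name}@{platform}",
                "metabolite_name": name,
                "platform": platform,
                "hmdb_class": cls,
                "hmdb_subclass": sub,
                "is_lipid": cls.startswith("Lipids"),
                "index": j,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def _draw_trajectories(
    groups: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Two annual percent changes (relative to W2) consistent with group."""
    n = len(groups)
    deltas = rng.uniform(-2.0, 2.0, size=(n, 2))
    which = rng.integers(0, 2, size=n)
    mag = rng.uniform(3.2, 8.0, size=n)
    for i, g in enumerate(groups):
        if g == "gain":
            deltas[i, which[i]] = mag[i]
        elif g in ("intentional_loss", "unintentional_loss"):
            deltas[i, which[i]] = -mag[i]
    return deltas


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (participants, metabolites, qc_replicates, truth).

    Deterministic in (config, seed); seed defaults to config.seed.
    """
    seed = config.seed if seed is None else seed
    n = config.n_participants
    ids = pd.Index([f"P{i:06d}" for i in range(n)], name="id")

    # --- participants stream: demographics, anthropometry, lifestyle ---
    rng = _rng(seed, "participants")
    age = np.round(rng.normal(74.7, 2.9, n), 1)
    sex = np.where(rng.random(n) < 0.50, "men", "women")
    race = np.where(rng.random(n) < 0.35, "Black", "White")
    height = np.where(
        sex == "men", rng.normal(173.0, 6.5, n), rng.normal(160.0, 6.0, n)
    )
    bmi = 27.1 * np.exp(rng.normal(0.0, config.weight_noise_sd / 100.0, n))
    w2 = bmi * (height / 100.0) ** 2
    prior = rng.uniform(-2.9, 2.9, n)
    w1 = w2 / (1.0 + prior / 100.0)
    smoking = (rng.random(n) < 0.08).astype(int)
    pct_fat = rng.normal(34.9, 7.6, n)
    total_fat = rng.normal(26.7, 8.5, n)
    thigh = rng.normal(224.7, 55.9, n)
    appetite = rng.choice(
        ["very good", "good", "moderate/poor/fluctuating"],
        size=n,
        p=[0.44, 0.38, 0.18],
    )
    hei = rng.normal(70.3, 11.9, n)
    calories = np.exp(rng.normal(np.log(1744.0), 0.33, n))
    protein = 0.038 * calories + rng.normal(0.0, 8.0, n)
    fat = 0.040 * calories + rng.normal(0.0, 10.0, n)
    il6 = np.exp(rng.normal(np.log(2.2), 0.55, n))
    crp = np.exp(rng.normal(np.log(3.0), 0.80, n))
    cvd = (rng.random(n) < 0.27).astype(int)
    htn = (rng.random(n) < 0.52).astype(int)
    diabetes = (rng.random(n) < 0.39).astype(int)
    cancer = (rng.random(n) < 0.18).astype(int)
    pulmonary = (rng.random(n) < 0.11).astype(int)
    meds = rng.poisson(2.5, n)
    walk_pace = rng.choice(
        ["brisk", "moderate", "strolling"], size=n, p=[0.25, 0.50, 0.25]
    )
    walk_hours = np.round(rng.exponential(1.5, n), 1)
    stair_hours = np.round(rng.exponential(0.5, n), 1)
    carries_load = (rng.random(n) < 0.30).astype(int)

    # --- confounders and latent metabolite signal ---
    conf_rng = _rng(seed, "groups")
    C = pd.DataFrame(
        {c.name: conf_rng.standard_normal(n) for c in config.confounders},
        index=ids,
    )
    meta = _feature_names(config)
    load = np.zeros((len(config.confounders), config.n_features))
    for ci, c in enumerate(config.confounders):
        for f in c.features:
            load[ci, f] = c.loading
    sd_j = np.sqrt(1.0 + (load**2).sum(axis=0))
    mu = np.empty(config.n_features)
    logm = np.empty((n, config.n_features))
    for j in range(config.n_features):
        frng = _rng(seed, "metabolites", j)
        mu[j] = frng.uniform(np.log(1e4), np.log(1e6))
        eps = frng.standard_normal(n)
        logm[:, j] = mu[j] + eps
    if len(config.confounders):
        logm += C.to_numpy() @ load
    z = (logm - mu) / sd_j

    # --- outcome draw: multinomial logit with planted effects ---
    eta = np.zeros((n, len(CONTRAST_ORDER)))
    for k, contrast in enumerate(CONTRAST_ORDER):
        eta[:, k] = config.group_base_logits[contrast]
        for fidx, ctr, beta in config.planted_effects:
            if ctr == contrast:
                eta[:, k] += beta * z[:, fidx]
        for ci, c in enumerate(config.confounders):
            g = c.gamma.get(contrast, 0.0)
            if g:
                eta[:, k] += g * C.to_numpy()[:, ci]
    if not np.all(np.isfinite(eta)):
        bad = np.where(~np.isfinite(eta).all(axis=0))[0]
        raise FloatingPointError(
            f"non-finite linear predictor for contrast(s) {bad}: "
            "planted effects too extreme"
        )
    probs = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    probs -= probs.max(axis=1, keepdims=True)
    probs = np.exp(probs)
    probs /= probs.sum(axis=1, keepdims=True)
    u = conf_rng.random(n)
    codes = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    groups = np.array(GROUPS, dtype=object)[codes]

    # --- trajectories consistent with assigned group ---
    deltas = _draw_trajectories(groups, conf_rng)
    w3 = w2 * (1.0 + deltas[:, 0] / 100.0)
    w4 = w3 + w2 * deltas[:, 1] / 100.0

    # --- intention: determined by loss subgroup, background rate elsewhere ---
    irng = _rng(seed, "intention")
    background = irng.random(n) < config.intention_prob_given_loss
    intention = np.where(
        groups == "intentional_loss",
        True,
        np.where(groups == "unintentional_loss", False, background),
    ).astype(bool)

    participants = pd.DataFrame(
        {
            "fasting": True,
            "weight_y1": w1,
            "weight_y2": w2,
            "weight_y3": w3,
            "weight_y4": w4,
            "height_cm": height,
            "intention": intention,
            "age": age,
            "sex": sex,
            "race": race,
            "smoking": smoking,
            "pct_body_fat": pct_fat,
            "total_body_fat_kg": total_fat,
            "thigh_muscle_cm2": thigh,
            "appetite": appetite,
            "hei": hei,
            "calories_kcal": calories,
            "protein_g": protein,
            "fat_g": fat,
            "il6_pg_ml": il6,
            "crp_ug_ml": crp,
            "cvd": cvd,
            "hypertension": htn,
            "diabetes": diabetes,
            "cancer": cancer,
            "pulmonary": pulmonary,
            "n_medications": meds,
            "walk_pace": walk_pace,
            "walk_hours": walk_hours,
            "stair_hours": stair_hours,
            "carries_load": carries_load,
        },
        index=ids,
    )
    participants = pd.concat([participants, C], axis=1)

    # --- planted exclusions occupy the leading rows, disjoint by reason ---
    excl = config.planted_exclusions
    erng = _rng(seed, "exclusions")
    pos = 0
    for _ in range(excl.get("non_fasting", 0)):
        participants.iloc[pos, participants.columns.get_loc("fasting")] = False
        pos += 1
    for _ in range(excl.get("missing_both_weights", 0)):
        participants.iloc[
            pos, participants.columns.get_loc("weight_y3")
        ] = np.nan
        participants.iloc[
            pos, participants.columns.get_loc("weight_y4")
        ] = np.nan
        pos += 1
    for _ in range(excl.get("prior_year_unstable", 0)):
        r = erng.uniform(3.5, 8.0) * erng.choice([-1.0, 1.0])
        w2i = participants.iloc[pos]["weight_y2"]
        participants.iloc[pos, participants.columns.get_loc("weight_y1")] = (
            w2i / (1.0 + r / 100.0)
        )
        pos += 1
    for _ in range(excl.get("extreme_change", 0)):
        w2i = participants.iloc[pos]["weight_y2"]
        participants.iloc[pos, participants.columns.get_loc("weight_y3")] = (
            0.5 * w2i
        )
        pos += 1

    # --- observed metabolite matrix: censor, add platform duplicates ---
    thresholds = np.exp(mu + sd_j * stats.norm.ppf(
        np.array(
            [
                config.lod_overrides.get(j, config.lod_quantile)
                for j in range(config.n_features)
            ]
        )
    ))
    raw = np.exp(logm)
    observed = np.where(raw < thresholds, np.nan, raw)
    matrix = pd.DataFrame(observed, index=ids, columns=meta.index)
    censor = pd.Series(thresholds, index=meta.index, name="censor_threshold")

    dup_meta_rows = []
    for di, (fidx, platform, cv_extra) in enumerate(config.duplicate_spec):
        src = meta.index[fidx]
        name = meta.loc[src, "metabolite_name"]
        dup_id = f"{name}@{platform}"
        drng = _rng(seed, "metabolites", config.n_features + di)
        sigma = np.sqrt(np.log1p(cv_extra**2))
        vals = raw[:, fidx] * np.exp(drng.normal(0.0, sigma, n))
        matrix[dup_id] = np.where(vals < thresholds[fidx], np.nan, vals)
        censor[dup_id] = thresholds[fidx]
        dup_meta_rows.append(
            {
                "feature_id": dup_id,
                "metabolite_name": name,
                "platform": platform,
                "hmdb_class": meta.loc[src, "hmdb_class"],
                "hmdb_subclass": meta.loc[src, "hmdb_subclass"],
                "is_lipid": meta.loc[src, "is_lipid"],
                "index": config.n_features + di,
            }
        )
    if dup_meta_rows:
        meta = pd.concat(
            [meta, pd.DataFrame(dup_meta_rows).set_index("feature_id")]
        )

    # --- QC-pool replicates with controlled per-feature CV ---
    qrng = _rng(seed, "qc")
    cv_targets = {}
    for j, fid in enumerate(matrix.columns):
        if j < config.n_features:
            base_cv = config.qc_cv_overrides.get(
                j, float(qrng.uniform(*config.qc_cv_range))
            )
        else:  # duplicate feature: inflate the source CV
            fidx, _, cv_extra = config.duplicate_spec[j - config.n_features]
            base_cv = cv_targets[matrix.columns[fidx]] + cv_extra
        cv_targets[fid] = base_cv
    qc_rows = np.empty((config.qc_replicates, matrix.shape[1]))
    for j, fid in enumerate(matrix.columns):
        frng = _rng(seed, "qc", j)
        sigma = np.sqrt(np.log1p(cv_targets[fid] ** 2))
        gm = np.exp(mu[j if j < config.n_features
                       else config.duplicate_spec[j - config.n_features][0]])
        qc_rows[:, j] = gm * np.exp(
            frng.normal(0.0, sigma, config.qc_replicates)
        )
    qc_replicates = pd.DataFrame(
        qc_rows,
        index=[f"QCpool_{r + 1}" for r in range(config.qc_replicates)],
        columns=matrix.columns,
    )

    tracked = sorted(
        {f for f, _, _ in config.planted_effects}
        | {f for c in config.confounders for f in c.features}
    )
    latent_z = pd.DataFrame(
        {meta.index[j]: z[:, j] for j in tracked}, index=ids
    )
    truth = TruthRecord(
        assigned_group=pd.Series(groups, index=ids, name="assigned_group"),
        planted={
            (meta.index[f], c): b for f, c, b in config.planted_effects
        },
        confounders=C,
        censor_thresholds=censor,
        latent_z=latent_z,
        intention=pd.Series(intention, index=ids, name="intention"),
    )
    # feature_meta travels with the matrix via attrs (also written to disk)
    matrix.attrs["feature_meta"] = meta.drop(columns=["index"])
    return participants, matrix, qc_replicates, truth


def write_tables(
    outdir,
    participants: pd.DataFrame,
    matrix: pd.DataFrame,
    qc_replicates: pd.DataFrame,
    truth: TruthRecord,
) -> None:
    """Write participants/metabolites/feature_meta/qc/truth to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    participants.to_csv(out / "participants.tsv", sep="\t")
    matrix.to_csv(out / "metabolites.tsv", sep="\t")
    matrix.attrs["feature_meta"].to_csv(out / "feature_meta.tsv", sep="\t")
    qc_replicates.to_csv(out / "qc_replicates.tsv", sep="\t")
    truth.to_json(out / "truth.json")


def null_config(
    n_participants: int = 2000, n_features: int = 400, **kwargs
) -> SyntheticConfig:
    """A no-signal configuration (all planted effects and confounders off)."""
    return SyntheticConfig(
        n_participants=n_participants,
        n_features=n_features,
        planted_effects=(),
        confounders=(),
        **kwargs,
    )


def attenuation_oracle(
    config: SyntheticConfig,
    contrast: str,
    feature: int,
    confounder_set: list[str],
    n_oracle: int = 100_000,
    seed: int = 0,
) -> float:
    """Large-n simulation oracle for the expected percent attenuation.

    Simulates one very large cohort under ``config``, fits the base model
    (age/sex/race/BMI-category plus the feature's standardized latent
    value) and the base model plus the named confounder columns, and
    returns 100*(b1-b2)/b1 for the requested contrast.
    """
    if n_oracle < 10**5:
        raise ValueError("oracle requires n_oracle >= 1e5")
    needed = {feature} | {
        f for c in config.confounders for f in c.features
    } | {f for f, _, _ in config.planted_effects}
    big = replace(
        config,
        n_participants=n_oracle,
        n_features=max(needed) + 1,
        n_causal=None,
        lod_quantile=0.0,
        lod_overrides={},
        duplicate_spec=(),
        planted_exclusions={},
    )
    participants, matrix, _, truth = generate_cohort(big, seed)
    fid = matrix.columns[feature]
    zf = truth.latent_z[fid].to_numpy()
    bmi_cat = pd.Series(
        [
            cohort_prep.bmi_category(w, h)
            for w, h in zip(
                participants["weight_y2"], participants["height_cm"]
            )
        ],
        index=participants.index,
    )
    base_cols = {
        "(intercept)": np.ones(n_oracle),
        "age": participants["age"].to_numpy(float),
        "race[Black]": (participants["race"] == "Black").to_numpy(float),
        "sex[women]": (participants["sex"] == "women").to_numpy(float),
        "bmi_cat[25-30]": (bmi_cat == "25-30").to_numpy(float),
        "bmi_cat[>=30]": (bmi_cat == ">=30").to_numpy(float),
        "metabolite": zf,
    }
    categories = ["stable"] + sorted(set(GROUPS) - {"stable"})
    y = truth.assigned_group.map(
        {c: i for i, c in enumerate(categories)}
    ).to_numpy(int)
    X1 = np.column_stack(list(base_cols.values()))
    fit1 = fit_multinomial(y, X1, categories, list(base_cols))
    conf_cols = {c: truth.confounders[c].to_numpy() for c in confounder_set}
    X2 = np.column_stack(list(base_cols.values()) + list(conf_cols.values()))
    fit2 = fit_multinomial(
        y, X2, categories, list(base_cols) + list(conf_cols)
    )
    if not (fit1.converged and fit2.converged):
        raise RuntimeError("oracle fit did not converge")
    b1 = fit1.coef_for(contrast, "metabolite")
    b2 = fit2.coef_for(contrast, "metabolite")
    if abs(b1) < 1e-6:
        raise ZeroDivisionError("base coefficient ~0: attenuation undefined")
    return 100.0 * (b1 - b2) / b1
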