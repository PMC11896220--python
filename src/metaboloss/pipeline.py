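"""End-to-end orchestration: simulate -> prep -> qc -> mwas -> attenuate.

Each stage is a pure function of (inputs, config, seed) and writes plain
TSV/JSON outputs into the run directory; ``manifest.json`` records row
counts, seeds and content hashes so the exclusion/QC funnel is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attenuation as att
from . import cohort_prep, metabolite_qc, synthetic_cohort
from .multinomial_mwas import screen_metabolites

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Single-file configuration for the whole pipeline (YAML round-trip)."""

    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    classification: dict = field(
        default_factory=lambda: {
            "threshold_pct": 3.0,
            "extreme_pct": 40.0,
            "strategy": "any-interval",
        }
    )
    qc: dict = field(
        default_factory=lambda: {"min_detect": 0.90, "max_cv": 0.10}
    )
    mwas: dict = field(
        default_factory=lambda: {
            "covariate_sets": ["M_min", "M_bmi"],
            "q": 0.05,
            "fdr_family": "per_contrast",
        }
    )
    attenuation: dict = field(
        default_factory=lambda: {
            "sets": "all",
            "contrast": "unintentional_loss",
            "flag_threshold": 20.0,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        merged = cls()
        for key, val in raw.items():
            if isinstance(val, dict):
                getattr(merged, key).update(val)
            else:
                setattr(merged, key, val)
        return merged

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f: getattr(self, f) for f in self.__dataclass_fields__}, fh
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_REQUIRED_PARTICIPANT_COLS = {
    "fasting", "weight_y1", "weight_y2", "weight_y3", "weight_y4",
    "height_cm", "intention", "age", "sex", "race",
}


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    syn = synthetic_cohort.SyntheticConfig(
        **{**config.synthetic, "seed": config.seed}
    )
    tables = synthetic_cohort.generate_cohort(syn, config.seed)
    synthetic_cohort.write_tables(outdir, *tables)
    participants, matrix, qc, _ = tables
    return {
        "n_participants": len(participants),
        "n_features": matrix.shape[1],
        "n_qc_replicates": len(qc),
        "seed": config.seed,
    }


def stage_prep(config: PipelineConfig, outdir: Path) -> dict:
    records = _read_tsv(outdir / "participants.tsv")
    missing = _REQUIRED_PARTICIPANT_COLS - set(records.columns)
    if missing:
        raise ConfigError(f"participants.tsv lacks columns {sorted(missing)}")
    cls = cohort_prep.ClassificationConfig(**config.classification)
    cohort, tally = cohort_prep.prepare_cohort(records, cls)
    cohort.to_csv(outdir / "cohort_labeled.tsv", sep="\t")
    tally.to_json(outdir / "exclusions.json")
    return {
        "n_input": tally.n_input,
        "n_included": tally.n_included,
        "exclusions": tally.counts,
        "group_counts": cohort["four_group"].value_counts().to_dict(),
    }


def stage_qc(config: PipelineConfig, outdir: Path) -> dict:
    matrix = _read_tsv(outdir / "metabolites.tsv")
    meta = _read_tsv(outdir / "feature_meta.tsv")
    qc_reps = _read_tsv(outdir / "qc_replicates.tsv")
    cohort = _read_tsv(outdir / "cohort_labeled.tsv")
    matrix = matrix.loc[cohort.index]  # QC on the analysis sample
    processed, qc = metabolite_qc.process_metabolites(
        matrix, meta, qc_reps, **config.qc
    )
    processed.to_csv(outdir / "processed_metabolites.tsv", sep="\t")
    qc.to_csv(outdir / "feature_qc.tsv", sep="\t")
    return {
        "n_features_in": matrix.shape[1],
        "n_passed_filter": int(qc["passed_filter"].sum()),
        "n_retained_unique": processed.shape[1],
    }


def stage_mwas(config: PipelineConfig, outdir: Path) -> dict:
    processed = _read_tsv(outdir / "processed_metabolites.tsv")
    cohort = _read_tsv(outdir / "cohort_labeled.tsv")
    info = {}
    for cset in config.mwas.get("covariate_sets", ["M_bmi"]):
        table = screen_metabolites(
            processed,
            cohort,
            covariate_set=cset,
            q=config.mwas.get("q", 0.05),
            fdr_family=config.mwas.get("fdr_family", "per_contrast"),
        )
        table.to_csv(outdir / f"associations_{cset}.tsv", sep="\t", index=False)
        info[cset] = {
            "n_models": int(table["metabolite"].nunique()),
            "n_sig_p05": int(
                table.groupby("metabolite")["sig_p05"].any().sum()
            ),
            "n_not_converged": int((~table["converged"]).sum()),
        }
    return info


def stage_attenuate(config: PipelineConfig, outdir: Path) -> dict:
    processed = _read_tsv(outdir / "processed_metabolites.tsv")
    cohort = _read_tsv(outdir / "cohort_labeled.tsv")
    contrast = config.attenuation.get("contrast", "unintentional_loss")
    assoc = pd.read_csv(outdir / "associations_M_bmi.tsv", sep="\t")
    sig = sorted(
        assoc[(assoc["contrast"] == contrast) & assoc["sig_p05"]]["metabolite"]
    )
    if not sig:
        (outdir / "attenuation.tsv").write_text(
            "metabolite\tset\tbeta1\tbeta2\tpct\tn\tundefined\tconverged\n"
        )
        return {"n_significant": 0, "n_entries": 0}
    sets_cfg = config.attenuation.get("sets", "all")
    if sets_cfg == "all":
        sets = list(att.CONFOUNDER_SETS.values())
    else:
        sets = [att.CONFOUNDER_SETS[s] for s in sets_cfg]
    ledger = att.attenuation_ledger(
        processed, cohort, sig, sets, contrast=contrast
    )
    ledger.to_csv(outdir / "attenuation.tsv", sep="\t", index=False)
    summary, flagged = att.summarize_attenuation(
        ledger, config.attenuation.get("flag_threshold", 20.0)
    )
    summary.to_csv(outdir / "attenuation_summary.tsv", sep="\t", index=False)
    return {
        "n_significant": len(sig),
        "n_entries": len(ledger),
        "n_flagged": {k: len(v) for k, v in flagged.items()},
    }


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "qc": stage_qc,
    "mwas": stage_mwas,
    "attenuate": stage_attenuate,
}


def run_pipeline(
    config: PipelineConfig, outdir, stages: list[str] | None = None
) -> dict:
    """Run the requested stages in order and write manifest.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGES)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("seed", config.seed)
    for name in stages:
        if name not in STAGES:
            raise ConfigError(f"unknown stage {name!r}")
        manifest[name] = STAGES[name](config, out)
    manifest["files"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in {".tsv", ".json"} and p.name != "manifest.json"
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
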