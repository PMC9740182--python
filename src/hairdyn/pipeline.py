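"""End-to-end orchestration: simulate -> features -> associate -> train ->
evaluate -> QA, with one master seed fanned out per stage and every artifact
written to a run directory.

The master seed is expanded with a counter-based scheme
(``numpy.random.SeedSequence(master_seed, spawn_key=(stage_index,))``), so
each stage is independently reproducible: rerunning any stage with the same
config yields the same output regardless of the other stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qa as qa_mod
from .association import associate, batch_correct_and_zscore, forest_summary
from .model import evaluate, screen_features, split, stratified_performance, table_fingerprint, tune_and_fit
from .rqa import feature_table
from .simulate import CohortConfig, generate_cohort, generate_replicate_pair
from .strand_io import read_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "features", "associate", "train", "evaluate", "qa")


def stage_seed(master_seed: int, stage: str) -> int:
    """Counter-based per-stage seed below 2**31."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RqaSettings:
    target_rr: float = 0.10
    lmin: int = 2
    vmin: int = 2
    theiler_window: int = 1


@dataclass
class EmbeddingSettings:
    max_tau: int = 20
    max_m: int = 10
    rtol: float = 10.0
    atol: float = 2.0
    fnn_threshold: float = 0.05


@dataclass
class AssociationSettings:
    fdr_alpha: float = 0.05


@dataclass
class ModelSettings:
    train_fraction: float = 0.8
    folds: int = 5
    mbo_budget: int = 50
    screen_k: int = 64


@dataclass
class QaSettings:
    n_replicate_subjects: int = 5
    replicate_noise_sd: float | None = None


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    rqa: RqaSettings = field(default_factory=RqaSettings)
    embedding: EmbeddingSettings = field(default_factory=EmbeddingSettings)
    association: AssociationSettings = field(default_factory=AssociationSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    qa: QaSettings = field(default_factory=QaSettings)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.model.train_fraction < 1.0):
            raise ValueError("model.train_fraction must be in (0, 1)")
        if self.model.folds < 2:
            raise ValueError("model.folds must be >= 2")
        if self.rqa.target_rr <= 0 or self.rqa.target_rr > 1:
            raise ValueError("rqa.target_rr must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["perturbed_elements"] = sorted(self.cohort.perturbed_elements)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cohort = dict(data.pop("cohort", {}))
        if "perturbed_elements" in cohort:
            cohort["perturbed_elements"] = frozenset(cohort["perturbed_elements"])
        for key in ("period_range", "amp_range"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        kwargs = {"cohort": CohortConfig(**cohort)}
        for name, typ in (("rqa", RqaSettings), ("embedding", EmbeddingSettings),
                          ("association", AssociationSettings),
                          ("model", ModelSettings), ("qa", QaSettings)):
            kwargs[name] = typ(**data.pop(name, {}))
        kwargs["seed"] = int(data.pop("seed", 0))
        if data:
            raise ValueError(f"unknown pipeline config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, output_dir: str | Path,
                 resume: bool = False) -> dict:
    """Run every stage and write the artifact set; returns the run log.

    Artifacts: cohort bundle, features.csv + provenance.csv, association.csv
    + pathway_summary.csv, model_report.json + roc.csv, agreement.csv, and
    run_log.json (config fingerprint, stage seeds, split sizes).  With
    ``resume=True``, stages whose outputs already exist under an identical
    config fingerprint are reloaded instead of recomputed.
    """
    config.validate()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = config.fingerprint()
    log: dict = {"config_fingerprint": fingerprint,
                 "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES}}
    log_path = out / "run_log.json"
    prior = json.loads(log_path.read_text()) if (resume and log_path.exists()) else {}
    can_resume = resume and prior.get("config_fingerprint") == fingerprint

    def _fresh(path: Path) -> bool:
        return can_resume and path.exists()

    # --- simulate ---------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=log["stage_seeds"]["simulate"])
    manifest = out / "cohort" / "manifest.json"
    if _fresh(manifest):
        records, profiles = read_cohort(manifest)
        # Re-render latent-bearing strands for the QA stage.
        _, latent_profiles = generate_cohort(cohort_cfg)
    else:
        records, profiles = generate_cohort(cohort_cfg)
        latent_profiles = profiles
        write_cohort(records, profiles, out / "cohort", cohort_cfg)
    log["n_subjects"] = len(records)
    log["n_cases"] = sum(r.is_case for r in records)

    # --- features ---------------------------------------------------------
    features_path = out / "features.csv"
    if _fresh(features_path):
        features = pd.read_csv(features_path, index_col=0)
    else:
        result = feature_table(
            profiles, list(cohort_cfg.panel),
            target_rr=config.rqa.target_rr, lmin=config.rqa.lmin,
            vmin=config.rqa.vmin, theiler_window=config.rqa.theiler_window,
            max_tau=config.embedding.max_tau, max_m=config.embedding.max_m,
            rtol=config.embedding.rtol, atol=config.embedding.atol,
            fnn_threshold=config.embedding.fnn_threshold,
        )
        features = result.features
        features.to_csv(features_path)
        result.provenance.to_csv(out / "provenance.csv", index=False)
        log["excluded_subjects"] = result.excluded
    log["n_features"] = int(features.shape[1])

    # --- associate --------------------------------------------------------
    records = [r for r in records if r.subject_id in set(features.index)]
    batches = pd.Series({r.subject_id: r.batch for r in records})
    normalized = batch_correct_and_zscore(features, batches)
    assoc = associate(normalized, records, fdr_alpha=config.association.fdr_alpha)
    assoc.to_csv(out / "association.csv", index=False)
    forest_summary(assoc, config.association.fdr_alpha).to_csv(
        out / "pathway_summary.csv", index=False)
    log["n_significant"] = int(assoc["significant"].sum())

    # --- train ------------------------------------------------------------
    seed_train = log["stage_seeds"]["train"]
    labels = pd.Series({r.subject_id: int(r.is_case) for r in records})
    spec = split(list(normalized.index), train_fraction=config.model.train_fraction,
                 seed=seed_train)
    train_tbl = normalized.loc[list(spec.train_ids)]
    holdout_tbl = normalized.loc[list(spec.holdout_ids)]
    holdout_hash = table_fingerprint(holdout_tbl)
    log["split"] = {"train": len(spec.train_ids), "holdout": len(spec.holdout_ids),
                    "train_cases": int(labels[list(spec.train_ids)].sum()),
                    "holdout_cases": int(labels[list(spec.holdout_ids)].sum())}

    k = min(config.model.screen_k, train_tbl.shape[1])
    selected = screen_features(train_tbl, records, k=k)
    model, best_cfg, _ = tune_and_fit(
        train_tbl[selected], labels[list(spec.train_ids)],
        folds=config.model.folds, budget=config.model.mbo_budget, seed=seed_train)
    log["selected_features"] = selected
    log["best_hyperparameters"] = best_cfg

    # --- evaluate ---------------------------------------------------------
    assert table_fingerprint(holdout_tbl) == holdout_hash, "holdout rows mutated"
    scores = model.predict_proba(holdout_tbl[selected].to_numpy(dtype=float))[:, 1]
    y_holdout = labels[list(spec.holdout_ids)].to_numpy()
    report = evaluate(scores, y_holdout)
    sex = np.array([next(r.sex for r in records if r.subject_id == sid)
                    for sid in spec.holdout_ids])
    report.strata_reports = stratified_performance(scores, y_holdout, sex)
    (out / "model_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    report.roc_points.to_csv(out / "roc.csv", index=False)
    log["holdout_auc"] = report.auc

    # --- qa ---------------------------------------------------------------
    seed_qa = log["stage_seeds"]["qa"]
    n_rep = min(config.qa.n_replicate_subjects, len(latent_profiles))
    fractions = []
    rows = []
    for i, profile in enumerate(latent_profiles[:n_rep]):
        replicate = generate_replicate_pair(profile, config.qa.replicate_noise_sd,
                                            seed=seed_qa + i)
        pair = feature_table([profile, replicate], list(cohort_cfg.panel),
                             target_rr=config.rqa.target_rr,
                             theiler_window=config.rqa.theiler_window,
                             max_tau=config.embedding.max_tau)
        f = pair.features
        rep = qa_mod.replicate_agreement(f.iloc[0], f.iloc[1])
        fractions.append(rep.fraction_within_10pct)
        rows.append({"subject_id": profile.subject_id,
                     "fraction_within_10pct": rep.fraction_within_10pct,
                     "n_compared": rep.n_compared})
    pd.DataFrame(rows).to_csv(out / "agreement.csv", index=False)
    log["replicate_fraction_within_10pct"] = float(np.mean(fractions)) if fractions else None

    log_path.write_text(json.dumps(log, indent=2))
    return log
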