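"""Gradient-boosted diagnostic classifier and its ROC evaluation.

Workflow: simple random 80/20 split; transparent feature screening on the
training set only (top-k by association q-value); XGBoost tuned by 5-fold
cross-validated AUC under a surrogate-guided (model-based) hyperparameter
search; holdout evaluation at the Youden-optimal ROC operating point with
Clopper-Pearson intervals; and stratified AUC comparisons using a
DeLong-type (jackknife influence) variance on the shared scores.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint
from xgboost import XGBClassifier

from .association import associate
from .simulate import SubjectRecord

__all__ = [
    "SplitSpec",
    "ConfusionMatrix",
    "ModelReport",
    "split",
    "screen_features",
    "tune_and_fit",
    "evaluate",
    "stratified_performance",
]


@dataclass(frozen=True)
class SplitSpec:
    n_total: int
    train_fraction: float
    seed: int
    train_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.holdout_ids):
            raise ValueError("train and holdout sets overlap")
        if len(self.train_ids) + len(self.holdout_ids) != self.n_total:
            raise ValueError("split does not partition the cohort")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass
class ModelReport:
    roc_points: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float
    youden_threshold: float
    j: float
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    strata_reports: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "j": self.j,
            "confusion": asdict(self.confusion),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "accuracy_ci": list(self.accuracy_ci),
            "strata": self.strata_reports,
        }
        return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split(ids, labels=None, train_fraction: float = 0.8, seed: int = 0) -> SplitSpec:
    """Simple random (non-stratified) train/holdout assignment."""
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 subjects to split")
    n_train = _round_half_up(train_fraction * n)
    if n_train < 1 or n_train >= n:
        raise ValueError(f"train_fraction={train_fraction} leaves an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    holdout = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitSpec(n_total=n, train_fraction=train_fraction, seed=seed,
                     train_ids=train, holdout_ids=holdout)


def table_fingerprint(table: pd.DataFrame) -> str:
    """Stable content hash, used to assert holdout rows are untouched."""
    return hashlib.sha256(
        pd.util.hash_pandas_object(table, index=True).to_numpy().tobytes()
    ).hexdigest()


def screen_features(train_table: pd.DataFrame, train_subjects: list[SubjectRecord],
                    k: int = 64) -> list[str]:
    """Transparent screening rule: top-k features by training-set-only
    association q-value (ties broken by p).  The holdout is never seen."""
    if k > train_table.shape[1]:
        raise ValueError(f"k={k} exceeds the {train_table.shape[1]} available features")
    train_sids = set(train_table.index)
    subjects = [s for s in train_subjects if s.subject_id in train_sids]
    if len(subjects) != len(train_table):
        raise ValueError("train_subjects does not cover the training table")
    rows = associate(train_table, subjects)
    rows = rows[rows["flagged"].eq("")].sort_values(["q", "p"], kind="stable")
    return rows["feature_id"].head(k).tolist()


_SPACE = {
    "learning_rate": ("log", 0.01, 0.3),
    "max_depth": ("int", 2, 8),
    "subsample": ("float", 0.5, 1.0),
    "colsample_bytree": ("float", 0.5, 1.0),
    "min_child_weight": ("int", 1, 10),
    "n_estimators": ("int", 50, 400),
}


def _sample_config(rng: np.random.Generator) -> dict:
    cfg = {}
    for name, (kind, lo, hi) in _SPACE.items():
        if kind == "log":
            cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "int":
            cfg[name] = int(rng.integers(lo, hi + 1))
        else:
            cfg[name] = float(rng.uniform(lo, hi))
    return cfg


def _encode(cfg: dict) -> list[float]:
    return [float(cfg[name]) for name in _SPACE]


def _cv_auc(X: np.ndarray, y: np.ndarray, cfg: dict, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        clf = XGBClassifier(
            **cfg, objective="binary:logistic", eval_metric="logloss",
            tree_method="hist", n_jobs=1, random_state=seed, verbosity=0,
        )
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[va], clf.predict_proba(X[va])[:, 1]))
    return float(np.mean(aucs))


def tune_and_fit(train_table: pd.DataFrame, train_labels, folds: int = 5,
                 budget: int = 50, seed: int = 0):
    """Surrogate-guided hyperparameter search + final fit on all training data.

    The search draws an initial random design, then repeatedly proposes the
    expected-improvement maximizer over a random candidate pool under a
    random-forest surrogate of the cross-validated AUC (a desk-scale
    model-based-optimization loop).  Returns ``(model, best_config, history)``.
    """
    from sklearn.ensemble import RandomForestRegressor

    X = train_table.to_numpy(dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    if len(y) < folds * 5:
        raise ValueError(f"need >= {folds * 5} training subjects for {folds}-fold tuning")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)

    history: list[tuple[dict, float]] = []
    n_init = min(max(budget // 3, 1), 10, budget)
    for _ in range(n_init):
        cfg = _sample_config(rng)
        history.append((cfg, _cv_auc(X, y, cfg, folds, seed)))

    for _ in range(budget - n_init):
        Z = np.array([_encode(c) for c, _ in history])
        scores = np.array([s for _, s in history])
        surrogate = RandomForestRegressor(
            n_estimators=50, random_state=int(rng.integers(2**31)), n_jobs=1
        ).fit(Z, scores)
        candidates = [_sample_config(rng) for _ in range(256)]
        Zc = np.array([_encode(c) for c in candidates])
        per_tree = np.stack([t.predict(Zc) for t in surrogate.estimators_])
        mu, sd = per_tree.mean(axis=0), per_tree.std(axis=0) + 1e-9
        best = scores.max()
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        cfg = candidates[int(np.argmax(ei))]
        history.append((cfg, _cv_auc(X, y, cfg, folds, seed)))

    best_cfg, _ = max(history, key=lambda item: item[1])
    model = XGBClassifier(
        **best_cfg, objective="binary:logistic", eval_metric="logloss",
        tree_method="hist", n_jobs=1, random_state=seed, verbosity=0,
    )
    model.fit(X, y)
    return model, best_cfg, history


def _roc_sweep(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Full ROC: one operating point per candidate threshold (score >= t)."""
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    pos, neg = labels == 1, labels == 0
    rows = []
    for t in thresholds:
        pred = scores >= t
        rows.append({
            "threshold": t,
            "sensitivity": float((pred & pos).sum() / pos.sum()),
            "specificity": float((~pred & neg).sum() / neg.sum()),
        })
    return pd.DataFrame(rows)


def evaluate(scores, labels, alpha: float = 0.05) -> ModelReport:
    """ROC evaluation at the Youden-optimal threshold.

    J = sensitivity + specificity - 1 is maximized over all thresholds; ties
    resolve to the lowest qualifying threshold (favoring sensitivity, the
    natural choice for a screening aid).  Sensitivity/specificity/accuracy
    carry Clopper-Pearson 95% intervals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to evaluate")

    roc = _roc_sweep(scores, labels)
    j_curve = roc["sensitivity"] + roc["specificity"] - 1.0
    best_j = j_curve.max()
    youden_threshold = float(roc.loc[np.isclose(j_curve, best_j), "threshold"].min())

    pred = scores >= youden_threshold
    pos, neg = labels == 1, labels == 0
    cm = ConfusionMatrix(
        tp=int((pred & pos).sum()), fn=int((~pred & pos).sum()),
        tn=int((~pred & neg).sum()), fp=int((pred & neg).sum()),
    )
    auc = float(roc_auc_score(labels, scores))

    def _ci(successes: int, n: int) -> tuple[float, float]:
        lo, hi = proportion_confint(successes, n, alpha=alpha, method="beta")
        return float(lo), float(hi)

    return ModelReport(
        roc_points=roc,
        auc=auc,
        youden_threshold=youden_threshold,
        j=float(cm.sensitivity + cm.specificity - 1.0),
        confusion=cm,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        sensitivity_ci=_ci(cm.tp, cm.tp + cm.fn),
        specificity_ci=_ci(cm.tn, cm.tn + cm.fp),
        accuracy_ci=_ci(cm.tp + cm.tn, cm.n),
    )


def _jackknife_auc_diff_se(scores: np.ndarray, labels: np.ndarray,
                           mask: np.ndarray) -> tuple[float, float]:
    """Delete-one-subject SE of (stratum AUC - overall AUC) on shared scores."""
    n = len(scores)
    diff = roc_auc_score(labels[mask], scores[mask]) - roc_auc_score(labels, scores)
    pseudo = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = mask & keep
        if len(np.unique(labels[keep])) < 2 or len(np.unique(labels[sub])) < 2:
            continue
        d = roc_auc_score(labels[sub], scores[sub]) - roc_auc_score(labels[keep], scores[keep])
        pseudo.append(d)
    pseudo = np.asarray(pseudo)
    m = len(pseudo)
    se = float(np.sqrt((m - 1) / m * np.sum((pseudo - pseudo.mean()) ** 2))) if m > 1 else 0.0
    return float(diff), se


def stratified_performance(scores, labels, strata) -> dict[str, dict]:
    """Per-stratum AUC and its comparison against the overall AUC.

    ``strata`` maps each subject to a stratum label (sequence aligned with
    scores).  For every stratum containing both classes, reports the stratum
    AUC and a two-sided p-value for stratum-vs-overall AUC equality, using a
    delete-one jackknife variance of the AUC difference over the shared
    scores (a DeLong-type influence-function estimate).  Degenerate strata
    are flagged, not computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    strata = np.asarray(strata)
    overall_auc = float(roc_auc_score(labels, scores))
    reports: dict[str, dict] = {}
    for name in pd.unique(strata):
        mask = strata == name
        if len(np.unique(labels[mask])) < 2:
            reports[str(name)] = {"auc": None, "p": None, "n": int(mask.sum()),
                                  "flagged": "single-class stratum"}
            continue
        diff, se = _jackknife_auc_diff_se(scores, labels, mask)
        if se == 0.0:
            p = 1.0
        else:
            p = float(2 * norm.sf(abs(diff) / se))
        reports[str(name)] = {
            "auc": float(roc_auc_score(labels[mask], scores[mask])),
            "overall_auc": overall_auc,
            "p": min(p, 1.0),
            "n": int(mask.sum()),
            "flagged": "",
        }
    return reports
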