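"""The MEL-RAD classifier workflow.

A small multilayer perceptron (one hidden layer) predicts the probability
of 1-year progression from a handful of radiomic features. The development
cohort is split 60/40 into training and validation; 10-fold cross-validation
on the training split yields per-patient out-of-fold probabilities and
per-feature permutation-importance ranks; backward elimination repeatedly
drops the least important feature; and for each candidate feature set the
probability threshold maximizing the prevalence-weighted Efficiency

    EFF = P * Se + (1 - P) * Sp

on the validation split selects the operating point. The feature set and
threshold with the best EFF define the final model, which is then frozen
and applied unchanged to the external testing cohort. A patient is called
positive when the predicted probability strictly exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "MlpHyperparams",
    "TrainedMlp",
    "CvEnsemble",
    "PerformanceReport",
    "EliminationResult",
    "split_development",
    "train_mlp",
    "cross_validate",
    "feature_importance",
    "backward_eliminate",
    "efficiency",
    "select_threshold",
    "evaluate",
]

THRESHOLD_GRID = np.round(np.arange(0.0, 1.0001, 0.005), 3)


@dataclass(frozen=True)
class MlpHyperparams:
    """Hyperparameters of the single-hidden-layer perceptron.

    ``lambda_init``/``sigma_init``/``init_center``/``init_offset`` record the
    scaled-conjugate-gradient initialisation the model family was specified
    with; the training backend here is a seeded quasi-Newton (lbfgs) fit
    with ``n_restarts`` deterministic restarts, which passes the same
    separability contracts (see the methods note).
    """

    hidden_units: int = 4
    lambda_init: float = 5e-7
    sigma_init: float = 5e-5
    init_center: float = 0.0
    init_offset: float = 0.5
    alpha: float = 1e-4          # L2 penalty of the backend
    max_epochs: int = 800
    tol: float = 1e-7
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("need at least one hidden unit")
        if self.init_offset <= 0:
            raise ValueError("init_offset must be > 0")
        if self.lambda_init <= 0 or self.sigma_init <= 0:
            raise ValueError("lambda_init and sigma_init must be > 0")


@dataclass
class TrainedMlp:
    clf: MLPClassifier
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray

    def predict_proba(self, X) -> np.ndarray:
        """Probability of the positive class (1-year progression)."""
        X = self._matrix(X)
        Z = (X - self.scale_mean) / self.scale_sd
        return self.clf.predict_proba(Z)[:, 1]

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


@dataclass
class CvEnsemble:
    models: list[TrainedMlp]
    oof_probability: pd.Series     # per patient, model where it was held out
    mean_rank: pd.Series           # per feature, 1 = most important
    feature_names: list[str]

    def __post_init__(self):
        p = self.oof_probability.to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities outside [0, 1]")


@dataclass
class PerformanceReport:
    """Confusion counts at a threshold plus the derived metrics.

    Ratios with a zero denominator are reported as NaN and flagged in
    ``undefined`` rather than silently zeroed.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    eff: float
    auc: float
    c_statistic: float
    undefined: list[str] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, fp: int, tn: int, threshold: float = 0.5
    ) -> "PerformanceReport":
        """Report implied by a 2x2 confusion table (binary predictions)."""
        labels = np.r_[np.ones(tp + fn), np.zeros(fp + tn)].astype(int)
        probs = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        return evaluate(probs, labels, threshold=threshold)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "prevalence": self.prevalence,
            "eff": self.eff, "auc": self.auc, "c_statistic": self.c_statistic,
        }


@dataclass
class EliminationResult:
    stages: pd.DataFrame           # one row per feature-set size
    best_features: list[str]
    best_threshold: float
    final_model: TrainedMlp
    validation_report: PerformanceReport


# ---------------------------------------------------------------------------


def split_development(labels, ratio: float = 0.6, seed: int = 0):
    """Stratified train/validation split of the development cohort.

    Returns (train_idx, val_idx) as integer positions; sizes are within one
    patient of the exact ratio and the event fraction of each part within
    one patient of the overall fraction.
    """
    labels = np.asarray(labels).astype(int)
    if labels.size < 10:
        raise ValueError("development cohort too small to split")
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("each outcome stratum needs >= 2 patients")
    idx = np.arange(labels.size)
    train, val = train_test_split(
        idx, test_size=1.0 - ratio, stratify=labels, random_state=seed
    )
    return np.sort(train), np.sort(val)


def _fit_once(Z, y, hp: MlpHyperparams, random_state: int) -> MLPClassifier:
    clf = MLPClassifier(
        hidden_layer_sizes=(hp.hidden_units,),
        activation="tanh",
        solver="lbfgs",
        alpha=hp.alpha,
        max_iter=hp.max_epochs,
        tol=hp.tol,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Z, y)
    return clf


def train_mlp(X, y, hp: MlpHyperparams | None = None,
              feature_names: list[str] | None = None) -> TrainedMlp:
    """Train the perceptron on standardized features.

    Features are standardized to the training mean/SD. The best of
    ``n_restarts`` deterministic seeded fits (lowest final training loss)
    is kept, which makes optimisation on tiny datasets reproducible and
    robust to unlucky initialisations.
    """
    hp = hp or MlpHyperparams()
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need >= 2 examples of each class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    seeds = np.random.default_rng(hp.seed).integers(0, 2**31 - 1, hp.n_restarts)
    best = None
    for s in seeds:
        clf = _fit_once(Z, y, hp, int(s))
        if not np.isfinite(clf.loss_):
            raise FloatingPointError("non-finite training loss")
        if best is None or clf.loss_ < best.loss_:
            best = clf
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return TrainedMlp(clf=best, feature_names=names, scale_mean=mean, scale_sd=sd)


def feature_importance(
    model: TrainedMlp, X, y, n_shuffles: int = 20, seed: int = 0
) -> pd.Series:
    """Permutation importance: mean log-loss increase over shuffles.

    Shuffling is batched (all shuffled copies scored in one call), which is
    numerically identical to scoring them one at a time.
    """
    if isinstance(X, pd.DataFrame):
        X = X[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    base = log_loss(y, model.predict_proba(X), labels=[0, 1])
    n = X.shape[0]
    imp = {}
    for j, name in enumerate(model.feature_names):
        stacked = np.tile(X, (n_shuffles, 1))
        for s in range(n_shuffles):
            stacked[s * n : (s + 1) * n, j] = X[rng.permutation(n), j]
        probs = model.predict_proba(stacked)
        losses = [
            log_loss(y, probs[s * n : (s + 1) * n], labels=[0, 1])
            for s in range(n_shuffles)
        ]
        imp[name] = float(np.mean(losses) - base)
    return pd.Series(imp, name="importance")


def _ranks(importance: pd.Series) -> pd.Series:
    """Convert raw importances to ranks (1 = most important); ties broken
    lexicographically by feature name."""
    order = sorted(importance.index, key=lambda f: (-importance[f], f))
    return pd.Series({f: r + 1 for r, f in enumerate(order)}, name="rank")


def cross_validate(
    X: pd.DataFrame, y, hp: MlpHyperparams | None = None, k: int = 10
) -> CvEnsemble:
    """Stratified k-fold cross-validation with out-of-fold probabilities
    and permutation-importance ranks averaged over folds."""
    hp = hp or MlpHyperparams()
    y = np.asarray(y).astype(int)
    if len(X) < k:
        raise ValueError(f"need at least k={k} patients")
    if min(np.bincount(y, minlength=2)) < k:
        k = int(min(np.bincount(y, minlength=2)))
        if k < 2:
            raise ValueError("a class has too few members for cross-validation")
        warnings.warn(f"reduced fold count to {k} to keep folds stratified",
                      stacklevel=2)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=hp.seed)
    oof = np.full(len(X), np.nan)
    models, rank_rows = [], []
    for f, (tr, te) in enumerate(skf.split(Xm, y)):
        fold_hp = replace(hp, seed=hp.seed * 1009 + f)
        m = train_mlp(Xm[tr], y[tr], fold_hp, feature_names=names)
        models.append(m)
        oof[te] = m.predict_proba(Xm[te])
        imp = feature_importance(m, Xm[te], y[te], seed=fold_hp.seed)
        rank_rows.append(_ranks(imp))
    mean_rank = pd.concat(rank_rows, axis=1).mean(axis=1)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    return CvEnsemble(
        models=models,
        oof_probability=pd.Series(oof, index=index, name="probability"),
        mean_rank=mean_rank.rename("mean_rank"),
        feature_names=names,
    )


def efficiency(se: float, sp: float, prevalence: float) -> float:
    """EFF = P * Se + (1 - P) * Sp."""
    for name, v in (("Se", se), ("Sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return prevalence * se + (1.0 - prevalence) * sp


def select_threshold(probabilities, labels) -> tuple[float, PerformanceReport]:
    """Scan thresholds in 0.5% steps and keep the smallest one maximizing
    EFF at the observed prevalence."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    prev = labels.mean()
    best_t, best_eff = None, -1.0
    for t in THRESHOLD_GRID:
        pred = probabilities > t
        se = (pred & (labels == 1)).sum() / (labels == 1).sum()
        sp = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        eff = efficiency(se, sp, prev)
        if eff > best_eff + 1e-12:  # strict improvement: ties keep smallest t
            best_t, best_eff = float(t), float(eff)
    return best_t, evaluate(probabilities, labels, best_t)


def _safe_ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def evaluate(probabilities, labels, threshold: float) -> PerformanceReport:
    """Confusion counts and derived metrics at a fixed threshold.

    Positive means predicted probability strictly greater than the
    threshold. AUC uses the rank (Mann-Whitney) formulation via
    ``roc_auc_score``; the thresholded C-statistic is (Se + Sp) / 2.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = probabilities > threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    undefined: list[str] = []
    se = _safe_ratio(tp, tp + fn, "sensitivity", undefined)
    sp = _safe_ratio(tn, tn + fp, "specificity", undefined)
    ppv = _safe_ratio(tp, tp + fp, "ppv", undefined)
    npv = _safe_ratio(tn, tn + fn, "npv", undefined)
    prev = pos.mean()
    if np.isnan(se) or np.isnan(sp):
        eff = float("nan")
        undefined.append("eff")
        auc = float("nan")
        undefined.append("auc")
    else:
        eff = efficiency(se, sp, prev)
        auc = float(roc_auc_score(labels, probabilities))
    c_stat = (se + sp) / 2.0
    return PerformanceReport(
        tp=tp, fn=fn, fp=fp, tn=tn, threshold=float(threshold),
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        prevalence=float(prev), eff=eff, auc=auc, c_statistic=c_stat,
        undefined=undefined,
    )


def backward_eliminate(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    features: list[str],
    hp: MlpHyperparams | None = None,
    k: int = 10,
) -> EliminationResult:
    """Importance-ranked backward elimination with EFF-based selection.

    At each stage the current feature set is cross-validated on the training
    split, a full-training model is scored on the validation split, the
    EFF-maximizing threshold is recorded, and the feature with the worst
    mean importance rank is dropped. The stage (feature set + threshold)
    with the highest validation EFF wins; ties prefer the smaller set.
    """
    hp = hp or MlpHyperparams()
    if not features:
        raise ValueError("initial feature set is empty")
    y_train = np.asarray(y_train).astype(int)
    y_val = np.asarray(y_val).astype(int)

    current = list(features)
    records = []
    while current:
        if len(current) > 1:
            cv = cross_validate(X_train[current], y_train, hp, k=k)
            worst = max(
                cv.mean_rank.index, key=lambda f: (cv.mean_rank[f], f)
            )
        else:
            worst = current[0]
        stage_model = train_mlp(X_train[current], y_train, hp)
        val_probs = stage_model.predict_proba(X_val)
        thr, report = select_threshold(val_probs, y_val)
        records.append(
            {
                "n_features": len(current),
                "features": tuple(current),
                "threshold": thr,
                "eff": report.eff,
                "auc": report.auc,
                "dropped_next": worst if len(current) > 1 else "",
            }
        )
        if len(current) == 1:
            break
        current = [f for f in current if f != worst]

    stages = pd.DataFrame(records)
    # highest EFF; ties -> smallest feature set
    best_row = stages.sort_values(
        ["eff", "n_features"], ascending=[False, True], kind="stable"
    ).iloc[0]
    best_features = list(best_row["features"])
    final_model = train_mlp(X_train[best_features], y_train, hp)
    val_probs = final_model.predict_proba(X_val)
    thr, report = select_threshold(val_probs, y_val)
    return EliminationResult(
        stages=stages,
        best_features=best_features,
        best_threshold=thr,
        final_model=final_model,
        validation_report=report,
    )
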