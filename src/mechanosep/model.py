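"""Training and scoring of the cellular host-response index.

An L1-regularized logistic regression (the L1 penalty doubles as the feature
selector) is trained on per-subject feature vectors under a sequester-plus-
nested-cross-validation architecture; the final fit's log-odds are mapped
affinely onto the 0.1-10.0 score (ISI) whose distribution over the training
cohort is anchored to the published median/IQR, and the score is partitioned
into Green / Yellow / Red interpretation bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import BandDefinition, ScoreAnchors, ValidationPlan
from .evaluation import roc_auc

_BANDS = ("Green", "Yellow", "Red")


def sequester_split(subject_ids: np.ndarray, labels: np.ndarray,
                    plan: ValidationPlan) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out of the sequestered validation set.

    Returns ``(training_ids, sequestered_ids)``; sizes are deterministic
    given the plan's seed and fraction (307 subjects at the default fraction
    give 238 training / 69 sequestered).
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels).astype(int)
    if len(subject_ids) < 4:
        raise ValueError("need at least 4 subjects to sequester")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present before splitting")
    n_seq = int(round(plan.sequester_fraction * len(subject_ids)))
    train, seq = train_test_split(subject_ids, test_size=n_seq,
                                  stratify=labels, random_state=plan.seed)
    seq_set = set(seq.tolist())
    seq_labels = labels[[sid in seq_set for sid in subject_ids]]
    train_labels = labels[[sid not in seq_set for sid in subject_ids]]
    if len(np.unique(seq_labels)) < 2 or len(np.unique(train_labels)) < 2:
        raise ValueError("a class is absent from one side of the split")
    return np.asarray(train), np.asarray(seq)


def fit_l1_logistic(X: np.ndarray, y: np.ndarray,
                    lam: float) -> tuple[np.ndarray, float]:
    """Maximize sum log p(y|x.b + b0) - lam * ||b||_1 (intercept unpenalized).

    Expects standardized features.  Returns ``(beta, beta0)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the design matrix or labels")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    C = 1.0 / lam if lam > 0 else 1e10  # sklearn C = 1/lambda
    # liblinear bundles the intercept into the penalized weights; a large
    # intercept_scaling makes its effective penalty negligible (unpenalized
    # intercept up to numerical tolerance)
    clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                             intercept_scaling=1000.0, max_iter=3000,
                             tol=1e-5, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _standardize(X: np.ndarray, means=None, sds=None):
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds, means, sds


def _cv_auc_for_lambda(X, y, lam, k, seed) -> float:
    """Mean held-out AUC of an L1 fit at one penalty over a stratified k-fold."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn("fold with a single class skipped")
            continue
        Xtr, m, s = _standardize(X[tr])
        beta, beta0 = fit_l1_logistic(Xtr, y[tr], lam)
        Xte, _, _ = _standardize(X[te], m, s)
        aucs.append(roc_auc(Xte @ beta + beta0, y[te]))
    return float(np.mean(aucs)) if aucs else np.nan


def select_lambda(X, y, plan: ValidationPlan, seed: int | None = None) -> float:
    """Penalty maximizing mean k-fold CV AUC over the plan's grid."""
    seed = plan.seed if seed is None else seed
    scores = [_cv_auc_for_lambda(X, y, lam, plan.k_inner, seed)
              for lam in plan.lambda_grid]
    return float(plan.lambda_grid[int(np.nanargmax(scores))])


def nested_cv(X: np.ndarray, y: np.ndarray,
              plan: ValidationPlan) -> dict:
    """Nested cross-validation: inner folds choose the penalty, outer folds
    report held-out AUC with that penalty.

    Returns outer-fold AUCs, the penalty chosen in each outer fold, and the
    mean outer AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    outer_aucs, lambdas = [], []
    for rep in range(plan.n_repeats):
        outer = StratifiedKFold(n_splits=plan.k_outer, shuffle=True,
                                random_state=plan.seed + 101 * rep)
        for i, (tr, te) in enumerate(outer.split(X, y)):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                warnings.warn(f"outer fold {i} with a single class skipped")
                continue
            lam = select_lambda(X[tr], y[tr], plan,
                                seed=plan.seed + 1 + i + 17 * rep)
            Xtr, m, s = _standardize(X[tr])
            beta, beta0 = fit_l1_logistic(Xtr, y[tr], lam)
            Xte, _, _ = _standardize(X[te], m, s)
            outer_aucs.append(roc_auc(Xte @ beta + beta0, y[te]))
            lambdas.append(lam)
    return {"outer_aucs": outer_aucs, "lambdas": lambdas,
            "mean_auc": float(np.mean(outer_aucs))}


def repeated_kfold_auc(X: np.ndarray, y: np.ndarray, plan: ValidationPlan,
                       k: int = 10, n_repeats: int = 10,
                       lam: float | None = None) -> dict:
    """Repeated k-fold CV mirroring the stability analysis of the score.

    When ``lam`` is given (typically the penalty the final-model selection
    chose), each fold refits at that penalty; otherwise the penalty is
    re-selected inside every fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    aucs = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=plan.seed + 1000 + rep)
        for tr, te in skf.split(X, y):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            fold_lam = lam if lam is not None else select_lambda(
                X[tr], y[tr], plan, seed=plan.seed + rep)
            Xtr, m, s = _standardize(X[tr])
            beta, beta0 = fit_l1_logistic(Xtr, y[tr], fold_lam)
            Xte, _, _ = _standardize(X[te], m, s)
            aucs.append(roc_auc(Xte @ beta + beta0, y[te]))
    return {"aucs": aucs, "mean_auc": float(np.mean(aucs))}


def calibrate_score_map(logodds: np.ndarray,
                        anchors: ScoreAnchors | None = None) -> tuple[float, float]:
    """Affine map anchoring the training score distribution to the published
    median and IQR: a = target_IQR / IQR(logodds), b = target_median -
    a * median(logodds)."""
    anchors = anchors or ScoreAnchors()
    lo = np.asarray(logodds, dtype=float)
    if lo.size < 10:
        raise ValueError("need >= 10 log-odds values to calibrate")
    q1, med, q3 = np.percentile(lo, [25, 50, 75])
    if q3 - q1 <= 0:
        raise ValueError("zero IQR of log-odds: cannot calibrate the score map")
    a = (anchors.q3 - anchors.q1) / (q3 - q1)
    b = anchors.median - a * med
    return float(a), float(b)


@dataclass
class FittedScoreModel:
    """Final L1-logistic fit with the affine score map and band thresholds."""

    feature_names: list[str]
    beta: np.ndarray
    beta0: float
    lam: float
    means: np.ndarray
    sds: np.ndarray
    score_a: float
    score_b: float
    bands: BandDefinition = field(default_factory=BandDefinition)

    def __post_init__(self) -> None:
        if self.score_a <= 0:
            raise ValueError("score map slope must be positive (monotone score)")

    def logodds(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("feature vector contains missing values")
        Xs = (X - self.means) / self.sds
        return Xs @ self.beta + self.beta0

    def compute_isi(self, features: pd.DataFrame) -> np.ndarray:
        return map_to_score(self.logodds(features), self.score_a,
                            self.score_b, self.bands)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(), "beta0": self.beta0, "lambda": self.lam,
            "standardization_means": self.means.tolist(),
            "standardization_sds": self.sds.tolist(),
            "score_map": {"a": self.score_a, "b": self.score_b},
            "bands": {"green_max": self.bands.green_max,
                      "yellow_max": self.bands.yellow_max,
                      "score_min": self.bands.score_min,
                      "score_max": self.bands.score_max,
                      "granularity": self.bands.granularity},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(feature_names=d["feature_names"],
                   beta=np.array(d["beta"]), beta0=d["beta0"], lam=d["lambda"],
                   means=np.array(d["standardization_means"]),
                   sds=np.array(d["standardization_sds"]),
                   score_a=d["score_map"]["a"], score_b=d["score_map"]["b"],
                   bands=BandDefinition(
                       green_max=d["bands"]["green_max"],
                       yellow_max=d["bands"]["yellow_max"],
                       score_min=d["bands"]["score_min"],
                       score_max=d["bands"]["score_max"],
                       granularity=d["bands"]["granularity"]))


def map_to_score(logodds: np.ndarray, a: float, b: float,
                 bands: BandDefinition | None = None) -> np.ndarray:
    """ISI = clip(round(a * logodds + b, 0.1 grid), 0.1, 10.0)."""
    bands = bands or BandDefinition()
    raw = a * np.asarray(logodds, dtype=float) + b
    grid = np.round(raw / bands.granularity) * bands.granularity
    return np.clip(np.round(grid, 10), bands.score_min, bands.score_max)


def assign_band(isi, bands: BandDefinition | None = None):
    """Green iff score <= 5.4, Yellow iff 5.5-6.7, Red iff >= 6.8."""
    bands = bands or BandDefinition()
    scalar = np.isscalar(isi)
    s = np.atleast_1d(np.asarray(isi, dtype=float))
    g = bands.granularity
    on_grid = np.abs(s / g - np.round(s / g)) < 1e-6
    in_range = (s >= bands.score_min - 1e-9) & (s <= bands.score_max + 1e-9)
    if not np.all(on_grid & in_range):
        bad = s[~(on_grid & in_range)][0]
        raise ValueError(f"score {bad} is off the 0.1 grid or out of range")
    out = np.where(s <= bands.green_max + 1e-9, "Green",
                   np.where(s <= bands.yellow_max + 1e-9, "Yellow", "Red"))
    return str(out[0]) if scalar else out


def train_final_model(features: pd.DataFrame, labels: np.ndarray,
                      feature_names: list[str],
                      plan: ValidationPlan,
                      anchors: ScoreAnchors | None = None,
                      bands: BandDefinition | None = None) -> FittedScoreModel:
    """Fit the final model on the full training cohort.

    The penalty is chosen by k-fold CV on the same cohort, the model refit on
    everything, and the score map calibrated on the training log-odds.
    """
    bands = bands or BandDefinition()
    X = features[feature_names].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    lam = select_lambda(X, y, plan)
    Xs, means, sds = _standardize(X)
    beta, beta0 = fit_l1_logistic(Xs, y, lam)
    logodds = Xs @ beta + beta0
    a, b = calibrate_score_map(logodds, anchors)
    return FittedScoreModel(feature_names=list(feature_names), beta=beta,
                            beta0=beta0, lam=lam, means=means, sds=sds,
                            score_a=a, score_b=b, bands=bands)
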