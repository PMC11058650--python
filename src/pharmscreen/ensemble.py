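"""Ensemble optimisation of pharmacophore model outputs.

A screen of a molecule library against many pharmacophore models yields a
molecules x models matrix of binary hits ("prediction") and continuous fit
scores ("rescore").  Single models trade recall against precision badly under
1:50 class imbalance; two ensemble schemes fix that:

* **global voting** — keep the models whose individual AUC clears a
  threshold, then call a molecule active when a strict majority of the kept
  models do;
* **global stacking** — use the kept models' outputs as features for a
  gradient-boosted meta-classifier (XGBoost), in four feature modes:
  predictions only, rescores only, both, or both after random-forest feature
  selection.

The benchmarking protocol is a stratified 80:20 split with 3x10-fold
stratified cross-validation inside the 80% (30 per-fold values of
AUC / EF1% / GH / F1), a final refit, holdout metrics on the 20%, and paired
Wilcoxon signed-rank comparisons between methods across shared folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .metrics import RankedScreen, confusion, ef, f1, gh, rates, roc_auc

__all__ = [
    "ModelOutputMatrix",
    "EnsembleModel",
    "filter_models",
    "global_voting",
    "build_stacking_dataset",
    "feature_select",
    "train_meta",
    "evaluate_protocol",
    "wilcoxon_compare",
    "STACKING_MODES",
]

logger = logging.getLogger(__name__)

STACKING_MODES = ("predict", "score", "both")

#: Pinned meta-model hyperparameters (documented defaults; seed supplied per run).
META_PARAMS = dict(
    n_estimators=300,
    max_depth=2,
    learning_rate=0.05,
    subsample=1.0,
    colsample_bytree=1.0,
    reg_lambda=1.0,
    eval_metric="logloss",
    n_jobs=1,
)


@dataclass
class ModelOutputMatrix:
    """Molecules x models outputs of a pharmacophore screen, with labels."""

    molecule_ids: list[str]
    model_names: list[str]
    predictions: np.ndarray  # (n_molecules, n_models) 0/1
    rescores: np.ndarray  # (n_molecules, n_models) float, nan where no match
    labels: np.ndarray  # (n_molecules,) 0/1

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=int)
        self.rescores = np.asarray(self.rescores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = len(self.molecule_ids), len(self.model_names)
        if self.predictions.shape != (n, m) or self.rescores.shape != (n, m):
            raise ValueError("matrix shapes disagree")
        if self.labels.shape != (n,):
            raise ValueError("one label per molecule required")
        if len(set(self.model_names)) != m:
            raise ValueError("model names must be unique")

    def subset_rows(self, idx: np.ndarray) -> "ModelOutputMatrix":
        return ModelOutputMatrix(
            molecule_ids=[self.molecule_ids[i] for i in idx],
            model_names=list(self.model_names),
            predictions=self.predictions[idx],
            rescores=self.rescores[idx],
            labels=self.labels[idx],
        )

    def model_scores(self, name: str) -> np.ndarray:
        """Continuous score for one model: rescores with nan (no match)
        replaced by a value below every observed rescore, falling back to the
        binary predictions if the model has no finite rescores at all."""
        j = self.model_names.index(name)
        col = self.rescores[:, j].copy()
        finite = np.isfinite(col)
        if not finite.any():
            return self.predictions[:, j].astype(float)
        floor = col[finite].min() - 1.0
        col[~finite] = floor
        return col

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, mid in enumerate(self.molecule_ids):
            for j, name in enumerate(self.model_names):
                rows.append(
                    {
                        "molecule_id": mid,
                        "model": name,
                        "prediction": int(self.predictions[i, j]),
                        "rescore": self.rescores[i, j],
                        "label": int(self.labels[i]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ModelOutputMatrix":
        pivot_p = frame.pivot(index="molecule_id", columns="model", values="prediction")
        pivot_s = frame.pivot(index="molecule_id", columns="model", values="rescore")
        labels = frame.groupby("molecule_id")["label"].first()
        mids = list(pivot_p.index)
        return cls(
            molecule_ids=mids,
            model_names=list(pivot_p.columns),
            predictions=pivot_p.to_numpy(),
            rescores=pivot_s.to_numpy(),
            labels=labels.loc[mids].to_numpy(),
        )


@dataclass
class EnsembleModel:
    """Specification plus fitted state of an ensemble.

    ``kind`` is one of voting, stack_predict, stack_score, stack_global,
    stack_featsel.
    """

    kind: str
    auc_threshold: float = 0.6
    seed: int = 0
    p_top: list[str] = field(default_factory=list)
    selected_features: list[str] | None = None
    meta: object | None = None  # fitted classifier for stacking kinds

    KINDS = ("voting", "stack_predict", "stack_score", "stack_global", "stack_featsel")
    _MODE_BY_KIND = {
        "stack_predict": "predict",
        "stack_score": "score",
        "stack_global": "both",
        "stack_featsel": "both",
    }

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown ensemble kind {self.kind!r}")

    @property
    def mode(self) -> str | None:
        return self._MODE_BY_KIND.get(self.kind)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def filter_models(outputs: ModelOutputMatrix, theta: float) -> list[str]:
    """Model names with individual AUC >= theta, in descending AUC order.

    AUC is computed on the rescore-based continuous score (binary
    predictions when a model never produced a rescore).
    """
    if not (0.5 <= theta <= 1.0):
        raise ValueError("theta must lie in [0.5, 1]")
    aucs = []
    for name in outputs.model_names:
        scores = outputs.model_scores(name)
        _, _, auc = roc_auc(RankedScreen(scores=scores, labels=outputs.labels))
        aucs.append((auc, name))
    passing = [(a, n) for a, n in aucs if a >= theta]
    if not passing:
        raise ValueError("no_models_pass_threshold")
    passing.sort(key=lambda t: (-t[0], outputs.model_names.index(t[1])))
    return [n for _, n in passing]


def global_voting(outputs: ModelOutputMatrix, p_top: list[str]) -> np.ndarray:
    """Strict-majority vote over the selected models; exact ties -> inactive."""
    if not p_top:
        raise ValueError("p_top must be nonempty")
    cols = [outputs.model_names.index(n) for n in p_top]
    votes = outputs.predictions[:, cols].sum(axis=1)
    return (votes * 2 > len(p_top)).astype(int)


def voting_scores(outputs: ModelOutputMatrix, p_top: list[str]) -> np.ndarray:
    """Fraction of positive votes — the natural continuous score for voting."""
    cols = [outputs.model_names.index(n) for n in p_top]
    return outputs.predictions[:, cols].mean(axis=1)


def build_stacking_dataset(
    outputs: ModelOutputMatrix, p_top: list[str], mode: str = "both"
) -> pd.DataFrame:
    """Feature table for the meta-model.

    ``predict`` -> one binary column per model; ``score`` -> one rescore
    column per model (nan imputed below the observed minimum); ``both`` ->
    predictions first, then rescores, in P_top order.
    """
    if mode not in STACKING_MODES:
        raise ValueError(f"unknown stacking mode {mode!r}")
    if not p_top:
        raise ValueError("p_top must be nonempty")
    data: dict[str, np.ndarray] = {}
    if mode in ("predict", "both"):
        for name in p_top:
            data[f"pred:{name}"] = outputs.predictions[
                :, outputs.model_names.index(name)
            ]
    if mode in ("score", "both"):
        for name in p_top:
            data[f"score:{name}"] = outputs.model_scores(name)
    return pd.DataFrame(data, index=outputs.molecule_ids)


def feature_select(
    d_new: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 300,
) -> list[str]:
    """Random-forest importance screen: keep features above mean importance.

    Degenerate rule: with two or fewer features everything is kept (nothing
    can clear its own mean).  Raises on uniformly zero importances.
    """
    if d_new.shape[1] <= 2:
        return list(d_new.columns)
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(d_new.to_numpy(), np.asarray(labels, dtype=int))
    imp = rf.feature_importances_
    if not (imp > 0).any():
        raise ValueError("uninformative_features: all importances are zero")
    keep = imp > imp.mean()
    return [c for c, k in zip(d_new.columns, keep) if k]


class _ConstantModel:
    """Fallback when training labels contain a single class: predicts the
    majority class with full confidence (the all-inactive collapse)."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, x) -> np.ndarray:
        return np.full(len(x), self.value, dtype=int)

    def predict_proba(self, x) -> np.ndarray:
        p = np.zeros((len(x), 2))
        p[:, self.value] = 1.0
        return p


def train_meta(d_new: pd.DataFrame, labels: np.ndarray, seed: int = 0):
    """Fit the XGBoost meta-model on the stacking dataset.

    Single-class training data yields a constant majority-class model (with a
    warning) instead of an error — matching the behaviour of a screen whose
    selected models are too weak and imbalanced to learn from.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        maj = int(np.bincount(y, minlength=2).argmax())
        warnings.warn("single-class training labels: fitting a constant model")
        return _ConstantModel(maj)
    model = XGBClassifier(random_state=seed, **META_PARAMS)
    model.fit(d_new.to_numpy(), y)
    return model


def _ensemble_scores(
    ens: EnsembleModel, outputs: ModelOutputMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(predictions, continuous scores) of a fitted ensemble on a matrix."""
    if ens.kind == "voting":
        return global_voting(outputs, ens.p_top), voting_scores(outputs, ens.p_top)
    d = build_stacking_dataset(outputs, ens.p_top, ens.mode)
    if ens.selected_features is not None:
        d = d[ens.selected_features]
    proba = ens.meta.predict_proba(d.to_numpy())[:, 1]
    return (proba >= 0.5).astype(int), proba


def fit_ensemble(
    spec: EnsembleModel, outputs: ModelOutputMatrix
) -> EnsembleModel:
    """Fit an ensemble (meta-model and/or feature selection) on a training matrix.

    ``spec.p_top`` must already be set (model filtering happens once, on the
    full training portion, to keep the member set stable across CV folds).
    """
    fitted = EnsembleModel(
        kind=spec.kind,
        auc_threshold=spec.auc_threshold,
        seed=spec.seed,
        p_top=list(spec.p_top),
    )
    if spec.kind == "voting":
        return fitted
    d = build_stacking_dataset(outputs, fitted.p_top, fitted.mode)
    if spec.kind == "stack_featsel":
        fitted.selected_features = feature_select(d, outputs.labels, seed=spec.seed)
        d = d[fitted.selected_features]
    fitted.meta = train_meta(d, outputs.labels, seed=spec.seed)
    return fitted


def predict_ensemble(
    ens: EnsembleModel, outputs: ModelOutputMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted ensemble; returns (binary predictions, scores)."""
    return _ensemble_scores(ens, outputs)


def _screen_metrics(
    preds: np.ndarray, scores: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    counts = confusion(preds, labels)
    out = {"gh": gh(counts), "f1": f1(counts), **rates(counts)}
    ranked = RankedScreen(scores=scores, labels=labels)
    try:
        _, _, out["auc"] = roc_auc(ranked)
    except ValueError:
        out["auc"] = float("nan")
    try:
        out["ef1"] = ef(ranked, 1.0)
    except ValueError:
        out["ef1"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# validation protocol
# ---------------------------------------------------------------------------

def evaluate_protocol(
    spec: EnsembleModel,
    outputs: ModelOutputMatrix,
    seed: int = 0,
    n_splits: int = 10,
    n_repeats: int = 3,
    holdout_fraction: float = 0.2,
) -> dict:
    """Stratified 80:20 split, repeated stratified k-fold CV, holdout metrics.

    Model filtering (AUC >= theta) runs on the 80% training portion only, so
    the holdout never leaks into member selection.  Within the 80%, each of
    the ``n_repeats x n_splits`` folds refits the ensemble on the remaining
    folds and measures AUC / EF1% / GH / F1 on the held-out fold.  Finally
    the ensemble is refit on the full 80% and measured on the 20% holdout.
    """
    y = outputs.labels
    if y.sum() < 2 * n_splits:
        raise ValueError("too few actives for stratified cross-validation")
    idx = np.arange(len(y))
    train_idx, hold_idx = train_test_split(
        idx, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    train_idx = np.sort(train_idx)
    hold_idx = np.sort(hold_idx)
    train = outputs.subset_rows(train_idx)
    holdout = outputs.subset_rows(hold_idx)

    spec = EnsembleModel(
        kind=spec.kind, auc_threshold=spec.auc_threshold, seed=seed
    )
    spec.p_top = filter_models(train, spec.auc_threshold)

    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    fold_rows = []
    for fold_no, (fit_i, val_i) in enumerate(cv.split(np.zeros(len(train.labels)), train.labels)):
        fitted = fit_ensemble(spec, train.subset_rows(fit_i))
        val = train.subset_rows(val_i)
        preds, scores = predict_ensemble(fitted, val)
        m = _screen_metrics(preds, scores, val.labels)
        m["fold"] = fold_no
        fold_rows.append(m)
    folds = pd.DataFrame(fold_rows).set_index("fold")

    final = fit_ensemble(spec, train)
    preds, scores = predict_ensemble(final, holdout)
    holdout_metrics = _screen_metrics(preds, scores, holdout.labels)

    summary = {
        metric: {"mean": float(folds[metric].mean()), "sd": float(folds[metric].std())}
        for metric in ("auc", "ef1", "gh", "f1")
    }
    return {
        "p_top": spec.p_top,
        "fold_metrics": folds,
        "cv_summary": summary,
        "holdout": holdout_metrics,
        "fitted": final,
    }


def wilcoxon_compare(
    series_a: np.ndarray, series_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Two-sided paired Wilcoxon signed-rank test over shared CV folds.

    Zero-difference pairs are dropped; if every pair is tied the test is
    vacuous (p = 1, not significant).  Requires at least 6 pairs.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be equal-length 1-D arrays")
    if len(a) < 6:
        raise ValueError("insufficient pairs for a signed-rank test (need >= 6)")
    diffs = b - a
    if np.allclose(diffs, 0.0):
        return {"statistic": float("nan"), "p_value": 1.0, "significant": False}
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p), "significant": bool(p <= alpha)}
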