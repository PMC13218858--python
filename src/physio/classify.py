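"""Participant-wise cross-validated logistic discrimination of conditions.

Window-level 80-dimensional feature vectors are classified as GamePlay vs.
GameWatch with L2-regularized logistic regression under 10-fold
cross-validation performed participant-wise: every window of a participant
sits in one fold, so a participant never contributes to both training and
testing of the same fold and no within-subject information leaks through
standardization or imputation (both use training-fold statistics only).

The module also runs the two modality ablations (without EMG: 63 features;
without EMG and EDA: 51) on identical folds, and a single-feature screen
giving each feature's full-data logistic coefficient, Wald p (BH-FDR
corrected within the screen) and cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_NAMES, feature_subset
from .stats import bh_fdr

POSITIVE_CLASS = "GamePlay"


@dataclass
class FoldAssignment:
    """participant_id -> fold index; all of a participant's windows share
    one fold and fold sizes differ by at most one participant."""

    folds: dict[str, int]
    k: int
    seed: int


@dataclass
class CVReport:
    feature_set: str
    accuracy: float               # pooled over windows: correct / total
    per_fold: list[float]
    n_windows: int
    n_features: int
    seed: int


@dataclass
class SingleFeatureResult:
    feature: str
    beta: float     # logistic coefficient on the standardized feature
    p: float        # Wald test, BH-FDR corrected within the screen
    p_raw: float
    accuracy: float


def assign_folds(participants: pd.DataFrame, k: int = 10,
                 seed: int = 0) -> FoldAssignment:
    """Condition-stratified round-robin fold assignment.

    `participants` has columns ``participant_id`` and ``condition``.  After
    a seeded shuffle, one condition is dealt to folds 0, 1, ... and the
    other to folds k-1, k-2, ..., which balances both fold sizes and class
    mix (28 participants at k=10 give eight folds of 3 and two of 2).
    """
    if k < 2:
        raise ValueError("k must be >= 2 for held-out evaluation")
    ids = participants["participant_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("participant_ids must be unique")
    if len(ids) < k:
        raise ValueError("more folds than participants")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    conditions = sorted(participants["condition"].unique())
    for c_idx, cond in enumerate(conditions):
        members = sorted(
            participants.loc[participants["condition"] == cond,
                             "participant_id"])
        rng.shuffle(members)
        for i, pid in enumerate(members):
            folds[pid] = (i % k) if c_idx == 0 else (k - 1 - (i % k))
    return FoldAssignment(folds=folds, k=k, seed=seed)


def _design(matrix: pd.DataFrame, feature_set: list[str]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = matrix[feature_set].to_numpy(float)
    y = (matrix["condition"] == POSITIVE_CLASS).to_numpy()
    pids = matrix["participant_id"].to_numpy()
    return X, y, pids


def _fit_fold(X_tr, y_tr, X_te, C: float) -> np.ndarray:
    """Standardize + mean-impute with training statistics, fit, predict."""
    mu = np.nanmean(X_tr, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    X_tr = np.where(np.isnan(X_tr), mu, X_tr)
    X_te = np.where(np.isnan(X_te), mu, X_te)
    sd = X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    X_tr = (X_tr - mu) / sd
    X_te = (X_te - mu) / sd
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(X_tr, y_tr)
    return clf.predict(X_te)


def cross_validate(matrix: pd.DataFrame, feature_set: list[str],
                   folds: FoldAssignment, C: float = 1.0,
                   name: str | None = None) -> CVReport:
    """Participant-wise k-fold CV accuracy for one feature set.

    Accuracy is pooled over windows (total correct / total windows);
    per-fold accuracies are reported alongside.  A training fold with one
    class raises ``degenerate fold``.
    """
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    missing = [f for f in feature_set if f not in matrix.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing[:3]}")
    X, y, pids = _design(matrix, feature_set)
    fold_of = np.array([folds.folds[p] for p in pids])
    correct = 0
    per_fold = []
    for f in range(folds.k):
        te = fold_of == f
        tr = ~te
        if te.sum() == 0:
            per_fold.append(np.nan)
            continue
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate fold: single class in training")
        pred = _fit_fold(X[tr], y[tr], X[te], C)
        correct += int((pred == y[te]).sum())
        per_fold.append(float((pred == y[te]).mean()))
    return CVReport(
        feature_set=name or f"{len(feature_set)} features",
        accuracy=correct / len(y),
        per_fold=per_fold,
        n_windows=len(y),
        n_features=len(feature_set),
        seed=folds.seed,
    )


ABLATIONS: dict[str, tuple[str, ...]] = {
    "full": (),
    "no_emg": ("EMG",),
    "no_emg_eda": ("EMG", "EDA"),
}


def ablation_suite(matrix: pd.DataFrame, folds: FoldAssignment,
                   C: float = 1.0) -> dict[str, CVReport]:
    """Full / without-EMG / without-EMG-and-EDA models on identical folds."""
    out = {}
    for name, dropped in ABLATIONS.items():
        subset = feature_subset(dropped)
        out[name] = cross_validate(matrix, subset, folds, C=C, name=name)
    return out


def single_feature_screen(matrix: pd.DataFrame, folds: FoldAssignment,
                          C: float = 1.0, top_n: int | None = None
                          ) -> list[SingleFeatureResult]:
    """Per-feature logistic fits: beta and Wald p from the full data
    (standardized, mean-imputed), CV accuracy on the shared folds.

    Constant features are skipped.  p-values are BH-FDR corrected within
    the screen; results are sorted by accuracy, descending.
    """
    results = []
    p_raw = []
    for feat in FEATURE_NAMES:
        x = matrix[feat].to_numpy(float)
        y = (matrix["condition"] == POSITIVE_CLASS).to_numpy().astype(float)
        mu = np.nanmean(x)
        x = np.where(np.isnan(x), mu, x)
        sd = x.std()
        if not np.isfinite(sd) or sd == 0:
            continue
        xs = (x - mu) / sd
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
            beta = float(fit.params[1])
            converged = bool(fit.mle_retvals.get("converged", True))
            se = float(fit.bse[1])
            if converged and np.isfinite(se) and se < 1e3:
                p = float(fit.pvalues[1])
            else:  # (near-)perfect separation: Wald SE blows up, use LR
                p = float(fit.llr_pvalue)
        except Exception:  # pragma: no cover - separation and friends
            beta, p = np.inf, 0.0
        acc = cross_validate(matrix, [feat], folds, C=C, name=feat).accuracy
        results.append(SingleFeatureResult(
            feature=feat, beta=beta, p=np.nan, p_raw=p, accuracy=acc))
        p_raw.append(p)
    adj = bh_fdr(p_raw)
    for r, q in zip(results, adj):
        r.p = float(q)
    results.sort(key=lambda r: r.accuracy, reverse=True)
    return results[:top_n] if top_n is not None else results


def screen_table(results: list[SingleFeatureResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"feature": r.feature, "p": r.p, "beta": r.beta,
         "accuracy": r.accuracy}
        for r in results
    ])
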