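"""Classifiers for response prediction: weighted LS-SVM and random forests.

The least-squares SVM replaces the SVM's hinge loss with a squared error, so
training reduces to one symmetric linear system in the dual variables.  With
per-sample weights ``w_i`` correcting class imbalance the optimality
conditions read::

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + D(1/(g w))] [ alpha ] = [ y ]

where ``K`` is the kernel Gram matrix, ``g`` the regularization constant and
``D`` a diagonal matrix. We use the standard class-balancing weights
``w_i = N / (2 N_class(i))``, which make both classes contribute equally to
the loss. The decision value of a new profile is
``f(x) = sum_i alpha_i k(x, x_i) + b`` and is mapped to a response
probability through a two-parameter sigmoid fitted on training decision
values (Platt scaling).

Model quality is estimated by repeated stratified divisions into 2/3
training and 1/3 test lines; every supervised step (standardization, feature
ranking, grid search, calibration) is refit inside each training fold, and
the rank-based AUC on the held-out third is averaged over splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .datatypes import AnalysisConfig, Signature
from .feature_prep import two_sample_t

logger = logging.getLogger(__name__)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC: P(random positive outscores a random negative).

    Ties count one half. ``labels`` may be boolean or +/-1; both classes must
    be present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y > 0 if y.dtype != bool else y
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


# ---------------------------------------------------------------------------
# weighted LS-SVM
# ---------------------------------------------------------------------------

def _kernel_matrix(
    A: np.ndarray, B: np.ndarray, kernel: str, kernel_param: float | None
) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "radial":
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        sigma2 = kernel_param if kernel_param else float(A.shape[1])
        return np.exp(-np.maximum(sq, 0.0) / (2.0 * sigma2))
    raise ValueError(f"unknown kernel {kernel!r}")


def class_balance_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights N / (2 N_class); equal to 1 for balanced classes."""
    y = np.asarray(y)
    n = y.size
    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    return np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))


@dataclass
class LssvmModel:
    """Fitted weighted LS-SVM (dual form) with probability calibration."""

    X_train: np.ndarray
    y_train: np.ndarray
    kernel: str
    kernel_param: float | None
    gamma: float
    weights: np.ndarray
    alpha: np.ndarray
    b: float
    calib_slope: float = 1.0
    calib_offset: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = _kernel_matrix(
            np.asarray(X, dtype=float), self.X_train, self.kernel,
            self.kernel_param,
        )
        return K @ self.alpha + self.b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the sensitive (+1) class."""
        f = self.decision_function(X)
        z = self.calib_slope * f + self.calib_offset
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def train_weighted_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = 1.0,
    kernel: str = "linear",
    kernel_param: float | None = None,
    weights: np.ndarray | None = None,
    calibrate: bool = True,
) -> LssvmModel:
    """Solve the weighted LS-SVM saddle system for (b, alpha).

    ``y`` must be +/-1 with both classes present. Features are expected to be
    standardized on the training data by the caller. A singular system gets
    one ridge-jitter retry before failing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not set(np.unique(y)) <= {-1.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes coded +/-1")
    w = class_balance_weights(y) if weights is None else np.asarray(weights)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    K = _kernel_matrix(X, X, kernel, kernel_param)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.diag(1.0 / (gamma * w))
    rhs = np.concatenate(([0.0], y))
    try:
        sol = scipy.linalg.solve(A, rhs)
    except scipy.linalg.LinAlgError:
        A[1:, 1:] += 1e-8 * np.eye(n)
        try:
            sol = scipy.linalg.solve(A, rhs)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"LS-SVM system singular even after ridge jitter: {exc}"
            ) from exc
    model = LssvmModel(
        X_train=X, y_train=y, kernel=kernel, kernel_param=kernel_param,
        gamma=gamma, weights=w, alpha=sol[1:], b=float(sol[0]),
    )
    if calibrate:
        f = model.decision_function(X)
        model.calib_slope, model.calib_offset = _fit_sigmoid(f, y)
    return model


def _fit_sigmoid(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt scaling: logistic fit of class on the scalar decision value."""
    if np.ptp(f) < 1e-12:
        return 1.0, 0.0
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(f.reshape(-1, 1), (y > 0).astype(int))
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


# ---------------------------------------------------------------------------
# feature/hyperparameter grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    k: int
    gamma: float
    kernel: str
    kernel_param: float | None
    mean_inner_auc: float
    ranked_features: np.ndarray  # feature indices, best first, ranked on all data


def grid_search_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: tuple[int, ...] = (25, 50, 100, 200, 400),
    gamma_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    kernel: str = "linear",
    kernel_param: float | None = None,
    inner_folds: int = 3,
    seed: int = 0,
) -> GridSearchResult:
    """Choose feature count k and regularization by inner cross-validation.

    Features are ranked by absolute two-sample t statistic inside each inner
    training fold (never on validation lines); the (k, gamma) cell with the
    highest mean inner-fold AUC wins, ties resolved toward the smallest k and
    then the smallest gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    ks = sorted({min(k, p) for k in k_grid})
    gammas = sorted(gamma_grid)
    cells = [(k, g) for k in ks for g in gammas]
    sums = {c: 0.0 for c in cells}
    counts = {c: 0 for c in cells}
    n_class_min = min(int((y > 0).sum()), int((y < 0).sum()))
    folds = max(2, min(inner_folds, n_class_min))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2:
            continue
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xva = (X[va] - mu) / sd
        order = np.argsort(-np.abs(two_sample_t(Xtr, y[tr])), kind="stable")
        for k, g in cells:
            idx = order[:k]
            model = train_weighted_lssvm(
                Xtr[:, idx], y[tr], gamma=g, kernel=kernel,
                kernel_param=kernel_param, calibrate=False,
            )
            sums[(k, g)] += auc(model.decision_function(Xva[:, idx]), y[va])
            counts[(k, g)] += 1
    best = max(
        cells,
        key=lambda c: (
            sums[c] / max(counts[c], 1), -c[0], -c[1],
        ),
    )
    ranking = np.argsort(-np.abs(two_sample_t(X, y)), kind="stable")
    return GridSearchResult(
        k=best[0],
        gamma=best[1],
        kernel=kernel,
        kernel_param=kernel_param,
        mean_inner_auc=sums[best] / max(counts[best], 1),
        ranked_features=ranking,
    )


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Classification forest; probability = fraction of trees voting sensitive.

    ``mtry`` defaults to sqrt(p). Deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    y01 = (np.asarray(y) > 0).astype(int)
    if len(np.unique(y01)) < 2:
        raise ValueError("both classes required")
    mf = mtry if mtry is not None else "sqrt"
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mf, random_state=seed, n_jobs=1
    )
    rf.fit(X, y01)
    return rf


# ---------------------------------------------------------------------------
# multi-split evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """AUC estimates from repeated stratified train/test divisions."""

    compound: str
    method: str
    data_types: list[str]
    per_split_auc: list[float]
    seed: int
    splits: list[tuple[list[int], list[int]]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_split_auc))


def _standardize_columns(
    Xtr: np.ndarray, Xte: np.ndarray, binary_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardize continuous columns on the training rows; leave 0/1 as-is."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    mu = np.where(binary_cols, 0.0, mu)
    sd = np.where(binary_cols, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd, mu, sd


def detect_binary_columns(X: np.ndarray) -> np.ndarray:
    """Columns whose non-missing values are all 0/1 (mutation indicators)."""
    X = np.asarray(X, dtype=float)
    is01 = np.isnan(X) | (X == 0.0) | (X == 1.0)
    return is01.all(axis=0)


def evaluate_multisplit(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "lssvm",
    n_splits: int = 100,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    select_features: bool | None = None,
) -> EvaluationResult:
    """Mean test AUC over repeated stratified 2/3 | 1/3 divisions.

    The whole supervised pipeline — standardization, feature ranking, the
    (k, gamma) grid search, model fitting, calibration — is refit on each
    training fold; the held-out third only ever provides scores for the AUC.
    ``select_features`` defaults to on when more than 20 features are
    available (subtype baselines with a handful of indicators skip it).
    """
    cfg = config or AnalysisConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 labeled lines")
    if min(int((y > 0).sum()), int((y < 0).sum())) < 2:
        raise ValueError("need at least 2 lines per class")
    if method not in ("lssvm", "rf"):
        raise ValueError(f"unknown method {method!r}")
    if select_features is None:
        select_features = X.shape[1] > 20
    binary_cols = detect_binary_columns(X)
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=cfg.train_fraction, random_state=seed
    )
    aucs: list[float] = []
    splits: list[tuple[list[int], list[int]]] = []
    for split_no, (tr, te) in enumerate(sss.split(X, y)):
        if len(np.unique(y[te])) < 2:  # pragma: no cover - stratified guard
            logger.warning("split %d has a single-class test set; skipped",
                           split_no)
            continue
        Xtr, Xte, _, _ = _standardize_columns(X[tr], X[te], binary_cols)
        Xtr = np.nan_to_num(Xtr)
        Xte = np.nan_to_num(Xte)
        if method == "lssvm":
            if select_features:
                gs = grid_search_lssvm(
                    Xtr, y[tr], k_grid=cfg.k_grid, gamma_grid=cfg.gamma_grid,
                    kernel=cfg.kernel, inner_folds=cfg.inner_folds,
                    seed=seed + split_no,
                )
                idx = gs.ranked_features[: gs.k]
                g = gs.gamma
            else:
                gs = grid_search_lssvm(
                    Xtr, y[tr], k_grid=(Xtr.shape[1],),
                    gamma_grid=cfg.gamma_grid, kernel=cfg.kernel,
                    inner_folds=cfg.inner_folds, seed=seed + split_no,
                )
                idx = np.arange(Xtr.shape[1])
                g = gs.gamma
            model = train_weighted_lssvm(
                Xtr[:, idx], y[tr], gamma=g, kernel=cfg.kernel,
                calibrate=False,
            )
            scores = model.decision_function(Xte[:, idx])
        else:
            rf = train_rf(
                Xtr, y[tr], n_trees=cfg.n_trees, seed=seed + split_no
            )
            scores = rf.predict_proba(Xte)[:, 1]
        aucs.append(auc(scores, y[te]))
        splits.append((tr.tolist(), te.tolist()))
    return EvaluationResult(
        compound="", method=method, data_types=[], per_split_auc=aucs,
        seed=seed, splits=splits,
    )


def train_signature(
    X: np.ndarray,
    y: np.ndarray,
    feature_keys: list[str],
    feature_data_types: list[str],
    compound: str,
    method: str = "lssvm",
    config: AnalysisConfig | None = None,
    evaluation: EvaluationResult | None = None,
    gi50_threshold: float = float("nan"),
    dynamic_range: float = 0.0,
    select_features: bool | None = None,
) -> Signature:
    """Fit the final model on all labeled lines and package it as a Signature.

    ``evaluation`` (from :func:`evaluate_multisplit`) supplies the per-split
    AUC record; the final model itself is refit on the full labeled set with
    the grid search re-run there.
    """
    cfg = config or AnalysisConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if select_features is None:
        select_features = X.shape[1] > 20
    binary_cols = detect_binary_columns(X)
    Xs, _, mu, sd = _standardize_columns(X, X, binary_cols)
    Xs = np.nan_to_num(Xs)
    per_split = evaluation.per_split_auc if evaluation else []
    mean_auc = float(np.mean(per_split)) if per_split else float("nan")
    if method == "lssvm":
        k_grid = cfg.k_grid if select_features else (Xs.shape[1],)
        gs = grid_search_lssvm(
            Xs, y, k_grid=k_grid, gamma_grid=cfg.gamma_grid,
            kernel=cfg.kernel, inner_folds=cfg.inner_folds, seed=cfg.seed,
        )
        idx = gs.ranked_features[: gs.k]
        model = train_weighted_lssvm(
            Xs[:, idx], y, gamma=gs.gamma, kernel=cfg.kernel, calibrate=True
        )
        # linear-kernel primal weights for reporting; dual payload for scoring
        if cfg.kernel == "linear":
            w_primal = model.X_train.T @ model.alpha
        else:
            w_primal = np.abs(two_sample_t(Xs[:, idx], y))
        selected = [
            (feature_keys[i], feature_data_types[i], float(w_primal[j]))
            for j, i in enumerate(idx)
        ]
        payload = {
            "kind": "lssvm",
            "feature_keys": [feature_keys[i] for i in idx],
            "feature_data_types": [feature_data_types[i] for i in idx],
            "means": mu[idx],
            "stds": sd[idx],
            "alpha": model.alpha,
            "b": model.b,
            "gamma": gs.gamma,
            "kernel": cfg.kernel,
            "kernel_param": gs.kernel_param,
            "X_train": model.X_train,
            "calib_slope": model.calib_slope,
            "calib_offset": model.calib_offset,
        }
        hyper = {
            "gamma": gs.gamma, "kernel": cfg.kernel, "k": int(gs.k),
            "inner_folds": cfg.inner_folds,
        }
    else:
        rf = train_rf(Xs, y, n_trees=cfg.n_trees, seed=cfg.seed)
        imp = rf.feature_importances_
        order = np.argsort(-imp, kind="stable")
        top = order[: min(len(order), max(cfg.k_grid))]
        selected = [
            (feature_keys[i], feature_data_types[i], float(imp[i]))
            for i in top
        ]
        payload = {
            "kind": "rf",
            "feature_keys": list(feature_keys),
            "feature_data_types": list(feature_data_types),
            "means": mu,
            "stds": sd,
            "_estimator": rf,  # runtime only; dropped on serialization
        }
        hyper = {
            "n_trees": cfg.n_trees, "mtry": "sqrt",
        }
    return Signature(
        compound_id=compound,
        method=method,
        data_types_used=sorted(set(feature_data_types)),
        selected_features=selected,
        hyperparameters=hyper,
        per_split_auc=[float(a) for a in per_split],
        mean_auc=mean_auc,
        gi50_threshold=float(gi50_threshold),
        dynamic_range=float(dynamic_range),
        model_payload=payload,
    )
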