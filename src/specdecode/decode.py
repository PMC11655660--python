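"""Multivariate decoding: pseudo-trials, standardization, PCA + linear SVM
with repeated stratified cross-validation, and cross-subtask
generalization.

The decoding unit is a *pseudo-trial*: the average of ``pseudo_size``
randomly grouped single trials of the same class, which raises
signal-to-noise at the cost of observation count.  Within each
cross-validation split the per-feature standardization and the PCA basis
are fitted on the training portion only and applied to the test portion —
nothing on the training side ever depends on test data.  Performance is the
area under the ROC curve (AUC) computed from continuous decision values,
and the whole procedure is repeated with fresh pseudo-trial draws so results
do not hinge on one particular grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._seeding import derive_int, derive_rng
from .containers import SignalFeatures

logger = logging.getLogger(__name__)


@dataclass
class DecodeConfig:
    """Decoding hyper-parameters.

    Defaults: 5-fold stratified CV repeated 25 times, PCA retaining 99% of
    the training-fold variance, pseudo-trials of 4, linear SVM with C = 1.
    """

    n_folds: int = 5
    n_reps: int = 25
    pca_variance: float = 0.99
    pseudo_size: int = 4
    C: float = 1.0
    tol: float = 1e-8  # SVM convergence; tight so back-projection is exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")
        if self.pseudo_size < 1:
            raise ValueError("pseudo_size must be >= 1")


@dataclass
class DecodingResult:
    """AUC for one (subject, contrast, signal) decoding."""

    auc: float
    rep_aucs: np.ndarray
    n_pseudotrials: int
    n_reps: int


@dataclass
class Standardization:
    train: np.ndarray
    test: np.ndarray | None
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over original features


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, SignalFeatures):
        return features.matrix
    return np.asarray(features, dtype=float)


def make_pseudotrials(
    features,
    labels,
    pseudo_size: int = 4,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average randomly grouped same-class trials into pseudo-trials.

    Within each class, observations are randomly partitioned into groups of
    ``pseudo_size`` and averaged; trials left over when the class size is
    not divisible are dropped.  Class counts are then equalized by randomly
    removing surplus pseudo-trials from the larger class.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = np.unique(y)
    grouped_X, grouped_y = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) < pseudo_size:
            raise ValueError(
                f"class {cls!r} has {len(idx)} observations, fewer than "
                f"pseudo_size={pseudo_size}"
            )
        perm = rng.permutation(idx)
        n_full = len(idx) // pseudo_size
        groups = perm[: n_full * pseudo_size].reshape(n_full, pseudo_size)
        grouped_X.append(X[groups].mean(axis=1))
        grouped_y.append(np.repeat(cls, n_full))
    n_keep = min(len(g) for g in grouped_X)
    out_X, out_y = [], []
    for gX, gy in zip(grouped_X, grouped_y):
        if len(gX) > n_keep:
            keep = np.sort(rng.choice(len(gX), size=n_keep, replace=False))
            gX, gy = gX[keep], gy[:n_keep]
        out_X.append(gX)
        out_y.append(gy)
    return np.concatenate(out_X, axis=0), np.concatenate(out_y)


def standardize(
    train: np.ndarray,
    test: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> Standardization:
    """Per-feature z-scoring with statistics from the training set only.

    Zero-variance features cannot be scaled and are dropped from both
    matrices, with a logged warning naming them.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    kept = sd > 0
    if not kept.all():
        names = (
            [feature_names[i] for i in np.flatnonzero(~kept)]
            if feature_names is not None
            else np.flatnonzero(~kept).tolist()
        )
        logger.warning("dropping zero-variance features: %s", names)
    train_s = (train[:, kept] - mean[kept]) / sd[kept]
    test_s = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        test_s = (test[:, kept] - mean[kept]) / sd[kept]
    return Standardization(train=train_s, test=test_s, mean=mean, sd=sd, kept=kept)


def fit_pca(train: np.ndarray, variance: float) -> PCA:
    """PCA keeping the smallest component count whose cumulative explained
    variance reaches ``variance``."""
    full = PCA(svd_solver="full").fit(train)
    if variance >= 1.0:
        return full
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance - 1e-12) + 1)
    full.components_ = full.components_[:k]
    full.explained_variance_ = full.explained_variance_[:k]
    full.explained_variance_ratio_ = full.explained_variance_ratio_[:k]
    full.n_components_ = k
    return full


def _fit_score(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    config: DecodeConfig,
) -> float:
    """standardize -> PCA -> linear SVM on the training side; AUC of the
    decision values on the test side (positive class = sorted-second)."""
    std = standardize(X_tr, X_te)
    pca = fit_pca(std.train, config.pca_variance)
    z_tr = pca.transform(std.train)
    z_te = pca.transform(std.test)
    clf = SVC(kernel="linear", C=config.C, tol=config.tol)
    clf.fit(z_tr, y_tr)
    scores = clf.decision_function(z_te)
    return float(roc_auc_score((y_te == clf.classes_[1]).astype(int), scores))


def decode_within(features, labels, config: DecodeConfig) -> DecodingResult:
    """Repeated stratified k-fold decoding of a binary contrast.

    Each repetition draws fresh pseudo-trials, runs stratified
    ``config.n_folds``-fold CV with per-split standardization, PCA and a
    linear SVM, and averages the per-fold AUCs; the result averages over
    repetitions.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("decode_within requires exactly two classes")
    rep_aucs = np.empty(config.n_reps)
    n_pseudo = 0
    for rep in range(config.n_reps):
        rng = derive_rng(config.seed, "pseudo", rep)
        Xp, yp = make_pseudotrials(X, y, config.pseudo_size, rng)
        n_pseudo = len(Xp)
        counts = pd.Series(yp).value_counts()
        if counts.min() < config.n_folds:
            raise ValueError(
                f"only {counts.min()} pseudo-trials in the smaller class; "
                f"cannot stratify {config.n_folds} folds"
            )
        skf = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=derive_int(config.seed, "fold", rep),
        )
        fold_aucs = [
            _fit_score(Xp[tr], yp[tr], Xp[te], yp[te], config)
            for tr, te in skf.split(Xp, yp)
        ]
        rep_aucs[rep] = np.mean(fold_aucs)
    return DecodingResult(
        auc=float(rep_aucs.mean()),
        rep_aucs=rep_aucs,
        n_pseudotrials=n_pseudo,
        n_reps=config.n_reps,
    )


def decode_cross(
    train_features,
    train_labels,
    test_features,
    test_labels,
    config: DecodeConfig,
) -> float:
    """Train on all pseudo-trials of one subtask, test on another.

    No fold splitting: the classifier (and its standardization and PCA,
    fitted on the training subtask only) sees every training pseudo-trial;
    the AUC is measured on the test subtask's pseudo-trials.  Averaged over
    ``config.n_reps`` fresh pseudo-trial draws.
    """
    if isinstance(train_features, SignalFeatures) and isinstance(
        test_features, SignalFeatures
    ):
        if train_features.feature_ids != test_features.feature_ids:
            raise ValueError("train and test feature_ids differ")
        if train_features.signal != test_features.signal:
            raise ValueError("train and test signals differ")
    X_a, y_a = _as_matrix(train_features), np.asarray(train_labels)
    X_b, y_b = _as_matrix(test_features), np.asarray(test_labels)
    aucs = np.empty(config.n_reps)
    for rep in range(config.n_reps):
        Xp_a, yp_a = make_pseudotrials(
            X_a, y_a, config.pseudo_size, derive_rng(config.seed, "cross-train", rep)
        )
        Xp_b, yp_b = make_pseudotrials(
            X_b, y_b, config.pseudo_size, derive_rng(config.seed, "cross-test", rep)
        )
        aucs[rep] = _fit_score(Xp_a, yp_a, Xp_b, yp_b, config)
    return float(aucs.mean())


def generalization_matrix(features_by_subtask: dict, config: DecodeConfig) -> pd.DataFrame:
    """Symmetric subtask x subtask table of direction-averaged AUC.

    ``features_by_subtask`` maps a subtask name to ``(features, labels)``.
    Diagonal entries are within-subtask decoding; off-diagonal entry (a, b)
    is the mean of the a->b and b->a cross-decoding AUCs.  Each cell's seed
    is derived from the involved subtask names, so the table is independent
    of dict ordering.
    """
    names = list(features_by_subtask)
    if len(names) < 2:
        raise ValueError("need at least two subtasks")
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        Xa, ya = features_by_subtask[a]
        cfg_a = replace(config, seed=derive_int(config.seed, "within", a))
        mat.loc[a, a] = decode_within(Xa, ya, cfg_a).auc
        for b in names[i + 1:]:
            Xb, yb = features_by_subtask[b]
            key = tuple(sorted((a, b)))
            cfg_ab = replace(config, seed=derive_int(config.seed, "cross", *key))
            fwd = decode_cross(Xa, ya, Xb, yb, cfg_ab)
            bwd = decode_cross(Xb, yb, Xa, ya, cfg_ab)
            mat.loc[a, b] = mat.loc[b, a] = 0.5 * (fwd + bwd)
    return mat
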