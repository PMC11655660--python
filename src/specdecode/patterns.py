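"""Interpretable spatial activation patterns from classifier weights.

Linear classifier weights are extraction filters, not activation maps: a
channel can receive a large weight purely to cancel noise shared with other
channels.  Multiplying the weights by the feature covariance (the Haufe
forward-model projection) converts them into the pattern of signal the
classifier actually tracks; for two Gaussian classes with equal covariance
this pattern is proportional to the difference of class means.

Sign convention: classes are ordered alphabetically, and positive pattern
values indicate greater signal in the second-named class (``hard`` for the
demand contrast, ``colour`` for the content contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import derive_rng
from .containers import SignalFeatures
from .decode import DecodeConfig, fit_pca, make_pseudotrials, standardize, _as_matrix
from sklearn.svm import SVC


@dataclass
class ActivationPattern:
    """Signed per-feature contribution vector, unit norm."""

    values: np.ndarray
    feature_ids: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern contains non-finite values")
        if len(self.values) != len(self.feature_ids):
            raise ValueError("values and feature_ids lengths differ")


@dataclass
class FullFit:
    """Classifier fitted on all pseudo-trials, with weights back-projected
    into the original feature space."""

    weights: np.ndarray  # original feature space; zero at dropped features
    standardized: np.ndarray  # kept-feature pseudo-trial matrix used for the fit
    kept: np.ndarray
    sd: np.ndarray  # per-feature sd used by the standardization
    classes: np.ndarray


def fit_full_weights(features, labels, config: DecodeConfig) -> FullFit:
    """Fit standardize -> PCA -> linear SVM on all pseudo-trials and
    back-project the weights through the PCA basis and the standardization
    scaling into the original feature space.

    With PCA disabled (variance fraction 1 on full-rank data) the
    back-projected weights equal a direct fit's weights.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    Xp, yp = make_pseudotrials(X, y, config.pseudo_size, derive_rng(config.seed, "full-fit"))
    std = standardize(Xp)
    pca = fit_pca(std.train, config.pca_variance)
    z = pca.transform(std.train)
    clf = SVC(kernel="linear", C=config.C, tol=config.tol)
    clf.fit(z, yp)
    w_pca = clf.coef_[0]
    w_std = pca.components_.T @ w_pca
    weights = np.zeros(X.shape[1])
    weights[std.kept] = w_std / std.sd[std.kept]
    return FullFit(
        weights=weights, standardized=std.train, kept=std.kept, sd=std.sd,
        classes=clf.classes_,
    )


def haufe_transform(weights: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Project weights to an activation pattern: covariance times weights,
    normalized to unit norm (Haufe patterns are defined only up to positive
    scale)."""
    X = np.asarray(features, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations for a covariance")
    if X.shape[1] != len(w):
        raise ValueError("weights length does not match feature count")
    cov = np.cov(X, rowvar=False)
    pattern = np.atleast_1d(cov @ w)
    norm = np.linalg.norm(pattern)
    return pattern / norm if norm > 0 else pattern


def activation_pattern(
    features: SignalFeatures, labels, config: DecodeConfig, provenance: dict | None = None
) -> ActivationPattern:
    """Full-fit weights followed by the Haufe projection.

    The covariance is computed from the standardized pseudo-trial features
    used to fit the classifier; weights enter in that same (standardized,
    kept-feature) space.  Dropped zero-variance features get value 0.
    """
    fit = fit_full_weights(features, labels, config)
    # haufe_transform needs the weights in the same (standardized) space as
    # the covariance; fit.weights carry a 1/sd factor from back-projection,
    # undone here.
    pattern_kept = haufe_transform(
        fit.weights[fit.kept] * fit.sd[fit.kept], fit.standardized
    )
    values = np.zeros(len(fit.kept))
    values[fit.kept] = pattern_kept
    norm = np.linalg.norm(values)
    if norm > 0:
        values /= norm
    return ActivationPattern(
        values=values,
        feature_ids=list(features.feature_ids),
        provenance=provenance or {"signal": features.signal},
    )


def aggregate_patterns(patterns: list[ActivationPattern]) -> ActivationPattern:
    """Group pattern: z-score each pattern across its features, then
    average elementwise across patterns (subjects and subtasks)."""
    if not patterns:
        raise ValueError("no patterns to aggregate")
    ids = patterns[0].feature_ids
    for p in patterns:
        if p.feature_ids != ids:
            raise ValueError("patterns have mismatched feature_ids")
    z = []
    for p in patterns:
        v = p.values
        sd = v.std()
        z.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
    return ActivationPattern(
        values=np.mean(z, axis=0), feature_ids=list(ids), provenance={"level": "group"}
    )


def percentile_mask(
    pattern: ActivationPattern, lower_percentile: float
) -> tuple[np.ndarray, np.ndarray]:
    """Retain features whose absolute value ranks at or above the given
    percentile of all absolute values; retained entries keep their sign.

    Ranking uses absolute values because group maps display both signed
    increases and decreases inside the retained range; ties at the
    threshold are all retained.  Returns ``(mask, masked_values)`` with
    non-retained entries set to 0.
    """
    if len(pattern.values) == 0:
        raise ValueError("empty pattern")
    if not 0 <= lower_percentile < 100:
        raise ValueError("lower_percentile must lie in [0, 100)")
    mag = np.abs(pattern.values)
    threshold = np.percentile(mag, lower_percentile)
    mask = mag >= threshold
    return mask, np.where(mask, pattern.values, 0.0)
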