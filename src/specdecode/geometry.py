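"""Low-dimensional representational geometry of the condition design.

Condition-mean feature vectors are embedded into the plane spanned by
their first two principal components; embeddings from different tasks (and
then different participants) are superimposed with a Procrustes alignment
restricted to rigid transforms — centering plus an orthogonal rotation or
reflection, with no scaling — so relative geometry (pairwise distances) is
preserved exactly while nuisance rotations are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .containers import SignalFeatures


@dataclass
class Embedding:
    """Conditions x 2 coordinates with explained-variance fractions."""

    points: np.ndarray
    condition_labels: list[tuple]
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be conditions x 2")
        if self.points.shape[0] != len(self.condition_labels):
            raise ValueError("labels do not match points")


def condition_means(
    features: SignalFeatures, by: tuple = ("task", "content", "demand")
) -> tuple[np.ndarray, list[tuple]]:
    """Elementwise trial mean per labelled condition.

    Returns ``(matrix, labels)`` with one row per condition cell, in sorted
    label order; raises naming any empty cell when a full crossing is
    expected by the caller.
    """
    lab = features.labels
    grouped = lab.groupby(list(by), sort=True, observed=True)
    rows, names = [], []
    for key, idx in grouped.groups.items():
        idx = np.asarray(idx)
        if len(idx) == 0:
            raise ValueError(f"empty condition cell {key}")
        rows.append(features.matrix[idx].mean(axis=0))
        names.append(key if isinstance(key, tuple) else (key,))
    return np.asarray(rows), names


def embed_pca2(means: np.ndarray, condition_labels: list[tuple]) -> Embedding:
    """Project condition means onto their first two principal axes.

    The output is centered; explained-variance fractions are relative to
    the total variance of the (centered) condition means.
    """
    means = np.asarray(means, dtype=float)
    if means.shape[0] < 3:
        raise ValueError("need at least 3 conditions")
    if means.shape[1] < 2:
        raise ValueError("need at least 2 features")
    centered = means - means.mean(axis=0)
    total = (centered**2).sum()
    if total == 0:
        raise ValueError("condition means have rank 0")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    points = u[:, :2] * s[:2]
    explained = s[:2] ** 2 / total
    return Embedding(
        points=points, condition_labels=list(condition_labels), explained_variance=explained
    )


def procrustes_align(
    reference: Embedding, target: Embedding
) -> tuple[Embedding, float]:
    """Center and rotate (orthogonal transform, reflections allowed, no
    scaling) the target onto the reference; returns the aligned target and
    the residual sum of squared distances (disparity)."""
    if reference.condition_labels != target.condition_labels:
        raise ValueError("embeddings have mismatched condition labels")
    ref = reference.points - reference.points.mean(axis=0)
    tgt = target.points - target.points.mean(axis=0)
    rot, _ = orthogonal_procrustes(tgt, ref)
    aligned = tgt @ rot
    disparity = float(((aligned - ref) ** 2).sum())
    return (
        Embedding(
            points=aligned,
            condition_labels=list(target.condition_labels),
            explained_variance=target.explained_variance,
        ),
        disparity,
    )


def average_aligned(embeddings: list[Embedding]) -> Embedding:
    """Align every embedding to the first one (the deterministic reference)
    and average the aligned coordinates elementwise."""
    if not embeddings:
        raise ValueError("no embeddings to average")
    ref = embeddings[0]
    ref_centered = Embedding(
        points=ref.points - ref.points.mean(axis=0),
        condition_labels=list(ref.condition_labels),
        explained_variance=ref.explained_variance,
    )
    stack = [ref_centered.points]
    for emb in embeddings[1:]:
        aligned, _ = procrustes_align(ref_centered, emb)
        stack.append(aligned.points)
    return Embedding(
        points=np.mean(stack, axis=0),
        condition_labels=list(ref.condition_labels),
        explained_variance=np.mean([e.explained_variance for e in embeddings], axis=0),
    )


def embedding_table(embeddings: dict, signal: str) -> pd.DataFrame:
    """Tidy table (signal, task_set, condition, pc1, pc2) for export."""
    rows = []
    for task_set, emb in embeddings.items():
        for label, (x, y) in zip(emb.condition_labels, emb.points):
            rows.append(
                {
                    "signal": signal,
                    "task_set": task_set,
                    "condition": "/".join(map(str, label)),
                    "pc1": x,
                    "pc2": y,
                }
            )
    return pd.DataFrame(rows)
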