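"""Group-level statistics.

Decoding AUCs are tested against chance with one-sample t tests (one-tailed,
since below-chance decoding is uninterpretable), with Benjamini-Hochberg
control of the false discovery rate across each family of tests.  Spatial
pattern similarity is quantified by within-participant Pearson correlations;
the significance of the mean correlation across participants comes from a
permutation test that shuffles the feature order of one pattern
independently within each participant, using the add-one Monte-Carlo
p estimator (1 + #extreme) / (K + 1), which never returns zero.  The
permutation test is two-tailed on |mean r| because both positive and
negative correlations are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeding import derive_rng
from .patterns import ActivationPattern


@dataclass
class PermutationOutcome:
    observed_mean_r: float
    null_values: np.ndarray
    p: float
    K: int
    seed: int


def group_auc_test(aucs, chance: float = 0.5, tail: str = "one") -> tuple[float, float]:
    """One-sample t test of per-subject AUCs against chance.

    ``tail='one'`` tests the greater-than-chance direction.
    Returns ``(t, p)``.
    """
    aucs = np.asarray(aucs, dtype=float)
    if len(aucs) < 2:
        raise ValueError("need at least 2 subjects")
    if aucs.std() == 0 and aucs[0] == chance:
        # degenerate but well-defined: no deviation from chance at all
        return 0.0, 0.5 if tail == "one" else 1.0
    alternative = {"one": "greater", "two": "two-sided"}[tail]
    res = stats.ttest_1samp(aucs, chance, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank,
    capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pattern_values(p) -> np.ndarray:
    return p.values if isinstance(p, ActivationPattern) else np.asarray(p, dtype=float)


def pattern_correlation(a, b) -> float:
    """Pearson correlation of two activation patterns across features."""
    va, vb = _pattern_values(a), _pattern_values(b)
    if isinstance(a, ActivationPattern) and isinstance(b, ActivationPattern):
        if a.feature_ids != b.feature_ids:
            raise ValueError("patterns have mismatched feature_ids")
    if len(va) < 3:
        raise ValueError("need at least 3 features")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined for zero-variance pattern")
    return float(stats.pearsonr(va, vb).statistic)


def permutation_corr_test(
    pairs: list[tuple], K: int = 1000, seed: int = 0
) -> PermutationOutcome:
    """Permutation test of the mean within-participant pattern correlation.

    ``pairs`` holds one ``(pattern_a, pattern_b)`` tuple per participant.
    The observed statistic is the mean Pearson r across participants; each
    of the K permutations shuffles pattern_b's feature order independently
    within each participant and recomputes the mean r.  Two-tailed:
    ``p = (1 + #{|null| >= |observed|}) / (K + 1)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(pairs) < 2:
        raise ValueError("need at least 2 participants")
    rng = derive_rng(seed, "perm-corr")
    # normalise once; a permutation only re-pairs entries, so r reduces to a
    # dot product of the unit-norm centred vectors
    normed = []
    for a, b in pairs:
        va, vb = _pattern_values(a), _pattern_values(b)
        if len(va) != len(vb):
            raise ValueError("pattern lengths differ within a participant")
        va = va - va.mean()
        vb = vb - vb.mean()
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError("correlation undefined for zero-variance pattern")
        normed.append((va / na, vb / nb))
    observed = float(np.mean([float(va @ vb) for va, vb in normed]))
    null = np.empty(K)
    for k in range(K):
        rs = [float(va @ rng.permutation(vb)) for va, vb in normed]
        null[k] = np.mean(rs)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (K + 1.0)
    return PermutationOutcome(
        observed_mean_r=observed, null_values=null, p=float(p), K=K, seed=seed
    )
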