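"""Univariate F-score feature ranking.

For a binary-labeled sample the F-score of feature *i* is

    F(i) = [ (m_i+ - m_i)^2 + (m_i- - m_i)^2 ]
           / [ s2_i+ + s2_i- ]

where ``m_i`` is the overall mean of feature *i*, ``m_i±`` the class
means, and ``s2_i±`` the within-class *sample* variances (denominator
n± − 1).  Larger F means better univariate separation.  The score is
invariant to per-feature affine rescaling and ignores interactions
between features — a known limitation that is part of the method.

Degenerate features with zero variance in both classes score 0 when the
class means coincide and +inf (flagged) when they differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FScoreResult", "f_score", "select_top_k"]


@dataclass
class FScoreResult:
    """Per-feature F values with the induced ranking.

    ``ranking`` sorts feature indices by decreasing F; ties are broken
    by ascending original index so the ranking is deterministic.
    ``degenerate`` flags features whose within-class variances both
    vanish with unequal class means (F is +inf there).
    """

    f: np.ndarray
    ranking: np.ndarray
    n_plus: int
    n_minus: int
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.f < 0):
            raise ValueError("F values must be non-negative")
        if sorted(self.ranking.tolist()) != list(range(self.f.size)):
            raise ValueError("ranking must be a permutation of feature indices")


def f_score(features: np.ndarray, labels: np.ndarray, positive) -> FScoreResult:
    """Compute the F-score of every feature column.

    Parameters
    ----------
    features
        Array of shape (n_samples, n_features).
    labels
        Per-sample class labels (exactly two classes present).
    positive
        The label treated as the positive class.

    Raises
    ------
    ValueError
        If either class has fewer than 2 members.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    pos = y == positive
    n_plus = int(pos.sum())
    n_minus = int((~pos).sum())
    if n_plus < 2 or n_minus < 2:
        raise ValueError("each class needs at least 2 members")

    overall = X.mean(axis=0)
    mean_p = X[pos].mean(axis=0)
    mean_m = X[~pos].mean(axis=0)
    var_p = X[pos].var(axis=0, ddof=1)
    var_m = X[~pos].var(axis=0, ddof=1)

    num = (mean_p - overall) ** 2 + (mean_m - overall) ** 2
    den = var_p + var_m
    degenerate = (den == 0) & (num > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    f[degenerate] = np.inf

    ranking = np.argsort(-f, kind="stable")
    return FScoreResult(f=f, ranking=ranking, n_plus=n_plus, n_minus=n_minus,
                        degenerate=degenerate)


def select_top_k(result: FScoreResult, k: int) -> np.ndarray:
    """Indices of the ``k`` features with the largest F values.

    Ties at the boundary resolve to the lower original index (the
    ranking's stable tie rule), so top-k selections nest as k grows.
    """
    if not 1 <= k <= result.f.size:
        raise ValueError(f"k={k} outside [1, {result.f.size}]")
    return result.ranking[:k]
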