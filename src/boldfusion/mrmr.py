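"""Minimum-redundancy-maximum-relevance (MRMR) feature selection.

Greedy forward selection driven by mutual information (MI): the first
feature maximises relevance ``I(Y; F_j)``; each later step adds the
candidate maximising either

* **MID** (mutual information difference):
  ``I(Y; F_j) - (1/|S|) * sum_{i in S} I(F_i; F_j)``, or
* **MIQ** (mutual information quotient):
  ``I(Y; F_j) / ((1/|S|) * sum_{i in S} I(F_i; F_j))``.

MI is a plug-in estimate (log base 2) on the joint histogram after
quantile-binning continuous features (default 8 bins), which is robust to
heavy-tailed feature distributions. Redundancy ``W`` over a selected set is
the mean of MI over *ordered* pairs including ``i = j`` (the literal double
sum), and relevance ``V`` is the mean of per-feature MI with the labels;
both are traced per selection step.

The incremental scheme caches pairwise MI against already-selected
features, so selecting ``m`` of ``K`` features costs ``O(K * m)`` MI
evaluations rather than scoring whole subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "discretize",
    "mutual_information",
    "relevance",
    "redundancy",
    "mrmr_select",
    "MrmrSelector",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 8


@dataclass
class FeatureMatrix:
    """n_samples x K feature values with per-sample class labels."""

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per sample required")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.feature_ids is None:
            self.feature_ids = [f"f{k}" for k in range(self.values.shape[1])]
        elif len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("one feature_id per column required")


@dataclass
class SelectionResult:
    """Ordered selected indices with per-step relevance/redundancy traces."""

    indices: list[int]
    relevance_trace: list[float]
    redundancy_trace: list[float]
    criterion: str
    scores: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)


def discretize(x, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Quantile-bin a sequence into integer codes ``0..bins-1``.

    Already-discrete inputs with at most ``bins`` distinct values are
    relabelled but otherwise untouched; constant inputs map to one bin.
    """
    x = np.asarray(x)
    uniq = np.unique(x)
    if uniq.size <= bins:
        return np.searchsorted(uniq, x).astype(np.int64)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _codes(x, bins: int) -> tuple[np.ndarray, int]:
    c = discretize(x, bins)
    return c, int(c.max()) + 1


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D contingency table of counts."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = pxy[mask] / (px @ py)[mask]
    return float((pxy[mask] * np.log2(ratio)).sum())


def mutual_information(x, y, bins: int = DEFAULT_BINS) -> float:
    """Plug-in mutual information (bits) between ``x`` and discrete ``y``.

    Continuous ``x`` is quantile-binned first; the estimate is always
    non-negative and symmetric in its arguments for discrete inputs.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    cx, nx = _codes(x, bins)
    cy, ny = _codes(y, bins)
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint.astype(np.float64))


def relevance(features: FeatureMatrix, S, bins: int = DEFAULT_BINS) -> float:
    """Mean MI between the labels and each feature in ``S`` (V)."""
    S = list(S)
    if not S:
        raise ValueError("S must be non-empty")
    return float(
        np.mean([mutual_information(features.values[:, j], features.labels, bins) for j in S])
    )


def redundancy(features: FeatureMatrix, S, bins: int = DEFAULT_BINS) -> float:
    """Mean MI over ordered feature pairs of ``S`` including i=j (W)."""
    S = list(S)
    if not S:
        raise ValueError("S must be non-empty")
    total = 0.0
    for i in S:
        for j in S:
            total += mutual_information(
                features.values[:, i], features.values[:, j], bins
            )
    return total / len(S) ** 2


def _mi_one_vs_many(code: np.ndarray, n_code: int, codes: np.ndarray, n_bins: int) -> np.ndarray:
    """MI between one coded feature and every column of a coded matrix."""
    n, k = codes.shape
    flat = (np.arange(k) * (n_code * n_bins))[None, :] + code[:, None] * n_bins + codes
    counts = np.bincount(flat.ravel(), minlength=k * n_code * n_bins)
    joints = counts.reshape(k, n_code, n_bins).astype(np.float64)
    pxy = joints / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pxy * np.log2(pxy / (px * py))
    return np.nansum(term, axis=(1, 2))


def mrmr_select(
    features: FeatureMatrix,
    m: int,
    criterion: str = "MID",
    bins: int = DEFAULT_BINS,
) -> SelectionResult:
    """Greedy MRMR selection of ``m`` features (MID or MIQ scoring).

    Ties break toward the lowest feature index. For MIQ, a candidate whose
    mean redundancy with the selected set is zero falls back to its MID
    score for that step (logged). Deterministic for a given matrix.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be 'MID' or 'MIQ'")
    X, y = features.values, features.labels
    n, K = X.shape
    if not 1 <= m <= K:
        raise ValueError(f"m must lie in [1, {K}], got {m}")
    if np.unique(y).size < 2:
        raise ValueError("selection requires at least 2 classes")

    codes = np.empty((n, K), dtype=np.int64)
    for j in range(K):
        codes[:, j] = discretize(X[:, j], bins)
    ycode, n_y = _codes(y, bins)

    rel = _mi_one_vs_many(ycode, n_y, codes, bins)
    self_mi = np.array(
        [_mi_from_joint(np.bincount(codes[:, j] * bins + codes[:, j],
                                    minlength=bins * bins).reshape(bins, bins).astype(float))
         for j in range(K)]
    )

    selected: list[int] = []
    scores: list[float] = []
    rel_trace: list[float] = []
    red_trace: list[float] = []
    red_sum = np.zeros(K)  # sum over i in S of I(F_i, F_j)
    remaining = np.ones(K, dtype=bool)
    v_sum = 0.0
    w_sum = 0.0  # ordered-pair sum including i=j

    first = int(np.argmax(rel))
    for step in range(m):
        if step == 0:
            best = first
            scores.append(float(rel[best]))
        else:
            mean_red = red_sum / len(selected)
            if criterion == "MID":
                score = rel - mean_red
            else:
                score = np.where(mean_red > 0, rel / np.where(mean_red > 0, mean_red, 1.0),
                                 rel - mean_red)
                if np.any((mean_red <= 0) & remaining):
                    logger.debug(
                        "MIQ: zero-redundancy candidates at step %d fall back to MID", step
                    )
            score = np.where(remaining, score, -np.inf)
            best = int(np.argmax(score))
            scores.append(float(score[best]))
        # cross-MI of the new pick against everything (cached for later steps)
        cross = _mi_one_vs_many(codes[:, best], bins, codes, bins)
        w_sum += self_mi[best] + 2.0 * sum(cross[i] for i in selected)
        v_sum += rel[best]
        red_sum += cross
        remaining[best] = False
        selected.append(best)
        rel_trace.append(v_sum / len(selected))
        red_trace.append(w_sum / len(selected) ** 2)
    return SelectionResult(
        indices=selected,
        relevance_trace=rel_trace,
        redundancy_trace=red_trace,
        criterion=criterion,
        scores=scores,
    )


class MrmrSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible transformer running MRMR selection on fit.

    Parameters
    ----------
    n_features_to_select : target number of features (clipped to K).
    criterion : 'MID' (difference, default) or 'MIQ' (quotient).
    bins : quantile bins for the MI estimator.
    """

    def __init__(self, n_features_to_select: int = 512, criterion: str = "MID",
                 bins: int = DEFAULT_BINS):
        self.n_features_to_select = n_features_to_select
        self.criterion = criterion
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        fm = FeatureMatrix(X, np.asarray(y))
        m = min(self.n_features_to_select, X.shape[1])
        self.selection_ = mrmr_select(fm, m, self.criterion, self.bins)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selection_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selection_.indices] = True
        return mask

    def transform(self, X):
        # preserve selection order (most relevant first) instead of column order
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "selection_")
        X = np.asarray(X)
        return X[:, self.selection_.indices]
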