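"""Information-based univariate feature selection.

Two scorers bracket the plausible readings of entropy-based UFS:

* ``mi``: mutual information I(feature; label) in bits after equal-frequency
  discretization — the supervised default.
* ``loo_entropy``: unsupervised leave-one-out dataset-entropy scoring.  The
  dataset's total (joint) entropy is estimated with a pairwise
  approximation, H(D) ≈ Σ_j H(X_j) − Σ_{j<k} I(X_j; X_k); a feature's score
  is the entropy the dataset loses when it is removed,
  score(f) = H(D) − H(D \\ f) = H(X_f) − Σ_{k≠f} I(X_f; X_k),
  i.e. the feature's *unique* information contribution.  A duplicated column
  scores ≈ 0 (its twin retains everything); a unique high-entropy column
  scores highest.

Discretization is equal-frequency with ⌈√n⌉ bins by default, which also
makes MI invariant to strictly monotone transforms of a feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (PARAM_ORDER, REGION_ORDER, FeatureMatrix,
                       parse_feature_name)

__all__ = [
    "RankedFeatures",
    "discretize",
    "entropy_bits",
    "mutual_information_bits",
    "mi_score",
    "loo_entropy_score",
    "loo_entropy_scores",
    "rank",
]


def discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization to integer codes.

    Columns with at most ``n_bins`` distinct values keep their values as
    categories (so a binary feature stays binary); otherwise quantile cuts
    on the mid-ranked values are used, with duplicate edges merged.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature column contains non-finite values")
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    # rank first so heavily tied columns still split into near-equal bins
    ranks = pd.Series(x).rank(method="first").to_numpy()
    codes = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def entropy_bits(codes: np.ndarray) -> float:
    """Shannon entropy (bits) of a discrete code vector."""
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def mutual_information_bits(a: np.ndarray, b: np.ndarray) -> float:
    """I(a; b) in bits from the joint contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz]
                                            / (pa @ pb)[nz])))


def _encode_labels(labels) -> np.ndarray:
    return pd.factorize(np.asarray(labels))[0]


def default_bins(n_instances: int) -> int:
    return int(np.ceil(np.sqrt(n_instances)))


def mi_score(feature: np.ndarray, labels, n_bins: int | None = None) -> float:
    """Mutual information (bits) between a discretized feature and labels.

    A feature that exactly copies a balanced binary label scores
    H(label) = 1.0 bit.  With a single label class present the score is 0
    (with a warning) — there is nothing to inform about.
    """
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        warnings.warn("only one class present; MI is 0", stacklevel=2)
        return 0.0
    if n_bins is None:
        n_bins = default_bins(len(y))
    codes = discretize(np.asarray(feature), n_bins)
    return mutual_information_bits(codes, y)


def _discretize_matrix(m: FeatureMatrix, n_bins: int) -> np.ndarray:
    return np.stack([discretize(m.values[c].to_numpy(), n_bins)
                     for c in m.values.columns], axis=1)


def loo_entropy_scores(m: FeatureMatrix,
                       n_bins: int | None = None) -> pd.Series:
    """Leave-one-out entropy score for every feature (see module docstring).

    Vectorised: pairwise MI of feature f with all others is computed from
    one one-hot matmul per feature.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least two features")
    if m.shape[1] == 2:
        warnings.warn("two-feature matrix: leave-one-out scores are "
                      "degenerate (each feature's score is its unique "
                      "information w.r.t. the other)", stacklevel=2)
    if n_bins is None:
        n_bins = default_bins(m.shape[0])
    codes = _discretize_matrix(m, n_bins)
    n, n_feat = codes.shape
    b = int(codes.max()) + 1
    onehot = np.zeros((n, n_feat * b))
    onehot[np.arange(n)[:, None], np.arange(n_feat) * b + codes] = 1.0
    marg = np.array([entropy_bits(codes[:, j]) for j in range(n_feat)])
    scores = np.empty(n_feat)
    for f in range(n_feat):
        joint = (onehot[:, f * b:(f + 1) * b].T @ onehot) / n  # (b, F*b)
        joint = joint.reshape(b, n_feat, b)
        pa = joint.sum(axis=(1, 2))[:, None, None] / n_feat
        pb = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * np.log2(joint / (pa * pb))
        mi_all = np.nansum(term, axis=(0, 2))  # I(f; k) for every k
        scores[f] = marg[f] - (mi_all.sum() - mi_all[f])
    return pd.Series(scores, index=m.values.columns)


def loo_entropy_score(m: FeatureMatrix, feature: str,
                      n_bins: int | None = None) -> float:
    """Score of one named feature under the leave-one-out entropy method."""
    return float(loo_entropy_scores(m, n_bins=n_bins)[feature])


@dataclass
class RankedFeatures:
    """Features in descending relevance order with their scores."""

    order: list[str]
    scores: pd.Series
    method: str
    n_bins: int

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def table(self, top_k: int | None = None) -> pd.DataFrame:
        """Reporting layout: rank, region, frequency bin, parameter, score."""
        names = self.order if top_k is None else self.order[:top_k]
        rows = []
        for rk, name in enumerate(names, start=1):
            try:
                param, region, center = parse_feature_name(name)
                row = {"rank": rk, "region": region,
                       "frequency_bin_hz": f"{center - 0.2:.1f}–{center:.1f}",
                       "parameter_type": param}
            except ValueError:
                row = {"rank": rk, "region": "", "frequency_bin_hz": "",
                       "parameter_type": name}
            row.update({"score": float(self.scores[name]),
                        "method": self.method})
            rows.append(row)
        return pd.DataFrame(rows)


def _tie_key(name: str) -> tuple:
    try:
        param, region, center = parse_feature_name(name)
    except ValueError:
        return (float("inf"), 0, 0, name)
    return (center, REGION_ORDER.index(region), PARAM_ORDER.index(param),
            name)


def rank(m: FeatureMatrix, labels=None, method: str = "mi",
         top_k: int | None = None,
         n_bins: int | None = None) -> RankedFeatures:
    """Rank all features by the chosen relevance score.

    ``method="mi"`` needs ``labels`` (one per matrix row);
    ``method="loo_entropy"`` is unsupervised.  Ties are broken
    deterministically by (lower frequency bin, region order
    anterior<posterior<left<right, amplitude before time).
    """
    if n_bins is None:
        n_bins = default_bins(m.shape[0])
    if method == "mi":
        if labels is None:
            raise ValueError("MI ranking requires labels")
        labels = np.asarray(labels)
        if len(labels) != m.shape[0]:
            raise ValueError("labels must align with matrix rows")
        scores = pd.Series(
            {c: mi_score(m.values[c].to_numpy(), labels, n_bins=n_bins)
             for c in m.values.columns})
    elif method == "loo_entropy":
        scores = loo_entropy_scores(m, n_bins=n_bins)
    else:
        raise ValueError(f"unknown UFS method {method!r}")
    order = sorted(scores.index, key=lambda c: (-scores[c], _tie_key(c)))
    if top_k is not None and top_k > len(order):
        warnings.warn(f"top_k={top_k} exceeds {len(order)} features; "
                      "clipped", stacklevel=2)
    return RankedFeatures(order, scores, method, n_bins)
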