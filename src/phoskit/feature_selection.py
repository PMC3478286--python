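"""Information-Gain ranking of CKSAAP features.

IG(X; Y) = H(X) - H(X | Y) measures how much observing the class label Y
(phosphorylated / not) reduces the uncertainty of a feature X.  Features
here are small-integer pair counts within a 27-residue window, so each
distinct count value is treated directly as a discrete category — no
binning.  Entropies are in bits (base-2 logs); the base cancels out of
the ranking.

Per the source method's own finding, IG ranking is reporting-only by
default: it surfaces the enriched pair motifs (SP, S×S, R××S, ...) but is
not used to prune features before SVM training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .encoding import feature_label

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IGRanking:
    """Ordered per-feature IG scores with human-readable pair labels.

    ``entries`` is a list of (feature_label, feature_index, ig_bits),
    sorted by IG descending with ties broken by ascending index.
    """

    entries: tuple
    class_entropy: float


def entropy(values) -> float:
    """Empirical Shannon entropy H(X) in bits, with 0·log 0 = 0."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("entropy of an empty sample is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / values.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(values, labels) -> float:
    """Empirical conditional entropy H(X | Y) in bits."""
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("conditional entropy of an empty sample is undefined")
    if values.shape[0] != labels.shape[0]:
        raise ValueError(
            f"length mismatch: {values.shape[0]} values vs {labels.shape[0]} labels"
        )
    total = 0.0
    for y in np.unique(labels):
        mask = labels == y
        w = mask.sum() / labels.size
        total += w * entropy(values[mask])
    return total


def information_gain(values, labels) -> float:
    """IG = H(X) - H(X | Y), clipped of negative floating-point dust."""
    ig = entropy(values) - conditional_entropy(values, labels)
    if ig < 0:
        if ig < -1e-9:
            raise AssertionError(f"information gain {ig} below rounding tolerance")
        ig = 0.0
    return ig


def rank_features(
    matrix: np.ndarray,
    labels,
    top_n: int = 20,
    k_max: int | None = None,
) -> IGRanking:
    """Rank feature columns of a fragment x feature matrix by IG.

    ``k_max`` fixes the label rendering; by default it is inferred from
    the column count (columns = 441 x (k_max+1)).  ``top_n`` larger than
    the feature count is clipped with a warning.
    """
    matrix = np.asarray(matrix)
    labels = np.asarray(labels)
    if matrix.shape[0] != labels.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but {labels.shape[0]} labels"
        )
    n_cols = matrix.shape[1]
    if k_max is None:
        if n_cols % 441 != 0:
            raise ValueError(
                f"cannot infer k_max: {n_cols} columns is not a multiple of 441"
            )
        k_max = n_cols // 441 - 1
    if top_n > n_cols:
        logger.warning("top_n=%d exceeds %d features; clipping", top_n, n_cols)
        top_n = n_cols
    scores = ig_scores(matrix, labels)
    order = np.lexsort((np.arange(n_cols), -scores))
    entries = tuple(
        (feature_label(int(j), k_max), int(j), float(scores[j]))
        for j in order[:top_n]
    )
    return IGRanking(entries=entries, class_entropy=entropy(labels))


def _entropy_rows(counts: np.ndarray, n: int) -> np.ndarray:
    """Entropy in bits of each row of a (rows, categories) count table."""
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def ig_scores(matrix: np.ndarray, labels) -> np.ndarray:
    """Per-column IG scores (unranked), for rankings and permutation checks.

    Integer matrices take a vectorized bincount path (identical results
    to column-wise :func:`information_gain`, which remains the reference
    and the fallback for non-integer data).
    """
    matrix = np.asarray(matrix)
    labels = np.asarray(labels)
    if matrix.shape[0] != labels.shape[0]:
        raise ValueError("matrix rows must match labels")
    if not np.issubdtype(matrix.dtype, np.integer):
        return np.array(
            [information_gain(matrix[:, j], labels) for j in range(matrix.shape[1])]
        )
    n, n_cols = matrix.shape
    shifted = matrix - matrix.min()
    n_vals = int(shifted.max()) + 1
    codes = shifted + np.arange(n_cols, dtype=np.int64) * n_vals
    counts = np.bincount(codes.ravel(), minlength=n_cols * n_vals).reshape(
        n_cols, n_vals
    )
    h_x = _entropy_rows(counts, n)
    h_cond = np.zeros(n_cols)
    for y in np.unique(labels):
        mask = labels == y
        sub = np.bincount(codes[mask].ravel(), minlength=n_cols * n_vals).reshape(
            n_cols, n_vals
        )
        h_cond += (mask.sum() / n) * _entropy_rows(sub, int(mask.sum()))
    return np.clip(h_x - h_cond, 0.0, None)


def mean_rank(rankings: list[IGRanking], top_n: int = 20) -> list[tuple]:
    """Average each feature's rank across replicate rankings.

    Only features present in every ranking's entry list are averaged
    (rank = 1-based position).  Returns (label, index, mean_rank) sorted
    by mean rank ascending, truncated to top_n.
    """
    if not rankings:
        raise ValueError("no rankings given")
    tables = []
    for ranking in rankings:
        tables.append(
            {idx: (rank, lab) for rank, (lab, idx, _) in enumerate(ranking.entries, 1)}
        )
    common = set(tables[0])
    for t in tables[1:]:
        common &= set(t)
    out = []
    for idx in common:
        ranks = [t[idx][0] for t in tables]
        out.append((tables[0][idx][1], idx, float(np.mean(ranks))))
    out.sort(key=lambda e: (e[2], e[1]))
    return out[:top_n]


def write_ranking(ranking: IGRanking, path) -> None:
    """Emit the ranking as TSV: rank, feature_label, spacing_k, ig_bits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tfeature_label\tspacing_k\tig_bits\n")
        for rank, (label, idx, ig) in enumerate(ranking.entries, 1):
            k = idx // 441
            fh.write(f"{rank}\t{label}\t{k}\t{ig:.6f}\n")
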