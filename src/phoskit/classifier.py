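"""RBF-kernel SVM ensembles over balanced replicates.

One soft-margin SVM with a radial basis kernel is trained per balanced
replicate; its (C, gamma) are chosen by exhaustive grid search over
{2^-7, ..., 2^8} x {2^-7, ..., 2^8} (256 combinations) maximizing
stratified 5-fold cross-validation accuracy.  Predictions average the
replicates' Platt-calibrated positive-class probabilities and call a
site positive when the ensemble probability reaches the decision
threshold (default 0.5, inclusive).

The quadratic program itself is delegated to libsvm via scikit-learn;
the protocol around it (grid, tie-breaking, ensembling, persistence) is
defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__
from .dataset import BalancedSet, SiteFragment
from .encoding import DEFAULT_K_MAX, cksaap_matrix

logger = logging.getLogger(__name__)

#: Powers 2^-7 .. 2^8 for both C and gamma: 16 x 16 = 256 grid points.
DEFAULT_GRID = tuple(float(2.0**e) for e in range(-7, 9))

BUNDLE_FORMAT = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one SVM plus the search protocol around it.

    ``C`` / ``gamma`` left as None means "select by grid search".
    """

    C: float | None = None
    gamma: float | None = None
    c_grid: tuple = DEFAULT_GRID
    gamma_grid: tuple = DEFAULT_GRID
    cv_folds: int = 5
    threshold: float = 0.5


@dataclass(frozen=True)
class GridSearchResult:
    C: float
    gamma: float
    #: every evaluated (C, gamma, mean CV accuracy), in evaluation order
    scores: tuple
    n_evaluated: int


@dataclass(frozen=True)
class ReplicateModel:
    """One replicate's fitted SVM with its selected hyperparameters."""

    svc: object
    C: float
    gamma: float
    seed: int
    replicate_index: int


@dataclass(frozen=True)
class ModelBundle:
    """The per-replicate SVMs plus everything needed to encode new sites."""

    models: tuple
    residue_type: str
    k_max: int
    half_window: int
    threshold: float
    train_keys: frozenset = frozenset()  # (protein_id, position) provenance
    version: str = __version__

    @property
    def replicate_seeds(self) -> list[int]:
        return [m.seed for m in self.models]


def _cv_folds(y: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def grid_search(
    X: np.ndarray, y, config: ModelConfig = ModelConfig(), seed: int = 0
) -> GridSearchResult:
    """Exhaustively evaluate every (C, gamma) grid point by CV accuracy.

    All combinations are scored on the same stratified fold assignment
    (reproducible from ``seed``); the maximizer wins, with ties broken by
    smaller C then smaller gamma.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs samples from both classes")
    if min(np.bincount(y.astype(int))) < config.cv_folds:
        raise ValueError(
            f"fewer samples per class than cv_folds={config.cv_folds}"
        )
    folds = _cv_folds(y, config.cv_folds, seed)
    # The RBF kernel exp(-gamma * ||x-y||^2) is recomputed for every grid
    # point and fold by a naive search; precomputing the squared-distance
    # matrix once makes each fit cost only the optimizer, not the kernel.
    D = euclidean_distances(X, squared=True)
    scores = []
    for gamma in sorted(config.gamma_grid):
        K = np.exp(-gamma * D)
        for C in sorted(config.c_grid):
            accs = []
            for tr, te in folds:
                clf = SVC(kernel="precomputed", C=C)
                clf.fit(K[np.ix_(tr, tr)], y[tr])
                accs.append(clf.score(K[np.ix_(te, tr)], y[te]))
            scores.append((float(C), float(gamma), float(np.mean(accs))))
    best = min(scores, key=lambda s: (-s[2], s[0], s[1]))
    scores.sort(key=lambda s: (s[0], s[1]))
    return GridSearchResult(
        C=best[0], gamma=best[1], scores=tuple(scores), n_evaluated=len(scores)
    )


def train_replicate(
    bset: BalancedSet,
    k_max: int = DEFAULT_K_MAX,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> ReplicateModel:
    """Fit one replicate's probability-calibrated RBF SVM.

    Encodes the replicate's fragments with CKSAAP internally.  When the
    config leaves C/gamma unset, the full grid search runs first; the
    final model adds Platt-style sigmoid calibration fitted on
    cross-validated decision values, so predictions are probabilities in
    [0, 1].
    """
    X = cksaap_matrix([f.window for f in bset.fragments], k_max).astype(np.float64)
    y = bset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("replicate contains a single class; cannot train")
    if config.C is None or config.gamma is None:
        gs = grid_search(X, y, config, seed=seed)
        C, gamma = gs.C, gs.gamma
        logger.info(
            "replicate %d: grid search over %d points selected C=%g gamma=%g",
            bset.replicate_index,
            gs.n_evaluated,
            C,
            gamma,
        )
    else:
        C, gamma = config.C, config.gamma
    svc = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    svc.fit(X, y)
    return ReplicateModel(
        svc=svc, C=C, gamma=gamma, seed=seed, replicate_index=bset.replicate_index
    )


def train_ensemble(
    balanced_sets: list[BalancedSet],
    k_max: int = DEFAULT_K_MAX,
    half_window: int = 13,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> ModelBundle:
    """Train one SVM per balanced replicate and bundle them for prediction."""
    if not balanced_sets:
        raise ValueError("no balanced sets given")
    residue_type = balanced_sets[0].residue_type
    rep_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=len(balanced_sets)
    )
    models = tuple(
        train_replicate(bset, k_max, config, seed=int(s))
        for bset, s in zip(balanced_sets, rep_seeds)
    )
    keys = frozenset(
        (f.protein_id, f.position)
        for bset in balanced_sets
        for f in bset.fragments
    )
    modal = max(
        {(m.C, m.gamma) for m in models},
        key=lambda cg: sum((m.C, m.gamma) == cg for m in models),
    )
    logger.info("modal selected (C, gamma) across replicates: %s", modal)
    return ModelBundle(
        models=models,
        residue_type=residue_type,
        k_max=k_max,
        half_window=half_window,
        threshold=config.threshold,
        train_keys=keys,
    )


def predict(
    bundle: ModelBundle, fragments: list[SiteFragment]
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged positive probability and call for each fragment.

    The probability is the arithmetic mean of the replicate models'
    calibrated positive-class probabilities; the call is positive when
    the mean reaches the bundle threshold (inclusive at the boundary).
    """
    if not fragments:
        return np.zeros(0), np.zeros(0, dtype=bool)
    for f in fragments:
        if f.residue_type != bundle.residue_type:
            raise ValueError(
                f"fragment {f.protein_id}:{f.position} has residue type "
                f"{f.residue_type!r}; bundle models {bundle.residue_type!r}"
            )
    X = cksaap_matrix([f.window for f in fragments], bundle.k_max).astype(
        np.float64
    )
    probs = np.mean(
        [m.svc.predict_proba(X)[:, list(m.svc.classes_).index(1)] for m in bundle.models],
        axis=0,
    )
    return probs, probs >= bundle.threshold


def save_bundle(bundle: ModelBundle, path) -> None:
    """Persist a bundle (joblib archive with a format-version stamp)."""
    joblib.dump({"format": BUNDLE_FORMAT, "version": bundle.version, "bundle": bundle}, path)


def load_bundle(path) -> ModelBundle:
    """Load a persisted bundle, refusing archives from other format versions."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != BUNDLE_FORMAT:
        raise ValueError(
            f"unsupported model archive format in {path} "
            f"(expected format {BUNDLE_FORMAT})"
        )
    if payload.get("version") != __version__:
        raise ValueError(
            f"model archive was written by package version "
            f"{payload.get('version')}; this is {__version__}"
        )
    return payload["bundle"]
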