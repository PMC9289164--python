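"""Cluster-proportion slide barcodes and the boosted-tree classifier.

The barcode representation summarizes a slide at one magnification as a
``K``-vector of cluster proportions: tile embeddings from the *training*
slides are pooled and clustered with mini-batch k-means (default
``K = 150``); every slide's tiles are then assigned to their nearest
centroid and the slide is represented by the fraction of its tiles in
each cluster.  Multi-scale barcodes concatenate the per-magnification
blocks slide-wise in descending magnification order.  Slides with fewer
than 64 tiles at any selected magnification are discarded (too few
tiles make the proportions unstable).

Classification uses gradient-boosted trees with per-sample class
prevalence weights and random-search tuning over learning rate, depth,
subsample ratios and regularization; :class:`BarcodeClassifier` follows
the model/results idiom.  Evaluation uses Monte Carlo cross-validation
(repeated random patient-wise resplits) with a t-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import MiniBatchKMeans

from .evaluation import confusion_and_f1

__all__ = [
    "ClusterModel",
    "Barcode",
    "fit_corpus_clusters",
    "assign_clusters",
    "compute_barcode",
    "filter_min_tiles",
    "concat_barcodes",
    "class_prevalence_weights",
    "BarcodeClassifier",
    "BarcodeClassifierResults",
    "monte_carlo_cv",
    "t_confidence_interval",
    "DEFAULT_K",
    "MIN_TILES",
    "DEFAULT_HP_SPACE",
]

DEFAULT_K = 150
MIN_TILES = 64

#: random-search space over the five tuned axes
DEFAULT_HP_SPACE = {
    "learning_rate": (0.03, 0.3),
    "max_depth": (2, 8),
    "subsample": (0.6, 1.0),
    "colsample_bytree": (0.5, 1.0),
    "reg_lambda": (0.5, 5.0),
}


@dataclass
class ClusterModel:
    """Per-magnification corpus clustering (centroids + fit metadata)."""

    mag: float
    centroids: np.ndarray = field(repr=False)
    batch_size: int = 1024
    seed: int = 0
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_metadata(self) -> dict:
        return {"mag": self.mag, "K": self.k, "seed": self.seed, "n_iter": self.n_iter}


@dataclass
class Barcode:
    """Concatenated per-magnification cluster-proportion vector."""

    slide_id: str
    mags: tuple
    vector: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)

    def block(self, mag) -> np.ndarray:
        """Slice out one magnification's K-length block (lossless)."""
        k = len(self.vector) // len(self.mags)
        i = list(self.mags).index(mag)
        return self.vector[i * k : (i + 1) * k]


def fit_corpus_clusters(pooled, mag, k: int = DEFAULT_K, batch_size: int = 1024, seed: int = 0) -> ClusterModel:
    """Mini-batch k-means over training-set tiles pooled across slides.

    Fitting must only ever see training slides; assignment of held-out
    slides never updates the centroids.
    """
    X = np.asarray(pooled, dtype=np.float64)
    if X.shape[0] < k:
        raise ValueError("insufficient tiles for K clusters")
    km = MiniBatchKMeans(
        n_clusters=k,
        batch_size=batch_size,
        random_state=seed,
        n_init=3,
        max_iter=100,
    )
    km.fit(X)
    return ClusterModel(
        mag=mag,
        centroids=km.cluster_centers_.copy(),
        batch_size=batch_size,
        seed=seed,
        n_iter=int(km.n_iter_),
    )


def assign_clusters(model: ClusterModel, embeddings) -> np.ndarray:
    """Nearest-centroid label per row (Euclidean, lowest index on ties)."""
    X = embeddings.matrix if hasattr(embeddings, "matrix") else np.asarray(embeddings)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    C = model.centroids
    if X.shape[1] != C.shape[1]:
        raise ValueError("embedding/centroid dimension mismatch")
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; argmin returns lowest index
    d2 = (X * X).sum(1, keepdims=True) - 2 * X @ C.T + (C * C).sum(1)
    return np.argmin(np.round(d2, 9), axis=1)


def compute_barcode(assignments, k: int) -> np.ndarray:
    """Cluster proportions: block[j] = #(assignments == j) / N."""
    a = np.asarray(assignments, dtype=np.int64)
    if a.size == 0:
        raise ValueError("slide has no tiles at this magnification")
    if a.min() < 0 or a.max() >= k:
        raise ValueError("assignment outside [0, K)")
    return np.bincount(a, minlength=k) / a.size


def filter_min_tiles(tile_counts: pd.DataFrame, mags, min_tiles: int = MIN_TILES) -> list:
    """Slide ids with >= min_tiles QC-passing tiles at EVERY selected mag.

    ``tile_counts`` is indexed by slide_id with one column per
    magnification.  Raising ``min_tiles`` never grows the retained set.
    """
    if len(tile_counts) == 0:
        return []
    cols = [m for m in mags]
    keep = (tile_counts[cols] >= min_tiles).all(axis=1)
    return list(tile_counts.index[keep])


def concat_barcodes(blocks: dict, slide_id: str, mags=None) -> Barcode:
    """Slide-wise concatenation of per-mag blocks, descending mag order."""
    mags = tuple(sorted(mags or blocks.keys(), reverse=True))
    parts = []
    for m in mags:
        if m not in blocks:
            raise ValueError("slide lacks barcode at requested magnification")
        parts.append(np.asarray(blocks[m], dtype=np.float64))
    return Barcode(slide_id=slide_id, mags=mags, vector=np.concatenate(parts))


def class_prevalence_weights(labels) -> np.ndarray:
    """Balanced per-sample weights: total / (n_present_classes * count_c).

    On a balanced cohort every weight is 1; minority samples are
    upweighted so each class contributes equal total weight.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    total = len(labels)
    per_class = total / (len(classes) * counts)
    lut = dict(zip(classes, per_class))
    return np.array([lut[l] for l in labels], dtype=np.float64)


class BarcodeClassifier:
    """Boosted-tree classifier over slide barcodes (model object).

    Parameters
    ----------
    X : (n_slides, K * n_mags) barcode matrix
    y : integer class labels
    sample_weight : optional per-slide weights (class prevalence)
    feature_names : optional list like ``["20x_c0", ...]`` mapping
        features back to (magnification, cluster) pairs.
    """

    def __init__(self, X, y, sample_weight=None, feature_names=None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64)
        if len(np.unique(self.y)) < 2:
            raise ValueError("degenerate label set")
        self.sample_weight = (
            np.asarray(sample_weight, dtype=np.float64)
            if sample_weight is not None
            else None
        )
        self.feature_names = list(feature_names) if feature_names is not None else None

    @classmethod
    def from_barcodes(cls, barcodes, y, sample_weight=None):
        bc0 = barcodes[0]
        k = len(bc0.vector) // len(bc0.mags)
        names = [f"{m:g}x_c{j}" for m in bc0.mags for j in range(k)]
        X = np.vstack([b.vector for b in barcodes])
        return cls(X, y, sample_weight=sample_weight, feature_names=names)

    def fit(self, hp_space=None, n_draws: int = 30, val_frac: float = 0.2, n_estimators: int = 200, seed: int = 0) -> "BarcodeClassifierResults":
        """Random-search the five tuned axes against validation macro F1.

        With ``n_draws = 0`` the mid-point of each axis is used without
        a search (cheap deterministic fits for testing).
        """
        from xgboost import XGBClassifier

        hp_space = hp_space or DEFAULT_HP_SPACE
        rng = np.random.default_rng(seed)
        n_classes = int(self.y.max()) + 1

        def draw():
            lo, hi = hp_space["learning_rate"]
            d_lo, d_hi = hp_space["max_depth"]
            return {
                "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                "max_depth": int(rng.integers(d_lo, d_hi + 1)),
                "subsample": float(rng.uniform(*hp_space["subsample"])),
                "colsample_bytree": float(rng.uniform(*hp_space["colsample_bytree"])),
                "reg_lambda": float(rng.uniform(*hp_space["reg_lambda"])),
            }

        def midpoint():
            return {
                "learning_rate": float(np.sqrt(np.prod(hp_space["learning_rate"]))),
                "max_depth": int(np.mean(hp_space["max_depth"])),
                "subsample": float(np.mean(hp_space["subsample"])),
                "colsample_bytree": float(np.mean(hp_space["colsample_bytree"])),
                "reg_lambda": float(np.mean(hp_space["reg_lambda"])),
            }

        def make(params, rs):
            return XGBClassifier(
                objective="multi:softprob",
                num_class=n_classes,
                n_estimators=n_estimators,
                tree_method="hist",
                random_state=rs,
                verbosity=0,
                n_jobs=1,
                **params,
            )

        if n_draws <= 0:
            best_params = midpoint()
            best_score = np.nan
        else:
            idx = np.arange(len(self.y))
            rng.shuffle(idx)
            n_val = max(1, int(round(val_frac * len(idx))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(np.unique(self.y[tr_idx])) < len(np.unique(self.y)):
                # re-draw stratified so every class appears in training
                tr_idx, val_idx = _stratified_holdout(self.y, val_frac, rng)
            best_params, best_score = None, -np.inf
            for _ in range(n_draws):
                params = draw()
                clf = make(params, int(rng.integers(2**31)))
                sw = self.sample_weight[tr_idx] if self.sample_weight is not None else None
                clf.fit(self.X[tr_idx], self.y[tr_idx], sample_weight=sw)
                pred = clf.predict(self.X[val_idx])
                _, _, macro, _ = confusion_and_f1(self.y[val_idx], pred, n_classes)
                if macro > best_score:
                    best_score, best_params = macro, params
        final = make(best_params, seed)
        final.fit(self.X, self.y, sample_weight=self.sample_weight)
        return BarcodeClassifierResults(self, final, best_params, best_score)


def _stratified_holdout(y, val_frac, rng):
    tr, val = [], []
    for c in np.unique(y):
        members = np.nonzero(y == c)[0]
        rng.shuffle(members)
        n_val = max(1, int(round(val_frac * len(members))))
        n_val = min(n_val, len(members) - 1)
        val.extend(members[:n_val])
        tr.extend(members[n_val:])
    return np.asarray(tr), np.asarray(val)


class BarcodeClassifierResults:
    """Fitted barcode classifier with tuned hyperparameters."""

    def __init__(self, model: BarcodeClassifier, booster, best_params, val_score):
        self.model = model
        self.booster = booster
        self.best_params = best_params
        self.val_score = val_score

    def predict(self, X) -> np.ndarray:
        return self.booster.predict(np.asarray(X, dtype=np.float64))

    def predict_proba(self, X) -> np.ndarray:
        return self.booster.predict_proba(np.asarray(X, dtype=np.float64))

    def feature_importance(self) -> pd.DataFrame:
        """Gain importance per feature, mapped to (mag, cluster) pairs."""
        imp = self.booster.feature_importances_
        names = self.model.feature_names or [f"f{i}" for i in range(len(imp))]
        mags = [n.split("_")[0] if "_" in n else "" for n in names]
        return pd.DataFrame({"feature": names, "mag": mags, "importance": imp})

    def summary(self) -> str:
        lines = [
            "Barcode classifier results",
            "=" * 42,
            f"slides:      {len(self.model.y)}",
            f"features:    {self.model.X.shape[1]}",
            f"classes:     {len(np.unique(self.model.y))}",
            f"tuned params: {self.best_params}",
        ]
        if self.val_score is not None and np.isfinite(self.val_score):
            lines.append(f"validation macro F1: {self.val_score:.3f}")
        return "\n".join(lines)


def t_confidence_interval(scores, level: float = 0.95) -> tuple:
    """(mean, half_width) of the t-based CI: mean +- t * sd / sqrt(n)."""
    s = np.asarray(scores, dtype=np.float64)
    n = len(s)
    mean = s.mean()
    if n < 2:
        return mean, 0.0
    sd = s.std(ddof=1)
    t = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return float(mean), float(t * sd / np.sqrt(n))


@dataclass
class MonteCarloCVResult:
    fold_scores: np.ndarray
    mean: float
    ci_half_width: float

    @property
    def ci(self) -> tuple:
        return (self.mean - self.ci_half_width, self.mean + self.ci_half_width)


def monte_carlo_cv(X, y, patients, fit_predict, n_folds: int = 5, holdout_frac: float = 0.2, metric=None, seed: int = 0) -> MonteCarloCVResult:
    """Repeated random patient-wise resplits with a t-based 95% CI.

    ``fit_predict(X_tr, y_tr, X_val, seed)`` must return predictions for
    the validation rows; ``metric(y_true, y_pred)`` defaults to macro F1.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    X = np.asarray(X)
    y = np.asarray(y)
    patients = np.asarray(patients)
    if metric is None:
        n_classes = int(y.max()) + 1

        def metric(a, b):
            return confusion_and_f1(a, b, n_classes)[2]

    rng = np.random.default_rng(seed)
    uniq = np.unique(patients)
    n_hold = int(round(holdout_frac * len(uniq)))
    if n_hold < 1 or n_hold >= len(uniq):
        raise ValueError("holdout too small for stratification")
    scores = []
    for _ in range(n_folds):
        held = rng.choice(uniq, size=n_hold, replace=False)
        val_mask = np.isin(patients, held)
        if len(np.unique(y[~val_mask])) < len(np.unique(y)):
            raise ValueError("holdout too small for stratification")
        pred = fit_predict(X[~val_mask], y[~val_mask], X[val_mask], int(rng.integers(2**31)))
        scores.append(metric(y[val_mask], pred))
    mean, hw = t_confidence_interval(scores)
    return MonteCarloCVResult(np.asarray(scores), mean, hw)
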