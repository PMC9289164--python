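"""Tile embeddings: weak-label tile classifier and provider interface.

Both slide-level aggregation methods in this package consume per-tile
embedding vectors h_k rather than pixels.  Embeddings can come from

* the **supervised baseline**: a tile classifier trained with weak
  slide-level labels (every tile inherits its slide's label); the
  embedding is the penultimate-layer activation, and slide-level scores
  for the baseline method are the mean of the tile class probabilities,
* any **pluggable provider** (e.g. a self-supervised network trained per
  magnification): a callable tiles -> N x M matrix with a declared
  dimension, keyed by magnification,
* the **synthetic pass-through**: the generator's matrices are used
  unchanged, so aggregation stages can be tested without any training.

The classifier is a small dense network with a declared penultimate
width (default 512, matching common convolutional backbones), trained
with Adam; per-epoch per-slide tile subsampling keeps training diverse
and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "ExtractorConfig",
    "TileClassifier",
    "train_tile_classifier",
    "extract_embeddings",
    "subsample_tiles_per_epoch",
    "mean_pool_slide_score",
    "featurize_tile_images",
    "EmbeddingStore",
]

DEFAULT_EMBED_DIM = 512
#: per-slide tile budgets per epoch for the self-supervised providers
PROVIDER_EPOCH_BUDGETS = {5: 500, 10: 500, 20: 1000}
#: per-slide tile budget per epoch for the supervised baseline
SUPERVISED_EPOCH_BUDGET = 500


@dataclass
class EmbeddingMatrix:
    """Per-slide, per-magnification tile embeddings (bag instances).

    ``matrix`` rows follow tile-manifest order; ``tile_index`` holds the
    (row, col) grid index of each embedded tile.
    """

    slide_id: str
    mag: float
    matrix: np.ndarray = field(repr=False)
    tile_index: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        self.tile_index = np.asarray(self.tile_index, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if len(self.tile_index) != len(self.matrix):
            raise ValueError("tile_index length must match matrix rows")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embeddings must be finite")

    @property
    def n_tiles(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ExtractorConfig:
    """Training configuration for the supervised tile classifier."""

    embed_dim: int = DEFAULT_EMBED_DIM
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 64
    epoch_budget: int = SUPERVISED_EPOCH_BUDGET
    augment_rotations: bool = True
    augment_flips: bool = True
    augment_color_jitter: bool = False
    feature_size: int = 16  # images are resized to feature_size**2 * 3 inputs


def subsample_tiles_per_epoch(tiles, budget: int, seed) -> list:
    """Uniform without-replacement sample of at most ``budget`` tiles.

    Slides with fewer than ``budget`` tiles contribute all their tiles.
    The sampled subset is returned in original order; deterministic for
    a given seed.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    tiles = list(tiles)
    if not tiles:
        raise ValueError("slide has no QC-passing tiles")
    if len(tiles) <= budget:
        return tiles
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(tiles), size=budget, replace=False))
    return [tiles[i] for i in idx]


def featurize_tile_images(images, feature_size: int = 16) -> np.ndarray:
    """Resize tile images to a small fixed grid and flatten to [0, 1]."""
    from skimage.transform import resize

    feats = []
    for img in images:
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        small = resize(
            img.astype(np.float64) / 255.0,
            (feature_size, feature_size, 3),
            anti_aliasing=True,
            preserve_range=True,
        )
        feats.append(small.ravel())
    return np.asarray(feats, dtype=np.float64)


class TileClassifier:
    """Dense tile classifier exposing its penultimate layer as embedding.

    Architecture: inputs -> tanh hidden layer of width ``embed_dim``
    (the embedding) -> linear softmax head.  An untrained model already
    emits finite embeddings of the declared width.
    """

    def __init__(self, n_features: int, n_classes: int, embed_dim: int = DEFAULT_EMBED_DIM, seed: int = 0):
        if n_classes < 2:
            raise ValueError("degenerate label set")
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / (n_features + embed_dim))
        s2 = np.sqrt(2.0 / (embed_dim + n_classes))
        self.W1 = rng.normal(0, s1, (n_features, embed_dim))
        self.b1 = np.zeros(embed_dim)
        self.W2 = rng.normal(0, s2, (embed_dim, n_classes))
        self.b2 = np.zeros(n_classes)
        self.n_features = n_features
        self.n_classes = n_classes
        self.embed_dim = embed_dim

    # -- forward ------------------------------------------------------
    def embed(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.tanh(X @ self.W1 + self.b1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.embed(X) @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    # -- training -----------------------------------------------------
    def fit(self, X, y, slide_ids=None, config: ExtractorConfig = None, seed: int = 0):
        """Weak-label training with per-slide per-epoch subsampling."""
        config = config or ExtractorConfig(embed_dim=self.embed_dim)
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate label set")
        rng = np.random.default_rng(seed)
        if slide_ids is None:
            slide_ids = np.zeros(len(X), dtype=np.int64)
        slide_ids = np.asarray(slide_ids)
        groups = {}
        for i, s in enumerate(slide_ids):
            groups.setdefault(s, []).append(i)
        adam = _Adam([self.W1, self.b1, self.W2, self.b2], lr=config.learning_rate)
        for _ in range(config.epochs):
            epoch_idx = []
            for s in groups:
                members = groups[s]
                epoch_idx.extend(
                    subsample_tiles_per_epoch(
                        members, config.epoch_budget, rng.integers(2**31)
                    )
                )
            epoch_idx = np.array(epoch_idx)
            rng.shuffle(epoch_idx)
            for start in range(0, len(epoch_idx), config.batch_size):
                b = epoch_idx[start : start + config.batch_size]
                self._step(X[b], y[b], adam)
        return self

    def _step(self, Xb, yb, adam):
        n = len(Xb)
        H = np.tanh(Xb @ self.W1 + self.b1)
        logits = H @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        P = e / e.sum(axis=1, keepdims=True)
        dlogits = P.copy()
        dlogits[np.arange(n), yb] -= 1.0
        dlogits /= n
        gW2 = H.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dH = dlogits @ self.W2.T
        dpre = dH * (1.0 - H * H)
        gW1 = Xb.T @ dpre
        gb1 = dpre.sum(axis=0)
        adam.step([gW1, gb1, gW2, gb2])


class _Adam:
    """Minimal Adam optimizer updating parameter arrays in place."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _augment_images(images, labels, config: ExtractorConfig, rng):
    """Rotation/flip augmentation applied image-wise (training only)."""
    out_imgs, out_labels = [], []
    for img, lab in zip(images, labels):
        out_imgs.append(img)
        out_labels.append(lab)
        if config.augment_rotations:
            out_imgs.append(np.rot90(img, k=int(rng.integers(1, 4))))
            out_labels.append(lab)
        if config.augment_flips:
            out_imgs.append(img[:, ::-1])
            out_labels.append(lab)
    return out_imgs, np.asarray(out_labels)


def train_tile_classifier(tiles, slide_labels, config: ExtractorConfig = None, slide_ids=None, seed: int = 0) -> TileClassifier:
    """Train the supervised weak-label tile classifier.

    ``tiles`` may be images (H x W x 3 arrays, featurized internally,
    with the configured augmentations) or pre-computed feature vectors.
    ``slide_labels`` gives the weak label of each tile (its slide's
    label).
    """
    config = config or ExtractorConfig()
    rng = np.random.default_rng(seed)
    labels = np.asarray(slide_labels)
    first = np.asarray(tiles[0])
    if first.ndim >= 2:
        tiles, labels = _augment_images(tiles, labels, config, rng)
        if slide_ids is not None:
            # augmented copies stay attached to their slide
            rep = len(tiles) // len(slide_ids)
            slide_ids = np.repeat(np.asarray(slide_ids), rep)[: len(tiles)]
        X = featurize_tile_images(tiles, config.feature_size)
    else:
        X = np.asarray(tiles, dtype=np.float64)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("degenerate label set")
    y = np.searchsorted(classes, labels)
    model = TileClassifier(X.shape[1], len(classes), config.embed_dim, seed=seed)
    model.classes_ = classes
    model.fit(X, y, slide_ids=slide_ids, config=config, seed=seed)
    return model


def extract_embeddings(model, tiles, mag, slide_id: str = "", tile_index=None, config: ExtractorConfig = None) -> EmbeddingMatrix:
    """Embed tiles with a trained model (no augmentation at inference).

    In synthetic-embedding mode ``model`` may be ``None`` and ``tiles``
    an :class:`EmbeddingMatrix`, returned unchanged (pass-through).
    """
    if isinstance(tiles, EmbeddingMatrix):
        return tiles
    if len(tiles) == 0:
        raise ValueError("no tiles to embed")
    config = config or ExtractorConfig()
    first = np.asarray(tiles[0])
    if first.ndim >= 2:
        X = featurize_tile_images(tiles, config.feature_size)
    else:
        X = np.asarray(tiles, dtype=np.float64)
    emb = model.embed(X)
    if tile_index is None:
        tile_index = np.column_stack([np.zeros(len(emb)), np.arange(len(emb))])
    return EmbeddingMatrix(slide_id=slide_id, mag=mag, matrix=emb, tile_index=tile_index)


def mean_pool_slide_score(tile_probabilities) -> tuple:
    """Aggregate tile class probabilities to one slide score.

    Returns ``(slide_probabilities, predicted_class)``; the prediction
    is the argmax with ties broken by lowest class index.
    """
    P = np.atleast_2d(np.asarray(tile_probabilities, dtype=np.float64))
    if P.shape[0] < 1:
        raise ValueError("need at least one tile")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("not a probability matrix")
    slide = P.mean(axis=0)
    return slide, int(np.argmax(slide))


class EmbeddingStore:
    """HDF5 store with groups /<slide_id>/<mag> holding embeddings."""

    def __init__(self, path):
        self.path = str(path)

    def write(self, matrices) -> None:
        with h5py.File(self.path, "a") as f:
            for em in matrices:
                grp = f.require_group(f"{em.slide_id}/{em.mag:g}")
                for name in ("embeddings", "tile_index"):
                    if name in grp:
                        del grp[name]
                grp.create_dataset("embeddings", data=em.matrix.astype(np.float32))
                grp.create_dataset("tile_index", data=em.tile_index.astype(np.int64))

    def read(self, slide_id, mag) -> EmbeddingMatrix:
        with h5py.File(self.path, "r") as f:
            grp = f[f"{slide_id}/{mag:g}"]
            return EmbeddingMatrix(
                slide_id=slide_id,
                mag=mag,
                matrix=grp["embeddings"][...],
                tile_index=grp["tile_index"][...],
            )

    def slides(self) -> list:
        with h5py.File(self.path, "r") as f:
            return sorted(f.keys())
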