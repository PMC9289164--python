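"""Attention-based multiple-instance learning on stacked embeddings.

A slide is a bag ``B = {x_1, ..., x_n}`` of tile embeddings with a
single slide-level label.  The pooling is the (non-gated) attention
mechanism

.. math::

    a_k = \\mathrm{softmax}_k\\big(w^\\top \\tanh(V h_k^\\top)\\big),
    \\qquad z = \\sum_k a_k h_k,

followed by a linear softmax head on the bag vector ``z``.  Attention
weights are strictly positive, sum to one, and are permutation
equivariant, which makes the model both order-independent and
interpretable (high-attention tiles mark regions of interest).

Multi-scale bags concatenate per-magnification embeddings row-wise in
descending magnification order: concentric tiling gives a strict 1:1
row correspondence; grid tiling duplicates each lower-magnification
embedding across the ``f**2`` higher-magnification tiles it covers.

:class:`AttentionMIL` follows the model/results idiom: the model holds
the bags and design choices, ``fit`` runs the optimization and returns a
:class:`MILResults` carrying parameters, training history, predictions
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import _Adam

__all__ = [
    "Bag",
    "AttentionParams",
    "MILTrainConfig",
    "attention_pool",
    "stack_concentric",
    "stack_grid",
    "median_frequency_weights",
    "AttentionMIL",
    "MILResults",
    "train_mil",
    "predict_mil",
]


@dataclass
class Bag:
    """One slide as a bag of (possibly multi-scale) instance embeddings."""

    slide_id: str
    label: int
    instances: np.ndarray = field(repr=False)  # N x D
    provenance: pd.DataFrame = None  # per row: contributing tile per mag

    def __post_init__(self):
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance row")


@dataclass
class AttentionParams:
    """Parameters of the attention pooling and classifier head."""

    V: np.ndarray  # L x D
    w: np.ndarray  # L
    head_W: np.ndarray = None  # D x n_classes
    head_b: np.ndarray = None


@dataclass
class MILTrainConfig:
    """Fitting configuration; defaults follow the tuned-axes starting grid."""

    bag_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    dropout: float = 0.25
    hidden: int = 128
    epochs: int = 50
    loss_mode: str = "median_frequency_weighted_CE"  # or "plain_CE"
    seed: int = 0

    def __post_init__(self):
        if self.bag_size < 1:
            raise ValueError("bag size must be >= 1")
        if self.loss_mode not in ("median_frequency_weighted_CE", "plain_CE"):
            raise ValueError("unknown loss mode")


def attention_pool(H: np.ndarray, params: AttentionParams):
    """Pool a bag to (z, a) with softmax attention (max-subtracted).

    ``a`` sums to one and every weight is strictly positive; ``z`` is
    the attention-weighted sum of the instance rows.
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    scores = np.tanh(H @ params.V.T) @ params.w
    if not np.isfinite(scores).all():
        raise FloatingPointError("numerical overflow")
    scores = scores - scores.max()
    e = np.exp(scores)
    a = e / e.sum()
    z = a @ H
    return z, a


def stack_concentric(embeddings_by_mag: dict, mags=None) -> np.ndarray:
    """Concatenate per-set embeddings across magnifications (1:1 rows).

    ``embeddings_by_mag`` maps magnification to an
    :class:`~scalestack.embeddings.EmbeddingMatrix` (or bare matrix)
    with one row per concentric set, in set order.  Rows are joined in
    descending magnification order.
    """
    mags = sorted(mags or embeddings_by_mag.keys(), reverse=True)
    mats = []
    n = None
    for m in mags:
        if m not in embeddings_by_mag:
            raise ValueError("concentric correspondence broken")
        em = embeddings_by_mag[m]
        mat = em.matrix if hasattr(em, "matrix") else np.asarray(em)
        if n is None:
            n = len(mat)
        elif len(mat) != n:
            raise ValueError("concentric correspondence broken")
        mats.append(mat)
    return np.hstack(mats)


def stack_grid(embeddings_by_mag: dict, mags=None) -> tuple:
    """Duplicate-and-concatenate grid embeddings across magnifications.

    One output row per highest-selected-magnification tile: the tile's
    own embedding followed by its ancestors' embeddings at each lower
    magnification (descending order), each ancestor embedding duplicated
    across all its descendants.  Rows whose ancestor embedding is absent
    (e.g. the ancestor tile failed QC) are dropped; an ancestor grid
    index outside the slide's grid is a broken lineage.

    Returns ``(matrix, kept_row_indices)`` where the indices refer to
    rows of the highest-magnification embedding matrix.
    """
    mags = sorted(mags or embeddings_by_mag.keys(), reverse=True)
    top = embeddings_by_mag[mags[0]]
    top_mat = top.matrix if hasattr(top, "matrix") else np.asarray(top)
    if len(mags) == 1:
        return top_mat, np.arange(len(top_mat))
    top_index = np.asarray(top.tile_index)
    lookups = {}
    grid_extent = {}
    for m in mags[1:]:
        em = embeddings_by_mag[m]
        idx = np.asarray(em.tile_index)
        lookups[m] = {(int(r), int(c)): i for i, (r, c) in enumerate(idx)}
        grid_extent[m] = (
            int(idx[:, 0].max()) + 1 if len(idx) else 0,
            int(idx[:, 1].max()) + 1 if len(idx) else 0,
        )
    rows, kept = [], []
    for i, (r, c) in enumerate(top_index):
        parts = [top_mat[i]]
        ok = True
        for m in mags[1:]:
            f = int(round(mags[0] / m))
            pr, pc = int(r) // f, int(c) // f
            em = embeddings_by_mag[m]
            j = lookups[m].get((pr, pc))
            if j is None:
                nrow, ncol = grid_extent[m]
                if pr >= max(nrow, 1) or pc >= max(ncol, 1):
                    raise ValueError("broken lineage")
                ok = False  # ancestor failed QC: drop this stacked row
                break
            mat = em.matrix if hasattr(em, "matrix") else np.asarray(em)
            parts.append(mat[j])
        if ok:
            rows.append(np.concatenate(parts))
            kept.append(i)
    if not rows:
        return np.empty((0, 0)), np.array([], dtype=int)
    return np.vstack(rows), np.asarray(kept)


def median_frequency_weights(class_counts) -> np.ndarray:
    """Median-frequency balancing: w_c = median(counts) / count_c.

    Minority classes receive weights above 1, majority classes below 1;
    with equal counts every weight is exactly 1.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 1).any():
        raise ValueError("class absent from training set")
    return np.median(counts) / counts


class AttentionMIL:
    """Attention-MIL model over a collection of bags.

    Parameters
    ----------
    bags : sequence of Bag
    n_classes : int, optional
        Inferred from the bag labels when omitted.
    """

    def __init__(self, bags, n_classes: int = None):
        self.bags = list(bags)
        if not self.bags:
            raise ValueError("no bags")
        labels = np.array([b.label for b in self.bags])
        if n_classes is None:
            n_classes = int(labels.max()) + 1
        if len(np.unique(labels)) < 2:
            raise ValueError("degenerate label set")
        self.n_classes = n_classes
        self.dim = self.bags[0].instances.shape[1]
        for b in self.bags:
            if b.instances.shape[1] != self.dim:
                raise ValueError("bag/model scale mismatch")

    @classmethod
    def from_slides(cls, slides, labels, mags, tiling="grid"):
        """Build bags from synthetic slides (pass-through embeddings)."""
        bags = []
        for slide, y in zip(slides, labels):
            embs = {m: slide.embeddings[m] for m in mags}
            if tiling == "grid":
                H, _ = stack_grid(embs, mags)
            elif tiling == "concentric":
                H = stack_concentric(embs, mags)
            else:
                raise ValueError("tiling must be 'grid' or 'concentric'")
            bags.append(Bag(slide_id=slide.slide_id, label=int(y), instances=H))
        return cls(bags)

    def fit(self, config: MILTrainConfig = None) -> "MILResults":
        """Minimize (optionally median-frequency-weighted) cross-entropy.

        Per epoch each bag is subsampled without replacement to
        ``bag_size`` instances (whole bag when smaller), the attention
        pooling and head are evaluated, and parameters are updated with
        Adam.  Deterministic given the config seed up to floating-point
        associativity.
        """
        config = config or MILTrainConfig()
        rng = np.random.default_rng(config.seed)
        D, L, C = self.dim, config.hidden, self.n_classes
        V = rng.normal(0, np.sqrt(2.0 / (D + L)), (L, D))
        w = rng.normal(0, np.sqrt(1.0 / L), L)
        head_W = rng.normal(0, np.sqrt(2.0 / (D + C)), (D, C))
        head_b = np.zeros(C)
        counts = np.bincount(
            [b.label for b in self.bags], minlength=self.n_classes
        )
        if config.loss_mode == "median_frequency_weighted_CE":
            class_w = median_frequency_weights(np.maximum(counts, 1))
            class_w[counts == 0] = 0.0
        else:
            class_w = np.ones(self.n_classes)
        adam = _Adam(
            [V, w, head_W, head_b],
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
        )
        history = []
        order = np.arange(len(self.bags))
        for _ in range(config.epochs):
            rng.shuffle(order)
            epoch_loss = 0.0
            for bi in order:
                bag = self.bags[bi]
                H = bag.instances
                if len(H) > config.bag_size:
                    sel = rng.choice(len(H), size=config.bag_size, replace=False)
                    H = H[np.sort(sel)]
                loss = self._step(
                    H, bag.label, V, w, head_W, head_b, class_w, adam, config, rng
                )
                epoch_loss += loss
            history.append(epoch_loss / len(self.bags))
        params = AttentionParams(V=V, w=w, head_W=head_W, head_b=head_b)
        return MILResults(self, params, config, np.asarray(history))

    @staticmethod
    def _step(H, y, V, w, head_W, head_b, class_w, adam, config, rng):
        n = len(H)
        T = np.tanh(H @ V.T)  # N x L
        if config.dropout > 0:
            keep = (rng.random(T.shape) >= config.dropout) / (1 - config.dropout)
            Td = T * keep
        else:
            keep = None
            Td = T
        s = Td @ w
        s = s - s.max()
        e = np.exp(s)
        a = e / e.sum()
        z = a @ H
        logits = z @ head_W + head_b
        logits = logits - logits.max()
        el = np.exp(logits)
        p = el / el.sum()
        cw = class_w[y]
        loss = -cw * np.log(max(p[y], 1e-12))
        # backward
        dlogits = cw * p
        dlogits[y] -= cw
        g_head_W = np.outer(z, dlogits)
        g_head_b = dlogits
        dz = head_W @ dlogits
        da = H @ dz
        ds = a * (da - (a @ da))
        g_w = Td.T @ ds
        dTd = np.outer(ds, w)
        if keep is not None:
            dT = dTd * keep
        else:
            dT = dTd
        dpre = dT * (1.0 - T * T)
        g_V = dpre.T @ H
        adam.step([g_V, g_w, g_head_W, g_head_b])
        return float(loss)


class MILResults:
    """Fitted attention-MIL model: parameters, history, predictions."""

    def __init__(self, model: AttentionMIL, params: AttentionParams, config: MILTrainConfig, history: np.ndarray):
        self.model = model
        self.params = params
        self.config = config
        self.history = history

    def predict_bag(self, bag) -> tuple:
        """(class probabilities, attention weights) for one bag."""
        H = bag.instances if isinstance(bag, Bag) else np.atleast_2d(bag)
        if H.shape[1] != self.model.dim:
            raise ValueError("bag/model scale mismatch")
        z, a = attention_pool(H, self.params)
        logits = z @ self.params.head_W + self.params.head_b
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum(), a

    def predict(self, bags) -> np.ndarray:
        """Predicted class per bag (argmax, lowest index on ties)."""
        return np.array([int(np.argmax(self.predict_bag(b)[0])) for b in bags])

    def attention_map(self, bag) -> pd.DataFrame:
        """Attention weights joined to instance provenance for export."""
        proba, a = self.predict_bag(bag)
        prov = bag.provenance
        if prov is None:
            prov = pd.DataFrame({"instance": np.arange(len(a))})
        out = prov.copy()
        out["weight"] = a
        return out

    def summary(self) -> str:
        lines = [
            "Attention-MIL results",
            "=" * 42,
            f"bags:            {len(self.model.bags)}",
            f"classes:         {self.model.n_classes}",
            f"instance dim:    {self.model.dim}",
            f"attention width: {self.config.hidden}",
            f"loss mode:       {self.config.loss_mode}",
            f"epochs:          {self.config.epochs}",
            f"final loss:      {self.history[-1]:.4f}",
        ]
        return "\n".join(lines)


def train_mil(bags, config: MILTrainConfig = None) -> MILResults:
    """Functional wrapper: fit an :class:`AttentionMIL` on bags."""
    return AttentionMIL(bags).fit(config or MILTrainConfig())


def predict_mil(results: MILResults, bag) -> tuple:
    """Functional wrapper around :meth:`MILResults.predict_bag`."""
    return results.predict_bag(bag)
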