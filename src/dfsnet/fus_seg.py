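"""Fusion segmentation: pre-labels, the C x C multi-embedding pairing
space, max-pooled label matrix, feature expansion, and the inverted
residual block.

Two layers of the network each pass their per-point features through a
segmentation (Seg) block, giving two C-dimensional "pre-label" score
vectors per point.  For each point n the pairing matrix
M(n)[i, j] = F_i(n) * S_j(n) spans every cross pairing of the two
pre-label vectors; diagonal entries (i = j) are the real pairings and
off-diagonal entries the incorrect ones.  By default the pre-label
vectors are L2-normalized first, so entries are the terms of a cosine
similarity, and an auxiliary diagonal-dominance loss pushes real pairings
up and incorrect pairings down.  Max pooling over the first layer's class
axis turns M(n) into a 1 x C label vector; the resulting N x C label
matrix acts as per-class weights that expand the layer-2 features to
N x f x C, which a learned contraction over the class axis returns to
width f before an inverted residual block (f -> 2f -> f with a skip).
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .data_io import ValidationError
from .nn import BatchNorm, Linear, Tensor, softmax_cross_entropy

__all__ = [
    "SegBlock",
    "embedding_space",
    "pool_labels",
    "expand_features",
    "pairing_loss",
    "InvertedResidual",
    "DynamicLayer",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class SegBlock:
    """Shared per-point map from features to C class scores (pre-labels).

    A two-layer perceptron f -> max(f/2, C) -> C with batch normalization
    and ReLU after the hidden layer; the same map is applied to every
    point.
    """

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator):
        hidden = max(in_dim // 2, n_classes)
        self.fc1 = Linear(in_dim, hidden, rng)
        self.bn = BatchNorm(hidden)
        self.fc2 = Linear(hidden, n_classes, rng)
        self.in_dim = in_dim
        self.n_classes = n_classes

    def __call__(self, features: Tensor) -> Tensor:
        features = _as_tensor(features)
        if features.shape[-1] != self.in_dim:
            raise ValidationError(
                f"feature dim {features.shape[-1]} != SegBlock in_dim {self.in_dim}"
            )
        return self.fc2(self.bn(self.fc1(features)).relu())

    def parameters(self) -> List[Tensor]:
        return self.fc1.parameters() + self.bn.parameters() + self.fc2.parameters()


def _l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + eps).sqrt()
    return x / norm


def embedding_space(a, b, normalize: bool = True) -> Tensor:
    """Per-point C x C pairing matrix M(n)[i, j] = F_i(n) * S_j(n).

    With ``normalize=True`` (default) the two pre-label vectors are
    L2-normalized per point first, so each entry is a cosine-similarity
    term; the raw product is kept for ablation.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError(f"pre-label shapes must match (N, C): {a.shape} vs {b.shape}")
    if normalize:
        a, b = _l2_normalize(a), _l2_normalize(b)
    n, c = a.shape
    return a.reshape(n, c, 1) * b.reshape(n, 1, c)


def pool_labels(space: Tensor) -> Tensor:
    """Max-pool the pairing space over the first layer's class axis.

    Reduces each point's C x C matrix to a 1 x C label vector in the
    second layer's class coordinates, giving the N x C label matrix.
    """
    space = _as_tensor(space)
    if space.ndim != 3 or space.shape[1] != space.shape[2]:
        raise ValidationError(f"pairing space must be (N, C, C), got {space.shape}")
    return space.max(axis=1)


def expand_features(features, tags) -> Tensor:
    """Expand N x f features to an N x f x C volume via per-point outer
    product with the label matrix; the tags act as per-class weights."""
    features, tags = _as_tensor(features), _as_tensor(tags)
    if features.shape[0] != tags.shape[0]:
        raise ValidationError("features/tags point-count mismatch")
    n, f = features.shape
    c = tags.shape[1]
    return features.reshape(n, f, 1) * tags.reshape(n, 1, c)


def pairing_loss(space: Tensor, logit_scale: float = 1.0) -> Tensor:
    """Diagonal-dominance objective on the pairing space.

    Per point, each row of M(n) is treated as logits over the second
    layer's classes and scored against its own (diagonal) index with
    softmax cross-entropy — maximizing real pairings while minimizing
    incorrect ones.  Averaged over points and rows.
    """
    space = _as_tensor(space)
    n, c, _ = space.shape
    rows = (space * logit_scale).reshape(n * c, c)
    targets = np.tile(np.arange(c), n)
    return softmax_cross_entropy(rows, targets)


class InvertedResidual:
    """Per-point expand-transform-project block (f -> 2f -> f) with skip.

    Three shared linear maps with batch normalization and ReLU between
    them; with all parameters zero the block is exactly the identity.
    The projection map starts at zero, so the block is the identity at
    initialization and stacked blocks form a well-conditioned pipeline.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, 2 * dim, rng)
        self.bn1 = BatchNorm(2 * dim)
        self.fc2 = Linear(2 * dim, 2 * dim, rng)
        self.bn2 = BatchNorm(2 * dim)
        self.fc3 = Linear(2 * dim, dim, rng)
        self.fc3.weight.data[...] = 0.0
        self.dim = dim

    def __call__(self, features: Tensor) -> Tensor:
        features = _as_tensor(features)
        h = self.bn1(self.fc1(features)).relu()
        h = self.bn2(self.fc2(h)).relu()
        return self.fc3(h) + features

    def parameters(self) -> List[Tensor]:
        return (
            self.fc1.parameters()
            + self.bn1.parameters()
            + self.fc2.parameters()
            + self.bn2.parameters()
            + self.fc3.parameters()
        )

    def batchnorms(self) -> List[BatchNorm]:
        return [self.bn1, self.bn2]


class DynamicLayer:
    """One dynamic segmentation layer: Fus-Seg plus an inverted residual.

    Composes: Seg blocks on the two input layers -> pairing space ->
    max-pooled label matrix -> outer-product expansion of the layer-2
    features (N x f -> N x f x C) -> learned contraction over the class
    axis back to width f -> inverted residual.  Returns the output
    features together with the two pre-label score matrices (used for the
    auxiliary pairing loss and as intermediate predictions).
    """

    def __init__(
        self,
        layer1_dim: int,
        layer2_dim: int,
        n_classes: int,
        rng: np.random.Generator,
        normalize_pairings: bool = True,
    ):
        self.seg1 = SegBlock(layer1_dim, n_classes, rng)
        self.seg2 = SegBlock(layer2_dim, n_classes, rng)
        # contraction: a learned C -> 1 combination over the class axis,
        # one weight vector per feature channel (a 1-wide convolution
        # over the class axis). Initialized near the identity (bias 1,
        # small weights) so stacked layers start as a well-conditioned
        # residual pipeline.
        self.contract_w = Tensor(
            rng.normal(0.0, 0.1 / np.sqrt(n_classes), (n_classes, layer2_dim)),
            requires_grad=True,
        )
        self.contract_b = Tensor(np.ones(layer2_dim), requires_grad=True)
        self.residual = InvertedResidual(layer2_dim, rng)
        self.n_classes = n_classes
        self.normalize_pairings = normalize_pairings

    def __call__(
        self, layer1_features, layer2_features
    ) -> Tuple[Tensor, Tensor, Tensor, Tensor]:
        """Returns (output features, pre-labels 1, pre-labels 2, pairing space)."""
        layer1_features = _as_tensor(layer1_features)
        layer2_features = _as_tensor(layer2_features)
        if layer1_features.shape[0] != layer2_features.shape[0]:
            raise ValidationError("layer inputs must share the point count")
        pre1 = self.seg1(layer1_features)
        pre2 = self.seg2(layer2_features)
        space = embedding_space(pre1, pre2, normalize=self.normalize_pairings)
        tags = pool_labels(space)
        volume = expand_features(layer2_features, tags)  # (N, f, C)
        # contract the class axis: out[n, f] = sum_c V[n, f, c] W[c, f]
        # == feats[n, f] * (tags[n] . W[:, f]); the bias enters the gate
        # so that gate ~= 1 (identity) at initialization
        contracted = layer2_features * (tags @ self.contract_w + self.contract_b)
        out = self.residual(contracted)
        return out, pre1, pre2, space

    def parameters(self) -> List[Tensor]:
        return (
            self.seg1.parameters()
            + self.seg2.parameters()
            + [self.contract_w, self.contract_b]
            + self.residual.parameters()
        )

    def batchnorms(self) -> List[BatchNorm]:
        return [self.seg1.bn, self.seg2.bn] + self.residual.batchnorms()
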