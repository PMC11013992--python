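"""Local feature aggregation: positional encoding, sampling, grouping,
set-abstraction cascade, and reconstruction.

The positional encoder (PosE) maps raw coordinates to a high-dimensional
vector with sine/cosine channels at geometrically spaced wavelengths —
a training-free embedding.  A cascade of set-abstraction (SA) stages then
halves the point count at each stage (N -> N/2 -> N/4 -> N/8) while
doubling the feature width: each stage samples centroids (FPS or RS),
groups k nearest neighbors, encodes neighbor offsets with PosE, and
aggregates each group with summed max- and average-pooling.  Finally the
centroid features of every stage are propagated back to all N points by
inverse-distance-weighted interpolation and concatenated with the
full-resolution embedding, giving the per-point local feature map.

With the default configuration (initial embedding width 144, three
stages, doubling widths) the concatenated feature dimension is
144 + 288 + 576 + 1152 = 2160.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .data_io import ValidationError

__all__ = [
    "PosEConfig",
    "SAStage",
    "HierarchyFeatures",
    "pose_encode",
    "fps",
    "random_sample",
    "knn_group",
    "sa_stage",
    "build_stages",
    "lfa_forward",
    "lfa_output_dim",
]

_CHUNK = 512  # centroids per block in grouping/interpolation, bounds memory


@dataclass(frozen=True)
class PosEConfig:
    """Trigonometric positional-encoder parameters.

    FI is the embedding width (divisible by 6: three axes, sin/cos pairs);
    mu scales the coordinate magnitude and nu sets the wavelength base of
    the geometric frequency progression.
    """

    FI: int = 144
    mu: float = 1000.0
    nu: float = 100.0

    def __post_init__(self) -> None:
        if self.FI % 6 != 0 or self.FI <= 0:
            raise ValidationError(f"FI must be a positive multiple of 6, got {self.FI}")
        if self.mu <= 0 or self.nu <= 0:
            raise ValidationError("mu and nu must be positive")


@dataclass(frozen=True)
class SAStage:
    """One set-abstraction stage of the cascade."""

    stage_index: int
    n_centroids: int
    k: int = 64
    sampler: str = "fps"  # "fps" | "rs"
    grouping: str = "knn"  # "knn" | "none" (centroid-only, ablation arm)
    in_dim: int = 144

    @property
    def out_dim(self) -> int:
        return 2 * self.in_dim

    def __post_init__(self) -> None:
        if self.sampler not in ("fps", "rs"):
            raise ValidationError(f"unknown sampler {self.sampler!r}")
        if self.grouping not in ("knn", "none"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")


@dataclass
class HierarchyFeatures:
    """Stage-0 full-resolution embedding plus per-stage centroid outputs."""

    embedding: np.ndarray  # (N, FI)
    stage_coords: List[np.ndarray] = field(default_factory=list)  # (n_s, 3)
    stage_features: List[np.ndarray] = field(default_factory=list)  # (n_s, d_s)


def pose_encode(coords: np.ndarray, config: PosEConfig) -> np.ndarray:
    """Encode (N, 3) coordinates into an (N, FI) trigonometric feature map.

    Per axis a, channel pairs indexed by t = 0..FI/6-1 hold
    sin(mu * a / nu^(6t/FI)) and cos(mu * a / nu^(6t/FI)); the three
    per-axis blocks are concatenated in x, y, z order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError(f"coords must be (N, 3), got {coords.shape}")
    n_pairs = config.FI // 6
    t = np.arange(n_pairs)
    wavelength = config.nu ** (6.0 * t / config.FI)  # (n_pairs,)
    # phase[n, axis, t]
    phase = config.mu * coords[:, :, None] / wavelength[None, None, :]
    per_axis = np.empty((coords.shape[0], 3, 2 * n_pairs))
    per_axis[:, :, 0::2] = np.sin(phase)
    per_axis[:, :, 1::2] = np.cos(phase)
    return per_axis.reshape(coords.shape[0], config.FI)


def fps(coords: np.ndarray, m: int, start_index: int = 0) -> np.ndarray:
    """Farthest point sampling: m greedy maximin centroid indices.

    Starts at ``start_index``; each subsequent pick maximizes the minimum
    Euclidean distance to the already-selected set, ties broken by lowest
    index.  Returned in selection order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= m <= n:
        raise ValidationError(f"m must be in 1..{n}, got {m}")
    if not 0 <= start_index < n:
        raise ValidationError(f"start_index out of range: {start_index}")
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start_index
    min_d2 = np.sum((coords - coords[start_index]) ** 2, axis=1)
    min_d2[start_index] = -np.inf  # selected points are never re-picked
    for i in range(1, m):
        nxt = int(np.argmax(min_d2))  # argmax returns the first max: lowest index
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
        min_d2[nxt] = -np.inf
    return selected


def random_sample(coords: np.ndarray, m: int, seed: int) -> np.ndarray:
    """m distinct indices drawn uniformly without replacement."""
    n = np.asarray(coords).shape[0]
    if not 1 <= m <= n:
        raise ValidationError(f"m must be in 1..{n}, got {m}")
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=m, replace=False).astype(np.int64)


def knn_group(
    coords: np.ndarray, centroid_indices: np.ndarray, k: int
) -> np.ndarray:
    """For each centroid, the k nearest points (rows sorted by distance).

    The centroid itself is eligible and, being at distance zero, is always
    included.  Ties are broken by lowest point index.
    """
    coords = np.asarray(coords, dtype=np.float64)
    centroid_indices = np.asarray(centroid_indices, dtype=np.int64)
    n = coords.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in 1..{n}, got {k}")
    m = centroid_indices.shape[0]
    out = np.empty((m, k), dtype=np.int64)
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        centers = coords[centroid_indices[lo:hi]]
        d2 = (
            np.sum(centers**2, axis=1)[:, None]
            - 2.0 * centers @ coords.T
            + np.sum(coords**2, axis=1)[None, :]
        )
        # recompute exactly for near-ties: the expansion above loses precision
        order = np.argsort(d2, axis=1, kind="stable")[:, : min(k + 8, n)]
        exact = np.sum((coords[order] - centers[:, None, :]) ** 2, axis=2)
        sub = np.argsort(exact, axis=1, kind="stable")[:, :k]
        out[lo:hi] = np.take_along_axis(order, sub, axis=1)
    return out


def _tile_to_width(block: np.ndarray, width: int) -> np.ndarray:
    """Tile the last axis of ``block`` up to ``width`` channels."""
    reps = -(-width // block.shape[-1])
    return np.tile(block, (1,) * (block.ndim - 1) + (reps,))[..., :width]


def sa_stage(
    coords: np.ndarray,
    features: np.ndarray,
    stage: SAStage,
    pose_config: PosEConfig,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Run one set-abstraction stage.

    Samples ``stage.n_centroids`` centroids, groups neighbors, encodes the
    neighbor offsets relative to each centroid with PosE, combines them
    with the neighbor+centroid features, and aggregates each group with
    max pooling plus average pooling (summed).  Returns centroid
    coordinates (m, 3) and centroid features (m, 2*in_dim).

    The neighbor feature entering the pool is Concat(neighbor, centroid)
    modulated by the tiled relative-offset encoding e: (feat + e) * e.
    Because the encoding depends only on offsets, the stage is invariant
    to rigid translations of the whole cloud given identical sampling.
    """
    coords = np.asarray(coords, dtype=np.float64)
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != coords.shape[0]:
        raise ValidationError("coords/features length mismatch")
    if features.shape[1] != stage.in_dim:
        raise ValidationError(
            f"feature dim {features.shape[1]} != stage.in_dim {stage.in_dim}"
        )
    if stage.sampler == "fps":
        centroid_idx = fps(coords, stage.n_centroids)
    else:
        centroid_idx = random_sample(coords, stage.n_centroids, seed)
    if stage.grouping == "knn":
        groups = knn_group(coords, centroid_idx, min(stage.k, coords.shape[0]))
    else:
        groups = centroid_idx[:, None]  # each centroid alone (no grouping)
    m, k = groups.shape
    out_dim = stage.out_dim
    centroid_coords = coords[centroid_idx]
    out_features = np.empty((m, out_dim))
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        g = groups[lo:hi]
        rel = coords[g] - centroid_coords[lo:hi, None, :]  # (c, k, 3)
        enc = pose_encode(rel.reshape(-1, 3), pose_config).reshape(
            hi - lo, k, pose_config.FI
        )
        enc = _tile_to_width(enc, out_dim)
        grouped = np.concatenate(
            [
                features[g],
                np.broadcast_to(
                    features[centroid_idx[lo:hi], None, :],
                    (hi - lo, k, stage.in_dim),
                ),
            ],
            axis=2,
        )
        combined = (grouped + enc) * enc
        out_features[lo:hi] = combined.max(axis=1) + combined.mean(axis=1)
    return centroid_coords, out_features


def build_stages(
    n_points: int,
    n_stages: int = 3,
    FI: int = 144,
    k: int = 64,
    sampler: str = "fps",
    grouping: str = "knn",
) -> List[SAStage]:
    """The halving cascade: stage s keeps N / 2^s points, widths double."""
    if n_points % (2**n_stages) != 0:
        raise ValidationError(
            f"n_points={n_points} not divisible by 2^{n_stages}"
        )
    stages = []
    in_dim = FI
    for s in range(1, n_stages + 1):
        stages.append(
            SAStage(
                stage_index=s,
                n_centroids=n_points // 2**s,
                k=k,
                sampler=sampler,
                grouping=grouping,
                in_dim=in_dim,
            )
        )
        in_dim *= 2
    return stages


def lfa_output_dim(FI: int, n_stages: int) -> int:
    """Concatenated width FI + 2FI + ... + 2^S FI (= 2160 at defaults)."""
    return sum(FI * 2**s for s in range(n_stages + 1))


def _interpolate(
    points: np.ndarray,
    centroids: np.ndarray,
    values: np.ndarray,
    n_neighbors: int = 3,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of centroid values onto points."""
    k = min(n_neighbors, centroids.shape[0])
    out = np.empty((points.shape[0], values.shape[1]))
    for lo in range(0, points.shape[0], 4 * _CHUNK):
        hi = min(lo + 4 * _CHUNK, points.shape[0])
        d2 = (
            np.sum(points[lo:hi] ** 2, axis=1)[:, None]
            - 2.0 * points[lo:hi] @ centroids.T
            + np.sum(centroids**2, axis=1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
        nd2 = np.take_along_axis(d2, nn, axis=1)
        w = 1.0 / (nd2 ** (power / 2.0) + 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        out[lo:hi] = np.einsum("pk,pkf->pf", w, values[nn])
    return out


def lfa_forward(
    coords: np.ndarray,
    stages: Optional[List[SAStage]] = None,
    pose_config: Optional[PosEConfig] = None,
    seed: int = 0,
    return_hierarchy: bool = False,
):
    """Full local-feature-aggregation pass: (N, 3) -> (N, f).

    Runs the full-resolution embedding, the SA cascade, then propagates
    each stage's centroid features back to all N points (inverse-distance
    weighting over the 3 nearest centroids) and concatenates all hierarchy
    levels.  With the defaults, f = 2160.
    """
    coords = np.asarray(coords, dtype=np.float64)
    pose_config = pose_config or PosEConfig()
    if stages is None:
        stages = build_stages(coords.shape[0], FI=pose_config.FI)
    n = coords.shape[0]
    if stages:
        depth = len(stages)
        if n % (2**depth) != 0:
            raise ValidationError(f"N={n} not divisible by 2^{depth}")
        if stages[0].in_dim != pose_config.FI:
            raise ValidationError("first stage in_dim must equal FI")
    embedding = pose_encode(coords, pose_config)
    hierarchy = HierarchyFeatures(embedding=embedding)
    cur_coords, cur_feats = coords, embedding
    for s, stage in enumerate(stages):
        cur_coords, cur_feats = sa_stage(
            cur_coords, cur_feats, stage, pose_config, seed=seed + s
        )
        hierarchy.stage_coords.append(cur_coords)
        hierarchy.stage_features.append(cur_feats)
    parts = [embedding]
    for c, v in zip(hierarchy.stage_coords, hierarchy.stage_features):
        parts.append(_interpolate(coords, c, v))
    features = np.concatenate(parts, axis=1)
    if return_hierarchy:
        return features, hierarchy
    return features
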