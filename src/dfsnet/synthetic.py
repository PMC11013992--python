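"""Synthetic labeled orchard scenes.

Generates point clouds with the structure of nursery working scenes
scanned by a single-viewpoint LiDAR: a ground plane, 2-3 potted trees
(vertical cylindrical trunks, ellipsoidal canopy shells, truncated-cone
pots, slanted scaffold stakes) and, in complex scenes, people, indicator
signs and miscellaneous objects.  Points are sampled on primitive
surfaces proportionally to surface area (LiDAR returns come from
surfaces, not volumes), perturbed by isotropic Gaussian noise, and an
angular sector of each tree is deleted to mimic self-occlusion from a
scanner at the scene edge.  Scenes are normalized so the bounding-box
minimum corner is the origin.

Class imbalance is deliberate: ground and leaves dominate while trunks
and scaffolds are thin structures, mirroring real orchard scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .data_io import (
    ClassMap,
    DatasetSplit,
    PointCloud,
    ValidationError,
    split_scenes,
    write_manifest,
    write_xyzl,
)

__all__ = ["SceneConfig", "SceneRecipe", "TreeParams", "generate_scene", "generate_dataset"]


class ConfigurationError(ValueError):
    """The scene configuration is geometrically infeasible."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic working scene.

    ``n_trees=None`` draws 2 or 3 trees and ``points_per_scene=None``
    draws 10k-60k points, matching typical working-scene sizes; fix them
    for reduced benchmarks.  ``extent`` is the scene box in meters.
    """

    n_trees: Optional[int] = None
    extent: Tuple[float, float, float] = (10.0, 10.0, 6.0)
    points_per_scene: Optional[int] = None
    class_set: str = "simple"
    noise_sd: float = 0.01
    occlusion_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.points_per_scene is not None and self.points_per_scene < 1000:
            raise ValidationError("points_per_scene must be >= 1000")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 0 <= self.occlusion_fraction < 1:
            raise ValidationError("occlusion_fraction must be in [0, 1)")


@dataclass
class TreeParams:
    """Geometry of one tree, in the normalized scene frame."""

    center: np.ndarray  # (2,) trunk axis position in x, y
    radius: float
    height: float


@dataclass
class SceneRecipe:
    """Primitive parameters of a generated scene (normalized frame)."""

    trees: List[TreeParams] = field(default_factory=list)
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scanner: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Surface primitives: (label_name, area, sampler, tree_index)


class _Primitive:
    def __init__(self, label: str, area: float, sampler, tree: Optional[int] = None):
        self.label = label
        self.area = area
        self.sampler = sampler
        self.tree = tree


def _plane(ex: float, ey: float):
    def sample(rng, n):
        pts = np.zeros((n, 3))
        pts[:, 0] = rng.uniform(0, ex, n)
        pts[:, 1] = rng.uniform(0, ey, n)
        return pts

    return ex * ey, sample


def _cylinder(cx: float, cy: float, z0: float, z1: float, r: float):
    def sample(rng, n):
        theta = rng.uniform(0, 2 * math.pi, n)
        z = rng.uniform(z0, z1, n)
        return np.stack(
            [cx + r * np.cos(theta), cy + r * np.sin(theta), z], axis=1
        )

    return 2 * math.pi * r * (z1 - z0), sample


def _tilted_cylinder(p0: np.ndarray, p1: np.ndarray, r: float):
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    u = axis / length
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-8:
        v = np.cross(u, [1.0, 0.0, 0.0])
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    def sample(rng, n):
        t = rng.uniform(0, 1, n)[:, None]
        theta = rng.uniform(0, 2 * math.pi, n)[:, None]
        return p0 + t * axis + r * (np.cos(theta) * v + np.sin(theta) * w)

    return 2 * math.pi * r * length, sample


def _ellipsoid_shell(center: np.ndarray, radii: np.ndarray):
    a, b, c = radii
    p = 1.6075  # Thomsen's approximation for ellipsoid surface area
    area = 4 * math.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3) ** (1 / p)

    def sample(rng, n):
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return center + d * radii

    return area, sample


def _truncated_cone(cx: float, cy: float, z0: float, z1: float, r0: float, r1: float):
    slant = math.hypot(z1 - z0, r1 - r0)
    area = math.pi * (r0 + r1) * slant

    def sample(rng, n):
        s = rng.uniform(0, 1, n)
        theta = rng.uniform(0, 2 * math.pi, n)
        r = r0 + s * (r1 - r0)
        z = z0 + s * (z1 - z0)
        return np.stack(
            [cx + r * np.cos(theta), cy + r * np.sin(theta), z], axis=1
        )

    return area, sample


def _rect(origin: np.ndarray, u: np.ndarray, v: np.ndarray):
    area = float(np.linalg.norm(np.cross(u, v)))

    def sample(rng, n):
        s = rng.uniform(0, 1, n)[:, None]
        t = rng.uniform(0, 1, n)[:, None]
        return origin + s * u + t * v

    return area, sample


# ---------------------------------------------------------------------------


def _place_trunks(
    rng: np.random.Generator, n_trees: int, extent, min_spacing: float = 2.0
) -> np.ndarray:
    """Trunk positions with pairwise spacing >= 2 m (planting distance)."""
    margin = 1.5
    ex, ey = extent[0], extent[1]
    if ex - 2 * margin <= 0 or ey - 2 * margin <= 0:
        raise ConfigurationError(f"extent {extent} too small for tree margin")
    for _ in range(2000):
        pts = np.stack(
            [
                rng.uniform(margin, ex - margin, n_trees),
                rng.uniform(margin, ey - margin, n_trees),
            ],
            axis=1,
        )
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        d[np.diag_indices(n_trees)] = np.inf
        if d.min() >= min_spacing:
            return pts
    raise ConfigurationError(
        f"cannot place {n_trees} trunks at >= {min_spacing} m spacing in {extent}"
    )


def _build_primitives(
    rng: np.random.Generator, config: SceneConfig, class_map: ClassMap
) -> Tuple[List[_Primitive], List[TreeParams]]:
    ex, ey, ez = config.extent
    minimal = config.class_set == "minimal"
    complex_scene = config.class_set == "complex"
    n_trees = config.n_trees
    if n_trees is None:
        n_trees = int(rng.integers(2, 4))
    prims: List[_Primitive] = []
    area, sampler = _plane(ex, ey)
    prims.append(_Primitive("grounds", area, sampler))
    centers = _place_trunks(rng, n_trees, config.extent)
    trees: List[TreeParams] = []
    for ti in range(n_trees):
        cx, cy = centers[ti]
        radius = float(rng.uniform(0.05, 0.15))
        height = float(rng.uniform(1.5, min(3.0, ez - 1.2)))
        trees.append(TreeParams(center=centers[ti].copy(), radius=radius, height=height))
        area, sampler = _cylinder(cx, cy, 0.0, height, radius)
        prims.append(_Primitive("trunks", area, sampler, tree=ti))
        n_shells = int(rng.integers(2, 5))
        for _ in range(n_shells):
            c = np.array(
                [
                    cx + rng.uniform(-0.3, 0.3),
                    cy + rng.uniform(-0.3, 0.3),
                    height + rng.uniform(-0.1, 0.5),
                ]
            )
            radii = rng.uniform(0.5, 1.1, 3)
            area, sampler = _ellipsoid_shell(c, radii)
            prims.append(_Primitive("leaves", area, sampler, tree=ti))
        if not minimal:
            area, sampler = _truncated_cone(
                cx, cy, 0.0, 0.35, radius + 0.20, radius + 0.30
            )
            prims.append(_Primitive("pots", area, sampler, tree=ti))
            if ti == 0 or rng.uniform() < 0.5:
                phi = rng.uniform(0, 2 * math.pi)
                p0 = np.array([cx + 0.6 * math.cos(phi), cy + 0.6 * math.sin(phi), 0.0])
                lean = float(rng.uniform(1.0, 1.5))
                p1 = np.array([cx, cy, lean])
                area, sampler = _tilted_cylinder(p0, p1, 0.02)
                prims.append(_Primitive("scaffolds", area, sampler, tree=ti))
    if complex_scene:
        # a person: torso cylinder plus a head shell
        px, py = rng.uniform(0.5, ex - 0.5), rng.uniform(0.5, ey - 0.5)
        area, sampler = _cylinder(px, py, 0.0, 1.45, 0.18)
        prims.append(_Primitive("people", area, sampler))
        area, sampler = _ellipsoid_shell(
            np.array([px, py, 1.6]), np.array([0.11, 0.11, 0.13])
        )
        prims.append(_Primitive("people", area, sampler))
        # an indicator: thin post with a planar sign on top
        ix, iy = rng.uniform(0.5, ex - 0.5), rng.uniform(0.5, ey - 0.5)
        area, sampler = _cylinder(ix, iy, 0.0, 1.2, 0.02)
        prims.append(_Primitive("indicators", area, sampler))
        ang = rng.uniform(0, 2 * math.pi)
        u = np.array([0.45 * math.cos(ang), 0.45 * math.sin(ang), 0.0])
        area, sampler = _rect(np.array([ix - u[0] / 2, iy - u[1] / 2, 1.2]), u,
                              np.array([0.0, 0.0, 0.3]))
        prims.append(_Primitive("indicators", area, sampler))
        # a miscellaneous convex object
        ox, oy = rng.uniform(0.5, ex - 0.5), rng.uniform(0.5, ey - 0.5)
        radii = rng.uniform(0.1, 0.4, 3)
        area, sampler = _ellipsoid_shell(np.array([ox, oy, radii[2]]), radii)
        prims.append(_Primitive("others", area, sampler))
    for p in prims:
        if p.label not in class_map.mapping.values():
            raise ValidationError(f"primitive label {p.label!r} not in class map")
    return prims, trees


def generate_scene(config: SceneConfig, with_recipe: bool = False):
    """Generate one labeled, normalized scene.

    Deterministic per ``config.seed``.  With ``with_recipe=True`` also
    returns the :class:`SceneRecipe` (primitive geometry in the
    normalized frame) so geometric label consistency can be checked.
    """
    rng = np.random.default_rng(config.seed)
    class_map = ClassMap.from_name(config.class_set)
    prims, trees = _build_primitives(rng, config, class_map)
    n_points = config.points_per_scene
    if n_points is None:
        n_points = int(rng.integers(10_000, 60_001))
    areas = np.array([p.area for p in prims])
    counts = rng.multinomial(n_points, areas / areas.sum())
    coords_parts, label_parts, tree_parts = [], [], []
    for p, c in zip(prims, counts):
        if c == 0:
            continue
        coords_parts.append(p.sampler(rng, int(c)))
        label_parts.append(
            np.full(int(c), class_map.value_of(p.label), dtype=np.int64)
        )
        tree_parts.append(np.full(int(c), -1 if p.tree is None else p.tree))
    coords = np.concatenate(coords_parts)
    labels = np.concatenate(label_parts)
    tree_of = np.concatenate(tree_parts)

    scanner = np.array([config.extent[0] / 2.0, -5.0, 1.5])
    if config.occlusion_fraction > 0 and trees:
        keep = np.ones(coords.shape[0], dtype=bool)
        half_width = math.pi * config.occlusion_fraction
        for ti, tree in enumerate(trees):
            # occluded sector faces away from the scanner
            away = math.atan2(
                tree.center[1] - scanner[1], tree.center[0] - scanner[0]
            ) + rng.uniform(-0.3, 0.3)
            mask = tree_of == ti
            az = np.arctan2(
                coords[mask, 1] - tree.center[1], coords[mask, 0] - tree.center[0]
            )
            delta = np.angle(np.exp(1j * (az - away)))
            keep[mask] &= np.abs(delta) > half_width
        coords, labels = coords[keep], labels[keep]
    if config.noise_sd > 0:
        coords = coords + rng.normal(0.0, config.noise_sd, coords.shape)

    offset = coords.min(axis=0)
    coords = coords - offset
    for tree in trees:
        tree.center = tree.center - offset[:2]
    cloud = PointCloud(coords=coords, labels=labels,
                       name=f"synthetic_{config.seed}")
    if with_recipe:
        return cloud, SceneRecipe(trees=trees, offset=offset,
                                  scanner=scanner - offset)
    return cloud


def generate_dataset(
    n_scenes: int, config: SceneConfig, out_dir, train_fraction: float = 2 / 3
) -> DatasetSplit:
    """Write ``n_scenes`` XYZL scene files plus a train/test manifest.

    Per-scene seeds are derived from ``config.seed``; the split is the
    package-wide default 2/3 train fraction.
    """
    if n_scenes < 2:
        raise ValidationError("need at least 2 scenes to form a split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    names = []
    for i, s in enumerate(scene_seeds):
        cfg = SceneConfig(
            n_trees=config.n_trees,
            extent=config.extent,
            points_per_scene=config.points_per_scene,
            class_set=config.class_set,
            noise_sd=config.noise_sd,
            occlusion_fraction=config.occlusion_fraction,
            seed=int(s),
        )
        cloud = generate_scene(cfg)
        name = f"scene_{i:03d}"
        cloud.name = name
        write_xyzl(cloud, out_dir / f"{name}.txt")
        names.append(name)
    split = split_scenes(names, seed=config.seed, train_fraction=train_fraction)
    write_manifest(split, out_dir / "split.txt")
    return split
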