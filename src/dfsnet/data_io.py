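"""Point-cloud I/O and preprocessing for orchard-scene segmentation.

Scenes are plain-text files with one point per line, ``X Y Z`` or
``X Y Z Label`` (whitespace- or comma-delimited).  Coordinates are meters;
labels are small contiguous integers defined by a :class:`ClassMap`.
Scenes are normalized by translating the minimum corner of the axis-aligned
bounding box to the origin, then randomly subsampled to a fixed point count
before entering the network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PointCloud",
    "ClassMap",
    "DatasetSplit",
    "ParseError",
    "ValidationError",
    "read_xyzl",
    "write_xyzl",
    "read_ply",
    "normalize_scene",
    "subsample",
    "split_scenes",
    "write_manifest",
    "read_manifest",
]


class ParseError(ValueError):
    """A scene file could not be parsed."""


class ValidationError(ValueError):
    """An input violates a contract (shape, range, emptiness...)."""


@dataclass
class PointCloud:
    """N points with optional integer class labels.

    Attributes
    ----------
    coords : (N, 3) float array, meters.
    labels : optional (N,) int array of class values.
    name : scene identifier.
    """

    coords: np.ndarray
    labels: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"coords must be (N, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValidationError("point cloud must contain at least one point")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if not np.issubdtype(self.labels.dtype, np.integer):
                raise ValidationError("labels must be integers")
            self.labels = self.labels.astype(np.int64)
            if self.labels.shape != (self.coords.shape[0],):
                raise ValidationError(
                    f"labels shape {self.labels.shape} does not match "
                    f"N={self.coords.shape[0]}"
                )

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def validate_labels(self, class_map: "ClassMap") -> None:
        """Raise if any label value is outside the class map."""
        if self.labels is None:
            return
        bad = ~np.isin(self.labels, list(class_map.mapping))
        if bad.any():
            raise ValidationError(
                f"labels {sorted(set(self.labels[bad].tolist()))} not in "
                f"class map with C={class_map.n_classes}"
            )


@dataclass(frozen=True)
class ClassMap:
    """Bidirectional map between label values (0..C-1) and class names."""

    mapping: dict

    def __post_init__(self) -> None:
        values = sorted(self.mapping)
        if values != list(range(len(values))):
            raise ValidationError(
                f"label values must be contiguous 0..C-1, got {values}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.mapping)

    def name_of(self, value: int) -> str:
        return self.mapping[value]

    def value_of(self, name: str) -> int:
        for v, n in self.mapping.items():
            if n == name:
                return v
        raise KeyError(name)

    @staticmethod
    def complex() -> "ClassMap":
        """8-class orchard taxonomy (complex scenes)."""
        return ClassMap(
            {
                0: "leaves",
                1: "trunks",
                2: "pots",
                3: "scaffolds",
                4: "grounds",
                5: "people",
                6: "indicators",
                7: "others",
            }
        )

    @staticmethod
    def simple() -> "ClassMap":
        """5-class orchard taxonomy (tree + ground scenes)."""
        return ClassMap(
            {0: "leaves", 1: "trunks", 2: "pots", 3: "scaffolds", 4: "grounds"}
        )

    @staticmethod
    def minimal() -> "ClassMap":
        """3-class taxonomy for reduced synthetic benchmarks."""
        return ClassMap({0: "leaves", 1: "trunks", 2: "grounds"})

    @staticmethod
    def from_name(name: str) -> "ClassMap":
        try:
            return {
                "complex": ClassMap.complex,
                "simple": ClassMap.simple,
                "minimal": ClassMap.minimal,
            }[name]()
        except KeyError:
            raise ValidationError(f"unknown class set {name!r}") from None


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of scene identifiers."""

    train: list = field(default_factory=list)
    test: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValidationError(f"train/test overlap: {sorted(overlap)}")


def read_xyzl(path, has_labels: bool = True, name: Optional[str] = None) -> PointCloud:
    """Read an ``X Y Z [Label]`` text scene.

    Accepts whitespace- or comma-delimited fields.  Labels, when present,
    must parse as integers.
    """
    path = Path(path)
    coords: list = []
    labels: list = []
    want = 4 if has_labels else 3
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != want:
                raise ParseError(
                    f"{path}:{lineno}: expected {want} fields, got {len(parts)}"
                )
            try:
                xyz = [float(p) for p in parts[:3]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
            coords.append(xyz)
            if has_labels:
                lab = parts[3]
                try:
                    labels.append(int(lab))
                except ValueError:
                    # allow "3.0" style but reject true non-integers
                    try:
                        f = float(lab)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric label {lab!r}"
                        ) from None
                    if f != int(f):
                        raise ValidationError(
                            f"{path}:{lineno}: label {lab!r} is not an integer"
                        ) from None
                    labels.append(int(f))
    if not coords:
        raise ValidationError(f"{path}: empty scene file")
    return PointCloud(
        coords=np.array(coords, dtype=np.float64),
        labels=np.array(labels, dtype=np.int64) if has_labels else None,
        name=name if name is not None else path.stem,
    )


def write_xyzl(cloud: PointCloud, path) -> Path:
    """Write a scene as space-delimited text with 6-decimal coordinates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i in range(cloud.n_points):
            x, y, z = cloud.coords[i]
            if cloud.has_labels:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {int(cloud.labels[i])}\n")
            else:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    return path


def read_ply(path, label_property: str = "label", name: Optional[str] = None) -> PointCloud:
    """Read a PLY point cloud (ascii or binary_little_endian).

    Vertex properties ``x, y, z`` become coordinates; an integer vertex
    property named ``label_property``, when present, becomes the labels.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list = []  # (name, numpy dtype) for the vertex element
        in_vertex = False
        _types = {
            "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
            "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
            "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
            "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
        }
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii").strip().split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ParseError(f"{path}: list property on vertex element")
                props.append((tokens[2], _types[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ParseError(f"{path}: no vertex element")
        dtype = np.dtype([(n, "<" + t) for n, t in props])
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append(tuple(fh.readline().split()))
            data = np.array(rows, dtype=dtype)
        else:
            data = np.frombuffer(fh.read(n_vertex * dtype.itemsize), dtype=dtype)
    for axis in ("x", "y", "z"):
        if axis not in data.dtype.names:
            raise ParseError(f"{path}: missing vertex property {axis!r}")
    coords = np.stack(
        [data["x"], data["y"], data["z"]], axis=1
    ).astype(np.float64)
    labels = None
    if label_property in data.dtype.names:
        labels = data[label_property].astype(np.int64)
    return PointCloud(coords=coords, labels=labels,
                      name=name if name is not None else path.stem)


def normalize_scene(cloud: PointCloud) -> PointCloud:
    """Translate the bounding-box minimum corner to the origin.

    A pure translation: pairwise distances are preserved exactly and the
    operation is idempotent.
    """
    origin = cloud.coords.min(axis=0)
    return PointCloud(
        coords=cloud.coords - origin,
        labels=None if cloud.labels is None else cloud.labels.copy(),
        name=cloud.name,
    )


def subsample(cloud: PointCloud, n_points: int, seed: int) -> PointCloud:
    """Draw exactly ``n_points`` points, uniformly at random.

    Without replacement when the cloud has at least ``n_points`` points,
    with replacement otherwise (so fixed-size batches are always possible).
    Deterministic for a fixed seed.
    """
    if n_points <= 0:
        raise ValidationError(f"n_points must be positive, got {n_points}")
    rng = np.random.default_rng(seed)
    replace = cloud.n_points < n_points
    idx = rng.choice(cloud.n_points, size=n_points, replace=replace)
    return PointCloud(
        coords=cloud.coords[idx],
        labels=None if cloud.labels is None else cloud.labels[idx],
        name=cloud.name,
    )


def split_scenes(
    scenes: Sequence[str], seed: int, train_fraction: float = 2 / 3
) -> DatasetSplit:
    """Random disjoint train/test split of scene identifiers.

    The default train fraction of 2/3 mirrors typical orchard-dataset
    splits (e.g. 206/309, 360/535 scenes).
    """
    scenes = list(scenes)
    if not scenes:
        raise ValidationError("no scenes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    n_train = int(round(train_fraction * len(scenes)))
    n_train = min(max(n_train, 1), len(scenes) - 1) if len(scenes) > 1 else 1
    train = [scenes[i] for i in sorted(order[:n_train])]
    test = [scenes[i] for i in sorted(order[n_train:])]
    return DatasetSplit(train=train, test=test, seed=seed)


def write_manifest(split: DatasetSplit, path) -> Path:
    """Write a two-column ``scene split`` manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for scene in split.train:
            fh.write(f"{scene} train\n")
        for scene in split.test:
            fh.write(f"{scene} test\n")
    return path


def read_manifest(path) -> DatasetSplit:
    train, test = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("train", "test"):
                raise ParseError(f"{path}:{lineno}: bad manifest line {raw!r}")
            (train if parts[1] == "train" else test).append(parts[0])
    return DatasetSplit(train=train, test=test)
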