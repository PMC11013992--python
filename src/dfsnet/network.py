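"""The full segmentation network: input layer -> local feature
aggregation -> dynamic segmentation layers -> fully connected output.

The LFA stage is training-free, so per-scene feature maps are computed
once and cached; training optimizes only the dynamic segmentation head
(Seg blocks, class-axis contractions, inverted residuals) and the output
layer.  The loss is per-point softmax cross-entropy plus a
lambda-weighted diagonal-dominance pairing loss from each dynamic
layer's multi-embedding space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data_io import ClassMap, PointCloud, ValidationError, normalize_scene, subsample
from .fus_seg import DynamicLayer, pairing_loss
from .lfa import PosEConfig, build_stages, lfa_forward, lfa_output_dim
from .nn import AdamW, Linear, Tensor, softmax_cross_entropy

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "DFSNet",
    "build",
    "train",
    "predict",
    "save_model",
    "load_model",
]


class TrainingDiagnosticError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class NetworkConfig:
    """Architecture configuration.

    The reference configuration is 4096 points, FI=144, three SA stages
    and three dynamic segmentation layers; smaller values are used for
    reduced synthetic benchmarks.  ``class_set`` picks the label taxonomy
    (complex C=8, simple C=5, minimal C=3).
    """

    n_points: int = 4096
    class_set: str = "complex"
    n_dynamic_layers: int = 3
    FI: int = 144
    mu: float = 1000.0
    nu: float = 100.0
    n_stages: int = 3
    k: int = 64
    sampler: str = "fps"
    grouping: str = "knn"
    normalize_pairings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_dynamic_layers <= 3:
            raise ValidationError("n_dynamic_layers must be in 1..3")
        if self.n_points % (2**self.n_stages) != 0:
            raise ValidationError(
                f"n_points={self.n_points} not divisible by 2^{self.n_stages}"
            )

    @property
    def class_map(self) -> ClassMap:
        return ClassMap.from_name(self.class_set)

    @property
    def n_classes(self) -> int:
        return self.class_map.n_classes

    @property
    def pose_config(self) -> PosEConfig:
        return PosEConfig(FI=self.FI, mu=self.mu, nu=self.nu)

    @property
    def feature_dim(self) -> int:
        return lfa_output_dim(self.FI, self.n_stages)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (AdamW recipe)."""

    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 1e-4
    epochs: int = 150
    optimizer: str = "adamw"
    batch_size: int = 8
    lambda_pairing: float = 0.1
    val_fraction: float = 0.1
    class_weighting: bool = False
    early_stop_acc: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if min(self.lr, self.eps, self.weight_decay, self.batch_size) <= 0:
            raise ValidationError("optimizer hyperparameters must be positive")


class DFSNet:
    """Point-cloud semantic segmentation network.

    ``forward`` maps an (N, 3) coordinate array to (N, C) class scores.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.feature_dim
        c = config.n_classes
        self.dynamic_layers = [
            DynamicLayer(f, f, c, rng, normalize_pairings=config.normalize_pairings)
            for _ in range(config.n_dynamic_layers)
        ]
        self.output = Linear(f, c, rng)

    # -- structure ----------------------------------------------------------

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for layer in self.dynamic_layers:
            params += layer.parameters()
        params += self.output.parameters()
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def set_training(self, flag: bool) -> None:
        for layer in self.dynamic_layers:
            for bn in layer.batchnorms():
                bn.training = flag

    # -- forward ------------------------------------------------------------

    def compute_features(self, coords: np.ndarray) -> np.ndarray:
        """Training-free LFA features for one scene, (N, 3) -> (N, f)."""
        cfg = self.config
        stages = build_stages(
            np.asarray(coords).shape[0],
            n_stages=cfg.n_stages,
            FI=cfg.FI,
            k=cfg.k,
            sampler=cfg.sampler,
            grouping=cfg.grouping,
        )
        return lfa_forward(coords, stages, cfg.pose_config, seed=cfg.seed)

    def head_forward(self, features: np.ndarray):
        """Dynamic segmentation head on precomputed LFA features.

        Layer wiring: the first dynamic layer pairs the LFA output with
        itself; each subsequent layer pairs the previous layer's input
        (Layer 1) with its output (Layer 2, the running features).
        Returns (class scores (N, C), list of pairing spaces).
        """
        x = Tensor(np.asarray(features, dtype=np.float64))
        prev, cur = x, x
        spaces = []
        for layer in self.dynamic_layers:
            out, _pre1, _pre2, space = layer(prev, cur)
            spaces.append(space)
            prev, cur = cur, out
        return self.output(cur), spaces

    def forward(self, coords: np.ndarray) -> Tensor:
        scores, _ = self.head_forward(self.compute_features(coords))
        return scores


def build(config: NetworkConfig) -> DFSNet:
    """Construct the network; initialization is deterministic per seed."""
    return DFSNet(config)


# ---------------------------------------------------------------------------
# Training


def _prepare_scene(
    model: DFSNet, cloud: PointCloud, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    if not cloud.has_labels:
        raise ValidationError(f"scene {cloud.name!r} has no labels")
    cloud = subsample(normalize_scene(cloud), model.config.n_points, seed)
    feats = model.compute_features(cloud.coords)
    return feats, cloud.labels


def train(
    model: DFSNet,
    train_scenes: Sequence[PointCloud],
    config: TrainConfig,
    log_path=None,
) -> List[dict]:
    """Train the segmentation head; returns the per-epoch log.

    Scenes are normalized, subsampled to the model's point count and
    featurized once up front.  Each optimizer step accumulates gradients
    over a batch of scenes.  Log rows carry epoch, mean loss, training
    accuracy and (when a validation split exists) validation accuracy.
    """
    if len(train_scenes) == 0:
        raise ValidationError("empty training set")
    if config.optimizer != "adamw":
        raise ValidationError(f"unknown optimizer {config.optimizer!r}")
    rng = np.random.default_rng(config.seed)
    prepared = [
        _prepare_scene(model, sc, int(rng.integers(2**31)))
        for sc in train_scenes
    ]
    n_val = int(round(config.val_fraction * len(prepared)))
    n_val = n_val if len(prepared) - n_val >= 1 else 0
    order0 = rng.permutation(len(prepared))
    val_set = [prepared[i] for i in order0[:n_val]]
    fit_set = [prepared[i] for i in order0[n_val:]]

    class_w = None
    if config.class_weighting:
        # inverse-frequency weights (mean ~1 over classes), capped so a
        # near-absent class cannot dominate the gradient
        all_labels = np.concatenate([lab for _, lab in fit_set])
        c = model.config.n_classes
        freq = np.bincount(all_labels, minlength=c) / all_labels.size
        class_w = np.minimum(1.0 / np.maximum(c * freq, 1e-12), 20.0)

    opt = AdamW(
        model.parameters(),
        lr=config.lr,
        betas=config.betas,
        eps=config.eps,
        weight_decay=config.weight_decay,
    )
    log: List[dict] = []
    for epoch in range(1, config.epochs + 1):
        model.set_training(True)
        order = rng.permutation(len(fit_set))
        losses, correct, total = [], 0, 0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo : lo + config.batch_size]
            opt.zero_grad()
            for i in batch:
                feats, labels = fit_set[i]
                scores, spaces = model.head_forward(feats)
                loss = softmax_cross_entropy(
                    scores, labels,
                    None if class_w is None else class_w[labels],
                )
                if config.lambda_pairing != 0.0:
                    for space in spaces:
                        loss = loss + config.lambda_pairing * pairing_loss(space)
                if not np.isfinite(loss.data):
                    raise TrainingDiagnosticError(
                        f"non-finite loss at epoch {epoch}"
                    )
                loss.backward(np.float64(1.0 / len(batch)))
                losses.append(float(loss.data))
                pred = np.argmax(scores.data, axis=1)
                correct += int((pred == labels).sum())
                total += labels.size
            opt.step()
        row = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "acc": correct / total,
        }
        if val_set:
            model.set_training(False)
            vc, vt = 0, 0
            for feats, labels in val_set:
                scores, _ = model.head_forward(feats)
                vc += int((np.argmax(scores.data, axis=1) == labels).sum())
                vt += labels.size
            row["val_acc"] = vc / vt
        log.append(row)
        if config.early_stop_acc is not None and row["acc"] >= config.early_stop_acc:
            break
    model.set_training(False)
    if log_path is not None:
        _write_log(log, log_path)
    return log


def _write_log(log: List[dict], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["epoch", "loss", "acc"] + (["val_acc"] if "val_acc" in log[0] else [])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in log:
            fh.write(",".join(str(row.get(c, "")) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Prediction and persistence


def predict(model: DFSNet, cloud: PointCloud, seed: int = 0) -> PointCloud:
    """Predict per-point labels for a scene.

    The scene is normalized and, if its size differs from the model's
    point count, randomly subsampled (or padded by resampling) to fit.
    Ties in the class scores resolve to the lowest class value.
    """
    cloud = normalize_scene(cloud)
    if cloud.n_points != model.config.n_points:
        cloud = subsample(cloud, model.config.n_points, seed)
    model.set_training(False)
    scores, _ = model.head_forward(model.compute_features(cloud.coords))
    labels = np.argmax(scores.data, axis=1)  # argmax takes the first max
    return PointCloud(coords=cloud.coords, labels=labels, name=cloud.name)


def save_model(model: DFSNet, path) -> Path:
    """Serialize configuration, parameters and batch-norm statistics."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    stats = []
    for layer in model.dynamic_layers:
        stats += layer.batchnorms()
    for i, bn in enumerate(stats):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(
        path,
        config=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **arrays,
    )
    return path


def load_model(path) -> DFSNet:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config"]).decode())
    model = DFSNet(NetworkConfig(**cfg_dict))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"param_{i}"].copy()
    stats = []
    for layer in model.dynamic_layers:
        stats += layer.batchnorms()
    for i, bn in enumerate(stats):
        bn.running_mean = data[f"bn_mean_{i}"].copy()
        bn.running_var = data[f"bn_var_{i}"].copy()
    return model
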