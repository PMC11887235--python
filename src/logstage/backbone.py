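"""Convolutional feature extractor f_theta and staging head g_W.

The model maps a single-channel grayscale slice to a feature vector (the
penultimate fully connected activation) and four stage logits.  Four
desk-scale architectures are provided; they share the interface so the
clustering/training loop is architecture-agnostic:

``tiny_cnn``
    three conv blocks, the default for tests and phantoms.
``vgg_small``
    reduced-width VGG-style stack (two convs per block).
``resnet_small``
    a small residual network (identity-skip blocks).
``alex_small``
    a reduced AlexNet-style stack (5x5 stem).

Features for clustering are read from the penultimate layer after its ReLU,
so they are nonnegative — convenient for the distributional clustering
downstream.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .imaging_io import RasterImage, stack_pixels

__all__ = ["BackboneConfig", "FeatureMatrix", "StagingModel", "build_model",
           "extract_features", "classify", "save_model", "load_model"]

ARCHITECTURES = ("tiny_cnn", "vgg_small", "resnet_small", "alex_small")


@dataclass(frozen=True)
class BackboneConfig:
    arch: str = "tiny_cnn"
    in_size: tuple[int, int] = (64, 64)
    feature_dim: int = 64
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHITECTURES}")
        if self.feature_dim <= 0 or self.n_classes <= 0:
            raise ValueError("feature_dim and n_classes must be positive")


@dataclass(frozen=True)
class FeatureMatrix:
    """N x D matrix of per-image feature vectors with source ids."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"feature matrix must be 2D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")
        if v.shape[0] != len(self.ids):
            raise ValueError("number of ids does not match number of rows")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _conv_stack(cfg: BackboneConfig, rng: np.random.Generator) -> nn.Sequential:
    if cfg.arch == "tiny_cnn":
        layers = [
            nn.Conv2d(1, 8, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(8, 16, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(16, 32, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
        ]
    elif cfg.arch == "vgg_small":
        layers = [
            nn.Conv2d(1, 8, 3, rng), nn.ReLU(), nn.Conv2d(8, 8, 3, rng), nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Conv2d(8, 16, 3, rng), nn.ReLU(), nn.Conv2d(16, 16, 3, rng), nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Conv2d(16, 32, 3, rng), nn.ReLU(), nn.Conv2d(32, 32, 3, rng), nn.ReLU(),
            nn.MaxPool2x2(),
        ]
    elif cfg.arch == "resnet_small":
        layers = [
            nn.Conv2d(1, 16, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.ResidualBlock(16, rng), nn.MaxPool2x2(),
            nn.ResidualBlock(16, rng), nn.MaxPool2x2(),
        ]
    elif cfg.arch == "alex_small":
        layers = [
            nn.Conv2d(1, 12, 5, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(12, 24, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2d(24, 32, 3, rng), nn.ReLU(), nn.MaxPool2x2(),
        ]
    else:  # pragma: no cover - guarded by BackboneConfig
        raise ValueError(cfg.arch)
    return nn.Sequential(layers)


class StagingModel:
    """f_theta (conv stack + feature FC) and g_W (linear stage head)."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv = _conv_stack(cfg, rng)
        self.flatten = nn.Flatten()
        # probe the conv stack to size the first FC layer
        probe = np.zeros((1, 1, *cfg.in_size))
        flat_dim = self.flatten.forward(self.conv.forward(probe)).shape[1]
        self.fc_feat = nn.Linear(flat_dim, cfg.feature_dim, rng)
        self.feat_relu = nn.ReLU()
        self.head = nn.Linear(cfg.feature_dim, cfg.n_classes, rng)
        self._head_reinit_count = 0

    # ---- forward ---------------------------------------------------------
    def _to_batch(self, images: Sequence[RasterImage] | np.ndarray) -> np.ndarray:
        if isinstance(images, np.ndarray):
            x = images
        else:
            x = stack_pixels(images)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != tuple(self.cfg.in_size):
            raise ValueError(
                f"input shape {x.shape[1:]} != model in_size {self.cfg.in_size}"
            )
        return x[:, None, :, :]  # add channel axis

    def forward(self, images) -> tuple[np.ndarray, np.ndarray]:
        """Return (features N x feature_dim, logits N x n_classes)."""
        x = self._to_batch(images)
        feats = self.feat_relu.forward(self.fc_feat.forward(
            self.flatten.forward(self.conv.forward(x))))
        logits = self.head.forward(feats)
        return feats, logits

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.fc_feat.backward(self.feat_relu.backward(g))
        self.conv.backward(self.flatten.backward(g))

    def trainable_layers(self) -> list[nn.Layer]:
        return [self.conv, self.fc_feat, self.head]

    def reinit_head(self, seed: int) -> None:
        """Fresh g_W; pseudo-label indices are arbitrary across rounds."""
        self._head_reinit_count += 1
        rng = np.random.default_rng(np.random.SeedSequence(
            (self.cfg.seed, 0x4EAD, seed, self._head_reinit_count)))
        self.head = nn.Linear(self.cfg.feature_dim, self.cfg.n_classes, rng)

    # ---- persistence -----------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "cfg": self.cfg,
            "params": [p.copy() for l in self.trainable_layers() for p in l.params()],
        }

    def load_state_dict(self, state: dict) -> None:
        params = [p for l in self.trainable_layers() for p in l.params()]
        if len(params) != len(state["params"]):
            raise ValueError("checkpoint does not match architecture")
        for dst, src in zip(params, state["params"]):
            dst[...] = src


def build_model(cfg: BackboneConfig) -> StagingModel:
    """Instantiate a staging model with seeded, deterministic initialization."""
    return StagingModel(cfg)


def extract_features(
    model: StagingModel, images: Sequence[RasterImage], batch_size: int = 32
) -> FeatureMatrix:
    """Penultimate-layer activations for each image (evaluation mode)."""
    ids = [im.source_id or str(i) for i, im in enumerate(images)]
    rows = []
    for start in range(0, len(images), batch_size):
        feats, _ = model.forward(list(images[start : start + batch_size]))
        rows.append(feats)
    return FeatureMatrix(np.concatenate(rows), ids=tuple(ids))


def classify(model: StagingModel, img: RasterImage) -> np.ndarray:
    """Stage probability vector (softmax over the 4 logits)."""
    _, logits = model.forward([img])
    return nn.softmax(logits)[0]


def save_model(model: StagingModel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model.state_dict(), fh)
    return path


def load_model(path: str | Path) -> StagingModel:
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    model = StagingModel(state["cfg"])
    model.load_state_dict(state)
    return model
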