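"""Alternating pseudo-label training: cluster features, train on the labels.

One round = (1) extract features of a clean central-crop view of every
training image, (2) cluster them into four groups with sIB (or k-means for
the ablation), (3) treat the cluster ids as stage labels and run a few
epochs of minibatch SGD on the negative log-softmax loss with train-time
augmentation.  Rounds alternate until the label assignment stabilizes.

Cluster identities are arbitrary and change between rounds, so the linear
stage head is reinitialized at the start of every round while the
convolutional backbone keeps learning.  Clusters are anonymous (C0..C3)
until a labeled subset pins them to stages T1..T4 via the Hungarian
assignment on the confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .augment import AugmentSpec, augment_image, central_crop, resize_image
from .backbone import FeatureMatrix, StagingModel, extract_features, classify
from .imaging_io import RasterImage
from .log_filter import DEFAULT_SIGMA, log_enhance
from .sib import SibConfig, kmeans_baseline, nmi, sib_cluster

__all__ = [
    "TrainConfig", "PseudoLabelSet", "preprocess_images", "pseudo_label_round",
    "train_round", "fit", "predict_stage", "hungarian_mapping", "STAGE_NAMES",
]

logger = logging.getLogger(__name__)

STAGE_NAMES = ("T1", "T2", "T3", "T4")

#: warn when one cluster swallows more than this share of the data
COLLAPSE_SHARE = 0.70


@dataclass(frozen=True)
class TrainConfig:
    rounds: int = 5
    epochs_per_round: int = 3
    batch_size: int = 16
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    sib: SibConfig = field(default_factory=SibConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    use_log_filter: bool = True
    log_sigma: float = DEFAULT_SIGMA
    clusterer: str = "sib"  # {"sib", "kmeans"} -- ablation axis
    cluster_margins: tuple[int, ...] = (0, 8, 16)  # multi-scale cluster views
    feature_whiten: bool = False  # PCA-whiten features before clustering
    epoch_ramp: bool = True  # round r trains epochs_per_round*(r+1) epochs

    def __post_init__(self) -> None:
        for name in ("rounds", "epochs_per_round", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.clusterer not in ("sib", "kmeans"):
            raise ValueError(f"clusterer must be 'sib' or 'kmeans', got {self.clusterer!r}")


@dataclass(frozen=True)
class PseudoLabelSet:
    """Cluster assignment of one round, used as training labels."""

    round: int
    assignment: dict[str, int]  # source_id -> cluster in {0..3}
    objective: float

    def labels_for(self, images: Sequence[RasterImage]) -> np.ndarray:
        missing = [im.source_id for im in images if im.source_id not in self.assignment]
        if missing:
            raise ValueError(f"images not covered by pseudo-labels: {missing[:5]}")
        return np.array([self.assignment[im.source_id] for im in images])


def _standardize(px: np.ndarray) -> np.ndarray:
    sd = px.std()
    return (px - px.mean()) / sd if sd > 0 else px - px.mean()


def preprocess_images(images: Sequence[RasterImage], cfg: TrainConfig) -> list[RasterImage]:
    """LoG-enhance (optional) and per-image standardize; applied once upfront."""
    out = []
    for im in images:
        if cfg.use_log_filter:
            im = log_enhance(im, cfg.log_sigma)
        out.append(RasterImage(_standardize(im.pixels), spacing=im.spacing,
                               source_id=im.source_id))
    return out


def _cluster_view(im: RasterImage, in_size: tuple[int, int], margin: int) -> RasterImage:
    big = resize_image(im, (in_size[0] + margin, in_size[1] + margin))
    return central_crop(big, in_size)


def whiten_split(values: np.ndarray) -> np.ndarray:
    """PCA-whiten feature rows, then split each signed axis into (+, -) parts.

    Training against its own pseudo-labels drives the backbone toward a few
    dominant activation directions; whitening equalizes the axes so the
    clustering keeps seeing the full feature geometry.  The positive/negative
    split re-expresses the signed whitened coordinates as the nonnegative
    matrix the distributional clustering expects, losing no information.
    """
    from sklearn.decomposition import PCA

    n, d = values.shape
    comps = min(n - 1, d)
    if comps < 2:
        return np.clip(values, 0.0, None)
    z = PCA(n_components=comps, whiten=True, random_state=0).fit_transform(values)
    return np.concatenate([np.clip(z, 0.0, None), np.clip(-z, 0.0, None)], axis=1)


def pseudo_label_round(
    model: StagingModel,
    images: Sequence[RasterImage],
    cfg: TrainConfig,
    round_index: int | None = None,
) -> PseudoLabelSet:
    """Cluster central-crop features of ``images`` into 4 pseudo-stages.

    ``round_index`` defaults to an internal counter on the model so repeated
    calls number their rounds monotonically.
    """
    if len(images) < cfg.sib.k:
        raise ValueError(f"need at least {cfg.sib.k} images, got {len(images)}")
    if round_index is None:
        round_index = getattr(model, "_pseudo_round", -1) + 1
    model._pseudo_round = round_index

    blocks = []
    for margin in cfg.cluster_margins:
        views = [_cluster_view(im, model.cfg.in_size, margin) for im in images]
        blocks.append(extract_features(model, views).values)
    ids = tuple(im.source_id for im in images)
    feats = FeatureMatrix(np.concatenate(blocks, axis=1), ids=ids)
    if cfg.feature_whiten:
        feats = FeatureMatrix(whiten_split(feats.values), ids=feats.ids)
    if cfg.clusterer == "sib":
        state = sib_cluster(feats, replace(cfg.sib, seed=cfg.sib.seed + round_index))
        assignment = state.assignment
        objective = state.objective
    else:
        assignment = kmeans_baseline(feats, k=cfg.sib.k, seed=cfg.sib.seed + round_index)
        objective = float("nan")

    shares = np.bincount(assignment, minlength=cfg.sib.k) / len(assignment)
    if shares.max() > COLLAPSE_SHARE:
        logger.warning(
            "round %d: cluster %d holds %.0f%% of samples (possible collapse)",
            round_index, int(shares.argmax()), 100 * shares.max(),
        )
    mapping = {im.source_id: int(c) for im, c in zip(images, assignment)}
    return PseudoLabelSet(round=round_index, assignment=mapping, objective=objective)


def train_round(
    model: StagingModel,
    images: Sequence[RasterImage],
    labels: PseudoLabelSet,
    cfg: TrainConfig,
) -> dict:
    """A few epochs of minibatch SGD against the round's pseudo-labels.

    The stage head is reinitialized first (cluster ids are not aligned
    across rounds); the backbone continues from its current parameters.
    Returns a report with the per-epoch mean loss trace.
    """
    y = labels.labels_for(images)
    model.reinit_head(seed=cfg.seed + labels.round)
    opt = nn.SGD(model.trainable_layers(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, labels.round)))
    n = len(images)
    spec = cfg.augment
    if spec.out_size != model.cfg.in_size:
        spec = replace(spec, out_size=model.cfg.in_size)

    loss_trace = []
    draw_base = labels.round * cfg.epochs_per_round * n
    for epoch in range(cfg.epochs_per_round):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = np.stack([
                augment_image(images[i], spec, draw_base + epoch * n + int(i)).pixels
                for i in idx
            ])
            _, logits = model.forward(batch)
            loss, dlogits = nn.cross_entropy_loss(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        loss_trace.append(float(np.mean(losses)))
    return {"round": labels.round, "loss_trace": loss_trace}


def fit(
    images: Sequence[RasterImage],
    model: StagingModel,
    cfg: TrainConfig,
    truth: Sequence[int] | None = None,
) -> tuple[StagingModel, list[dict]]:
    """Run ``cfg.rounds`` alternations of clustering and training.

    ``truth`` (stages 1..4), when given, is used only for monitoring: each
    history entry then records the NMI between pseudo-labels and truth.
    History schema per round: ``{round, sib_objective, loss_trace,
    nmi_prev_round, nmi_truth}``.
    """
    if len(images) < 4:
        raise ValueError("need at least 4 images")
    images = preprocess_images(images, cfg)
    history: list[dict] = []
    prev: PseudoLabelSet | None = None
    for r in range(cfg.rounds):
        pseudo = pseudo_label_round(model, images, cfg, round_index=r)
        # early pseudo-labels are noisy: train lightly on them, harder as
        # the labeling stabilizes, so bad initial partitions don't entrench
        round_cfg = cfg
        if cfg.epoch_ramp:
            round_cfg = replace(cfg, epochs_per_round=cfg.epochs_per_round * (r + 1))
        report = train_round(model, images, pseudo, round_cfg)
        y = pseudo.labels_for(images)
        entry = {
            "round": r,
            "sib_objective": pseudo.objective,
            "loss_trace": report["loss_trace"],
            "nmi_prev_round": (nmi(prev.labels_for(images), y) if prev is not None else None),
        }
        if truth is not None:
            entry["nmi_truth"] = nmi(np.asarray(truth), y)
        history.append(entry)
        prev = pseudo
    model._last_pseudo = prev
    return model, history


def hungarian_mapping(pseudo: Sequence[int], truth: Sequence[int]) -> np.ndarray:
    """Cluster -> stage permutation maximizing labeled agreement.

    ``pseudo`` in {0..3}, ``truth`` in {1..4}.  Returns ``perm`` with
    ``perm[cluster] = stage``; a pure relabeling fixed by the Hungarian
    algorithm on the 4x4 confusion matrix.
    """
    pseudo = np.asarray(pseudo)
    truth = np.asarray(truth)
    if pseudo.shape != truth.shape:
        raise ValueError("pseudo and truth must have equal length")
    conf = np.zeros((4, 4))
    for c, s in zip(pseudo, truth):
        conf[int(c), int(s) - 1] += 1
    rows, cols = linear_sum_assignment(-conf)
    perm = np.zeros(4, dtype=int)
    perm[rows] = cols + 1
    return perm


def predict_stage(
    model: StagingModel,
    image: RasterImage,
    cfg: TrainConfig | None = None,
    mapping: np.ndarray | None = None,
) -> tuple[str, np.ndarray]:
    """Predict the stage of one raw image.

    Applies the same preprocessing as training, classifies, then relabels
    the argmax cluster through ``mapping`` (cluster -> stage permutation);
    without a mapping, clusters map to stages in index order.  The returned
    probability vector is ordered by stage T1..T4.
    """
    cfg = cfg or TrainConfig()
    [prepped] = preprocess_images([image], cfg)
    view = resize_image(prepped, model.cfg.in_size)
    probs_cluster = classify(model, view)
    if mapping is None:
        mapping = np.arange(1, 5)
    mapping = np.asarray(mapping)
    if sorted(mapping.tolist()) != [1, 2, 3, 4]:
        raise ValueError(f"mapping must be a permutation of stages 1..4, got {mapping}")
    probs_stage = np.zeros(4)
    for cluster, stage in enumerate(mapping):
        probs_stage[stage - 1] = probs_cluster[cluster]
    stage = int(np.argmax(probs_stage)) + 1
    return STAGE_NAMES[stage - 1], probs_stage
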