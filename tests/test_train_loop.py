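"""Pseudo-label rounds, SGD training rounds and the cluster-stage mapping."""

import numpy as np
import pytest

from logstage.augment import AugmentSpec
from logstage.backbone import BackboneConfig, build_model
from logstage.imaging_io import RasterImage
from logstage.sib import SibConfig
from logstage.train_loop import (PseudoLabelSet, TrainConfig, fit,
                                 hungarian_mapping, predict_stage,
                                 pseudo_label_round, train_round)


def _texture_images(rng, n_per_class=2, size=(64, 64)):
    """Four strongly distinct texture families, n_per_class images each."""
    images, labels = [], []
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]]
    patterns = [
        np.sin(xx / 2.0),                     # vertical stripes
        np.sin(yy / 2.0),                     # horizontal stripes
        np.sin((xx + yy) / 3.0),              # diagonal stripes
        np.sin(xx / 2.0) * np.sin(yy / 2.0),  # checkers
    ]
    idx = 0
    for c, base in enumerate(patterns):
        for _ in range(n_per_class):
            noise = rng.normal(0, 0.05, size)
            images.append(RasterImage(base + noise, source_id=f"tex{idx}"))
            labels.append(c + 1)
            idx += 1
    return images, np.array(labels)


@pytest.fixture
def quick_cfg():
    return TrainConfig(
        rounds=1, epochs_per_round=1, batch_size=4, learning_rate=0.01,
        seed=0, sib=SibConfig(seed=0, restarts=2),
        augment=AugmentSpec(seed=0), use_log_filter=False, epoch_ramp=False,
    )


class TestPseudoLabelRound:
    def test_duplicate_pairs_co_cluster(self, rng, quick_cfg):
        """Identical images must always land in the same cluster."""
        base, _ = _texture_images(rng, n_per_class=1)
        images = []
        for i, im in enumerate(base):
            images.append(RasterImage(im.pixels, source_id=f"a{i}"))
            images.append(RasterImage(im.pixels, source_id=f"b{i}"))
        model = build_model(BackboneConfig(seed=0))
        pseudo = pseudo_label_round(model, images, quick_cfg, round_index=0)
        for i in range(4):
            assert pseudo.assignment[f"a{i}"] == pseudo.assignment[f"b{i}"]

    def test_deterministic_given_seed(self, rng, quick_cfg):
        images, _ = _texture_images(rng)
        m1 = build_model(BackboneConfig(seed=1))
        m2 = build_model(BackboneConfig(seed=1))
        p1 = pseudo_label_round(m1, images, quick_cfg, round_index=0)
        p2 = pseudo_label_round(m2, images, quick_cfg, round_index=0)
        assert p1 == p2

    def test_round_counter_increments(self, rng, quick_cfg):
        images, _ = _texture_images(rng)
        model = build_model(BackboneConfig(seed=0))
        r0 = pseudo_label_round(model, images, quick_cfg)
        r1 = pseudo_label_round(model, images, quick_cfg)
        assert (r0.round, r1.round) == (0, 1)

    def test_too_few_images_rejected(self, rng, quick_cfg):
        model = build_model(BackboneConfig(seed=0))
        with pytest.raises(ValueError):
            pseudo_label_round(model, [RasterImage(np.zeros((64, 64)))], quick_cfg)


class TestTrainRound:
    def test_zero_learning_rate_freezes_backbone(self, rng, quick_cfg):
        images, _ = _texture_images(rng)
        model = build_model(BackboneConfig(seed=0))
        labels = PseudoLabelSet(
            round=0, assignment={im.source_id: i % 4 for i, im in enumerate(images)},
            objective=0.0)
        conv_before = [p.copy() for p in model.conv.params()]
        head_before = model.head.w.copy()
        from dataclasses import replace

        train_round(model, images, labels, replace(quick_cfg, learning_rate=0.0))
        for p, q in zip(model.conv.params(), conv_before):
            assert np.array_equal(p, q)
        # the head is reinitialized at round start even at lr 0
        assert not np.array_equal(model.head.w, head_before)

    def test_overfits_separable_textures(self, rng):
        """Loss falls and training accuracy tops 0.95 on 4 easy classes."""
        images, labels_true = _texture_images(rng, n_per_class=4)
        model = build_model(BackboneConfig(seed=0))
        labels = PseudoLabelSet(
            round=0,
            assignment={im.source_id: int(l) - 1 for im, l in zip(images, labels_true)},
            objective=0.0)
        cfg = TrainConfig(rounds=1, epochs_per_round=20, batch_size=8,
                          learning_rate=0.02, seed=0, use_log_filter=False,
                          epoch_ramp=False,
                          augment=AugmentSpec(rotation_degrees=(0.0,), seed=0,
                                              crop="central", allow_flip_h=False))
        report = train_round(model, images, labels, cfg)
        assert report["loss_trace"][-1] < report["loss_trace"][0]
        _, logits = model.forward(images)
        acc = np.mean(logits.argmax(axis=1) == labels.labels_for(images))
        assert acc >= 0.95

    def test_identical_images_carry_no_cluster_information(self, rng, quick_cfg):
        """With all-identical inputs the preserved information I(T;Y) is zero
        and the classifier cannot beat the label-marginal entropy."""
        from dataclasses import replace

        base = RasterImage(rng.uniform(0, 1, (64, 64)), source_id="base")
        images = [RasterImage(base.pixels, source_id=f"dup{i}") for i in range(8)]
        model = build_model(BackboneConfig(seed=0))
        cfg = replace(quick_cfg, epochs_per_round=3)
        pseudo = pseudo_label_round(model, images, cfg, round_index=0)
        # objective = I(T;Y) - H(T)/lambda with I(T;Y) = 0 for identical rows
        assert pseudo.objective <= 1e-9
        counts = np.bincount(list(pseudo.assignment.values()), minlength=4)
        assert np.all(counts > 0)  # four clusters survive even degenerately
        report = train_round(model, images, pseudo, cfg)
        marginal = counts / counts.sum()
        h_marginal = -np.sum(marginal * np.log(marginal))
        # identical inputs give identical outputs: loss is floored by H(labels)
        assert report["loss_trace"][-1] >= h_marginal - 0.05
        assert report["loss_trace"][-1] <= np.log(4) + 0.6

    def test_uncovered_image_rejected(self, rng, quick_cfg):
        images, _ = _texture_images(rng)
        model = build_model(BackboneConfig(seed=0))
        labels = PseudoLabelSet(round=0, assignment={"nope": 0}, objective=0.0)
        with pytest.raises(ValueError):
            train_round(model, images, labels, quick_cfg)


class TestFit:
    def test_single_round_composition(self, rng, quick_cfg):
        images, _ = _texture_images(rng)
        model = build_model(BackboneConfig(seed=0))
        model, history = fit(images, model, quick_cfg)
        assert len(history) == 1
        assert set(history[0]) >= {"round", "sib_objective", "loss_trace", "nmi_prev_round"}

    def test_history_tracks_truth_nmi(self, rng, quick_cfg):
        images, truth = _texture_images(rng)
        model = build_model(BackboneConfig(seed=0))
        from dataclasses import replace

        _, history = fit(images, model, replace(quick_cfg, rounds=2), truth=truth)
        assert all("nmi_truth" in h for h in history)
        assert all(0.0 <= h["nmi_truth"] <= 1.0 for h in history)

    def test_every_round_has_four_nonempty_clusters(self, rng, quick_cfg):
        images, _ = _texture_images(rng, n_per_class=3)
        model = build_model(BackboneConfig(seed=0))
        from dataclasses import replace

        cfg = replace(quick_cfg, rounds=2)
        model, _ = fit(images, model, cfg)
        counts = np.bincount(list(model._last_pseudo.assignment.values()), minlength=4)
        assert np.all(counts > 0)


class TestHungarianMapping:
    def test_recovers_known_permutation(self, rng):
        truth = rng.integers(1, 5, 80)
        perm = np.array([3, 1, 4, 2])  # cluster c -> stage perm[c]
        inv = {s: c for c, s in enumerate(perm)}
        pseudo = np.array([inv[s] for s in truth])
        assert np.array_equal(hungarian_mapping(pseudo, truth), perm)

    def test_mapping_is_permutation_even_under_noise(self, rng):
        truth = rng.integers(1, 5, 60)
        pseudo = rng.integers(0, 4, 60)
        perm = hungarian_mapping(pseudo, truth)
        assert sorted(perm.tolist()) == [1, 2, 3, 4]


class TestPredictStage:
    def test_identity_mapping_argmax(self, rng, quick_cfg):
        model = build_model(BackboneConfig(seed=0))
        img = RasterImage(rng.uniform(0, 1, (64, 64)))
        name, probs = predict_stage(model, img, quick_cfg)
        assert name == f"T{np.argmax(probs) + 1}"
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_mapping_relabels(self, rng, quick_cfg):
        model = build_model(BackboneConfig(seed=0))
        img = RasterImage(rng.uniform(0, 1, (64, 64)))
        _, p_id = predict_stage(model, img, quick_cfg, mapping=np.array([1, 2, 3, 4]))
        _, p_swap = predict_stage(model, img, quick_cfg, mapping=np.array([4, 2, 3, 1]))
        assert p_swap[0] == p_id[3] and p_swap[3] == p_id[0]

    def test_invalid_mapping_rejected(self, rng, quick_cfg):
        model = build_model(BackboneConfig(seed=0))
        img = RasterImage(rng.uniform(0, 1, (64, 64)))
        with pytest.raises(ValueError):
            predict_stage(model, img, quick_cfg, mapping=np.array([1, 1, 2, 3]))
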