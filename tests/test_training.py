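"""Trainers: degenerate contracts, selection rules, equivalences."""

import numpy as np
import pytest

from antdet.estimators import (HybridDetector, ProbabilisticNNFitDistiller,
                               PseudoLabelDetector, RandomNNFitDistiller)
from antdet.foreground import annotate_sequence, extract_foreground_fe1
from antdet.models import build_model, predict_proba
from antdet.training import (AnnotationSource, EnsembleConfig, TrainConfig,
                             _selection_probs, average_ensemble_predict,
                             make_network_sources, render_human_annotation,
                             train_hybrid, train_probabilistic_nn_fit,
                             train_random_nn_fit, train_single_source)

FAST = dict(batch_size=2, crop_size=16, total_iters=30, lr_switch_iter=20)


@pytest.fixture(scope="module")
def tiny_data():
    from antdet.synthetic import SynthConfig, generate_video

    video = generate_video(SynthConfig(frame_height=32, frame_width=32,
                                       n_frames=10, n_ants=1,
                                       n_distractors=0, wind_prob=0.0,
                                       seed=21))
    labels = annotate_sequence(
        extract_foreground_fe1(video.frames, T=2.5),
        min_area=3, boundary_radius=1)
    return video.frames.astype(np.float32), labels


def _params(model):
    return [p.value.copy() for p in model.parameters()]


def _same_params(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSingleSource:
    def test_zero_iterations_returns_initialization(self, tiny_data):
        frames, labels = tiny_data
        model = build_model(depth=1, base_channels=4, seed=0)
        init = _params(model)
        cfg = TrainConfig(**{**FAST, "total_iters": 0, "lr_switch_iter": 0})
        model, history = train_single_source(frames, labels, model, cfg)
        assert _same_params(init, _params(model))
        assert history == []

    def test_loss_decreases(self, tiny_data):
        frames, labels = tiny_data
        model = build_model(depth=1, base_channels=4, seed=0)
        cfg = TrainConfig(batch_size=2, crop_size=16, total_iters=120,
                          lr_switch_iter=90, seed=3)
        _, history = train_single_source(frames, labels, model, cfg)
        assert np.mean(history[-20:]) < np.mean(history[:20])

    def test_invalid_label_values_rejected(self, tiny_data):
        frames, labels = tiny_data
        bad = labels.copy()
        bad[0, 0, 0] = 7
        model = build_model(depth=1, base_channels=4, seed=0)
        with pytest.raises(ValueError):
            train_single_source(frames, bad, model,
                                TrainConfig(**FAST))

    def test_deterministic_given_seed(self, tiny_data):
        frames, labels = tiny_data
        outs = []
        for _ in range(2):
            model = build_model(depth=1, base_channels=4, seed=0)
            model, _ = train_single_source(frames, labels, model,
                                           TrainConfig(**FAST, seed=5))
            outs.append(_params(model))
        assert _same_params(*outs)


@pytest.mark.parametrize("n_heads", [1, 2])
def test_one_step_on_fixed_batch_decreases_loss(n_heads, rng):
    """A single small-lr gradient step on a fixed batch lowers the loss
    (the step machinery shared by every trainer)."""
    from antdet._nn import Adam, cross_entropy_loss_grad

    model = build_model(depth=1, base_channels=4, n_heads=n_heads, seed=0)
    xb = rng.random((2, 1, 16, 16)).astype(np.float32)
    ys = [rng.integers(0, 3, (2, 16, 16)) for _ in range(n_heads)]
    adam = Adam(model.parameters(), lr=1e-3)

    def losses():
        scores = model.forward(xb, train=True)
        return [cross_entropy_loss_grad(scores[h], ys[h])
                for h in range(n_heads)]

    before = losses()
    model.zero_grad()
    model.backward([g for _, g in before])
    adam.step()
    after = losses()
    assert sum(l for l, _ in after) < sum(l for l, _ in before)


def test_training_on_clean_labels_reaches_high_f1():
    """A detector trained on clean rasterized ground-truth labels of a
    clip detects held-out frames of the same generative process at
    F1 >= 0.9."""
    from antdet.evaluation import evaluate_video, labelmap_to_centers
    from antdet.synthetic import (SynthConfig, generate_video,
                                  rasterize_gt_labelmap)

    # no distractor: this checks learning from clean labels, not the
    # disk-vs-ellipse discrimination the noise injectors exist to stress
    video = generate_video(SynthConfig(seed=31, n_distractors=0))
    labels = rasterize_gt_labelmap(video, boundary_radius=2)
    split = 36
    det = PseudoLabelDetector(batch_size=4, crop_size=32, total_iters=600,
                              lr_switch_iter=450,
                              class_weights=(1.0, 5.0, 5.0),
                              random_state=0)
    det.fit(video.frames[:split], labels[:split])
    pred = [labelmap_to_centers(lm, min_area=5)
            for lm in det.predict(video.frames[split:])]
    scores = evaluate_video(video.gt_centers[split:], pred,
                            dist_threshold=5.0)
    assert scores.f1 >= 0.9


class TestSelectionRule:
    def test_hand_softmax(self):
        """d = [0, ln 3] at temperature 1 gives p = [0.75, 0.25]."""
        p = _selection_probs(np.array([[0.0, np.log(3.0)]]), 1.0)
        np.testing.assert_allclose(p, [[0.75, 0.25]], atol=1e-12)

    def test_zero_temperature_limit_is_greedy(self):
        p = _selection_probs(np.array([[0.0, 0.1]]), 1e-6)
        np.testing.assert_allclose(p, [[1.0, 0.0]], atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        d = rng.random((8, 5))
        p = _selection_probs(d, 0.1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestProbabilisticNNFit:
    def test_identical_sources_uniform_selection(self, tiny_data):
        frames, labels = tiny_data
        model = build_model(depth=1, base_channels=4, seed=0)
        sources = [AnnotationSource("a", labels),
                   AnnotationSource("b", labels.copy())]
        _, _, log = train_probabilistic_nn_fit(
            frames, sources, model, TrainConfig(**FAST),
            EnsembleConfig(temperature=0.1, warmup_iters=0))
        for rec in log:
            np.testing.assert_allclose(rec["mean_probs"], [0.5, 0.5],
                                       atol=1e-9)

    def test_k1_reduces_to_single_source(self, tiny_data):
        frames, labels = tiny_data
        cfg = TrainConfig(**FAST, seed=2)

        m_single = build_model(depth=1, base_channels=4, seed=0)
        m_single, _ = train_single_source(frames, labels, m_single, cfg)

        m_prob = build_model(depth=1, base_channels=4, seed=0)
        m_prob, _, _ = train_probabilistic_nn_fit(
            frames, [AnnotationSource("a", labels)], m_prob, cfg,
            EnsembleConfig(warmup_iters=5))

        m_rand = build_model(depth=1, base_channels=4, seed=0)
        m_rand, _, _ = train_random_nn_fit(
            frames, [AnnotationSource("a", labels)], m_rand, cfg,
            switch_iter=10)

        assert _same_params(_params(m_single), _params(m_prob))
        assert _same_params(_params(m_single), _params(m_rand))

    def test_mismatched_sources_rejected(self, tiny_data):
        frames, labels = tiny_data
        model = build_model(depth=1, base_channels=4, seed=0)
        with pytest.raises(ValueError):
            train_probabilistic_nn_fit(
                frames, [AnnotationSource("a", labels),
                         AnnotationSource("b", labels[:4])],
                model, TrainConfig(**FAST), EnsembleConfig())


class TestRandomNNFit:
    def test_stage_structure_in_selection_log(self, tiny_data):
        """Uniform probabilities before the switch, one-hot after."""
        frames, labels = tiny_data
        noisy = labels.copy()
        noisy[:, ::3, ::3] = 0
        model = build_model(depth=1, base_channels=4, seed=0)
        _, _, log = train_random_nn_fit(
            frames, [AnnotationSource("a", labels),
                     AnnotationSource("b", noisy)],
            model, TrainConfig(**FAST), switch_iter=15)
        for rec in log[:15]:
            np.testing.assert_allclose(rec["mean_probs"], [0.5, 0.5])
        for rec in log[15:]:
            assert set(np.round(rec["mean_probs"], 6)) <= {0.0, 0.5, 1.0}


class TestHybrid:
    def test_requires_two_heads(self, tiny_data):
        frames, labels = tiny_data
        model = build_model(n_heads=1, depth=1, base_channels=4, seed=0)
        with pytest.raises(ValueError):
            train_hybrid(frames, labels, labels, model, TrainConfig(**FAST))

    def test_empty_human_pool_matches_single_source_on_head1(self, tiny_data):
        """With no human annotations the hybrid trainer degenerates to
        single-source training through head 1: identical trunk and head-1
        parameters, head-2 parameters untouched."""
        frames, labels = tiny_data
        cfg = TrainConfig(**FAST, seed=4)
        m2 = build_model(n_heads=2, depth=1, base_channels=4, seed=0)
        head2_init = [p.value.copy() for p in m2.heads[1].parameters()]
        m2, _, _ = train_hybrid(frames, labels, None, m2, cfg,
                                ha_indices=np.zeros(0, dtype=int))
        assert all(np.array_equal(a, b.value) for a, b in
                   zip(head2_init, m2.heads[1].parameters()))

        m1 = build_model(n_heads=1, depth=1, base_channels=4, seed=0)
        m1, _ = train_single_source(frames, labels, m1, cfg)
        for pa, pb in zip(m1.heads[0].parameters(), m2.heads[0].parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_empty_algorithm_pool_leaves_head1_at_init(self, tiny_data):
        frames, labels = tiny_data
        det = HybridDetector(depth=1, base_channels=4, **FAST,
                             random_state=0)
        det.fit(frames, algorithm_labels=None, human_labels=labels,
                algorithm_indices=np.zeros(0, dtype=int),
                human_indices=np.arange(len(frames)))
        ref = build_model(n_heads=2, depth=1, base_channels=4, seed=0)
        for pa, pb in zip(det.model_.heads[0].parameters(),
                          ref.heads[0].parameters()):
            assert np.array_equal(pa.value, pb.value)
        assert det.effective_fuse_ == "head2"

    def test_symmetric_labels_heads_track_each_other(self, tiny_data):
        """Identical AA and HA labels: both heads' smoothed losses fall
        substantially and end within a bounded gap of each other (the
        heads converge at different rates from their random inits, but
        neither may stall)."""
        frames, labels = tiny_data
        cfg = TrainConfig(batch_size=4, crop_size=16, total_iters=400,
                          lr_switch_iter=300, seed=0)
        model = build_model(n_heads=2, depth=1, base_channels=4, seed=0)
        _, _, head_losses = train_hybrid(frames, labels, labels.copy(),
                                         model, cfg)
        h1 = np.array([a for a, _ in head_losses])
        h2 = np.array([b for _, b in head_losses])
        q = len(h1) // 4
        assert h1[-q:].mean() < 0.6 * h1[:q].mean()
        assert h2[-q:].mean() < 0.6 * h2[:q].mean()
        assert abs(h1[-q:].mean() - h2[-q:].mean()) < 0.5


class TestNetworkSources:
    def test_teacher_argmax_becomes_source(self, tiny_data):
        frames, _ = tiny_data
        t1 = build_model(depth=1, base_channels=4, seed=1)
        t2 = build_model(depth=1, base_channels=4, seed=1)
        s1, s2 = make_network_sources(frames, [t1, t2])
        assert s1.origin == "network"
        assert np.array_equal(s1.labelmaps, s2.labelmaps)
        assert s1.labelmaps.shape == frames.shape

    def test_average_ensemble_single_teacher_is_argmax(self, tiny_data):
        frames, _ = tiny_data
        teacher = build_model(depth=1, base_channels=4, seed=2)
        lm = average_ensemble_predict([teacher], frames[:4])
        probs = predict_proba(teacher, frames[:4])[0]
        assert np.array_equal(lm, np.argmax(probs, axis=-1))

    def test_average_ensemble_identical_teachers(self, tiny_data):
        frames, _ = tiny_data
        t = build_model(depth=1, base_channels=4, seed=2)
        a = average_ensemble_predict([t], frames[:2])
        b = average_ensemble_predict([t, t, t], frames[:2])
        assert np.array_equal(a, b)


class TestRenderHumanAnnotation:
    def test_no_centers_all_background(self):
        lm = render_human_annotation([[]], (16, 16))
        assert (lm == 0).all()

    def test_disk_radius_2_has_13_pixels(self):
        lm = render_human_annotation([[(5.0, 5.0)]], (11, 11),
                                     disk_radius=2, boundary_radius=0)
        assert int((lm[0] == 1).sum()) == 13

    def test_close_centers_merge_into_one_component(self):
        from skimage.measure import label as cc_label

        lm = render_human_annotation([[(5.0, 5.0), (8.0, 5.0)]], (16, 16),
                                     disk_radius=2, boundary_radius=0)
        assert cc_label(lm[0] == 1).max() == 1

    def test_out_of_bounds_center_warns_and_clips(self):
        with pytest.warns(UserWarning):
            lm = render_human_annotation([[(-3.0, 5.0)]], (11, 11),
                                         disk_radius=2)
        assert lm.shape == (1, 11, 11)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        det = PseudoLabelDetector(total_iters=10)
        assert det.get_params()["total_iters"] == 10
        det.set_params(base_channels=4)
        assert det.base_channels == 4

    def test_unfitted_predict_raises(self, tiny_data):
        frames, _ = tiny_data
        with pytest.raises(AttributeError):
            PseudoLabelDetector().predict(frames)

    def test_fit_predict_centers(self, tiny_data):
        frames, labels = tiny_data
        det = PseudoLabelDetector(depth=1, base_channels=4, **FAST,
                                  random_state=0)
        det.fit(frames, labels)
        centers = det.predict_centers(frames[:2], min_area=1)
        assert len(centers) == 2
        for c in centers:
            assert c.ndim == 2 and c.shape[1] == 2

    def test_distiller_selection_log_recorded(self, tiny_data):
        frames, labels = tiny_data
        det = ProbabilisticNNFitDistiller(depth=1, base_channels=4, **FAST,
                                          warmup_iters=5, random_state=0)
        det.fit(frames, [labels, labels.copy()])
        assert len(det.selection_log_) == FAST["total_iters"]

    def test_random_distiller_fit(self, tiny_data):
        frames, labels = tiny_data
        det = RandomNNFitDistiller(depth=1, base_channels=4, **FAST,
                                   switch_iter=10, random_state=0)
        det.fit(frames, [labels, labels.copy()])
        assert det.predict(frames[:2]).shape == (2, 32, 32)
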