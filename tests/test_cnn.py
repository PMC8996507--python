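"""Contrast enumeration, LeNet arithmetic, training and identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingmorph import (CnnSpec, TrainingSchedule, build_cnn,
                       enumerate_contrasts, make_contrast_input)
from wingmorph.cnn import (ContrastCNNClassifier, DegenerateLabelsError,
                           cnn_jackknife, contrast_accuracy, identify, train)


def shade_images(rng, n_per=8, dark=60.0, light=200.0, side=28, noise=5.0):
    imgs = [np.clip(np.full((side, side), dark) + rng.normal(0, noise, (side, side)), 0, 255)
            for _ in range(n_per)]
    imgs += [np.clip(np.full((side, side), light) + rng.normal(0, noise, (side, side)), 0, 255)
             for _ in range(n_per)]
    labels = ["dark"] * n_per + ["light"] * n_per
    return imgs, labels


class TestContrasts:
    def test_count_is_n_times_n_minus_one(self):
        pairs = enumerate_contrasts(["a", "a", "b"])
        assert len(pairs) == 6
        rels = [p.relation for p in pairs]
        assert rels.count("within-group") == 2
        assert rels.count("between-group") == 4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["a", "b"]), min_size=2, max_size=12))
    def test_within_group_count_identity(self, labels):
        pairs = enumerate_contrasts(labels)
        assert len(pairs) == len(labels) * (len(labels) - 1)
        within = sum(p.relation == "within-group" for p in pairs)
        expected = sum(labels.count(g) * (labels.count(g) - 1)
                       for g in set(labels))
        assert within == expected

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            enumerate_contrasts(["a"])

    def test_contrast_input_properties(self, rng):
        a = rng.uniform(0, 255, (28, 28))
        b = rng.uniform(0, 255, (28, 28))
        assert np.all(make_contrast_input(a, a) == 0.0)
        np.testing.assert_allclose(make_contrast_input(a, b),
                                   make_contrast_input(b, a))
        full = make_contrast_input(np.zeros((8, 8)), np.full((8, 8), 255.0))
        np.testing.assert_allclose(full, 1.0)
        with pytest.raises(ValueError):
            make_contrast_input(a, b[:10])


class TestSchedule:
    def test_default_iterations_reconstruct_replicated_consumption(self):
        sched = TrainingSchedule()
        assert sched.resolved_iterations(37671) == int(np.ceil(3 * 37671 / 64))
        assert sched.contrasts_per_epoch(37671) == sched.resolved_iterations(37671) * 64

    def test_explicit_iterations_bookkeeping(self):
        sched = TrainingSchedule(epochs=3, iterations_per_epoch=1767, batch_size=64)
        assert sched.contrasts_per_epoch() == 1767 * 64
        assert sched.total_contrasts() == 3 * 1767 * 64


class TestLeNetArithmetic:
    def test_28_input_shapes(self):
        shapes = CnnSpec(input_side=28).layer_shapes()
        assert shapes == [(1, 28, 28), (10, 25, 25), (10, 25, 25), (10, 12, 12),
                          (20, 9, 9), (20, 9, 9), (20, 4, 4), (320,), (2,), (2,)]

    def test_40_input_shapes(self):
        shapes = CnnSpec(input_side=40).layer_shapes()
        assert (10, 37, 37) in shapes and (10, 18, 18) in shapes
        assert (20, 15, 15) in shapes and (20, 7, 7) in shapes
        assert CnnSpec(input_side=40).flatten_size == 980

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            CnnSpec(input_side=8).layer_shapes()

    def test_seeded_initialization_identical(self):
        a, b = build_cnn(seed=3), build_cnn(seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        c = build_cnn(seed=4)
        assert not np.array_equal(a.W1, c.W1)


class TestTraining:
    def test_separable_classes_classified_perfectly(self, rng):
        imgs, labels = shade_images(rng)
        pairs = enumerate_contrasts(labels)
        sched = TrainingSchedule(epochs=1, iterations_per_epoch=50, seed=1)
        model = train(pairs, imgs, sched)
        assert contrast_accuracy(model, pairs, imgs) == 1.0

    def test_untrained_model_near_chance(self, rng):
        imgs, labels = shade_images(rng, noise=40.0)
        pairs = enumerate_contrasts(labels)
        # balanced subset of contrasts
        within = [p for p in pairs if p.relation == "within-group"]
        between = [p for p in pairs if p.relation == "between-group"]
        balanced = within + between[:len(within)]
        sched = TrainingSchedule(epochs=1, iterations_per_epoch=1, seed=5)
        model = train(pairs, imgs, sched)   # one step ~ untrained
        model.net = type(model.net)(model.spec, seed=99)   # reset weights
        acc = contrast_accuracy(model, balanced, imgs)
        assert acc == pytest.approx(0.5, abs=0.25)

    def test_same_seed_identical_loss_trace(self, rng):
        imgs, labels = shade_images(rng, n_per=4)
        pairs = enumerate_contrasts(labels)
        sched = TrainingSchedule(epochs=2, iterations_per_epoch=10, seed=7)
        t1 = train(pairs, imgs, sched).loss_trace
        t2 = train(pairs, imgs, sched).loss_trace
        assert t1 == t2

    def test_one_relation_class_missing_rejected(self, rng):
        imgs, _ = shade_images(rng, n_per=3)
        pairs = enumerate_contrasts(["same"] * 6)
        sched = TrainingSchedule(epochs=1, iterations_per_epoch=2)
        with pytest.raises(DegenerateLabelsError):
            train(pairs, imgs[:6], sched)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    imgs, labels = shade_images(rng)
    pairs = enumerate_contrasts(labels)
    model = train(pairs, imgs,
                  TrainingSchedule(epochs=1, iterations_per_epoch=50, seed=2))
    return model, imgs, labels


class TestIdentify:
    def test_query_matching_reference_identified(self, trained):
        model, imgs, labels = trained
        group, score = identify(model, imgs[0], imgs[1:], labels[1:])
        assert group == "dark" and score > 0

    def test_score_antisymmetric_under_group_swap(self, trained):
        model, imgs, labels = trained
        swapped = ["light" if l == "dark" else "dark" for l in labels[1:]]
        _, s1 = identify(model, imgs[0], imgs[1:], labels[1:])
        _, s2 = identify(model, imgs[0], imgs[1:], swapped)
        assert s1 == pytest.approx(-s2)

    def test_empty_reference_group_rejected(self, trained):
        model, imgs, _ = trained
        with pytest.raises(ValueError):
            identify(model, imgs[0], imgs[1:4], ["dark"] * 3)


class TestJackknife:
    def test_separable_classes_perfect_and_deterministic(self, rng):
        imgs, labels = shade_images(rng, n_per=5)
        sched = TrainingSchedule(epochs=1, iterations_per_epoch=25, seed=3)
        a = cnn_jackknife(imgs, labels, sched, n_targets=4, seed=9)
        b = cnn_jackknife(imgs, labels, sched, n_targets=4, seed=9)
        assert a.accuracy == 1.0
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_too_many_targets_rejected(self, rng):
        imgs, labels = shade_images(rng, n_per=2)
        with pytest.raises(ValueError):
            cnn_jackknife(imgs, labels, TrainingSchedule(), n_targets=10, seed=0)


class TestEstimator:
    def test_fit_predict_on_separable_images(self, rng):
        imgs, labels = shade_images(rng, n_per=5)
        clf = ContrastCNNClassifier(epochs=1, iterations_per_epoch=30, seed=0)
        clf.fit(imgs, labels)
        assert list(clf.predict(imgs[:4])) == labels[:4]
        assert clf.get_params()["epochs"] == 1
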