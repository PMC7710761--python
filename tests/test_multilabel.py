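"""Multilabel decoders: class groupings, feature geometry, decoding sanity."""

import numpy as np
import pytest

from mlcsp.core import ALL_LABELS, REST, BodyPart, label_by_name
from mlcsp.csp import trial_covariances
from mlcsp.evaluation import accuracy
from mlcsp.multilabel import (
    BinaryProblem,
    fit_mc2cmi,
    fit_mc2smi,
    mc2cmi_problems,
    mc2smi_problems,
    predict,
    transform,
)

L = label_by_name


class TestProblemGroupings:
    def test_mc2cmi_groupings_match_published_lists(self):
        expected = {
            BodyPart.LEFT_HAND: (
                {"left hand", "left hand and feet", "both hands", "both hands and feet"},
                {"rest", "feet", "right hand", "right hand and feet"},
            ),
            BodyPart.FEET: (
                {"feet", "left hand and feet", "right hand and feet", "both hands and feet"},
                {"rest", "left hand", "right hand", "both hands"},
            ),
            BodyPart.RIGHT_HAND: (
                {"right hand", "both hands", "right hand and feet", "both hands and feet"},
                {"rest", "left hand", "feet", "left hand and feet"},
            ),
        }
        problems = mc2cmi_problems()
        assert len(problems) == 3
        for problem in problems:
            c1, c2 = expected[problem.part]
            assert {lab.name for lab in problem.class1_labels} == c1
            assert {lab.name for lab in problem.class2_labels} == c2
            # partition of all 8 classes, 4 vs 4, rest always in class 2
            assert problem.class1_labels | problem.class2_labels == set(ALL_LABELS)
            assert len(problem.class1_labels) == len(problem.class2_labels) == 4
            assert REST in problem.class2_labels

    def test_mc2smi_groupings_are_single_mi_vs_rest(self):
        problems = mc2smi_problems()
        singles = set()
        for problem in problems:
            assert problem.class2_labels == frozenset({REST})
            (single,) = problem.class1_labels
            singles.add(single)
        assert singles == {L("left hand"), L("feet"), L("right hand")}

    def test_overlapping_groupings_rejected(self):
        with pytest.raises(ValueError):
            BinaryProblem(
                BodyPart.FEET, frozenset({REST, L("feet")}), frozenset({REST})
            )


class TestFitTransform:
    def test_mc2cmi_structure_and_feature_geometry(self, small_session):
        decoder = fit_mc2cmi(small_session)
        assert len(decoder.models) == 3
        assert decoder.n_features == 18
        X = transform(decoder, small_session)
        assert X.shape == (small_session.n_trials, 18)
        # each 6-dim module block independently satisfies sum(exp(v)) = 1
        for block in range(3):
            sums = np.exp(X[:, 6 * block : 6 * block + 6]).sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_transform_blocks_equal_per_module_features(self, small_session):
        from mlcsp.csp import features_from_covariances, select_filters

        decoder = fit_mc2cmi(small_session)
        covs = trial_covariances(small_session.data)
        X = transform(decoder, small_session, covs=covs)
        for p, model in enumerate(decoder.models):
            block = features_from_covariances(select_filters(model, decoder.m), covs)
            np.testing.assert_allclose(X[:, 6 * p : 6 * p + 6], block)

    def test_training_accuracy_high_on_clean_data(self, clean_session):
        decoder = fit_mc2cmi(clean_session)
        pred, _ = predict(decoder, clean_session)
        assert accuracy(pred, clean_session.class_indices) >= 95.0

    def test_missing_class_rejected(self, small_session):
        keep = [i for i, lab in enumerate(small_session.labels) if lab.class_index != 3]
        with pytest.raises(ValueError, match="left hand and feet"):
            fit_mc2cmi(small_session.subset(keep))

    def test_channel_mismatch_rejected(self, small_session):
        from mlcsp.core import EpochSet

        decoder = fit_mc2cmi(small_session)
        bad = EpochSet(
            data=small_session.data[:, :20, :],
            labels=list(small_session.labels),
            sampling_rate=small_session.sampling_rate,
        )
        with pytest.raises(ValueError):
            transform(decoder, bad)


class TestMC2SMI:
    def test_fit_uses_only_single_mi_and_rest(self, small_session):
        """Dropping every combined-MI trial does not change the fitted decoder."""
        singles = {0, 1, 2, 4}
        keep = [
            i for i, lab in enumerate(small_session.labels) if lab.class_index in singles
        ]
        full = fit_mc2smi(small_session, seed=1)
        reduced = fit_mc2smi(small_session.subset(keep), seed=1)
        for a, b in zip(full.models, reduced.models):
            np.testing.assert_allclose(a.W, b.W)
        np.testing.assert_allclose(full.lda.means, reduced.lda.means)

    def test_synthesized_rest_blocks_come_from_rest_trials(self, small_session):
        """Every synthesized 18-dim vector is assembled from existing donor blocks."""
        from mlcsp.csp import features_from_covariances, select_filters

        decoder = fit_mc2smi(small_session, seed=2)
        covs = trial_covariances(small_session.data)
        y = small_session.class_indices
        # reconstruct donor feature pools per module
        for p, model in enumerate(decoder.models):
            feats = features_from_covariances(select_filters(model, 3), covs)
            rest_pool = feats[y == 0]
            single_pool = feats[y == (1 << p)]
            # LDA class means of rest (class 0) must lie in the convex hull of
            # rest donors only: check the mean matches a mean of rest donors
            block_mean = decoder.lda.means[0, 6 * p : 6 * p + 6]
            dist_rest = np.abs(block_mean - rest_pool.mean(axis=0)).max()
            dist_single = np.abs(block_mean - single_pool.mean(axis=0)).max()
            assert dist_rest < dist_single

    def test_missing_rest_rejected(self, small_session):
        keep = [i for i, lab in enumerate(small_session.labels) if not lab.is_rest]
        with pytest.raises(ValueError, match="rest"):
            fit_mc2smi(small_session.subset(keep))

    def test_smi_approaches_cmi_on_clean_superposition_data(self, clean_session):
        """With no surround ERS and high SNR, single-MI training suffices."""
        y = clean_session.class_indices
        rng = np.random.default_rng(0)
        test_idx = np.concatenate(
            [rng.permutation(np.flatnonzero(y == c))[:3] for c in range(8)]
        )
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        train, test = clean_session.subset(train_idx), clean_session.subset(test_idx)
        acc_cmi = accuracy(predict(fit_mc2cmi(train), test)[0], y[test_idx])
        acc_smi = accuracy(predict(fit_mc2smi(train, seed=0), test)[0], y[test_idx])
        assert acc_smi >= acc_cmi - 15.0


class TestPredict:
    def test_posterior_rows_sum_to_one(self, small_session):
        decoder = fit_mc2cmi(small_session)
        _, scores = predict(decoder, small_session)
        assert scores.shape == (small_session.n_trials, 8)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_give_chance_accuracy(self, small_session):
        """Permutation control: decoding shuffled labels stays near 12.5%."""
        rng = np.random.default_rng(6)
        perm = rng.permutation(small_session.n_trials)
        shuffled = small_session.with_data(small_session.data)
        shuffled.labels = [small_session.labels[i] for i in perm]
        # train on permuted labels (class counts intact), score vs true labels
        decoder = fit_mc2cmi(shuffled)
        pred, _ = predict(decoder, small_session)
        acc = accuracy(pred, small_session.class_indices)
        assert acc < 30.0  # well below genuine decoding, near 8-class chance
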