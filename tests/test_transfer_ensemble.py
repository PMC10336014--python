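"""Pre-training, fine-tuning, ensembling and uncertainty maps."""

import numpy as np
import pytest

from liver4d.core_io import minutes_to_pairs
from liver4d.network import ArchConfig, TrainConfig
from liver4d.phantom import AnatomyParams, make_subject
from liver4d.transfer_ensemble import (
    Ensemble,
    budget_samples,
    ensemble_predict,
    finetune,
    pretrain,
    train_direct,
    uncertainty_map,
)

ARCH = ArchConfig(in_shape=(32, 32, 3), base_filters=2, dropout_rate=0.0)
FAST = TrainConfig(learning_rate=2e-3, epochs=2, batch_size=16, seed=0)


@pytest.fixture(scope="module")
def two_subjects():
    p = AnatomyParams(liver_extent_mm=(30.0, 26.0, 32.0), max_si_excursion_mm=10.0)
    return (
        make_subject(p, seed=10, grid=32, subject_id="S00"),
        make_subject(p, seed=11, grid=32, subject_id="T00"),
    )


@pytest.fixture(scope="module")
def pretrained(two_subjects):
    src, _ = two_subjects
    return pretrain([src], 0.25, 2, [0, 1], FAST, ARCH)


class TestBudgets:
    def test_budget_sample_counts(self, two_subjects):
        src, _ = two_subjects
        tr, va, _ = budget_samples(src, 0.5, seed=0)
        assert len(tr) + len(va) == minutes_to_pairs(0.5) == 90

    def test_pretrain_pool_counts(self, two_subjects):
        # j minutes over k subjects pools k * minutes_to_pairs(j) pairs
        assert minutes_to_pairs(2) * 16 == 5760


class TestPretrainFinetune:
    def test_members_independent_inits(self, pretrained):
        a, b = pretrained
        assert a.provenance["family"] == "pre"
        assert a.provenance["seed"] != b.provenance["seed"]
        assert any(
            not np.array_equal(wa, wb)
            for wa, wb in zip(a.net.get_weights(), b.net.get_weights())
        )

    def test_zero_epoch_finetune_is_identity(self, pretrained, two_subjects):
        _, tgt = two_subjects
        from dataclasses import replace

        ft = finetune(pretrained[0], tgt, 0.25, replace(FAST, epochs=0))
        for wa, wb in zip(ft.net.get_weights(), pretrained[0].net.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        assert ft.provenance["family"] == "pre+TL"

    def test_finetune_recomputes_target_norm(self, pretrained, two_subjects):
        _, tgt = two_subjects
        ft = finetune(pretrained[0], tgt, 0.25, FAST)
        assert ft.norm.subject_id == "T00"
        assert pretrained[0].norm.subject_id == "pooled"

    def test_direct_provenance_and_determinism(self, two_subjects):
        _, tgt = two_subjects
        a = train_direct(tgt, 0.25, FAST, ARCH, seed=3)
        b = train_direct(tgt, 0.25, FAST, ARCH, seed=3)
        assert a.provenance["family"] == "direct"
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)


class TestEnsemble:
    def _stacks(self, rng):
        return rng.normal(size=(1, 3, 32, 32))

    def test_duplicated_members_mean_equals_single(self, pretrained):
        rng = np.random.default_rng(0)
        m = pretrained[0]
        ens = Ensemble(members=[m, m, m])
        stacks = self._stacks(rng)
        mean, members = ensemble_predict(ens, stacks)
        np.testing.assert_allclose(mean, members[0])

    def test_single_member_equivalence(self, pretrained):
        rng = np.random.default_rng(0)
        stacks = self._stacks(rng)
        mean, _ = ensemble_predict(Ensemble(members=[pretrained[0]]), stacks)
        solo = pretrained[0].predict(stacks) * pretrained[0].norm.std + pretrained[0].norm.mean
        np.testing.assert_allclose(mean, solo)

    def test_mean_permutation_invariant(self, pretrained):
        rng = np.random.default_rng(1)
        stacks = self._stacks(rng)
        m1, _ = ensemble_predict(Ensemble(members=list(pretrained)), stacks)
        m2, _ = ensemble_predict(Ensemble(members=list(pretrained[::-1])), stacks)
        np.testing.assert_allclose(m1, m2)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            Ensemble(members=[])


class TestUncertaintyMap:
    def test_identical_members_zero_map(self):
        pred = np.full((4, 4), 3.0)
        m = uncertainty_map(np.stack([pred, pred, pred]))
        np.testing.assert_array_equal(m.values, 0.0)

    def test_hand_cov(self):
        m = uncertainty_map(np.array([[[1.0]], [[3.0]]]))
        assert np.isclose(m.values[0, 0], 0.5)  # std 1, mean 2 (population)

    def test_sample_std_flag(self):
        m = uncertainty_map(np.array([[[1.0]], [[3.0]]]), sample_std=True)
        assert np.isclose(m.values[0, 0], np.sqrt(2.0) / 2.0)

    def test_epsilon_guard_flags_degenerate_mean(self):
        m = uncertainty_map(np.array([[[-1.0]], [[1.0]]]))
        assert m.guarded[0, 0]
        assert m.values[0, 0] == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            uncertainty_map(np.ones((1, 2, 2)))

    def test_nonnegative_and_scale_free(self):
        rng = np.random.default_rng(2)
        preds = rng.normal(5.0, 1.0, size=(4, 6, 6))
        a = uncertainty_map(preds)
        b = uncertainty_map(3.0 * preds)
        assert np.all(a.values >= 0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)


def test_finetune_rejects_architecture_mismatch(pretrained):
    big = make_subject(AnatomyParams(), seed=20, grid=64, subject_id="T99")
    with pytest.raises(ValueError, match="architecture mismatch"):
        finetune(pretrained[0], big, 0.25, FAST)
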