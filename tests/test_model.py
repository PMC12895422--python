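"""Training protocol, transfer learning, prediction contracts."""

import numpy as np
import pytest

from molorbimage import (ExcitationImageModel, FixtureSpec, RVGGParams,
                         SplitSpec, TrainingConfig, build_model,
                         generate_fixtures, transfer_learn)
from tests.test_nn import _simulate_schedule


class TestTrainingProtocol:
    def test_memorizes_small_fixture(self, trained_results, fixture_dataset):
        """Capacity sanity: training RMSE < 0.02 eV on 16 images."""
        _, ds = fixture_dataset
        pred = trained_results.predict(ds)
        rmse = float(np.sqrt(np.mean((pred - ds.targets) ** 2)))
        assert rmse < 0.02

    def test_lr_history_obeys_schedule_exactly(self, trained_results):
        h = trained_results.history
        expected = _simulate_schedule(h["val_loss"],
                                      trained_results.lr_init_used)
        assert h["lr"] == expected

    def test_history_lengths_consistent(self, trained_results):
        h = trained_results.history
        assert len(h["train_loss"]) == len(h["val_loss"]) == len(h["lr"])

    def test_seeded_reproducibility(self, fixture_dataset):
        _, ds = fixture_dataset
        cfg = TrainingConfig(batch_size=16, max_epochs=20, seed=11,
                             split=(0.75, 0.25, 0.0))
        r1 = ExcitationImageModel(ds, RVGGParams(((1, 4),), (8,)), cfg).fit()
        r2 = ExcitationImageModel(ds, RVGGParams(((1, 4),), (8,)), cfg).fit()
        assert r1.history["val_loss"] == r2.history["val_loss"]

    def test_gap_loss_weight_changes_training(self, fixture_dataset):
        _, ds = fixture_dataset
        base = dict(batch_size=16, max_epochs=15, seed=5, split=(1.0, 0.0, 0.0))
        arch = RVGGParams(((1, 4),), (8,))
        r0 = ExcitationImageModel(
            ds, arch, TrainingConfig(gap_loss_weight=0.0, **base)).fit()
        r20 = ExcitationImageModel(
            ds, arch, TrainingConfig(gap_loss_weight=20.0, **base)).fit()
        p0 = r0.predict(ds)
        p20 = r20.predict(ds)
        assert not np.allclose(p0, p20)

    def test_dataset_without_targets_rejected(self, fixture_dataset):
        from molorbimage import ImageDataset
        _, ds = fixture_dataset
        with pytest.raises(ValueError, match="target"):
            ExcitationImageModel(ImageDataset(images=ds.images))


@pytest.fixture(scope="module")
def related_sets():
    """Two fixture sets sharing the target-generating function."""
    _, a = generate_fixtures(FixtureSpec(n_molecules=24, seed=21))
    _, b = generate_fixtures(FixtureSpec(n_molecules=16, seed=22))
    return a, b


@pytest.fixture(scope="module")
def pretrained(related_sets):
    a, _ = related_sets
    cfg = TrainingConfig(batch_size=24, max_epochs=300, seed=1,
                         split=(1.0, 0.0, 0.0))
    return ExcitationImageModel(a, config=cfg).fit()


class TestTransferLearning:
    def test_transfer_starts_below_random_init(self, related_sets, pretrained):
        """Initial loss on a related set beats random init in >= 8/10 seeds."""
        _, b = related_sets
        xb, yb = b.pixel_array(), b.targets
        pre_rmse = float(np.sqrt(np.mean((pretrained.predict(b) - yb) ** 2)))
        wins = 0
        for seed in range(10):
            net = build_model(pretrained.model.arch, b.n_mo, seed=seed)
            rand = net.forward(xb, training=False)
            rand_rmse = float(np.sqrt(np.mean((rand - yb) ** 2)))
            wins += pre_rmse < rand_rmse
        assert wins >= 8

    def test_finetune_runs_at_lr_1e4_by_default(self, related_sets,
                                                pretrained):
        _, b = related_sets
        cfg = TrainingConfig(batch_size=16, max_epochs=5, seed=2,
                             split=(1.0, 0.0, 0.0))
        res = transfer_learn(pretrained, b, cfg)
        assert res.transferred
        assert res.lr_init_used == 1e-4
        assert res.history["lr"][0] == 1e-4

    def test_zero_epoch_transfer_is_identity(self, related_sets, pretrained):
        _, b = related_sets
        cfg = TrainingConfig(batch_size=16, seed=2, split=(1.0, 0.0, 0.0))
        res = transfer_learn(pretrained, b, cfg, max_epochs=0)
        for s0, s1 in zip(res.net_state, pretrained.net_state):
            for k in s0:
                np.testing.assert_array_equal(s0[k], s1[k])


class TestPrediction:
    def test_output_shape_and_order(self, trained_results, fixture_dataset):
        _, ds = fixture_dataset
        pred = trained_results.predict(ds)
        assert pred.shape == (len(ds), 6)

    def test_batch_composition_invariance(self, trained_results,
                                          fixture_dataset):
        _, ds = fixture_dataset
        x = ds.pixel_array()
        full = trained_results.predict(x)
        one = trained_results.predict(x[4])
        np.testing.assert_allclose(one[0], full[4], atol=1e-6)
        perm = np.random.default_rng(0).permutation(len(x))
        np.testing.assert_allclose(trained_results.predict(x[perm]),
                                   full[perm], atol=1e-12)

    def test_checkpoint_roundtrip(self, trained_results, fixture_dataset,
                                  tmp_path):
        from molorbimage import ExcitationImageResults
        _, ds = fixture_dataset
        path = tmp_path / "ckpt.h5"
        trained_results.save(path)
        net, arch, n_mo = ExcitationImageResults.load_network(path)
        assert n_mo == ds.n_mo
        x = ds.pixel_array()
        np.testing.assert_allclose(net.forward(x, training=False),
                                   trained_results.predict(x), atol=1e-12)

    def test_summary_mentions_key_quantities(self, trained_results):
        text = trained_results.summary()
        assert "parameters" in text and "RMSE" in text


class TestSplits:
    def test_partition_is_disjoint_and_exhaustive(self):
        spec = SplitSpec(10, 3, 4, seed=5)
        tr, va, te = spec.indices()
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx.tolist()) == list(range(17))
        assert (len(tr), len(va), len(te)) == (10, 3, 4)

    def test_default_fractions_match_reference_ratios(self):
        spec = SplitSpec.from_fractions(40000, (0.8, 0.08, 0.12), seed=0)
        assert (spec.n_train, spec.n_val, spec.n_test) == (32000, 3200, 4800)
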